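"""Synthetic 0 Mg²⁺-style LFP and cell-attached traces with known ground truth.

The generator emulates the statistical structure of evolving epileptiform
activity in acute brain slices: a quiet baseline epoch, then short
(<1 s) interictal-type discharges whose rate settles over the first ~20
events and whose band power escalates toward the first seizure-like
event (SLE), one or more long (>10 s) rhythmic SLEs, and optional
post-SLE interictal discharges.  Two stock parameterizations emulate the
wild-type-like cohort (few, rapidly intensifying preictal discharges)
and the knockout-like cohort (many discharges with compressed γ
escalation and a late first SLE).

Discharges are sums of band-limited tones under raised-cosine-edged
envelopes: the simplest waveform whose per-band power is directly
controllable, which is all the downstream analysis measures.  Background
noise is pink (1/f^α, synthesized by spectral shaping of white noise)
plus white noise plus an optional 50 Hz mains sinusoid.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .recording import Recording

__all__ = [
    "NoiseModel",
    "DischargeModel",
    "IEIModel",
    "SLEModel",
    "FiringModel",
    "SynthConfig",
    "GroundTruth",
    "SchedulingError",
    "generate_recording",
    "generate_cohort",
    "generate_spike_trace",
    "default_wt_config",
    "default_ko_config",
    "reduced_wt_config",
    "reduced_ko_config",
    "match_events",
]

#: Representative synthesis frequency (Hz) for each conventional LFP band.
#: The γ tone sits at 60 Hz, safely outside the 48–52 Hz mains-omission band.
BAND_SYNTH_FREQS: Dict[str, float] = {
    "delta": 2.5,
    "theta": 6.0,
    "alpha": 10.0,
    "beta": 20.0,
    "gamma": 60.0,
    "high_gamma": 110.0,
}

#: Duration above which an event counts as seizure-like.
SLE_THRESHOLD_S = 10.0


class SchedulingError(ValueError):
    """The configured event schedule does not fit in the recording."""


@dataclass(frozen=True)
class NoiseModel:
    """Background noise: pink + white + optional 50 Hz mains line."""

    pink_exponent: float = 1.0  # spectral slope of log-power vs log-freq
    pink_sd_uV: float = 8.0
    white_sd_uV: float = 4.0
    line_50hz_amplitude_uV: float = 2.0

    def __post_init__(self) -> None:
        if not (0 <= self.pink_exponent <= 2):
            raise ValueError("pink_exponent must lie in [0, 2]")
        for name in ("pink_sd_uV", "white_sd_uV", "line_50hz_amplitude_uV"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def baseline_sd_uV(self) -> float:
        return math.hypot(self.pink_sd_uV, self.white_sd_uV)


@dataclass(frozen=True)
class DischargeModel:
    """Short pathological discharges preceding (and following) the SLEs.

    Durations are log-normal with median ``exp(duration_lognorm_mu)``
    constrained below 1 s.  Band amplitudes escalate multiplicatively per
    event up to the first SLE: every band grows at
    ``common_escalation_rate`` and the γ/high-γ bands additionally at
    ``gamma_escalation_rate`` (the genotype-differing knob), each gain
    capped at ``escalation_gain_max``.
    """

    n_preictal: int = 15
    duration_lognorm_mu: float = math.log(0.35)
    duration_lognorm_sigma: float = 0.35
    band_amplitudes_uV: Dict[str, float] = field(
        default_factory=lambda: {
            "delta": 60.0,
            "theta": 30.0,
            "alpha": 25.0,
            "beta": 25.0,
            "gamma": 40.0,
            "high_gamma": 20.0,
        }
    )
    gamma_escalation_rate: float = 0.12
    common_escalation_rate: float = 0.04
    escalation_gain_max: float = 6.0
    n_preictal_jitter_rel_sd: float = 0.0  # log-normal jitter of the count

    def __post_init__(self) -> None:
        if self.n_preictal < 0:
            raise ValueError("n_preictal must be nonnegative")
        if math.exp(self.duration_lognorm_mu) >= 1.0:
            raise ValueError("median discharge duration must be below 1 s")
        if self.gamma_escalation_rate < 0 or self.common_escalation_rate < 0:
            raise ValueError("escalation rates must be nonnegative")
        unknown = set(self.band_amplitudes_uV) - set(BAND_SYNTH_FREQS)
        if unknown:
            raise ValueError(f"unknown bands: {sorted(unknown)}")


@dataclass(frozen=True)
class IEIModel:
    """Inter-event interval settling: exponential decay with event number.

    ``iei(k) = settled + (initial − settled) · exp(−k / settling_constant)``
    for the interval preceding event ``k`` (k = 0 is the first discharge,
    whose delay is measured from the solution switch).
    """

    initial_iei_s: float = 120.0
    settled_iei_s: float = 25.0
    settling_constant_events: float = 7.0
    jitter_rel_sd: float = 0.2  # log-normal multiplicative jitter

    def __post_init__(self) -> None:
        if min(self.initial_iei_s, self.settled_iei_s) <= 0:
            raise ValueError("IEIs must be positive")
        if self.settling_constant_events <= 0:
            raise ValueError("settling_constant_events must be positive")

    def iei_s(self, k: int) -> float:
        return self.settled_iei_s + (
            self.initial_iei_s - self.settled_iei_s
        ) * math.exp(-k / self.settling_constant_events)


@dataclass(frozen=True)
class SLEModel:
    """Seizure-like events: sustained rhythmic discharge trains (>10 s)."""

    duration_s: float = 20.0
    rhythm_hz: float = 3.0
    amplitude_uV: float = 250.0

    def __post_init__(self) -> None:
        if self.duration_s <= SLE_THRESHOLD_S:
            raise ValueError("SLE duration must exceed 10 s")
        if not (1.0 <= self.rhythm_hz <= 20.0):
            raise ValueError("rhythm_hz must lie in [1, 20]")
        if self.amplitude_uV <= 0:
            raise ValueError("amplitude_uV must be positive")


@dataclass(frozen=True)
class FiringModel:
    """Cell-attached firing during discharges."""

    aps_per_event: int = 10
    max_rate_hz: float = 100.0
    halfwidth_ms: float = 0.5
    amplitude_uV: float = 60.0
    noise_sd_uV: float = 2.0

    def __post_init__(self) -> None:
        if self.aps_per_event < 0:
            raise ValueError("aps_per_event must be nonnegative")
        if self.max_rate_hz <= 0 or self.halfwidth_ms <= 0:
            raise ValueError("max_rate_hz and halfwidth_ms must be positive")


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterization of one synthetic recording."""

    sample_rate_hz: float = 10_000.0
    total_duration_s: float = 3600.0
    baseline_duration_s: float = 30.0
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    discharge_model: DischargeModel = field(default_factory=DischargeModel)
    iei_model: IEIModel = field(default_factory=IEIModel)
    sle_model: SLEModel = field(default_factory=SLEModel)
    n_sles: int = 2
    n_interictal: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0 or self.total_duration_s <= 0:
            raise ValueError("rates and durations must be positive")
        if self.baseline_duration_s < 10.0:
            raise ValueError("baseline_duration_s must be at least 10 s")
        if self.n_sles < 0 or self.n_interictal < 0:
            raise ValueError("event counts must be nonnegative")

    @property
    def t0_solution_switch_s(self) -> float:
        """The 0 Mg²⁺ solution switch: end of the baseline epoch."""
        return self.baseline_duration_s


@dataclass
class GroundTruth:
    """The injected event schedule of one synthetic recording."""

    event_onsets_s: np.ndarray
    event_offsets_s: np.ndarray
    event_classes: List[str]
    per_event_band_amplitudes: List[Dict[str, float]]
    spike_times_s: Optional[np.ndarray] = None
    t0_solution_switch_s: float = 0.0

    def __post_init__(self) -> None:
        on = np.asarray(self.event_onsets_s, dtype=float)
        off = np.asarray(self.event_offsets_s, dtype=float)
        if on.size and np.any(np.diff(on) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(off <= on):
            raise ValueError("offsets must follow onsets")
        self.event_onsets_s = on
        self.event_offsets_s = off
        self._check_class_sequence()

    def _check_class_sequence(self) -> None:
        seen_sle = False
        for c in self.event_classes:
            if c == "SLE":
                seen_sle = True
            elif c == "interictal" and not seen_sle:
                raise ValueError("interictal label before the first SLE")
            elif c == "preictal" and seen_sle:
                raise ValueError("preictal label after the first SLE")

    @property
    def n_events(self) -> int:
        return self.event_onsets_s.size

    @property
    def durations_s(self) -> np.ndarray:
        return self.event_offsets_s - self.event_onsets_s

    @property
    def first_sle_onset_s(self) -> Optional[float]:
        for onset, c in zip(self.event_onsets_s, self.event_classes):
            if c == "SLE":
                return float(onset)
        return None


# ---------------------------------------------------------------------------
# noise synthesis


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f^exponent noise by spectral shaping of white noise."""
    if n == 0:
        return np.zeros(0)
    white = rng.standard_normal(n)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _render_noise(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    n = int(round(cfg.total_duration_s * cfg.sample_rate_hz))
    nm = cfg.noise_model
    out = np.zeros(n)
    if nm.pink_sd_uV > 0:
        out += nm.pink_sd_uV * _pink_noise(n, nm.pink_exponent, rng)
    if nm.white_sd_uV > 0:
        out += nm.white_sd_uV * rng.standard_normal(n)
    if nm.line_50hz_amplitude_uV > 0:
        t = np.arange(n) / cfg.sample_rate_hz
        phase = rng.uniform(0, 2 * np.pi)
        out += nm.line_50hz_amplitude_uV * np.sin(2 * np.pi * 50.0 * t + phase)
    return out


# ---------------------------------------------------------------------------
# event waveforms


def _edge_envelope(n: int, fs: float, ramp_s: float) -> np.ndarray:
    """Flat envelope with raised-cosine on/off ramps of ``ramp_s`` seconds."""
    env = np.ones(n)
    r = min(int(round(ramp_s * fs)), n // 2)
    if r > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = ramp
        env[-r:] = ramp[::-1]
    return env


def _render_discharge(
    duration_s: float,
    fs: float,
    band_amplitudes: Dict[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    n = max(int(round(duration_s * fs)), 4)
    t = np.arange(n) / fs
    env = _edge_envelope(n, fs, ramp_s=min(0.05, duration_s / 4))
    x = np.zeros(n)
    for band, amp in band_amplitudes.items():
        if amp <= 0:
            continue
        f = BAND_SYNTH_FREQS[band]
        phase = rng.uniform(0, 2 * np.pi)
        x += amp * np.sin(2 * np.pi * f * t + phase)
    return x * env


def _render_sle(
    duration_s: float, fs: float, rhythm_hz: float, amplitude_uV: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sustained rhythmic discharge train.

    A mixed-band carrier is amplitude-modulated at the SLE rhythm; the
    modulation floor keeps every analysis bin suprathreshold so the SLE
    segments as one continuous event.
    """
    n = max(int(round(duration_s * fs)), 4)
    t = np.arange(n) / fs
    ph = rng.uniform(0, 2 * np.pi, size=4)
    carrier = (
        np.sin(2 * np.pi * 15.0 * t + ph[0])
        + 0.6 * np.sin(2 * np.pi * 60.0 * t + ph[1])
        + 0.5 * np.sin(2 * np.pi * 6.0 * t + ph[2])
    )
    mod = 0.6 + 0.4 * np.sin(2 * np.pi * rhythm_hz * t + ph[3])
    env = _edge_envelope(n, fs, ramp_s=0.05)
    return amplitude_uV * mod * carrier * env


# ---------------------------------------------------------------------------
# scheduling


def _escalation_gains(dm: DischargeModel, k: int) -> Dict[str, float]:
    """Per-band multiplicative gain for preictal event index ``k``."""
    cap = dm.escalation_gain_max
    g_common = min((1.0 + dm.common_escalation_rate) ** k, cap)
    g_gamma = min((1.0 + dm.gamma_escalation_rate) ** k, cap)
    gains = {}
    for band, amp in dm.band_amplitudes_uV.items():
        g = g_common * (g_gamma if band in ("gamma", "high_gamma") else 1.0)
        gains[band] = amp * g
    return gains


def _draw_duration(dm: DischargeModel, rng: np.random.Generator) -> float:
    d = float(rng.lognormal(dm.duration_lognorm_mu, dm.duration_lognorm_sigma))
    return float(np.clip(d, 0.15, 0.95 * SLE_THRESHOLD_S))


def _build_schedule(
    cfg: SynthConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, List[str], List[Dict[str, float]]]:
    """Lay out onsets/offsets/classes/amplitudes; raise if it overflows."""
    dm, im = cfg.discharge_model, cfg.iei_model
    min_gap = 1.0  # s between consecutive events; avoids merged detections

    n_pre = dm.n_preictal
    if dm.n_preictal_jitter_rel_sd > 0 and n_pre > 0:
        # multiplier clipped to the spread seen across real slices (~0.3-2.3x)
        mult = float(
            np.clip(rng.lognormal(0.0, dm.n_preictal_jitter_rel_sd), 0.3, 2.3)
        )
        n_pre = max(2, int(round(n_pre * mult)))

    onsets: List[float] = []
    offsets: List[float] = []
    classes: List[str] = []
    amps: List[Dict[str, float]] = []

    def jitter() -> float:
        if im.jitter_rel_sd > 0:
            return float(rng.lognormal(0.0, im.jitter_rel_sd))
        return 1.0

    cursor = cfg.t0_solution_switch_s
    # preictal discharges with settling IEI and escalating amplitudes
    for k in range(n_pre):
        iei = im.iei_s(k) * jitter()
        onset = max(cursor + iei, (offsets[-1] + min_gap) if offsets else 0.0)
        dur = _draw_duration(dm, rng)
        onsets.append(onset)
        offsets.append(onset + dur)
        classes.append("preictal")
        amps.append(_escalation_gains(dm, k))
        cursor = onset
    final_gain = _escalation_gains(dm, max(n_pre - 1, 0))

    # seizure-like events, with interictal discharges after the first SLE
    sle_gap = 1.5 * im.settled_iei_s
    for s in range(cfg.n_sles):
        onset = (offsets[-1] + sle_gap * jitter()) if offsets else (
            cursor + im.initial_iei_s
        )
        dur = cfg.sle_model.duration_s * (1.0 + 0.05 * abs(rng.standard_normal()))
        onsets.append(onset)
        offsets.append(onset + dur)
        classes.append("SLE")
        amps.append({"sle_amplitude": cfg.sle_model.amplitude_uV})
        if s == 0:
            for _ in range(cfg.n_interictal):
                iei = im.settled_iei_s * jitter()
                onset = offsets[-1] + max(iei, min_gap)
                dur = _draw_duration(dm, rng)
                onsets.append(onset)
                offsets.append(onset + dur)
                classes.append("interictal")
                amps.append(dict(final_gain))

    if offsets and offsets[-1] + 2.0 > cfg.total_duration_s:
        raise SchedulingError(
            f"schedule ends at {offsets[-1]:.1f} s but the recording is only "
            f"{cfg.total_duration_s:.1f} s long; increase total_duration_s"
        )
    return (
        np.asarray(onsets),
        np.asarray(offsets),
        classes,
        amps,
    )


# ---------------------------------------------------------------------------
# public generators


def generate_recording(cfg: SynthConfig) -> Tuple[Recording, GroundTruth]:
    """Generate one LFP recording plus its ground-truth event schedule.

    The trace is background noise plus the scheduled discharges and SLEs;
    the baseline epoch (first ``baseline_duration_s`` seconds) is event
    free.  Identical ``cfg`` (including its seed) gives bit-identical
    output.
    """
    rng = np.random.default_rng(cfg.seed)
    trace = _render_noise(cfg, rng)
    fs = cfg.sample_rate_hz
    onsets, offsets, classes, amps = _build_schedule(cfg, rng)
    for onset, offset, cls, amp in zip(onsets, offsets, classes, amps):
        i0 = int(round(onset * fs))
        if cls == "SLE":
            wave = _render_sle(
                offset - onset, fs, cfg.sle_model.rhythm_hz,
                cfg.sle_model.amplitude_uV, rng,
            )
        else:
            wave = _render_discharge(offset - onset, fs, amp, rng)
        i1 = min(i0 + wave.size, trace.size)
        trace[i0:i1] += wave[: i1 - i0]
    rec = Recording(
        samples=trace,
        sample_rate_hz=fs,
        channel_role="LFP",
        baseline_window_s=(0.0, cfg.baseline_duration_s),
        id=f"synth-seed{cfg.seed}",
    )
    gt = GroundTruth(
        event_onsets_s=onsets,
        event_offsets_s=offsets,
        event_classes=classes,
        per_event_band_amplitudes=amps,
        t0_solution_switch_s=cfg.t0_solution_switch_s,
    )
    return rec, gt


def generate_cohort(
    config_wt: SynthConfig,
    config_ko: SynthConfig,
    n_wt: int = 6,
    n_ko: int = 10,
    seed: int = 0,
) -> Tuple[List[Tuple[Recording, GroundTruth]], List[Tuple[Recording, GroundTruth]]]:
    """Generate a two-group cohort with per-recording seeds.

    Per-recording seeds are derived deterministically from the cohort
    seed, so recordings are independent given the seed and the whole
    cohort is reproducible bit-for-bit.
    """
    if n_wt < 1 or n_ko < 1:
        raise ValueError("cohort sizes must be at least 1")
    child_seeds = _spawn_seeds(seed, n_wt + n_ko)
    wt, ko = [], []
    for i in range(n_wt):
        cfg = replace(config_wt, seed=child_seeds[i])
        rec, gt = generate_recording(cfg)
        rec.id = f"WT-{i:02d}"
        wt.append((rec, gt))
    for j in range(n_ko):
        cfg = replace(config_ko, seed=child_seeds[n_wt + j])
        rec, gt = generate_recording(cfg)
        rec.id = f"KO-{j:02d}"
        ko.append((rec, gt))
    return wt, ko


def _spawn_seeds(seed: int, n: int) -> List[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def spike_template(halfwidth_ms: float, sample_rate_hz: float) -> np.ndarray:
    """Stereotyped biphasic spike with controlled main-lobe FWHM.

    A positive Gaussian lobe (FWHM = ``halfwidth_ms``) followed by a
    small, wide, delayed undershoot; the undershoot is kept far enough
    from the main lobe that the measured full width at half maximum stays
    within one sample period of the nominal value.
    """
    fs = sample_rate_hz
    if halfwidth_ms / 1000.0 * fs < 4:
        raise ValueError(
            f"halfwidth {halfwidth_ms} ms is unresolvable at {fs} Hz "
            "(need ≥4 samples across the half-width)"
        )
    sigma_s = halfwidth_ms / 1000.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    span = 12.0 * sigma_s
    t = np.arange(-span, span, 1.0 / fs)
    main = np.exp(-(t**2) / (2 * sigma_s**2))
    under = -0.25 * np.exp(-((t - 6 * sigma_s) ** 2) / (2 * (3 * sigma_s) ** 2))
    return main + under


def generate_spike_trace(
    event_schedule: GroundTruth,
    firing_model: FiringModel,
    sample_rate_hz: float,
    seed: int,
    total_duration_s: Optional[float] = None,
) -> Recording:
    """Render a cell-attached trace with spikes inside the event windows.

    Each event window receives ``aps_per_event`` spikes; the first
    inter-spike interval is exactly ``1/max_rate_hz`` (so the scheduled
    within-event maximal rate equals the configured one) and the
    remaining spikes are placed at jittered intervals no shorter than
    that.  The resulting spike times are recorded in
    ``event_schedule.spike_times_s``.
    """
    fm = firing_model
    fs = sample_rate_hz
    template = spike_template(fm.halfwidth_ms, fs)  # validates resolvability
    rng = np.random.default_rng(seed)
    if total_duration_s is None:
        pad = 5.0
        last = (
            float(event_schedule.event_offsets_s[-1])
            if event_schedule.n_events
            else 10.0
        )
        total_duration_s = last + pad
    n = int(round(total_duration_s * fs))
    trace = (
        fm.noise_sd_uV * rng.standard_normal(n) if fm.noise_sd_uV > 0 else np.zeros(n)
    )
    min_isi = 1.0 / fm.max_rate_hz
    spike_times: List[float] = []
    for onset, offset in zip(
        event_schedule.event_onsets_s, event_schedule.event_offsets_s
    ):
        k = fm.aps_per_event
        if k == 0:
            continue
        window = offset - onset
        need = (k - 1) * min_isi
        if need >= window:
            raise SchedulingError(
                f"{k} spikes at max rate {fm.max_rate_hz} Hz need "
                f"{need:.3f} s but the event window is {window:.3f} s"
            )
        t = onset + 0.1 * (window - need) * rng.uniform()
        times = [t]
        for i in range(1, k):
            isi = min_isi if i == 1 else min_isi * (1.0 + rng.uniform(0.0, 1.5))
            t = times[-1] + isi
            times.append(t)
        # rescale the tail if jitter pushed past the window
        if times[-1] > offset:
            scale = (offset - times[0]) / (times[-1] - times[0])
            times = [times[0] + (x - times[0]) * scale for x in times]
        spike_times.extend(times)
    half = template.size // 2
    for t in spike_times:
        i = int(round(t * fs))
        lo, hi = i - half, i - half + template.size
        tlo, thi = max(lo, 0), min(hi, n)
        if tlo < thi:
            trace[tlo:thi] += fm.amplitude_uV * template[tlo - lo : thi - lo]
    event_schedule.spike_times_s = np.asarray(sorted(spike_times))
    return Recording(
        samples=trace,
        sample_rate_hz=fs,
        channel_role="cell_attached",
        baseline_window_s=(0.0, min(10.0, total_duration_s)),
        id="synth-cell-attached",
    )


# ---------------------------------------------------------------------------
# stock configurations


def default_wt_config(seed: int = 0) -> SynthConfig:
    """Wild-type-like study conditions at full scale.

    ~15 preictal discharges per slice with rapid γ escalation and an
    early first SLE, in a one-hour recording sampled at 10 kHz.
    """
    return SynthConfig(
        sample_rate_hz=10_000.0,
        total_duration_s=3600.0,
        baseline_duration_s=30.0,
        discharge_model=DischargeModel(
            n_preictal=15,
            gamma_escalation_rate=0.12,
            common_escalation_rate=0.04,
            n_preictal_jitter_rel_sd=0.28,
        ),
        iei_model=IEIModel(
            initial_iei_s=120.0, settled_iei_s=25.0, settling_constant_events=7.0
        ),
        n_sles=2,
        n_interictal=4,
        seed=seed,
    )


def default_ko_config(seed: int = 0) -> SynthConfig:
    """Knockout-like study conditions at full scale.

    ~85 preictal discharges with compressed γ escalation and a late
    first SLE; the discharge *rate* settles like the wild-type one.
    """
    return SynthConfig(
        sample_rate_hz=10_000.0,
        total_duration_s=6000.0,
        baseline_duration_s=30.0,
        discharge_model=DischargeModel(
            n_preictal=85,
            gamma_escalation_rate=0.015,
            common_escalation_rate=0.04,
            n_preictal_jitter_rel_sd=0.5,
        ),
        iei_model=IEIModel(
            initial_iei_s=120.0, settled_iei_s=25.0, settling_constant_events=7.0
        ),
        n_sles=1,
        n_interictal=4,
        seed=seed,
    )


def reduced_wt_config(seed: int = 0) -> SynthConfig:
    """Wild-type-like conditions scaled down for replicate studies.

    Same qualitative structure as :func:`default_wt_config` (few events,
    fast γ escalation, early SLE) at 500 Hz sampling and ~5 min duration,
    so hundreds of recordings can be analyzed end-to-end.
    """
    return SynthConfig(
        sample_rate_hz=500.0,
        total_duration_s=450.0,
        baseline_duration_s=20.0,
        discharge_model=DischargeModel(
            n_preictal=12,
            gamma_escalation_rate=0.5,
            common_escalation_rate=0.08,
            n_preictal_jitter_rel_sd=0.28,
        ),
        iei_model=IEIModel(
            initial_iei_s=24.0, settled_iei_s=8.0, settling_constant_events=5.0
        ),
        sle_model=SLEModel(duration_s=14.0),
        n_sles=2,
        n_interictal=3,
        seed=seed,
    )


def reduced_ko_config(seed: int = 0) -> SynthConfig:
    """Knockout-like conditions scaled down for replicate studies."""
    return SynthConfig(
        sample_rate_hz=500.0,
        total_duration_s=900.0,
        baseline_duration_s=20.0,
        discharge_model=DischargeModel(
            n_preictal=36,
            gamma_escalation_rate=0.02,
            common_escalation_rate=0.08,
            n_preictal_jitter_rel_sd=0.35,
        ),
        iei_model=IEIModel(
            initial_iei_s=24.0, settled_iei_s=8.0, settling_constant_events=5.0
        ),
        sle_model=SLEModel(duration_s=14.0),
        n_sles=1,
        n_interictal=3,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ground-truth matching (detector validation)


def match_events(
    gt: GroundTruth,
    detected_onsets_s: Sequence[float],
    detected_offsets_s: Sequence[float],
    tol_s: float = 0.128,
) -> Dict[str, object]:
    """Match ground-truth events to detections.

    A ground-truth event is *recovered* when some detection's onset and
    offset both lie within ``tol_s`` of the true ones; it is *hit* when
    any detection overlaps it at all.  Returns recovery/hit counts and
    the boolean per-event recovery vector.
    """
    det_on = np.asarray(detected_onsets_s, dtype=float)
    det_off = np.asarray(detected_offsets_s, dtype=float)
    recovered = np.zeros(gt.n_events, dtype=bool)
    hit = np.zeros(gt.n_events, dtype=bool)
    for i, (a, b) in enumerate(zip(gt.event_onsets_s, gt.event_offsets_s)):
        overlap = (det_on < b) & (det_off > a)
        hit[i] = overlap.any()
        close = (np.abs(det_on - a) <= tol_s) & (np.abs(det_off - b) <= tol_s)
        recovered[i] = close.any()
    return {
        "n_true": gt.n_events,
        "n_detected": det_on.size,
        "n_recovered": int(recovered.sum()),
        "n_hit": int(hit.sum()),
        "recovered": recovered,
        "recovery_rate": float(recovered.mean()) if gt.n_events else 1.0,
    }
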