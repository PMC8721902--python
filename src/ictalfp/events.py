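"""Event classification, band power, normalization, and the γ/δ ratio.

Detected discharges are classified by the bimodal-duration rule
(seizure-like events last longer than 10 s; short events are *preictal*
before the first SLE and *interictal* after it), integrated over the
conventional LFP bands, normalized per band to the range between
baseline power and the 95th percentile of per-event power across the
recording, and summarized by the ratio of normalized γ to normalized δ
power — a proxy for local firing relative to synaptic drive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .spectral import RawEventInterval, ZSpectrogram

logger = logging.getLogger(__name__)

__all__ = [
    "BandScheme",
    "DetectedEvent",
    "NormalizationContext",
    "classify_events",
    "band_power",
    "compute_normalization_context",
    "normalize_band_power",
    "gamma_delta_ratio",
    "per_epoch_band_means",
    "characterize_recording",
    "events_to_table",
    "SLE_THRESHOLD_S",
]

#: Duration (s) above which an event is seizure-like; strictly greater-than.
SLE_THRESHOLD_S = 10.0

_DEFAULT_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
    "high_gamma": (80.0, 150.0),
}


@dataclass(frozen=True)
class BandScheme:
    """Conventional LFP frequency bands.

    Membership is half-open ``[low, high)`` with the topmost band closed
    at its upper edge, so every analysis frequency belongs to exactly one
    band.  Frequencies inside the mains-omission band are excluded from
    band integration when ``exclude_notch_from_bands`` is set.
    """

    bands: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BANDS)
    )
    exclude_notch_from_bands: bool = True

    def __post_init__(self) -> None:
        edges = sorted(self.bands.values())
        for (lo1, hi1), (lo2, hi2) in zip(edges, edges[1:]):
            if lo2 < hi1:
                raise ValueError("bands may only touch at shared edges")

    @property
    def top_edge_hz(self) -> float:
        return max(hi for _, hi in self.bands.values())

    def freq_mask(
        self,
        band: str,
        freq_centers_hz: np.ndarray,
        notch_mask: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        lo, hi = self.bands[band]
        f = np.asarray(freq_centers_hz)
        if hi >= self.top_edge_hz:  # topmost band closed above
            m = (f >= lo) & (f <= hi)
        else:
            m = (f >= lo) & (f < hi)
        if self.exclude_notch_from_bands and notch_mask is not None:
            m &= ~np.asarray(notch_mask, dtype=bool)
        return m


@dataclass
class DetectedEvent:
    """A classified discharge with raw and normalized band powers."""

    interval: RawEventInterval
    class_label: str = "preictal"
    raw_band_power: Dict[str, float] = field(default_factory=dict)
    normalized_band_power: Optional[Dict[str, float]] = None
    gamma_delta_ratio: Optional[float] = None
    ratio_excluded: bool = False

    @property
    def onset_s(self) -> float:
        return self.interval.onset_s

    @property
    def offset_s(self) -> float:
        return self.interval.offset_s

    @property
    def duration_s(self) -> float:
        return self.interval.duration_s


@dataclass
class NormalizationContext:
    """Per-band anchors of the normalization.

    ``baseline_power`` is the band power of a baseline segment of the
    median event duration (so baseline and event powers integrate over
    comparable spans); ``p95_range`` is the configured percentile of
    per-event band power across the whole recording minus the baseline
    power.  Normalized power maps the baseline to 0 and the percentile
    to 1.
    """

    baseline_power: Dict[str, float]
    p95_range: Dict[str, float]
    percentile: float = 95.0


def classify_events(
    events: Sequence[RawEventInterval],
    sle_threshold_s: float = SLE_THRESHOLD_S,
) -> Tuple[List[DetectedEvent], Optional[float]]:
    """Label events preictal / interictal / SLE by the first-SLE rule.

    An event is an SLE iff its duration strictly exceeds
    ``sle_threshold_s``; a short event is preictal when it ends before
    the first SLE begins and interictal otherwise.  With no SLE in the
    recording every short event is preictal.

    Returns ``(classified_events, first_sle_onset_s)``.
    """
    onsets = [e.onset_s for e in events]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("events must be sorted by onset")
    first_sle: Optional[float] = None
    for e in events:
        if e.duration_s > sle_threshold_s:
            first_sle = e.onset_s
            break
    out = []
    for e in events:
        if e.duration_s > sle_threshold_s:
            label = "SLE"
        elif first_sle is None or e.offset_s < first_sle:
            label = "preictal"
        else:
            label = "interictal"
        out.append(DetectedEvent(interval=e, class_label=label))
    return out, first_sle


def band_power(
    power: np.ndarray,
    freq_centers_hz: np.ndarray,
    interval: RawEventInterval,
    scheme: BandScheme = BandScheme(),
    notch_mask: Optional[np.ndarray] = None,
    aggregate: str = "sum",
) -> Dict[str, float]:
    """Total raw power of one event per frequency band.

    Power is summed over the event's time bins and the frequency centers
    inside each band (``aggregate="mean"`` averages over time bins
    instead).
    """
    n_bins = power.shape[1]
    i0, i1 = interval.onset_bin, interval.offset_bin
    if i0 < 0 or i1 >= n_bins:
        raise ValueError(
            f"event bins [{i0}, {i1}] outside spectrogram range [0, {n_bins})"
        )
    if aggregate not in ("sum", "mean"):
        raise ValueError("aggregate must be 'sum' or 'mean'")
    seg = power[:, i0 : i1 + 1]
    out = {}
    for band in scheme.bands:
        m = scheme.freq_mask(band, freq_centers_hz, notch_mask)
        if aggregate == "sum":
            total = seg[m].sum()
        else:
            total = seg[m].sum(axis=0).mean()
        out[band] = float(total)
    return out


def compute_normalization_context(
    power: np.ndarray,
    zs: ZSpectrogram,
    events: Sequence[DetectedEvent],
    scheme: BandScheme = BandScheme(),
    baseline_window_s: Optional[Tuple[float, float]] = None,
    percentile: float = 95.0,
    aggregate: str = "sum",
    range_mode: str = "baseline_to_percentile",
) -> NormalizationContext:
    """Normalization anchors from the recording's own event population.

    ``range_mode="baseline_to_percentile"`` (default) takes the range as
    the configured percentile of per-event band power minus the baseline
    band power — the baseline and the full ictal activity as the two
    anchors.  ``range_mode="interpercentile"`` instead uses the central
    95% spread of per-event powers (2.5th to 97.5th percentile).
    """
    if not events:
        raise ValueError("cannot build a normalization context without events")
    if baseline_window_s is None:
        lo = float(zs.time_bin_centers_s[0] - zs.bin_width_s / 2)
        hi = lo + 10.0
        baseline_window_s = (lo, hi)
    half = zs.bin_width_s / 2.0
    inside = np.flatnonzero(
        (zs.time_bin_centers_s - half >= baseline_window_s[0] - 1e-9)
        & (zs.time_bin_centers_s + half <= baseline_window_s[1] + 1e-9)
    )
    if inside.size < 2:
        raise ValueError("baseline window holds fewer than 2 spectrogram bins")
    median_bins = int(
        np.median([e.interval.offset_bin - e.interval.onset_bin + 1 for e in events])
    )
    per_event = {
        band: np.array([e.raw_band_power[band] for e in events])
        for band in scheme.bands
    }
    baseline_power, p95_range = {}, {}
    for band in scheme.bands:
        m = scheme.freq_mask(band, zs.freq_centers_hz, zs.notch_mask)
        per_bin = power[np.ix_(m, inside)].sum(axis=0)
        base = float(per_bin.mean() * (median_bins if aggregate == "sum" else 1.0))
        baseline_power[band] = base
        if range_mode == "interpercentile":
            lo_p, hi_p = np.percentile(
                per_event[band], [100 - percentile, percentile]
            )
            rng = float(hi_p - lo_p)
        else:
            rng = float(np.percentile(per_event[band], percentile) - base)
        if rng <= 0:
            raise ValueError(
                f"non-positive normalization range for band {band!r}; "
                "the recording may contain too few or degenerate events"
            )
        p95_range[band] = rng
    return NormalizationContext(
        baseline_power=baseline_power, p95_range=p95_range, percentile=percentile
    )


def normalize_band_power(
    events: Sequence[DetectedEvent], context: NormalizationContext
) -> List[DetectedEvent]:
    """Affine per-band normalization: baseline → 0, percentile anchor → 1."""
    for band, rng in context.p95_range.items():
        if rng <= 0:
            raise ValueError(f"p95_range must be positive (band {band!r})")
    for e in events:
        e.normalized_band_power = {
            band: (e.raw_band_power[band] - context.baseline_power[band])
            / context.p95_range[band]
            for band in context.p95_range
        }
    return list(events)


def gamma_delta_ratio(event: DetectedEvent) -> Optional[float]:
    """Ratio of normalized γ to normalized δ power for one event.

    Events whose normalized δ power is zero or negative cannot yield a
    meaningful ratio; they are flagged (``ratio_excluded``) and dropped
    from downstream ratio statistics.
    """
    if event.normalized_band_power is None:
        raise ValueError("normalize_band_power must run before the ratio")
    delta = event.normalized_band_power["delta"]
    gamma = event.normalized_band_power["gamma"]
    if delta <= 0:
        event.ratio_excluded = True
        event.gamma_delta_ratio = None
        logger.info(
            "event at %.3f s excluded from ratio statistics "
            "(normalized delta = %.3g)",
            event.onset_s,
            delta,
        )
        return None
    event.gamma_delta_ratio = float(gamma / delta)
    return event.gamma_delta_ratio


def per_epoch_band_means(
    events: Sequence[DetectedEvent],
    first_sle_onset_s: Optional[float],
    epoch_s: float = 200.0,
) -> pd.DataFrame:
    """Mean normalized band power in sequential epochs before the first SLE.

    Events are binned by time-before-SLE into ``epoch_s`` epochs; epoch 0
    is the one immediately preceding the SLE and an event exactly on a
    boundary joins the later (closer-to-SLE) epoch.  Epochs containing no
    events are absent from the table, not reported as zero.
    """
    if first_sle_onset_s is None:
        raise ValueError(
            "no SLE in this recording; bin events by absolute time instead"
        )
    rows = []
    for e in events:
        before = first_sle_onset_s - e.onset_s
        if before <= 0 or e.class_label == "SLE":
            continue
        epoch = int(np.ceil(before / epoch_s)) - 1
        row = {"epoch": epoch, "onset_s": e.onset_s}
        row.update(
            {f"norm_{b}": v for b, v in (e.normalized_band_power or {}).items()}
        )
        rows.append(row)
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    value_cols = [c for c in df.columns if c.startswith("norm_")]
    out = df.groupby("epoch")[value_cols].mean()
    out["n_events"] = df.groupby("epoch").size()
    out = out.reset_index().sort_values("epoch", ascending=False)
    out["epoch_start_s_before_sle"] = (out["epoch"] + 1) * epoch_s
    return out.reset_index(drop=True)


def characterize_recording(
    raw_events: Sequence[RawEventInterval],
    power: np.ndarray,
    zs: ZSpectrogram,
    scheme: BandScheme = BandScheme(),
    baseline_window_s: Optional[Tuple[float, float]] = None,
    sle_threshold_s: float = SLE_THRESHOLD_S,
    percentile: float = 95.0,
    aggregate: str = "sum",
) -> Tuple[List[DetectedEvent], Optional[float]]:
    """Classify, integrate, normalize and ratio all events of a recording."""
    events, first_sle = classify_events(raw_events, sle_threshold_s)
    for e in events:
        e.raw_band_power = band_power(
            power, zs.freq_centers_hz, e.interval, scheme, zs.notch_mask, aggregate
        )
    if events:
        ctx = compute_normalization_context(
            power, zs, events, scheme, baseline_window_s, percentile, aggregate
        )
        normalize_band_power(events, ctx)
        for e in events:
            gamma_delta_ratio(e)
    return events, first_sle


def events_to_table(
    events: Sequence[DetectedEvent], recording_id: str = "recording"
) -> pd.DataFrame:
    """Tab-friendly event table: one row per event, powers per band."""
    rows = []
    for e in events:
        row = {
            "recording_id": recording_id,
            "onset_s": e.onset_s,
            "offset_s": e.offset_s,
            "duration_s": e.duration_s,
            "class": e.class_label,
            "peak_z": e.interval.peak_z,
            "gamma_delta_ratio": e.gamma_delta_ratio,
        }
        for band, v in e.raw_band_power.items():
            row[f"raw_{band}"] = v
        for band, v in (e.normalized_band_power or {}).items():
            row[f"norm_{band}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
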