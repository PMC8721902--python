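"""Per-recording ictogenesis dynamics.

Summaries of how pathological activity evolves after the switch to
0 Mg²⁺ media: preictal event counts, cumulative discharge durations,
latency to the first seizure-like event, time to the Nth discharge,
inter-event intervals as a function of event number (the discharge rate
settles over roughly the first 20 events), and the gradient of
cumulative duration versus event number (a constant gradient means
discharge durations are stationary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .events import DetectedEvent

__all__ = [
    "RecordingDynamics",
    "dynamics_summary",
    "iei_series",
    "cumulative_duration_gradient",
    "fit_iei_settling",
]


@dataclass
class RecordingDynamics:
    """Dynamics metrics of one recording, times relative to t0."""

    n_preictal: int
    n_interictal: int
    n_sle: int
    cumulative_preictal_duration_s: float
    latency_first_sle_s: Optional[float]
    time_to_nth_discharge_s: Dict[int, float]
    iei_by_event_number: np.ndarray
    cumulative_duration_gradient_s_per_event: Optional[float]
    n_sles_in_window: int

    @property
    def n_events(self) -> int:
        return self.n_preictal + self.n_interictal + self.n_sle


def dynamics_summary(
    events: Sequence[DetectedEvent],
    t0_solution_switch_s: float = 0.0,
    sle_count_window_s: float = 1800.0,
) -> RecordingDynamics:
    """Summarize classified events relative to the solution switch ``t0``.

    ``latency_first_sle_s`` is the onset of the first SLE minus ``t0``
    (``None`` without an SLE); ``time_to_nth_discharge_s[n]`` is the
    onset of the nth event (1-based, onset order) minus ``t0``;
    ``n_sles_in_window`` counts SLE onsets within
    ``[t0, t0 + sle_count_window_s]`` — the first-30-minutes count at
    the default window.
    """
    events = list(events)
    if events and t0_solution_switch_s > events[0].onset_s + 1e-9:
        raise ValueError("t0 must not be later than the first event onset")
    labels = [e.class_label for e in events]
    pre = [e for e in events if e.class_label == "preictal"]
    sles = [e for e in events if e.class_label == "SLE"]
    latency = sles[0].onset_s - t0_solution_switch_s if sles else None
    gradient = None
    if len(pre) >= 2:
        gradient, _, _ = cumulative_duration_gradient(pre)
    return RecordingDynamics(
        n_preictal=len(pre),
        n_interictal=labels.count("interictal"),
        n_sle=len(sles),
        cumulative_preictal_duration_s=float(sum(e.duration_s for e in pre)),
        latency_first_sle_s=latency,
        time_to_nth_discharge_s={
            n: e.onset_s - t0_solution_switch_s
            for n, e in enumerate(events, start=1)
        },
        iei_by_event_number=iei_series(events)["iei_s"],
        cumulative_duration_gradient_s_per_event=gradient,
        n_sles_in_window=sum(
            1
            for e in sles
            if t0_solution_switch_s
            <= e.onset_s
            <= t0_solution_switch_s + sle_count_window_s
        ),
    )


def iei_series(
    events: Sequence[DetectedEvent], first_m_events: int = 15
) -> Dict[str, np.ndarray]:
    """Onset-to-onset inter-event intervals, by event number.

    Returns the full series plus the series truncated to the first
    ``first_m_events`` events (length ``first_m_events − 1``), which
    makes group comparisons sample the same early epoch when one group
    produces many more discharges than the other.
    """
    onsets = np.array([e.onset_s for e in events], dtype=float)
    iei = np.diff(onsets) if onsets.size >= 2 else np.empty(0)
    return {
        "iei_s": iei,
        "event_number": np.arange(1, iei.size + 1),
        "first_m_iei_s": iei[: max(first_m_events - 1, 0)],
    }


def cumulative_duration_gradient(
    events: Sequence[DetectedEvent],
) -> Tuple[float, float, float]:
    """OLS slope of cumulative event duration versus event number.

    For stationary durations the cumulative plot is linear and the
    gradient equals the typical discharge duration.  Returns
    ``(gradient_s_per_event, intercept_s, residual_sd_s)``.
    """
    durations = np.array([e.duration_s for e in events], dtype=float)
    if durations.size < 2:
        raise ValueError("need at least 2 events for a gradient")
    x = np.arange(1, durations.size + 1, dtype=float)
    y = np.cumsum(durations)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sd = float(resid.std(ddof=2)) if durations.size > 2 else 0.0
    return float(slope), float(intercept), sd


def fit_iei_settling(
    iei_s: np.ndarray, p0: Optional[Tuple[float, float, float]] = None
) -> Dict[str, float]:
    """Fit an exponential settling law to an IEI-vs-event-number series.

    Model: ``iei(k) = settled + (initial − settled) · exp(−k / tau)``
    with ``k`` the 0-based interval index.  Returns the fitted
    parameters; used to check that the generator's configured settling
    constant is recoverable from the analyzed schedule.
    """
    iei_s = np.asarray(iei_s, dtype=float)
    if iei_s.size < 4:
        raise ValueError("need at least 4 intervals to fit settling")
    k = np.arange(iei_s.size, dtype=float)

    def model(k, settled, initial, tau):
        return settled + (initial - settled) * np.exp(-k / tau)

    if p0 is None:
        p0 = (float(iei_s[-3:].mean()), float(iei_s[0]), max(iei_s.size / 5, 1.0))
    popt, _ = curve_fit(model, k, iei_s, p0=p0, maxfev=20000)
    settled, initial, tau = popt
    return {
        "settled_iei_s": float(settled),
        "initial_iei_s": float(initial),
        "settling_constant_events": float(tau),
    }
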