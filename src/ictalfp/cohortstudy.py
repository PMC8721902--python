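"""End-to-end cohort studies on synthetic two-genotype cohorts.

This module wires the full chain — generation, spectral detection,
classification, band-power normalization, dynamics, and group statistics
— into reusable study functions: single-cohort analyses, replicate
studies of group-effect recovery, and detector benchmarks against the
generator's ground truth.  The analysis drivers and the acceptance
script are thin wrappers around these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dynamics import RecordingDynamics, dynamics_summary
from .events import BandScheme, DetectedEvent, characterize_recording
from .recording import Recording
from .spectral import SpectrogramSpec, detect_events
from .stats import bootstrap_mean, bootstrap_z_comparison, ranksum_test
from .synth import (
    GroundTruth,
    SynthConfig,
    generate_cohort,
    generate_recording,
    match_events,
    reduced_ko_config,
    reduced_wt_config,
)

__all__ = [
    "RecordingAnalysis",
    "analyze_recording",
    "run_cohort_study",
    "replicate_cohort_study",
    "detector_benchmark",
]


@dataclass
class RecordingAnalysis:
    """Everything the pipeline derives from one LFP recording."""

    recording_id: str
    events: List[DetectedEvent]
    first_sle_onset_s: Optional[float]
    dynamics: RecordingDynamics
    preictal_ratios: np.ndarray  # per-event γ/δ of non-excluded preictal events


def analyze_recording(
    rec: Recording,
    spec: SpectrogramSpec = SpectrogramSpec(),
    scheme: BandScheme = BandScheme(),
    threshold_sd: float = 3.0,
    t0_solution_switch_s: Optional[float] = None,
    sle_count_window_s: float = 1800.0,
) -> RecordingAnalysis:
    """Detect, classify, normalize and summarize one recording."""
    raw_events, zs, power = detect_events(rec, spec, threshold_sd)
    events, first_sle = characterize_recording(
        raw_events, power, zs, scheme, rec.baseline_window_s
    )
    if t0_solution_switch_s is None:
        t0_solution_switch_s = rec.baseline_window_s[1]
    dyn = dynamics_summary(events, t0_solution_switch_s, sle_count_window_s)
    ratios = np.array(
        [
            e.gamma_delta_ratio
            for e in events
            if e.class_label == "preictal" and e.gamma_delta_ratio is not None
        ]
    )
    return RecordingAnalysis(
        recording_id=rec.id,
        events=events,
        first_sle_onset_s=first_sle,
        dynamics=dyn,
        preictal_ratios=ratios,
    )


def _summary_row(group: str, ana: RecordingAnalysis) -> Dict[str, object]:
    d = ana.dynamics
    return {
        "group": group,
        "recording_id": ana.recording_id,
        "n_preictal": d.n_preictal,
        "n_interictal": d.n_interictal,
        "n_sle": d.n_sle,
        "cumulative_preictal_duration_s": d.cumulative_preictal_duration_s,
        "latency_first_sle_s": d.latency_first_sle_s,
        "n_sles_in_window": d.n_sles_in_window,
        "cumdur_gradient_s_per_event": d.cumulative_duration_gradient_s_per_event,
        "mean_gamma_delta_ratio": (
            float(ana.preictal_ratios.mean()) if ana.preictal_ratios.size else np.nan
        ),
        "median_gamma_delta_ratio": (
            float(np.median(ana.preictal_ratios))
            if ana.preictal_ratios.size
            else np.nan
        ),
    }


def run_cohort_study(
    seed: int = 0,
    config_wt: Optional[SynthConfig] = None,
    config_ko: Optional[SynthConfig] = None,
    n_wt: int = 6,
    n_ko: int = 10,
    n_bootstrap: int = 10_000,
    sle_count_window_s: float = 1800.0,
) -> Dict[str, object]:
    """Generate and analyze one two-genotype cohort end to end.

    Returns the per-recording summary table, pooled per-event γ/δ
    ratios, and the group comparisons (rank-sum on per-recording
    summaries; bootstrap z on pooled per-event ratios).
    """
    config_wt = config_wt or reduced_wt_config()
    config_ko = config_ko or reduced_ko_config()
    wt, ko = generate_cohort(config_wt, config_ko, n_wt, n_ko, seed)
    rows, pooled = [], {"WT": [], "KO": []}
    analyses: Dict[str, List[RecordingAnalysis]] = {"WT": [], "KO": []}
    truths: Dict[str, List[GroundTruth]] = {"WT": [], "KO": []}
    for group, cohort, cfg in (("WT", wt, config_wt), ("KO", ko, config_ko)):
        for rec, gt in cohort:
            ana = analyze_recording(
                rec,
                t0_solution_switch_s=cfg.t0_solution_switch_s,
                sle_count_window_s=sle_count_window_s,
            )
            rows.append(_summary_row(group, ana))
            pooled[group].extend(ana.preictal_ratios.tolist())
            analyses[group].append(ana)
            truths[group].append(gt)
    summary = pd.DataFrame(rows)
    comparisons = {}
    for metric in ("n_preictal", "latency_first_sle_s", "mean_gamma_delta_ratio"):
        a = summary.loc[summary.group == "WT", metric].dropna().to_numpy()
        b = summary.loc[summary.group == "KO", metric].dropna().to_numpy()
        w, p = ranksum_test(a, b)
        comparisons[metric] = {
            "wt_median": float(np.median(a)) if a.size else np.nan,
            "ko_median": float(np.median(b)) if b.size else np.nan,
            "p_ranksum": p,
        }
    ratios_wt = np.asarray(pooled["WT"])
    ratios_ko = np.asarray(pooled["KO"])
    z = p_z = np.nan
    if ratios_wt.size >= 2 and ratios_ko.size >= 2:
        res_wt = bootstrap_mean(ratios_wt, n_bootstrap, seed=seed * 2 + 1)
        res_ko = bootstrap_mean(ratios_ko, n_bootstrap, seed=seed * 2 + 2)
        z, p_z = bootstrap_z_comparison(res_wt, res_ko)
    return {
        "summary": summary,
        "pooled_ratios": {"WT": ratios_wt, "KO": ratios_ko},
        "comparisons": comparisons,
        "ratio_bootstrap_z": float(z),
        "ratio_bootstrap_p": float(p_z),
        "analyses": analyses,
        "ground_truths": truths,
    }


def replicate_cohort_study(
    n_replicates: int = 100,
    seed: int = 0,
    config_wt: Optional[SynthConfig] = None,
    config_ko: Optional[SynthConfig] = None,
    n_wt: int = 6,
    n_ko: int = 10,
    n_bootstrap: int = 10_000,
) -> pd.DataFrame:
    """Repeat the cohort study and record group-effect recovery per replicate.

    For each replicate: rank-sum p-values and effect directions for
    preictal counts, first-SLE latency, and per-recording mean γ/δ
    ratio, plus the bootstrap z of the pooled per-event γ/δ means.
    """
    rows = []
    for r in range(n_replicates):
        study = run_cohort_study(
            seed=seed + 1000 * r,
            config_wt=config_wt,
            config_ko=config_ko,
            n_wt=n_wt,
            n_ko=n_ko,
            n_bootstrap=n_bootstrap,
        )
        comp = study["comparisons"]
        rows.append(
            {
                "replicate": r,
                "p_n_preictal": comp["n_preictal"]["p_ranksum"],
                "ko_more_preictal": comp["n_preictal"]["ko_median"]
                > comp["n_preictal"]["wt_median"],
                "p_latency": comp["latency_first_sle_s"]["p_ranksum"],
                "ko_longer_latency": comp["latency_first_sle_s"]["ko_median"]
                > comp["latency_first_sle_s"]["wt_median"],
                "p_ratio": comp["mean_gamma_delta_ratio"]["p_ranksum"],
                "wt_higher_ratio": comp["mean_gamma_delta_ratio"]["wt_median"]
                > comp["mean_gamma_delta_ratio"]["ko_median"],
                "z_ratio": study["ratio_bootstrap_z"],
            }
        )
    return pd.DataFrame(rows)


def detector_benchmark(
    n_recordings: int = 20,
    seed: int = 0,
    config: Optional[SynthConfig] = None,
    tol_s: float = 0.128,
) -> Dict[str, object]:
    """Detector recovery and matched pure-noise false-positive benchmark.

    Half the seeds use the wild-type-like reduced config and half the
    knockout-like one; each recording is paired with a matched
    events-disabled noise trace on which the fraction of suprathreshold
    bins is measured.
    """
    from .spectral import (
        compute_spectrogram,
        detect_suprathreshold_bins,
        transform_power,
        zscore_spectrogram,
    )

    spec = SpectrogramSpec()
    recovery, noise_frac = [], []
    for i in range(n_recordings):
        if config is not None:
            cfg = replace(config, seed=seed + i)
        elif i % 2 == 0:
            cfg = replace(reduced_wt_config(), seed=seed + i)
        else:
            cfg = replace(reduced_ko_config(), seed=seed + i)
        rec, gt = generate_recording(cfg)
        raw_events, zs, power = detect_events(rec, spec)
        res = match_events(
            gt,
            [e.onset_s for e in raw_events],
            [e.offset_s for e in raw_events],
            tol_s=tol_s,
        )
        recovery.append(res["recovery_rate"])
        noise_cfg = replace(
            cfg,
            discharge_model=replace(cfg.discharge_model, n_preictal=0),
            n_sles=0,
            n_interictal=0,
        )
        noise_rec, _ = generate_recording(noise_cfg)
        p, c, f = compute_spectrogram(noise_rec, spec)
        nzs = zscore_spectrogram(
            transform_power(p, spec), c, f, noise_rec.baseline_window_s, spec
        )
        noise_frac.append(float(detect_suprathreshold_bins(nzs).mean()))
    return {
        "recovery_rates": np.asarray(recovery),
        "mean_recovery": float(np.mean(recovery)),
        "noise_bin_fractions": np.asarray(noise_frac),
        "max_noise_fraction": float(np.max(noise_frac)),
    }
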