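"""End-to-end pipeline over recording files, with persisted configuration.

Ties the stages together for file-based use: read recordings (delimited
text or EDF), detect and classify events, integrate and normalize band
powers, summarize dynamics, optionally analyze paired cell-attached
traces, and compare groups.  Every run writes its fully resolved
configuration (YAML) next to the outputs, and a structured log records
every parameter and every event excluded from ratio statistics, so each
number in the report is traceable to a stage, a parameter set, and a
seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .cohortstudy import RecordingAnalysis, analyze_recording
from .events import BandScheme, events_to_table
from .recording import Recording, read_recording
from .spectral import SpectrogramSpec, save_zspectrogram_h5
from .spikes import detect_spikes, spike_stats_by_class, spikes_per_event
from .stats import compare_groups

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """At least one pipeline stage failed; see the per-file error report."""


@dataclass
class PipelineConfig:
    """Fully resolved parameterization of one pipeline run."""

    spectrogram: SpectrogramSpec = field(default_factory=SpectrogramSpec)
    bands: BandScheme = field(default_factory=BandScheme)
    threshold_sd: float = 3.0
    merge_gap_bins: int = 0
    sle_threshold_s: float = 10.0
    normalization_percentile: float = 95.0
    band_aggregate: str = "sum"
    sle_count_window_s: float = 1800.0
    iei_first_m_events: int = 15
    spike_threshold_mad: float = 5.0
    spike_refractory_ms: float = 1.0
    spike_highpass_hz: float = 100.0
    n_bootstrap: int = 10_000
    seed: int = 0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload["spectrogram"]["notch_band_hz"] = list(
            payload["spectrogram"]["notch_band_hz"]
        )
        payload["bands"]["bands"] = {
            k: list(v) for k, v in payload["bands"]["bands"].items()
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        spec_kw = dict(raw.pop("spectrogram", {}))
        if "notch_band_hz" in spec_kw:
            spec_kw["notch_band_hz"] = tuple(spec_kw["notch_band_hz"])
        bands_kw = dict(raw.pop("bands", {}))
        if "bands" in bands_kw:
            bands_kw["bands"] = {
                k: tuple(v) for k, v in bands_kw["bands"].items()
            }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            spectrogram=SpectrogramSpec(**spec_kw),
            bands=BandScheme(**bands_kw),
            **raw,
        )


def _load_input(item, config: PipelineConfig) -> Tuple[Recording, str]:
    """Accept (Recording, group) or (path, group)."""
    obj, group = item
    if isinstance(obj, Recording):
        return obj, group
    return read_recording(obj), group


def run_pipeline(
    inputs: Sequence[Tuple[object, str]],
    config: PipelineConfig = PipelineConfig(),
    output_dir: str | Path = "pipeline_out",
    cell_attached: Optional[Dict[str, object]] = None,
    save_spectrograms: bool = False,
) -> Dict[str, object]:
    """Run the full analysis over labeled recordings and write the bundle.

    Parameters
    ----------
    inputs
        Sequence of ``(recording_or_path, group_label)`` pairs.
    cell_attached
        Optional map from recording id to a paired cell-attached
        ``Recording`` (or path); spikes are assigned to that recording's
        LFP-defined event windows.
    save_spectrograms
        Persist each z-spectrogram as HDF5 (sizable; off by default).

    Writes per-recording event tables, a per-recording summary table, a
    group comparison report (TSV + JSON), spike statistics when paired
    traces are given, and the resolved config.  Raises
    :exc:`PipelineError` after processing if any recording failed.
    """
    if not len(inputs):
        raise ValueError("no input recordings given")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ictalfp")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    failures: Dict[str, str] = {}
    summary_rows: List[dict] = []
    event_tables: List[pd.DataFrame] = []
    spike_rows: List[dict] = []
    analyses: Dict[str, RecordingAnalysis] = {}
    groups: Dict[str, str] = {}
    try:
        logger.info("pipeline config: %s", asdict(config))
        for item in inputs:
            try:
                rec, group = _load_input(item, config)
                ana = analyze_recording(
                    rec,
                    spec=config.spectrogram,
                    scheme=config.bands,
                    threshold_sd=config.threshold_sd,
                    sle_count_window_s=config.sle_count_window_s,
                )
                analyses[rec.id] = ana
                groups[rec.id] = group
                table = events_to_table(ana.events, rec.id)
                table.insert(0, "group", group)
                event_tables.append(table)
                d = ana.dynamics
                summary_rows.append(
                    {
                        "group": group,
                        "recording_id": rec.id,
                        "n_preictal": d.n_preictal,
                        "n_interictal": d.n_interictal,
                        "n_sle": d.n_sle,
                        "cumulative_preictal_duration_s": d.cumulative_preictal_duration_s,
                        "latency_first_sle_s": d.latency_first_sle_s,
                        "n_sles_in_window": d.n_sles_in_window,
                        "mean_gamma_delta_ratio": (
                            float(np.mean(ana.preictal_ratios))
                            if ana.preictal_ratios.size
                            else np.nan
                        ),
                    }
                )
                if save_spectrograms:
                    _, zs, _ = _respectrogram(rec, config)
                    save_zspectrogram_h5(zs, out / f"{rec.id}.zspec.h5")
                if cell_attached and rec.id in cell_attached:
                    ca = cell_attached[rec.id]
                    if not isinstance(ca, Recording):
                        ca = read_recording(ca, channel_role="cell_attached")
                    train = detect_spikes(
                        ca,
                        config.spike_threshold_mad,
                        config.spike_refractory_ms,
                        config.spike_highpass_hz,
                    )
                    stats = spikes_per_event(train, ana.events)
                    for cls, vals in spike_stats_by_class(stats).items():
                        spike_rows.append(
                            {"group": group, "recording_id": rec.id, "class": cls, **vals}
                        )
            except Exception as exc:  # noqa: BLE001 - per-file isolation
                rec_id = getattr(item[0], "id", str(item[0]))
                failures[rec_id] = f"{type(exc).__name__}: {exc}"
                logger.error("recording %s failed: %s", rec_id, failures[rec_id])
        summary = pd.DataFrame(summary_rows)
        summary.to_csv(out / "recording_summary.tsv", sep="\t", index=False)
        if event_tables:
            pd.concat(event_tables, ignore_index=True).to_csv(
                out / "events.tsv", sep="\t", index=False
            )
        if spike_rows:
            pd.DataFrame(spike_rows).to_csv(
                out / "spike_stats.tsv", sep="\t", index=False
            )
        report = _comparison_report(summary, config)
        pd.DataFrame(report).to_csv(out / "group_comparisons.tsv", sep="\t", index=False)
        (out / "group_comparisons.json").write_text(json.dumps(report, indent=1))
        if failures:
            (out / "failures.json").write_text(json.dumps(failures, indent=1))
            raise PipelineError(
                f"{len(failures)} recording(s) failed: {sorted(failures)}"
            )
        return {
            "summary": summary,
            "analyses": analyses,
            "groups": groups,
            "comparisons": report,
            "output_dir": out,
        }
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()


def _respectrogram(rec: Recording, config: PipelineConfig):
    from .spectral import detect_events

    return detect_events(rec, config.spectrogram, config.threshold_sd)


def _comparison_report(summary: pd.DataFrame, config: PipelineConfig) -> List[dict]:
    report: List[dict] = []
    if summary.empty or summary["group"].nunique() != 2:
        return report
    g1, g2 = sorted(summary["group"].unique())
    for metric in (
        "n_preictal",
        "cumulative_preictal_duration_s",
        "latency_first_sle_s",
        "n_sles_in_window",
        "mean_gamma_delta_ratio",
    ):
        a = summary.loc[summary.group == g1, metric].dropna().to_numpy(float)
        b = summary.loc[summary.group == g2, metric].dropna().to_numpy(float)
        if a.size < 2 or b.size < 2:
            continue
        try:
            cmp = compare_groups(
                a, b, metric, n_resamples=config.n_bootstrap, seed=config.seed
            )
            p_ranksum, z, p_z = cmp.p_ranksum, cmp.z_score_bootstrap, cmp.p_z_two_sided
        except ValueError:
            # constant metric in both groups: rank-sum still defined,
            # bootstrap z is not
            from .stats import ranksum_test

            _, p_ranksum = ranksum_test(a, b)
            z = p_z = float("nan")
            logger.info("metric %s degenerate for bootstrap z", metric)
        report.append(
            {
                "metric": metric,
                "group_a": g1,
                "group_b": g2,
                "n_a": int(a.size),
                "n_b": int(b.size),
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "p_ranksum": p_ranksum,
                "z_bootstrap": z,
                "p_z": p_z,
                "n_resamples": config.n_bootstrap,
                "seed": config.seed,
            }
        )
    return report
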