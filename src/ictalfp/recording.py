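"""Recording container and file I/O.

A :class:`Recording` is a uniformly sampled single-channel voltage trace
(microvolts) with a sampling rate, a channel role (extracellular LFP,
cell-attached, or the whole-cell reference channel), and an annotated
baseline epoch used for per-frequency normalization of the spectrogram.

Recordings round-trip through two-column delimited text
(``time_s<TAB>voltage_uV``); EDF files are read through :mod:`mne` when it
is available.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

logger = logging.getLogger(__name__)

#: Valid channel roles.
CHANNEL_ROLES = ("LFP", "cell_attached", "whole_cell_reference")

#: Minimum baseline-epoch length in seconds.
MIN_BASELINE_S = 10.0


@dataclass
class Recording:
    """A uniformly sampled voltage trace.

    Parameters
    ----------
    samples
        Voltage samples in microvolts.
    sample_rate_hz
        Sampling rate; must place 150 Hz below Nyquist for spectral work.
    channel_role
        One of ``LFP``, ``cell_attached``, ``whole_cell_reference``.
    baseline_window_s
        ``(start, end)`` of the quiet baseline epoch in seconds from the
        start of the trace.  Must be at least 10 s long.  When ``None`` the
        first 10 s are used and a warning is logged.
    id
        Free-form label used in output tables.
    """

    samples: np.ndarray
    sample_rate_hz: float
    channel_role: str = "LFP"
    baseline_window_s: Optional[Tuple[float, float]] = None
    id: str = "recording"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(
                f"channel_role must be one of {CHANNEL_ROLES}, "
                f"got {self.channel_role!r}"
            )
        if self.baseline_window_s is None:
            # defaulted window is clamped to the trace; an explicitly
            # annotated window is validated strictly below
            logger.warning(
                "%s: no baseline annotation; defaulting to the first %.0f s",
                self.id,
                min(MIN_BASELINE_S, self.duration_s),
            )
            self.baseline_window_s = (0.0, min(MIN_BASELINE_S, self.duration_s))
        else:
            start, end = self.baseline_window_s
            # spectral baseline normalization needs >=10 s; spike channels
            # are exempt (their baseline is never used for z-scoring)
            if self.channel_role == "LFP" and end - start < MIN_BASELINE_S - 1e-9:
                raise ValueError(
                    f"baseline window must span at least {MIN_BASELINE_S} s, "
                    f"got {end - start:.3f} s"
                )
        start, end = self.baseline_window_s
        if start < 0 or end > self.duration_s + 1e-9:
            raise ValueError("baseline window must lie inside the recording")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    def with_role(self, role: str) -> "Recording":
        return replace(self, channel_role=role)


# ---------------------------------------------------------------------------
# delimited-text I/O


def write_recording_text(rec: Recording, path: str | Path) -> Path:
    """Write ``time_s<TAB>voltage_uV`` delimited text with a header line."""
    path = Path(path)
    header = (
        f"# id={rec.id} sample_rate_hz={rec.sample_rate_hz} "
        f"channel_role={rec.channel_role} "
        f"baseline_s={rec.baseline_window_s[0]}:{rec.baseline_window_s[1]}\n"
        "time_s\tvoltage_uV"
    )
    data = np.column_stack([rec.times_s, rec.samples])
    np.savetxt(path, data, fmt="%.6f\t%.6f", header=header, comments="")
    return path


def read_recording_text(
    path: str | Path,
    *,
    baseline_window_s: Optional[Tuple[float, float]] = None,
    channel_role: str = "LFP",
    id: Optional[str] = None,
) -> Recording:
    """Read a two-column (time, voltage) delimited text file.

    The sampling rate is inferred from the median time step.  A header of
    the form written by :func:`write_recording_text` is honored for
    metadata unless overridden by keyword arguments.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
    data = _loadtxt_skipping_header(path)
    t, v = data[:, 0], data[:, 1]
    dt = np.median(np.diff(t))
    if dt <= 0:
        raise ValueError(f"{path}: time column is not increasing")
    fs = float(meta.get("sample_rate_hz", 1.0 / dt))
    if baseline_window_s is None and "baseline_s" in meta:
        lo, hi = meta["baseline_s"].split(":")
        baseline_window_s = (float(lo), float(hi))
    return Recording(
        samples=v,
        sample_rate_hz=fs,
        channel_role=meta.get("channel_role", channel_role),
        baseline_window_s=baseline_window_s,
        id=id or meta.get("id", path.stem),
    )


def _loadtxt_skipping_header(path: Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                continue  # column-name header line
    if not rows:
        raise ValueError(f"{path}: no numeric rows found")
    return np.asarray(rows, dtype=float)


def read_recording_edf(
    path: str | Path,
    *,
    channel: int | str = 0,
    baseline_window_s: Optional[Tuple[float, float]] = None,
    channel_role: str = "LFP",
) -> Recording:
    """Read one channel of an EDF file (requires :mod:`mne`)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("EDF reading requires the 'mne' package") from exc
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if isinstance(channel, str):
        idx = raw.ch_names.index(channel)
    else:
        idx = int(channel)
    data = raw.get_data()[idx] * 1e6  # mne loads volts; convert to µV
    return Recording(
        samples=data,
        sample_rate_hz=float(raw.info["sfreq"]),
        channel_role=channel_role,
        baseline_window_s=baseline_window_s,
        id=Path(path).stem,
    )


def read_recording(path: str | Path, **kwargs) -> Recording:
    """Dispatch on extension: ``.edf`` via mne, anything else as text."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_recording_edf(path, **kwargs)
    return read_recording_text(path, **kwargs)


# ---------------------------------------------------------------------------
# ground-truth sidecar


def write_ground_truth_json(gt, path: str | Path) -> Path:
    """Write a ground-truth event schedule as a JSON sidecar.

    Layout: ``{"events": [{"onset_s":..,"offset_s":..,"class":..}, ...],
    "spike_times_s": [...]}``.
    """
    path = Path(path)
    payload = {
        "events": [
            {"onset_s": float(a), "offset_s": float(b), "class": c}
            for a, b, c in zip(
                gt.event_onsets_s, gt.event_offsets_s, gt.event_classes
            )
        ],
        "spike_times_s": (
            [float(t) for t in gt.spike_times_s]
            if gt.spike_times_s is not None
            else None
        ),
    }
    path.write_text(json.dumps(payload, indent=1))
    return path
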