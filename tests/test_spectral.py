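"""Spectral detection: STFT oracle, z-scoring, thresholding, segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import get_window

from ictalfp.recording import Recording
from ictalfp.spectral import (
    RawEventInterval,
    SpectrogramSpec,
    ZSpectrogram,
    compute_spectrogram,
    cumulative_suprathreshold,
    detect_events,
    detect_suprathreshold_bins,
    segment_events,
    transform_power,
    zscore_spectrogram,
)


def brute_force_power(x, fs, spec):
    """Independent oracle: per-window DFT evaluated at the target freqs."""
    L = spec.window_samples(fs)
    hop = spec.hop_samples(fs)
    w = get_window(spec.window_function, L, fftbins=False)
    freqs = spec.freq_centers_hz
    n_bins = (x.size - L) // hop + 1
    out = np.empty((freqs.size, n_bins))
    for t in range(n_bins):
        seg = x[t * hop : t * hop + L] * w
        for k, f in enumerate(freqs):
            X = np.sum(seg * np.exp(-2j * np.pi * f * np.arange(L) / fs))
            out[k, t] = np.abs(X) ** 2
    return out


def test_power_matches_brute_force_dft(spec):
    """Vectorized STFT equals a per-window DFT at the exact target freqs."""
    rng = np.random.default_rng(0)
    fs = 1000.0
    x = rng.standard_normal(int(2 * fs))
    rec = Recording(x, fs, baseline_window_s=None)
    power, _, _ = compute_spectrogram(rec, spec)
    oracle = brute_force_power(x, fs, spec)
    rel = np.abs(power - oracle) / np.maximum(oracle, 1e-30)
    assert rel.max() < 1e-9


def test_zero_trace_gives_zero_power(spec):
    rec = Recording(np.zeros(5000), 1000.0)
    power, _, _ = compute_spectrogram(rec, spec)
    assert np.all(power == 0)


def test_sinusoid_peaks_at_nearest_frequency(spec):
    """A 40 Hz tone maximizes mean power in the row nearest 40 Hz."""
    fs = 1000.0
    t = np.arange(int(10 * fs)) / fs
    rec = Recording(np.sin(2 * np.pi * 40.0 * t), fs)
    power, _, freqs = compute_spectrogram(rec, spec)
    peak_row = int(np.argmax(power.mean(axis=1)))
    assert peak_row == int(np.argmin(np.abs(freqs - 40.0)))


def test_bin_count_closed_form(spec):
    """60 s at 10 kHz with 0.128 s bins, 50% overlap -> 936 time bins."""
    fs = 10_000.0
    rec = Recording(np.random.default_rng(1).standard_normal(int(60 * fs)), fs)
    power, centers, _ = compute_spectrogram(rec, spec)
    assert power.shape[1] == centers.size == 936


def test_spectrogram_input_validation(spec):
    with pytest.raises(ValueError, match="shorter than one"):
        compute_spectrogram(Recording(np.zeros(100), 10_000.0), spec)
    with pytest.raises(ValueError, match="Nyquist"):
        compute_spectrogram(Recording(np.zeros(2000), 250.0), spec)


def test_zscore_hand_example(spec):
    """Baseline bins {1,2,3} (sample SD 1) and a later bin 5 -> z = 3."""
    n_t = 5
    power = np.full((2, n_t), 2.0)
    power[0] = [1.0, 2.0, 3.0, 2.0, 5.0]
    power[1] = [4.0, 5.0, 6.0, 5.0, 5.0]
    centers = np.array([0.5, 1.5, 2.5, 3.5, 4.5])
    freqs = np.array([10.0, 20.0])
    spec1 = SpectrogramSpec(bin_width_s=1.0, notch_band_hz=(48.0, 52.0))
    zs = zscore_spectrogram(power, centers, freqs, (0.0, 3.0), spec1)
    assert zs.z[0, -1] == pytest.approx((5 - 2) / 1.0)
    assert zs.z[1, -1] == pytest.approx(0.0)


def test_zscore_baseline_self_normalization(noise_recording, spec):
    """z-scoring the baseline against itself gives per-row mean 0, SD 1."""
    power, centers, freqs = compute_spectrogram(noise_recording, spec)
    zs = zscore_spectrogram(
        power, centers, freqs, noise_recording.baseline_window_s, spec
    )
    half = zs.bin_width_s / 2
    inside = (centers - half >= -1e-9) & (
        centers + half <= noise_recording.baseline_window_s[1] + 1e-9
    )
    rows = zs.z[:, inside]
    assert np.abs(rows.mean(axis=1)).max() < 1e-6
    assert np.abs(rows.std(axis=1, ddof=1) - 1).max() < 1e-6


def test_zscore_degenerate_constant_raises(spec):
    rec = Recording(np.zeros(int(30 * 500)), 500.0, baseline_window_s=(0, 12))
    power, centers, freqs = compute_spectrogram(rec, spec)
    with pytest.raises(ValueError, match="degenerate"):
        zscore_spectrogram(power, centers, freqs, rec.baseline_window_s, spec)


def _make_zs(z, spec, bin_width=0.128, hop=0.064):
    n = z.shape[1]
    centers = bin_width / 2 + hop * np.arange(n)
    return ZSpectrogram(
        z=z,
        time_bin_centers_s=centers,
        freq_centers_hz=spec.freq_centers_hz[: z.shape[0]],
        baseline_mean=np.zeros(z.shape[0]),
        baseline_sd=np.ones(z.shape[0]),
        notch_mask=spec.notch_mask()[: z.shape[0]],
        bin_width_s=bin_width,
        hop_s=hop,
    )


def test_threshold_marks_only_exceeding_bins(spec):
    z = np.zeros((50, 6))
    z[3, 2] = 4.0  # one frequency in one bin
    zs = _make_zs(z, spec)
    mask = detect_suprathreshold_bins(zs)
    assert list(np.flatnonzero(mask)) == [2]
    assert not detect_suprathreshold_bins(_make_zs(np.full((50, 6), 2.9), spec)).any()


def test_notched_frequencies_never_trigger(spec):
    """z=10 confined to 48-52 Hz rows is ignored by detection."""
    notch_rows = np.flatnonzero(spec.notch_mask())
    assert notch_rows.size > 0
    z = np.zeros((50, 5))
    z[notch_rows, :] = 10.0
    assert not detect_suprathreshold_bins(_make_zs(z, spec)).any()


def test_segment_run_geometry(spec):
    """F F T T T F F -> one event spanning 3 bins; duration (3+1)*hop."""
    z = np.zeros((50, 7))
    z[0, 2:5] = 5.0
    zs = _make_zs(z, spec)
    events = segment_events(detect_suprathreshold_bins(zs), zs)
    assert len(events) == 1
    ev = events[0]
    assert ev.duration_s == pytest.approx(4 * 0.064)
    assert ev.onset_s == pytest.approx(2 * 0.064)
    assert ev.peak_z == 5.0


def test_segment_merge_gap(spec):
    z = np.zeros((50, 3))
    z[0, [0, 2]] = 4.0
    zs = _make_zs(z, spec)
    mask = detect_suprathreshold_bins(zs)
    assert len(segment_events(mask, zs, merge_gap_bins=0)) == 2
    assert len(segment_events(mask, zs, merge_gap_bins=1)) == 1


def test_segment_empty(spec):
    zs = _make_zs(np.zeros((50, 10)), spec)
    assert segment_events(np.zeros(10, bool), zs) == []


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.lists(st.booleans(), min_size=1, max_size=60))
def test_segment_matches_run_length_oracle(mask):
    """Segmentation equals a brute-force run-length scan."""
    spec = SpectrogramSpec()
    zs = _make_zs(np.where(np.asarray(mask)[None, :], 5.0, 0.0), spec)
    events = segment_events(np.asarray(mask, bool), zs)
    # oracle: linear scan
    runs, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        if not m and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    assert [(e.onset_bin, e.offset_bin) for e in events] == runs


def test_cumulative_counts():
    mask = np.array([False, True, True, False])
    out = cumulative_suprathreshold(mask, np.arange(4) * 0.064)
    assert list(out["cumulative"]) == [0, 1, 2, 2]
    assert out["cumulative"][-1] == mask.sum()
    assert np.all(np.diff(out["cumulative"]) >= 0)
    zero = cumulative_suprathreshold(np.zeros(5, bool), np.arange(5.0))
    assert not zero["cumulative"].any()


def test_shift_equivariance(spec):
    """Delaying the trace by integer hops delays every onset equally."""
    cfg_fs = 500.0
    rng = np.random.default_rng(3)
    base = rng.standard_normal(int(40 * cfg_fs))
    t = np.arange(int(0.4 * cfg_fs)) / cfg_fs
    burst = 30 * np.sin(2 * np.pi * 20 * t)
    x1 = base.copy()
    x1[int(20 * cfg_fs) : int(20 * cfg_fs) + burst.size] += burst
    hop = spec.hop_samples(cfg_fs)
    shift_bins = 5
    x2 = np.concatenate([base[: shift_bins * hop], x1])[: x1.size + shift_bins * hop]
    rec1 = Recording(x1, cfg_fs, baseline_window_s=(0, 12))
    rec2 = Recording(x2, cfg_fs, baseline_window_s=(0, 12))
    ev1, _, _ = detect_events(rec1, spec)
    ev2, _, _ = detect_events(rec2, spec)
    assert len(ev1) == len(ev2) > 0
    delay = shift_bins * hop / cfg_fs
    for a, b in zip(ev1, ev2):
        assert b.onset_s - a.onset_s == pytest.approx(delay, abs=1e-9)


def test_burst_z_exceeds_threshold_in_window(spec):
    """An injected burst >=5x baseline SD pushes z above 3 inside its window."""
    fs = 500.0
    rng = np.random.default_rng(8)
    x = rng.standard_normal(int(40 * fs))
    t = np.arange(int(0.5 * fs)) / fs
    onset = 25.0
    x[int(onset * fs) : int(onset * fs) + t.size] += 10 * np.sin(2 * np.pi * 15 * t)
    rec = Recording(x, fs, baseline_window_s=(0, 12))
    power, centers, freqs = compute_spectrogram(rec, spec)
    zs = zscore_spectrogram(
        transform_power(power, spec), centers, freqs, rec.baseline_window_s, spec
    )
    inside = (centers >= onset) & (centers <= onset + 0.5)
    assert zs.z[:, inside].max() > 3
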