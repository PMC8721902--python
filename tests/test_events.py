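"""Classification, band-power integration, normalization, γ/δ ratio."""

import numpy as np
import pytest

from ictalfp.events import (
    BandScheme,
    DetectedEvent,
    NormalizationContext,
    band_power,
    classify_events,
    gamma_delta_ratio,
    normalize_band_power,
    per_epoch_band_means,
)
from ictalfp.spectral import RawEventInterval


def _interval(onset, duration, onset_bin=0, offset_bin=0):
    return RawEventInterval(
        onset_s=onset,
        offset_s=onset + duration,
        onset_bin=onset_bin,
        offset_bin=offset_bin,
        peak_z=5.0,
    )


class TestClassification:
    def test_label_sequence(self):
        """Durations (0.3, 0.5, 12, 0.4) -> preictal, preictal, SLE, interictal."""
        events = [
            _interval(10.0, 0.3),
            _interval(20.0, 0.5),
            _interval(30.0, 12.0),
            _interval(50.0, 0.4),
        ]
        out, first_sle = classify_events(events)
        assert [e.class_label for e in out] == [
            "preictal",
            "preictal",
            "SLE",
            "interictal",
        ]
        assert first_sle == 30.0

    def test_empty(self):
        out, first_sle = classify_events([])
        assert out == [] and first_sle is None

    def test_exact_threshold_is_not_sle(self):
        """10.0 s exactly is NOT seizure-like (strict >10 s rule)."""
        out, first_sle = classify_events([_interval(5.0, 10.0)])
        assert out[0].class_label == "preictal"
        assert first_sle is None

    def test_no_sle_all_preictal(self):
        out, _ = classify_events([_interval(1.0, 0.2), _interval(2.0, 0.3)])
        assert {e.class_label for e in out} == {"preictal"}

    def test_unsorted_raises(self):
        with pytest.raises(ValueError, match="sorted"):
            classify_events([_interval(5.0, 0.2), _interval(1.0, 0.2)])

    def test_pure_function_of_durations_and_position(self):
        """Labels depend only on durations and the first-SLE position."""
        events = [
            _interval(10.0, 0.3, 1, 2),
            _interval(30.0, 12.0, 5, 200),
            _interval(50.0, 0.4, 300, 301),
        ]
        base = [e.class_label for e in classify_events(events)[0]]
        # change metadata (bins, peak z) without touching times
        for e in events:
            e.onset_bin += 7
            e.offset_bin += 7
            e.peak_z = 99.0
        assert [e.class_label for e in classify_events(events)[0]] == base


class TestBandPower:
    def test_zero_power_matrix(self):
        freqs = np.geomspace(1, 150, 50)
        bp = band_power(np.zeros((50, 10)), freqs, _interval(0, 1, 2, 5))
        assert all(v == 0 for v in bp.values())

    def test_out_of_range_interval_raises(self):
        freqs = np.geomspace(1, 150, 50)
        with pytest.raises(ValueError, match="outside"):
            band_power(np.zeros((50, 10)), freqs, _interval(0, 1, 2, 99))

    def test_half_open_membership_at_8hz(self):
        """A center exactly at 8 Hz belongs to alpha, not theta."""
        freqs = np.array([5.0, 8.0, 12.0])
        power = np.zeros((3, 4))
        power[1, :] = 1.0  # all power at exactly 8 Hz
        bp = band_power(power, freqs, _interval(0, 1, 0, 3))
        assert bp["alpha"] == pytest.approx(4.0)
        assert bp["theta"] == 0.0

    def test_top_band_closed_at_upper_edge(self):
        freqs = np.array([100.0, 150.0])
        power = np.ones((2, 2))
        bp = band_power(power, freqs, _interval(0, 1, 0, 1))
        assert bp["high_gamma"] == pytest.approx(4.0)

    def test_sum_decomposition(self, wt_analysis):
        """Band powers partition total non-notch 1-150 Hz event power."""
        zs, power = wt_analysis["zs"], wt_analysis["power"]
        scheme = BandScheme()
        for ev in wt_analysis["events"][:5]:
            bp = band_power(
                power, zs.freq_centers_hz, ev, scheme, zs.notch_mask
            )
            seg = power[~zs.notch_mask, ev.onset_bin : ev.offset_bin + 1]
            assert sum(bp.values()) == pytest.approx(seg.sum(), rel=1e-12)

    def test_gamma_burst_concentrates_in_gamma(self, wt_analysis):
        """The generator's γ tone lands in the γ band of the detector grid."""
        zs = wt_analysis["zs"]
        scheme = BandScheme()
        m = scheme.freq_mask("gamma", zs.freq_centers_hz, zs.notch_mask)
        assert zs.freq_centers_hz[m].min() >= 30
        assert zs.freq_centers_hz[m].max() <= 80


class TestNormalization:
    def _ctx(self):
        return NormalizationContext(
            baseline_power={"delta": 2.0, "gamma": 1.0},
            p95_range={"delta": 4.0, "gamma": 5.0},
        )

    def _event(self, delta, gamma):
        e = DetectedEvent(interval=_interval(0, 1))
        e.raw_band_power = {"delta": delta, "gamma": gamma}
        return e

    def test_anchor_identities(self):
        """raw = baseline -> 0; raw = baseline + range -> 1."""
        ctx = self._ctx()
        events = [self._event(2.0, 1.0), self._event(6.0, 6.0)]
        normalize_band_power(events, ctx)
        assert events[0].normalized_band_power == {"delta": 0.0, "gamma": 0.0}
        assert events[1].normalized_band_power == {"delta": 1.0, "gamma": 1.0}

    def test_monotonicity(self):
        ctx = self._ctx()
        raws = [3.0, 10.0, 5.0, 2.5]
        events = [self._event(r, r) for r in raws]
        normalize_band_power(events, ctx)
        normed = [e.normalized_band_power["delta"] for e in events]
        assert np.argsort(normed).tolist() == np.argsort(raws).tolist()

    def test_nonpositive_range_raises(self):
        ctx = NormalizationContext(
            baseline_power={"delta": 1.0}, p95_range={"delta": 0.0}
        )
        with pytest.raises(ValueError, match="positive"):
            normalize_band_power([self._event(1, 1)], ctx)


class TestRatio:
    def _event(self, gamma_n, delta_n):
        e = DetectedEvent(interval=_interval(0, 1))
        e.normalized_band_power = {"gamma": gamma_n, "delta": delta_n}
        return e

    @pytest.mark.parametrize(
        "gamma_n,delta_n,expected", [(0.5, 0.5, 1.0), (0.8, 0.4, 2.0)]
    )
    def test_ratio_arithmetic(self, gamma_n, delta_n, expected):
        assert gamma_delta_ratio(self._event(gamma_n, delta_n)) == pytest.approx(
            expected
        )

    def test_nonpositive_delta_flagged(self):
        e = self._event(0.5, 0.0)
        assert gamma_delta_ratio(e) is None
        assert e.ratio_excluded

    def test_missing_normalization_raises(self):
        e = DetectedEvent(interval=_interval(0, 1))
        with pytest.raises(ValueError, match="normalize"):
            gamma_delta_ratio(e)


class TestEpochMeans:
    def _events(self, onsets, gammas, first_sle):
        out = []
        for onset, g in zip(onsets, gammas):
            e = DetectedEvent(interval=_interval(onset, 0.4))
            e.normalized_band_power = {"gamma": g, "delta": 0.5}
            out.append(e)
        return out

    def test_single_epoch_equals_plain_mean(self):
        events = self._events([900.0, 950.0, 990.0], [0.2, 0.4, 0.6], 1000.0)
        table = per_epoch_band_means(events, 1000.0)
        assert len(table) == 1
        assert table["norm_gamma"].iloc[0] == pytest.approx(0.4)

    def test_boundary_event_joins_later_epoch(self):
        """An event exactly 200 s before the SLE joins the closer epoch."""
        events = self._events([800.0], [1.0], 1000.0)
        table = per_epoch_band_means(events, 1000.0, epoch_s=200.0)
        assert table["epoch"].iloc[0] == 0

    def test_no_sle_raises_with_guidance(self):
        with pytest.raises(ValueError, match="absolute time"):
            per_epoch_band_means([], None)

    def test_escalating_gamma_is_nondecreasing_toward_sle(self, wt_analysis):
        """γ escalation in the generator shows up as rising epoch means."""
        from ictalfp.events import characterize_recording

        events, first_sle = characterize_recording(
            wt_analysis["events"],
            wt_analysis["power"],
            wt_analysis["zs"],
            baseline_window_s=wt_analysis["rec"].baseline_window_s,
        )
        assert first_sle is not None
        table = per_epoch_band_means(events, first_sle, epoch_s=50.0)
        gammas = table["norm_gamma"].to_numpy()  # ordered far -> near SLE
        assert gammas[-1] > gammas[0]
        assert np.all(np.diff(gammas) > -0.05)  # allow small sampling dips


def test_label_consistency_on_pipeline_run(wt_analysis):
    """No interictal before the first SLE, no preictal after it."""
    events, first_sle = classify_events(wt_analysis["events"])
    for e in events:
        if e.class_label == "preictal":
            assert e.offset_s < first_sle
        elif e.class_label == "interictal":
            assert e.onset_s > first_sle
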