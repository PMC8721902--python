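"""Shared fixtures: small synthetic recordings with known ground truth."""

import numpy as np
import pytest

from ictalfp.recording import Recording
from ictalfp.spectral import SpectrogramSpec, detect_events
from ictalfp.synth import (
    DischargeModel,
    NoiseModel,
    SynthConfig,
    generate_recording,
    reduced_wt_config,
)


@pytest.fixture(scope="session")
def spec() -> SpectrogramSpec:
    return SpectrogramSpec()


@pytest.fixture(scope="session")
def wt_recording():
    """One reduced-scale wild-type-like recording plus ground truth."""
    cfg = reduced_wt_config(seed=42)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def wt_analysis(wt_recording, spec):
    """Full detection chain on the wild-type-like fixture recording."""
    rec, gt = wt_recording
    events, zs, power = detect_events(rec, spec)
    return {"rec": rec, "gt": gt, "events": events, "zs": zs, "power": power}


@pytest.fixture()
def noise_recording():
    """Short events-free recording with the default noise model."""
    cfg = SynthConfig(
        sample_rate_hz=500.0,
        total_duration_s=60.0,
        baseline_duration_s=15.0,
        discharge_model=DischargeModel(n_preictal=0),
        n_sles=0,
        n_interictal=0,
        seed=7,
    )
    rec, _ = generate_recording(cfg)
    return rec


@pytest.fixture()
def white_noise_recording():
    rng = np.random.default_rng(11)
    return Recording(
        samples=rng.standard_normal(500 * 40),
        sample_rate_hz=500.0,
        baseline_window_s=(0.0, 12.0),
        id="white",
    )
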