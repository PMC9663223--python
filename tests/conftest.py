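import numpy as np
import pytest

from fnirs_upb.features import build_feature_matrix
from fnirs_upb.io import ROI_LABELS
from fnirs_upb.preprocess import preprocess_recording
from fnirs_upb.synthetic import NoiseParams, SyntheticConfig, generate_recording


def flat_amplitudes(value: float = 0.3) -> dict:
    """Zero condition contrast: every ROI gets the same amplitude in both tasks."""
    return {cond: {roi: value for roi in ROI_LABELS} for cond in ("Task1", "Task2")}


def quiet_noise() -> NoiseParams:
    return NoiseParams(
        cardiac_amp=0.0,
        resp_amp=0.0,
        mayer_amp=0.0,
        drift_amp=0.0,
        white_amp=0.0,
        hbr_white_um=0.0,
    )


@pytest.fixture(scope="session")
def default_subject():
    """One default-config synthetic subject, preprocessed, with its feature matrix."""
    cfg = SyntheticConfig(seed=7)
    rec, gt = generate_recording(cfg, 0)
    epochs = preprocess_recording(rec)
    fm = build_feature_matrix(epochs)
    return cfg, rec, gt, epochs, fm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
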