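import numpy as np
import pytest

from lmotools import (
    LMOPreset,
    MeasurementConfig,
    NoiseModel,
    PerfusionModel,
)


@pytest.fixture
def cfg():
    return MeasurementConfig()


@pytest.fixture
def noiseless():
    return NoiseModel(patch_sd=0.0, mea_sd=0.0, drift_slope=0.0)


@pytest.fixture
def perfusion():
    return PerfusionModel()


@pytest.fixture
def simple_preset():
    """Fast-desensitizing construct so the plateau is reached well within 1 s."""
    return LMOPreset(
        name="test",
        peak_photocurrent=-500.0,
        true_ce=0.4,
        desensitization_ratio=0.8,
        expression_cv=0.0,
    )


@pytest.fixture
def short_sweeps_kwargs():
    """Trimmed sweep durations for unit tests (wash-in ~96% complete)."""
    return dict(pre_perfusion_s=2.0, post_perfusion_s=30.0)
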