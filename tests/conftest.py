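import numpy as np
import pytest

from contextgates import (
    Characterization,
    ContextSpec,
    GateContext,
    GateTruth,
    NoiseModel,
    SensorMap,
)


@pytest.fixture
def zero_noise() -> NoiseModel:
    """Deterministic instrument: no cell-to-cell noise, no size coupling."""
    return NoiseModel(sigma_lognormal=0.0, scatter_sigma=0.0, size_coupling=0.0)


@pytest.fixture
def sensor() -> SensorMap:
    return SensorMap.default()


@pytest.fixture
def truth() -> GateTruth:
    return GateTruth(
        gate_name="PhlF-P1",
        repressor_family="PhlF",
        ymin_true=0.05,
        ymax_true=3.0,
        k_true=0.4,
        n_true=2.5,
    )


@pytest.fixture
def one_context() -> ContextSpec:
    return ContextSpec(backbone="pAN", host="EcDH5a")


def char_from_curve(x, y, gate="AmtR-A1", backbone="pAN", host="EcDH5a") -> Characterization:
    """Characterization directly from arrays (no cytometry stage)."""
    return Characterization(
        gate_context=GateContext(gate_name=gate, backbone=backbone, host=host),
        inputs=tuple(float(v) for v in x),
        outputs=tuple(float(v) for v in y),
    )


def char_from_truth(truth: GateTruth, x=None, gate=None, **ctx) -> Characterization:
    """Noiseless characterization sampled from a gate's true response."""
    if x is None:
        x = np.geomspace(0.01, 10.0, 13)
    y = truth.response(np.asarray(x))
    return char_from_curve(x, y, gate=gate or truth.gate_name, **ctx)
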