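import numpy as np
import pytest

from pedecg import nn, synthcohort, workflows
from pedecg.model import ConvBlockSpec, ModelSpec, TrainConfig, build_model, train


@pytest.fixture(scope="session")
def small_cohort():
    """12 clean records (6 per class), strong class effect."""
    records, manifest = synthcohort.generate_cohort(
        6, ("normal", "obese"), seed=11, effect_size=1.0)
    return records, manifest


def tiny_spec(filters=(8, 8)) -> ModelSpec:
    return ModelSpec(blocks=tuple(
        ConvBlockSpec(f, 3, 1, "relu", False, 0.0) for f in filters),
        dense_units=16)


@pytest.fixture(scope="session")
def tiny_beat_data():
    """Small separable beat dataset straight from the pipeline."""
    ds = workflows.synthetic_dataset(12, seed=21, effect_size=1.0)
    return ds


@pytest.fixture(scope="session")
def tiny_trained(tiny_beat_data):
    """A small CNN trained on the tiny dataset (seconds, not minutes)."""
    ds = tiny_beat_data
    cfg = TrainConfig(max_epochs=10, early_stop_patience=10, batch_size=64,
                      seed=5)
    net = build_model(tiny_spec(), cfg)
    fitted = train(net, ds.split("train"), ds.split("val"), cfg)
    return fitted, ds


@pytest.fixture()
def float64_engine():
    """Run the network engine in float64 (for finite-difference checks)."""
    saved = nn.DTYPE
    nn.DTYPE = np.float64
    try:
        yield
    finally:
        nn.DTYPE = saved
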