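import numpy as np
import pytest

from fedct.core import TASK_CALC, TASK_HCO, TASK_MS
from fedct.phantom import (
    AnnotatorModel,
    ClientSpec,
    FederationSpec,
    PhantomConfig,
    default_annotators,
    make_federation,
    make_phantom,
)


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """A 24^3 phantom that keeps every structure inside the grid; small
    enough that per-test generation stays cheap."""
    return PhantomConfig(
        grid_shape=(24, 24, 24),
        spacing_mm=(2.0, 2.0, 2.0),
        annulus_radius_mm=8.0,
        annulus_center_mm=(23.0, 23.0, 20.0),
        ostia_height_mm=6.0,
        ms_offset_mm=(0.0, -4.0, -2.0),
        ms_gap_mm=3.0,
        n_calc_blobs=2,
        calc_radius_range_mm=(1.5, 2.5),
        jitter_deg=4.0,
        center_jitter_mm=2.0,
    )


@pytest.fixture(scope="session")
def sample(small_config):
    return make_phantom(small_config, seed=7)


@pytest.fixture(scope="session")
def small_spec() -> FederationSpec:
    """Two training clients plus one held-out client, a handful of samples."""
    return FederationSpec(
        clients=[
            ClientSpec("a", 4, {TASK_HCO: 3, TASK_MS: 3, TASK_CALC: 3}),
            ClientSpec("b", 4, {TASK_HCO: 3, TASK_CALC: 3}),
            ClientSpec("h", 4, {TASK_HCO: 2, TASK_MS: 2, TASK_CALC: 2}),
        ],
        test_fraction=0.25,
        held_out_clients={TASK_HCO: ("h",), TASK_MS: ("h",), TASK_CALC: ("h",)},
    )


@pytest.fixture(scope="session")
def small_federation(small_spec, small_config):
    annotators = default_annotators(small_spec, noise_sd_mm=0.5, bias_scale_mm=0.3, seed=5)
    shards, plan = make_federation(
        small_spec, small_config, annotators, seed=11, rounds=1, epochs=1
    )
    return shards, plan


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def clean_annotator():
    return AnnotatorModel(annotator_id="clean", bias_mm=(0, 0, 0), noise_sd_mm=0.0, swap_prob=0.0, seed=3)
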