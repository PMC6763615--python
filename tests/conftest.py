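import numpy as np
import pytest

from phosphoprofiler import SimulationConfig, builtin_layout
from phosphoprofiler.layouts import (
    KIND_NEGATIVE_CONTROL,
    KIND_POSITIVE_REFERENCE,
    KIND_TARGET,
    _build_grid_layout,
)


@pytest.fixture(scope="session")
def rtk_layout():
    return builtin_layout("RTK")


@pytest.fixture(scope="session")
def mapk_layout():
    return builtin_layout("MAPK")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_mini_layout(n_targets: int = 4):
    """A small custom membrane: n targets + 3 references + 1 PBS pair."""
    entries = [(f"Ref{i}", KIND_POSITIVE_REFERENCE, "", False) for i in range(1, 4)]
    entries += [(f"T{i}", KIND_TARGET, "", False) for i in range(1, n_targets + 1)]
    entries.append(("PBS", KIND_NEGATIVE_CONTROL, "", False))
    return _build_grid_layout("custom", entries, grid_cols=4)


@pytest.fixture
def mini_layout():
    return make_mini_layout()


@pytest.fixture
def clean_config():
    """Noise-free rendering conditions for exact round-trip checks."""
    return SimulationConfig(
        seed=7,
        noise_sd=0.0,
        duplicate_cv=0.0,
        background_gradient=0.0,
        measurement_log2_sd=0.0,
        effect_size=0.0,
        negative_intensity=0.0,
        gain=8.0,
    )
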