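import numpy as np
import pandas as pd
import pytest

from maxsdm import (
    EnvStack,
    GridSpec,
    Layer,
    VirtualSpeciesConfig,
    generate_env_stack,
    sample_occurrences,
    true_suitability,
)


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec(
        origin_lon=100.0, origin_lat=30.0, cell_size=0.5, n_rows=6, n_cols=8
    )


@pytest.fixture
def small_stack(small_grid) -> EnvStack:
    """A tiny 3-layer stack with one nodata cell shared across layers."""
    rng = np.random.default_rng(0)
    stack = EnvStack(small_grid)
    base = np.linspace(0, 10, small_grid.n_rows)[:, None] * np.ones(
        (1, small_grid.n_cols)
    )
    for i, name in enumerate(["temp", "prec", "elev"]):
        v = base + i + rng.normal(0, 0.1, small_grid.shape)
        v[0, 0] = small_grid.nodata
        stack.add(Layer(small_grid, v, name))
    return stack.harmonize_mask()


@pytest.fixture
def toy_pb():
    """Deterministic presence/background covariate tables (two covariates).

    Presences concentrate at high values of ``x``; ``noise`` is
    uninformative.
    """
    rng = np.random.default_rng(42)
    n_bg = 300
    bg = pd.DataFrame(
        {"x": rng.uniform(0, 10, n_bg), "noise": rng.uniform(0, 1, n_bg)}
    )
    pres = pd.DataFrame(
        {"x": rng.uniform(7, 10, 40), "noise": rng.uniform(0, 1, 40)}
    )
    return pres, bg


@pytest.fixture(scope="session")
def virtual_study():
    """A seeded virtual species: stack, truth, thinned presence table."""
    cfg = VirtualSpeciesConfig(seed=11, n_rows=60, n_cols=60)
    stack = generate_env_stack(cfg)
    truth = true_suitability(stack, cfg)
    occ = sample_occurrences(truth, 150, seed=12)
    return cfg, stack, truth, occ
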