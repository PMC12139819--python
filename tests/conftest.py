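import numpy as np
import pytest

from zigrow.model_design import DesignMatrices, ModelSpec, build_design
from zigrow.synthetic_data import SimConfig, simulate_trial
from zigrow.zig_engine import FitControl, fit_zig


def make_toy_design(
    n,
    factors_levels,
    zi=True,
    kc=2,
    seed=11,
    zero_frac=0.3,
    rng=None,
):
    """A small hand-made design for engine tests (not via trial tables)."""
    r = rng or np.random.default_rng(seed)
    cols = [np.ones(n)] + [r.normal(size=n) for _ in range(kc - 1)]
    X = np.column_stack(cols)
    codes = {f: r.integers(0, L, n) for f, L in factors_levels.items()}
    y = np.abs(r.normal(1.5, 1.0, n)) + 0.1
    if zi:
        y = np.where(r.random(n) < zero_frac, 0.0, y)
    names = tuple(f"x{i}" for i in range(kc))
    return DesignMatrices(
        y=y,
        is_zero=(y == 0),
        X=X,
        columns=names,
        X_zi=X if zi else None,
        columns_zi=names if zi else (),
        factors=tuple(factors_levels),
        codes=codes,
        n_levels=dict(factors_levels),
        level_labels={f: list(range(L)) for f, L in factors_levels.items()},
        scaling=None,
        spec=None,
    )


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_genotypes=15, n_gardens=8)


@pytest.fixture(scope="session")
def small_trial(small_cfg):
    return simulate_trial(small_cfg, 7)


@pytest.fixture(scope="session")
def small_fit(small_trial):
    data, _ = small_trial
    design = build_design(data, ModelSpec(variant="full"))
    return fit_zig(design, FitControl())


@pytest.fixture(scope="session")
def default_trial():
    return simulate_trial(SimConfig(), 1)
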