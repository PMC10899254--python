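import numpy as np
import pandas as pd
import pytest

from mbcwarm import (
    WarmingSimConfig,
    WorldSimConfig,
    generate_warming_pairs,
    generate_world,
    log_response_ratio,
)


@pytest.fixture(scope="session")
def warming_pairs() -> pd.DataFrame:
    """Default 130-pair world, no publication bias."""
    return generate_warming_pairs(WarmingSimConfig(seed=42))


@pytest.fixture(scope="session")
def effects(warming_pairs) -> pd.DataFrame:
    return log_response_ratio(warming_pairs)


@pytest.fixture(scope="session")
def small_world():
    """A small spatial world for fast structural tests."""
    cfg = WorldSimConfig(n_cells=400, n_obs=200, seed=7)
    obs, grid = generate_world(cfg)
    return cfg, obs, grid


def gaussian_predictor_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """IID-Gaussian predictor table (for distributional mask checks where the
    chi-square geometry must actually hold)."""
    from mbcwarm.simulate import CONTINUOUS_PREDICTORS, LAND_COVER_CLASSES

    df = pd.DataFrame(
        rng.standard_normal((n, len(CONTINUOUS_PREDICTORS))),
        columns=list(CONTINUOUS_PREDICTORS),
    )
    df["land_cover"] = rng.choice(LAND_COVER_CLASSES, n)
    return df
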