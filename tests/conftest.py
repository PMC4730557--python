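import numpy as np
import pandas as pd
import pytest

from rsfa.fluctuation import MOTION_COLUMNS, BoldRun
from rsfa.simulate import (
    GeneratorConfig,
    default_region_labels,
    generate_cohort,
    masks_from_labels,
)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Desk-scale study configuration shared across tests."""
    return GeneratorConfig(n_participants=8, seed=123, grid_shape=(16, 16, 4), n_volumes=250)


@pytest.fixture(scope="session")
def small_cohort(small_config) -> pd.DataFrame:
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def region_masks(small_config) -> dict:
    return masks_from_labels(default_region_labels(small_config.grid_shape))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def toy_bold_run(
    t: int = 120,
    tr: float = 1.97,
    grid=(6, 5, 4),
    seed: int = 0,
    constant_motion: bool = False,
) -> BoldRun:
    """A small hand-made run: white-noise voxels, simple masks, random-walk motion."""
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((*grid, t))
    gm = np.zeros(grid, dtype=bool)
    wm = np.zeros(grid, dtype=bool)
    csf = np.zeros(grid, dtype=bool)
    gm[:4] = True
    wm[4] = True
    csf[5] = True
    if constant_motion:
        motion = pd.DataFrame(np.ones((t, 6)) * 0.1, columns=MOTION_COLUMNS)
    else:
        walk = np.cumsum(rng.normal(0, 0.01, size=(t, 6)), axis=0)
        motion = pd.DataFrame(walk, columns=MOTION_COLUMNS)
    return BoldRun(data=data, tr=tr, gm_mask=gm, wm_mask=wm, csf_mask=csf, motion=motion)
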