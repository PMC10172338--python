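"""Shared fixtures: all data is generated programmatically at test time."""

import numpy as np
import pytest

from nicheshift.survey_data import build_count_table
from nicheshift.synthetic_scene import SceneSpec, make_scene


@pytest.fixture(scope="session")
def scene():
    """Default synthetic scene: 6 strata x 7 grids x 3 transects, seed 2."""
    return make_scene(SceneSpec(seed=2))


@pytest.fixture(scope="session")
def count_table(scene):
    return build_count_table(scene.records, scene.design, scene.stack)


@pytest.fixture(scope="session")
def marula_adult_fit(count_table):
    from nicheshift.abundance_model import ModelSpec, fit_zinb_glmm

    return fit_zinb_glmm(ModelSpec("marula", "adult"), count_table)


@pytest.fixture()
def toy_zinb_data():
    """Tiny grouped count data (3 grids x 3 transects) for likelihood oracles."""
    rng = np.random.default_rng(7)
    y = np.array([0, 2, 1, 0, 0, 5, 3, 0, 1])
    x = rng.uniform(-1, 1, size=9)
    gidx = np.repeat(np.arange(3), 3)
    return y, x, gidx
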