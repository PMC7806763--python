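import numpy as np
import pandas as pd
import pytest

from halluconn.atlas import generate_atlas
from halluconn.cohort import PlantedEffect, generate_cohort, generate_timeseries
from halluconn.connectome import as_weight_stack, build_connectomes


@pytest.fixture(scope="session")
def atlas10():
    return generate_atlas(10, "custom", seed=7)


@pytest.fixture(scope="session")
def aal90():
    return generate_atlas(90, "aal90-lobes")


@pytest.fixture(scope="session")
def small_cohort(atlas10):
    """Two groups of 20 with one strong planted increase on a 3-edge path."""
    subjects = generate_cohort({"HC": 20, "SCZ-H": 20}, seed=11)
    effect = PlantedEffect("SCZ-H", ((0, 1), (1, 2), (2, 3)), "increase", 0.5)
    ts = generate_timeseries(subjects, atlas10, [effect], timepoints=256, seed=12)
    return subjects, ts


@pytest.fixture(scope="session")
def small_connectomes(small_cohort):
    subjects, ts = small_cohort
    mats = build_connectomes(ts)
    return subjects, as_weight_stack(mats)


def random_symmetric(n, rng, density=1.0):
    """Random symmetric weight matrix in [0,1], zero diagonal."""
    W = rng.uniform(0.05, 1.0, size=(n, n))
    if density < 1.0:
        keep = rng.random((n, n)) < density
        W = W * keep
    W = np.triu(W, 1)
    return W + W.T
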