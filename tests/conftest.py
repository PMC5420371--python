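"""Shared fixtures: small simulated datasets, reused across test modules."""

import numpy as np
import pytest

from semdif.generate import make_hads_like_spec, simulate
from semdif.stage1 import run_stage1

BASE_SEED = 20260101


@pytest.fixture(scope="session")
def mg_clean_data():
    """Two groups, 7 items, no DIF, equal latent distributions."""
    spec = make_hads_like_spec("no_dif")
    return simulate(spec, n_per_group=800, seed=BASE_SEED)


@pytest.fixture(scope="session")
def mg_dif_data():
    """Two groups, 7 items, uniform DIF of 0.5 SD on item3."""
    spec = make_hads_like_spec("uniform_dif", dif_size=0.5, dif_items=(2,))
    return simulate(spec, n_per_group=1000, seed=BASE_SEED + 1)


@pytest.fixture(scope="session")
def md_data():
    """One group, 14 items, two factors, gender + age violators, DIF of
    0.35 on item5 from age."""
    from semdif.generate import DifDef
    spec = make_hads_like_spec("two_factor_14")
    spec.dif_defs = [DifDef(item=4, violator="age", kind="uniform", size=0.35)]
    return simulate(spec, n_per_group=1500, seed=BASE_SEED + 2)


@pytest.fixture(scope="session")
def mg_clean_stage1(mg_clean_data):
    return run_stage1(mg_clean_data, design="multigroup")


@pytest.fixture(scope="session")
def mg_dif_stage1(mg_dif_data):
    return run_stage1(mg_dif_data, design="multigroup")


@pytest.fixture(scope="session")
def md_stage1(md_data):
    return run_stage1(md_data, design="single",
                      covariate_names=["gender", "age"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(BASE_SEED)
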