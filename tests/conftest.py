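import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

from topoprofile.atlas import RegionAtlas

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")
from topoprofile.cohort import LongitudinalCohort, ZScoreCohort
from topoprofile.synthetic import make_design


@pytest.fixture(scope="session")
def design_full():
    """Full-size synthetic study design: 82 lateralized regions, 41 bilateral."""
    conn, atlas, design = make_design(V=82, seed=1)
    return conn, atlas, design


@pytest.fixture(scope="session")
def design_small():
    """Small synthetic design for fast unit tests (20 regions, 10 bilateral)."""
    conn, atlas, design = make_design(V=20, seed=2)
    return conn, atlas, design


@pytest.fixture()
def toy_atlas():
    """Four-region atlas: one bilateral pair plus two midline regions."""
    return RegionAtlas(
        names=("hip_L", "hip_R", "mid_a", "mid_b"),
        hemisphere=("left", "right", "midline", "midline"),
        pair_id=("hip", "hip", "mid_a", "mid_b"),
        coords=np.array([[-20.0, 0, 0], [20.0, 0, 0], [0, 10.0, 0], [0, -10.0, 5.0]]),
    )


def build_cohort(values, subjects, ages, regions, groups, covariates=None):
    """Assemble a LongitudinalCohort from parallel per-visit lists."""
    idx = pd.MultiIndex.from_arrays([subjects, ages], names=["subject", "age"])
    volumes = pd.DataFrame(np.asarray(values, float), index=idx, columns=regions)
    cov = (
        pd.DataFrame(covariates, index=idx)
        if covariates is not None
        else pd.DataFrame(index=idx)
    )
    return LongitudinalCohort(volumes=volumes, covariates=cov, groups=pd.Series(groups))


def build_zcohort(values, subjects, ages, regions, groups=None):
    idx = pd.MultiIndex.from_arrays([subjects, ages], names=["subject", "age"])
    volumes = pd.DataFrame(np.asarray(values, float), index=idx, columns=regions)
    ids = list(dict.fromkeys(subjects))
    grp = groups if groups is not None else pd.Series("patient", index=ids)
    return ZScoreCohort(
        volumes=volumes, covariates=pd.DataFrame(index=idx), groups=grp
    )
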