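import numpy as np
import pandas as pd
import pytest

import radrobust as rr
from radrobust.image import CtVolume, LesionMask


@pytest.fixture(scope="session")
def sphere_lesion():
    """A 20 mm effective-diameter HU-0 sphere on the default grid, air background."""
    [(spec, volume, mask)] = rr.generate_phantom_lesions(
        specs=[rr.LesionSpec(20.0, "spherical", 0.0)], background_hu=-1000.0
    )
    return spec, volume, mask


@pytest.fixture(scope="session")
def small_sphere_lesion():
    """A 10 mm effective-diameter HU-0 sphere."""
    [(spec, volume, mask)] = rr.generate_phantom_lesions(
        specs=[rr.LesionSpec(10.0, "spherical", 0.0)], background_hu=-1000.0
    )
    return spec, volume, mask


@pytest.fixture()
def cohort_table():
    config = rr.CohortConfig(
        n_wildtype=20,
        n_mutant=26,
        feature_specs={
            "f_strong": rr.FeatureSpec(0.0, 2.0, 1.0),
            "f_null": rr.FeatureSpec(0.0, 0.0, 1.0),
        },
        seed=11,
    )
    return rr.generate_cohort_table(config)


@pytest.fixture()
def phantom_table():
    rng = np.random.default_rng(5)
    base = pd.DataFrame(
        {"f_strong": rng.normal(0, 1, 24), "f_null": rng.normal(0, 1, 24)}
    )
    return rr.generate_phantom_table(
        24, rr.default_scan_conditions(), base, noise_scale=0.2, seed=6
    )


def make_volume(values, spacing=(1.0, 1.0, 1.0)):
    return CtVolume(np.asarray(values, dtype=float), spacing)


def make_mask(membership, spacing=(1.0, 1.0, 1.0)):
    return LesionMask(np.asarray(membership, dtype=bool), spacing)
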