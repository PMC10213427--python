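import warnings

import numpy as np
import pytest
from sklearn.exceptions import ConvergenceWarning

from mfdfc import CohortSpec, band_table, generate_cohort, make_scheme

warnings.filterwarnings("ignore", category=ConvergenceWarning)


@pytest.fixture(scope="session")
def bands_tr2():
    """The seven clipped N3L bands at TR = 2 s, 142 points, 4096 padding."""
    return band_table(2.0, 142, 4096)


@pytest.fixture(scope="session")
def slow4(bands_tr2):
    return next(b for b in bands_tr2 if b.name == "Slow-4")


@pytest.fixture(scope="session")
def slow5(bands_tr2):
    return next(b for b in bands_tr2 if b.name == "Slow-5")


@pytest.fixture(scope="session")
def combined_scheme():
    return make_scheme("Combined")


@pytest.fixture(scope="session")
def small_cohort():
    """8+8 subjects, 10 ROIs, full-length series, with one effect of each kind."""
    spec = CohortSpec(
        n_per_group=8,
        n_rois=10,
        n_timepoints=142,
        noise_sd=0.3,
        seed=42,
        falff_effects=((3, "Slow-5", 2.0),),
        dfc_effects=((1, 6, "Slow-4", 0.8, 0.0),),
    )
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
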