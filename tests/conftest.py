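import numpy as np
import pytest

from mcifs.io import combine_tissues
from mcifs.synthetic import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale planted cohort: 50 patients, 60 probes/tissue, 4+3 planted."""
    spec = SyntheticSpec(d=60, planted_tumor=4, planted_adjacent=3, effect=2.0, seed=3)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_combined(small_cohort):
    tumor, adjacent, ann, _ = small_cohort
    return combine_tissues(tumor, adjacent, ann)


@pytest.fixture(scope="session")
def small_truth(small_cohort):
    return small_cohort[3]


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
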