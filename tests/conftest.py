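import logging

import numpy as np
import pandas as pd
import pytest

from hmolink import CohortSimParams, make_fixture_cohort, simulate_cohort

logging.getLogger("hmolink").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 152-sample cohort with the printed status counts."""
    return make_fixture_cohort()


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-sample noisy cohort reused across statistics tests."""
    return simulate_cohort(CohortSimParams(n_samples=300, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_matrix(dosages, sample_prefix="T"):
    """Build a GenotypeMatrix from a dict rsid -> list of dosages."""
    from hmolink import GenotypeMatrix

    df = pd.DataFrame(
        {k: [np.nan if v is None else float(v) for v in vals]
         for k, vals in dosages.items()}
    )
    df.index = [f"{sample_prefix}{i}" for i in range(len(df))]
    return GenotypeMatrix(df)
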