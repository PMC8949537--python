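import numpy as np
import pandas as pd
import pytest

from dietcausal import CohortTruth, GwasTruth, generate_cohort, generate_gwas_pair
from dietcausal.mr import harmonize, select_instruments


@pytest.fixture(scope="session")
def pairwise_cohort() -> pd.DataFrame:
    """Continuous-outcome cohort with known paths a=0.5, b=0.3, c'=0.2."""
    truth = CohortTruth(
        n=20_000, a_coefs=(0.5,), b_coefs=(0.3,), c_prime=0.2, seed=1
    )
    return generate_cohort(truth)


@pytest.fixture(scope="session")
def serial_cohort() -> pd.DataFrame:
    """Serial cohort where only the chained path a1*d*b2 = 0.06 is active."""
    truth = CohortTruth(
        n=20_000,
        a_coefs=(0.5, 0.0),
        b_coefs=(0.0, 0.3),
        c_prime=0.0,
        d_coef=0.4,
        seed=7,
    )
    return generate_cohort(truth)


@pytest.fixture(scope="session")
def strong_instruments():
    """Harmonized set of strong, valid instruments with theta = 0.2."""
    rng = np.random.default_rng(11)
    truth = GwasTruth(
        k_snps=50,
        theta=0.2,
        gamma=rng.uniform(0.05, 0.15, 50),
        seed=11,
        palindromic_fraction=0.0,
    )
    exp_set, out_set = generate_gwas_pair(truth)
    return harmonize(select_instruments(exp_set, p_threshold=1.0), out_set)
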