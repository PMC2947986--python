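import numpy as np
import pandas as pd
import pytest

import imtrisk as ir


def genotype_categories(cohort_or_columns):
    cols = (cohort_or_columns.genotypes.columns
            if hasattr(cohort_or_columns, "genotypes") else cohort_or_columns)
    return {c: (0, 1, 2) for c in cols}


@pytest.fixture(scope="session")
def null_cohort():
    """Small cohort with no planted genetic effects."""
    return ir.generate_cohort(400, seed=11)


@pytest.fixture(scope="session")
def small_panel():
    return ir.default_panel(n_snps=20, n_established=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_features(rng_seed=5):
    """120 subjects, 3 genotype columns + 2 numeric columns, binary labels."""
    rng = np.random.default_rng(rng_seed)
    n = 120
    X = pd.DataFrame({
        "snpA": rng.integers(0, 3, n),
        "snpB": rng.integers(0, 3, n),
        "snpC": rng.integers(0, 3, n),
        "age": rng.normal(30, 5, n),
        "bmi": rng.normal(25, 4, n),
    }, index=[f"s{i}" for i in range(n)])
    y = rng.integers(0, 2, n)
    # make snpA informative
    X.loc[y == 1, "snpA"] = rng.choice(3, size=int((y == 1).sum()), p=[0.1, 0.3, 0.6])
    return X, y
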