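import numpy as np
import pandas as pd
import pytest

import cortigen as cg


@pytest.fixture(scope="session")
def cohort():
    return cg.generate_cohort(seed=11)


@pytest.fixture(scope="session")
def features(cohort):
    return cg.generate_features(cohort, cg.EffectConfig(seed=11))


@pytest.fixture(scope="session")
def null_features(cohort):
    return cg.generate_features(cohort, cg.EffectConfig(seed=11).null())


@pytest.fixture(scope="session")
def covars(cohort):
    return cohort[["age", "sex", "education"]]


def ols_oracle(y, X):
    """Brute-force normal-equations OLS: beta, t, two-sided p per column."""
    from scipy import stats

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return beta, t, p
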