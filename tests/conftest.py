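import warnings

import numpy as np
import pandas as pd
import pytest

from dietnet.cohort import default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """800-participant synthetic cohort with a little missingness."""
    return generate_cohort(default_config(n_participants=800, seed=11, missing_rate=0.01))


@pytest.fixture(scope="session")
def clean_cohort():
    """Complete 1500-participant cohort (no missing cells)."""
    return generate_cohort(default_config(n_participants=1500, seed=5, missing_rate=0.0))


from dietnet.benchmarks import mixed_mrf_spec as mrf_spec  # noqa: E402
from dietnet.benchmarks import planted_mixed_mrf  # noqa: E402


def chain_gaussian_table(n: int, p: int, rho: float, seed: int) -> pd.DataFrame:
    """Continuous table whose precision is a chain with off-diagonal -rho."""
    prec = np.eye(p)
    for i in range(p - 1):
        prec[i, i + 1] = prec[i + 1, i] = -rho
    cov = np.linalg.inv(prec)
    rng = np.random.default_rng(seed)
    X = rng.multivariate_normal(np.zeros(p), cov, size=n, method="cholesky")
    return pd.DataFrame(X, columns=[f"v{i}" for i in range(p)])


@pytest.fixture(autouse=True)
def _quiet_sklearn():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning)
        yield
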