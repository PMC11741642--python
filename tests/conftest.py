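import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset(rng):
    """Individual-level regression instance with sparse multivariate effects.

    Phenotypes are variance-standardized (yᵀy = n − 1 after centering) so the
    summary-statistic recovery convention applies exactly.
    """
    n, p, r = 400, 30, 3
    X = rng.binomial(2, 0.3, size=(n, p)).astype(float)
    B = np.zeros((p, r))
    causal = rng.choice(p, 5, replace=False)
    B[causal] = rng.standard_normal((5, r)) * 0.4
    Y = X @ B + rng.standard_normal((n, r))
    Yc = Y - Y.mean(axis=0)
    Ys = Yc / Yc.std(axis=0, ddof=1)
    return X, Ys, B
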