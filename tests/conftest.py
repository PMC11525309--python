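import numpy as np
import pandas as pd
import pytest

from mspe import linear_sem_spec


def population_theta(spec):
    """Free-parameter vector of the linear four-factor model at its
    population values (structural paths .2/.5/.3/.4/.3, loadings [1,.8,.7],
    phi12 = .5, standardized latents, equal indicator residuals .36)."""
    vals = {
        "gamma11": 0.2,
        "gamma12": 0.5,
        "beta21": 0.3,
        "gamma21": 0.4,
        "gamma22": 0.3,
        "phi1": 1.0,
        "phi2": 1.0,
        "phi12": 0.5,
        # standardizing residual variances at phi12 = .5
        "psi1": 1 - (0.04 + 0.25 + 0.10),
        "psi2": 0.324,
    }
    theta = []
    for label in spec.param_labels:
        mat, i, j = spec.labels[label]
        if label in vals:
            theta.append(vals[label])
        elif mat == "lam":
            theta.append(0.8 if i % 3 == 1 else 0.7)
        elif mat == "theta":
            theta.append(0.36)
        else:
            raise AssertionError(label)
    return np.array(theta)


@pytest.fixture(scope="session")
def study1_spec():
    return linear_sem_spec()


@pytest.fixture(scope="session")
def study1_theta0(study1_spec):
    return population_theta(study1_spec)


def exact_cov_data(sigma: np.ndarray, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Data whose sample covariance (divisor n) equals sigma exactly:
    random draws are whitened empirically, then colored by chol(sigma)."""
    p = sigma.shape[0]
    z = rng.standard_normal((n, p))
    z = z - z.mean(axis=0)
    s = z.T @ z / n
    z = z @ np.linalg.inv(np.linalg.cholesky(s)).T
    x = z @ np.linalg.cholesky(sigma).T
    cols = [f"x{i+1}" for i in range(6)] + [f"y{i+1}" for i in range(6)]
    return pd.DataFrame(x, columns=cols[:p])
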