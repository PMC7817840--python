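import numpy as np
import pytest

from infoscale import popsim


def make_exact_dataset(mean1, mean2, sigma, T, conditions=(0.0, 45.0)):
    """Two-condition dataset whose *sample* moments equal the given values.

    Trials are constructed so each condition has exactly the requested mean
    and sample covariance (ddof=1): a random matrix is centered, whitened by
    its own sample covariance factor, and recolored by chol(sigma).
    """
    mean1 = np.atleast_1d(np.asarray(mean1, dtype=float))
    mean2 = np.atleast_1d(np.asarray(mean2, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    n = mean1.size
    if T < n + 2:
        raise ValueError("need T >= n + 2 for exact moment construction")
    rng = np.random.default_rng(1234)
    target = np.linalg.cholesky(sigma)
    responses = []
    for mean in (mean1, mean2):
        z = rng.standard_normal((T, n))
        z -= z.mean(axis=0)
        s = np.cov(z, rowvar=False, ddof=1)
        z = z @ np.linalg.inv(np.linalg.cholesky(np.atleast_2d(s))).T @ target.T
        responses.append(mean + z)
    return popsim.TrialDataset(conditions=np.asarray(conditions, float), responses=responses)


@pytest.fixture(scope="session")
def gt_small():
    """12-neuron limited-information population with diagonal base noise."""
    cfg = popsim.PopulationConfig(n_neurons=12, i_inf=5.0, sigma0_kind="diagonal")
    return popsim.make_population(cfg, seed=101)


@pytest.fixture(scope="session")
def ds_small(gt_small):
    return popsim.sample_trials(gt_small, T=80, seed=102)


@pytest.fixture(scope="session")
def gt_corr():
    """Correlated (limited-range) population used for estimator checks."""
    cfg = popsim.PopulationConfig(n_neurons=20, i_inf=8.0, sigma0_kind="limited_range")
    return popsim.make_population(cfg, seed=103)


@pytest.fixture(scope="session")
def ds_corr(gt_corr):
    return popsim.sample_trials(gt_corr, T=150, seed=104)
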