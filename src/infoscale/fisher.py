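"""Generalized linear Fisher information: estimation and ideal-observer units.

The linear Fisher information for discriminating two stimuli is

    I = f'^T Sigma^-1 f',    f' = (f(theta2) - f(theta1)) / dtheta,

the information recoverable by the optimal linear decoder.  For coarse
discriminations this equals (d'/dtheta)^2 with d' from signal detection
theory.  The plug-in estimate from empirical moments is biased upward; the
bias-corrected estimator

    I_bc = I_naive * (2T - N - 3) / (2T - 2)  -  2N / (T dtheta^2)

is exactly unbiased under Gaussian sampling with T trials per condition and
the pooled (average) condition covariance.  Its sampling variance follows in
closed form from the noncentral-F distribution of the plug-in statistic and
is implemented here as the analytic variance backend.

All information values are rad^-2; thresholds cross the API in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.stats import norm

from .popsim import TrialDataset

__all__ = [
    "InfoEstimate",
    "empirical_moments",
    "naive_info",
    "bias_corrected_info",
    "info_estimate_variance",
    "optimal_decoder",
    "threshold_from_info",
    "info_for_threshold",
    "prob_correct",
]

_COND_WARN = 1e10


@dataclass(frozen=True)
class InfoEstimate:
    """A Fisher information estimate with its sampling variance.

    ``value`` may be negative after bias correction (unbiasedness is traded
    for positivity); ``variance`` is the estimator's sampling variance.
    """

    value: float            # rad^-2
    variance: float         # (rad^-2)^2
    n_neurons: int
    n_trials: int           # per condition
    delta_theta: float      # radians
    bias_corrected: bool = True

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("estimator variance must be nonnegative")
        if self.bias_corrected and self.n_neurons > 2 * self.n_trials - 4:
            raise ValueError("bias correction requires N <= 2T - 4")

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


def _resolve_subset(ds: TrialDataset, subset: Sequence[int] | None) -> np.ndarray:
    if subset is None:
        return np.arange(ds.n_neurons)
    idx = np.asarray(subset, dtype=int)
    if idx.size == 0:
        raise ValueError("subset must be nonempty")
    return idx


def empirical_moments(
    ds: TrialDataset, subset: Sequence[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical discrimination moments (f'_hat, Sigma_hat).

    f'_hat = (mean(r|theta2) - mean(r|theta1)) / dtheta, in activity units
    per radian; Sigma_hat is the average of the two per-condition sample
    covariances (ddof=1), pooling 2T - 2 degrees of freedom.
    """
    if ds.n_conditions != 2:
        raise ValueError("a two-condition dataset is required; use select_pair()")
    idx = _resolve_subset(ds, subset)
    r1 = ds.responses[0][:, idx]
    r2 = ds.responses[1][:, idx]
    if r1.shape[0] != r2.shape[0]:
        raise ValueError("trial counts must match across the two conditions")
    if r1.shape[0] < 2:
        raise ValueError("at least 2 trials per condition are required")
    dtheta = ds.delta_theta
    f_prime = (r2.mean(axis=0) - r1.mean(axis=0)) / dtheta
    sigma = 0.5 * (np.cov(r1, rowvar=False, ddof=1) + np.cov(r2, rowvar=False, ddof=1))
    sigma = np.atleast_2d(sigma)
    return f_prime, sigma


def _solve_spd(sigma: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Cholesky solve with a singularity error advising more trials."""
    try:
        c, low = cho_factor(sigma)
    except (LinAlgError, np.linalg.LinAlgError) as err:
        raise ValueError(
            "covariance is singular or not positive definite; Fisher information "
            "needs T per condition comfortably above the neuron count "
            "(T >= N + margin)"
        ) from err
    diag = np.diag(c)
    cond_est = (diag.max() / diag.min()) ** 2
    if cond_est > _COND_WARN:
        import warnings

        warnings.warn(
            f"covariance condition number ~{cond_est:.2e} exceeds {_COND_WARN:.0e}; "
            "information estimates may be unstable",
            RuntimeWarning,
            stacklevel=3,
        )
    return cho_solve((c, low), rhs)


def naive_info(f_prime: np.ndarray, sigma: np.ndarray) -> float:
    """Plug-in linear Fisher information f'^T Sigma^-1 f' (rad^-2).

    Invariant under any invertible linear transform applied jointly to f'
    and Sigma.  Uses a linear solve, never an explicit inverse.
    """
    f_prime = np.asarray(f_prime, dtype=float)
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    return float(f_prime @ _solve_spd(sigma, f_prime))


def _bc_constants(N: int, T: int, dtheta: float) -> tuple[float, float]:
    factor = (2 * T - N - 3) / (2 * T - 2)
    subtract = 2.0 * N / (T * dtheta**2)
    return factor, subtract


def bias_corrected_info(
    ds: TrialDataset,
    subset: Sequence[int] | None = None,
    variance_method: str = "analytic",
) -> InfoEstimate:
    """Bias-corrected Fisher information estimate with sampling variance.

    Requires 2T - N - 3 > 0.  The returned value is unbiased under the
    Gaussian sampling model and may be negative for weakly informative
    populations.
    """
    idx = _resolve_subset(ds, subset)
    N = idx.size
    T = ds.n_trials
    if 2 * T - N - 3 <= 0:
        raise ValueError(f"bias correction undefined: need N < 2T - 3 (N={N}, T={T})")
    f_hat, s_hat = empirical_moments(ds, idx)
    raw = naive_info(f_hat, s_hat)
    dtheta = ds.delta_theta
    factor, subtract = _bc_constants(N, T, dtheta)
    value = raw * factor - subtract
    if variance_method == "analytic":
        variance = _analytic_variance(value, N, T, dtheta)
    else:
        variance = info_estimate_variance(ds, idx, method=variance_method)
    return InfoEstimate(
        value=float(value),
        variance=float(variance),
        n_neurons=int(N),
        n_trials=int(T),
        delta_theta=float(dtheta),
        bias_corrected=True,
    )


def _analytic_variance(info_bc: float, N: int, T: int, dtheta: float) -> float:
    """Exact Gaussian-model variance of the bias-corrected estimator.

    With m = T*dtheta^2/2, the plug-in statistic m*I_naive is a Hotelling
    T-squared, i.e. a scaled noncentral F(N, 2T-N-1, m*I); propagating the
    noncentral-F variance through the bias correction gives

        Var = 2[(N + mI)^2 + (N + 2mI)(2T-N-3)] / (m^2 (2T-N-5)),

    evaluated at the plug-in lambda = m*max(I_bc, 0).
    """
    if 2 * T - N - 5 <= 0:
        raise ValueError("analytic variance requires N < 2T - 5")
    m = T * dtheta**2 / 2.0
    lam = m * max(info_bc, 0.0)
    num = (N + lam) ** 2 + (N + 2.0 * lam) * (2 * T - N - 3)
    return 2.0 * num / (m**2 * (2 * T - N - 5))


def info_estimate_variance(
    ds: TrialDataset,
    subset: Sequence[int] | None = None,
    method: str = "analytic",
    n_boot: int = 500,
    seed: int = 0,
) -> float:
    """Sampling variance of the bias-corrected information estimate.

    ``method="analytic"`` uses the closed form from the noncentral-F sampling
    distribution; ``method="bootstrap"`` resamples trials with replacement
    within each condition (``n_boot`` resamples) and returns the variance of
    the re-estimated values.
    """
    idx = _resolve_subset(ds, subset)
    N = idx.size
    T = ds.n_trials
    dtheta = ds.delta_theta
    if method == "analytic":
        f_hat, s_hat = empirical_moments(ds, idx)
        factor, subtract = _bc_constants(N, T, dtheta)
        value = naive_info(f_hat, s_hat) * factor - subtract
        return _analytic_variance(value, N, T, dtheta)
    if method == "bootstrap":
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB007]))
        r1 = ds.responses[0][:, idx]
        r2 = ds.responses[1][:, idx]
        factor, subtract = _bc_constants(N, T, dtheta)
        vals = np.empty(n_boot)
        for b in range(n_boot):
            i1 = rng.integers(0, T, T)
            i2 = rng.integers(0, T, T)
            x1, x2 = r1[i1], r2[i2]
            f_hat = (x2.mean(axis=0) - x1.mean(axis=0)) / dtheta
            s_hat = 0.5 * (
                np.cov(x1, rowvar=False, ddof=1) + np.cov(x2, rowvar=False, ddof=1)
            )
            vals[b] = naive_info(f_hat, np.atleast_2d(s_hat)) * factor - subtract
        return float(vals.var(ddof=1))
    raise ValueError(f"unknown variance method: {method!r}")


def optimal_decoder(f_prime: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Optimal linear readout w = Sigma^-1 f', scaled so w^T f' = 1.

    With this normalization theta_hat = w^T (r - f(theta0)) + theta0 is an
    unbiased stimulus estimator with variance 1/I.
    """
    f_prime = np.asarray(f_prime, dtype=float)
    w = _solve_spd(np.atleast_2d(np.asarray(sigma, dtype=float)), f_prime)
    scale = w @ f_prime
    if scale == 0:
        raise ValueError("f' is orthogonal to Sigma^-1 f'; decoder undefined")
    return w / scale


def threshold_from_info(info: float, pc: float = 0.8) -> float:
    """Discrimination threshold (degrees) at probability-correct ``pc``.

    Delta_theta = Phi^-1(pc) * sqrt(2 / I), converted to degrees.
    """
    if info <= 0:
        raise ValueError("information must be positive to define a threshold")
    if not 0.5 < pc < 1:
        raise ValueError("pc must lie in (0.5, 1)")
    return float(np.rad2deg(norm.ppf(pc) * np.sqrt(2.0 / info)))


def info_for_threshold(threshold_deg: float, pc: float = 0.8) -> float:
    """Information (rad^-2) required for a given threshold in degrees."""
    if threshold_deg <= 0:
        raise ValueError("threshold must be positive")
    if not 0.5 < pc < 1:
        raise ValueError("pc must lie in (0.5, 1)")
    dtheta = np.deg2rad(threshold_deg)
    return float(2.0 * norm.ppf(pc) ** 2 / dtheta**2)


def prob_correct(info: float, delta_theta: float) -> float:
    """Ideal-observer probability of correct discrimination.

    Phi(delta_theta * sqrt(I/2)) with delta_theta in radians; 0.5 at zero
    information or zero separation, monotone in both arguments.
    """
    if info < 0:
        raise ValueError("information must be nonnegative")
    return float(norm.cdf(abs(delta_theta) * np.sqrt(info / 2.0)))
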