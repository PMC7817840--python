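"""Information-vs-population-size curves and ordering-based analyses.

Information estimates at nested population sizes share data and are strongly
correlated, but the information *increments* from adding one neuron at a time
are statistically independent across sizes.  The scaling curve is therefore
summarized by the across-ordering mean and variance of these increments,
(mu_N, sigma2_N), estimated by a bootstrap over random neuron orderings;
cumulative moments are exact running sums.

All prefix informations along one ordering are obtained from a single
Cholesky factorization of the permuted covariance: the Cholesky factor of a
leading principal submatrix is the leading block of the full factor, so with
L L^T = Sigma_perm and y = L^-1 f'_perm, the naive information of the first
k neurons is simply sum(y[:k]^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.stats import norm

from .popsim import TrialDataset
from .fisher import InfoEstimate, empirical_moments, _bc_constants, _analytic_variance

__all__ = [
    "ScalingCurve",
    "FixedOrderCurve",
    "increment_curve",
    "increment_curve_from_moments",
    "ordering_prefix_infos",
    "greedy_ordering",
    "save_ordering",
    "load_ordering",
    "fixed_order_curve",
    "capture_size",
    "info_difference_test",
    "threshold_equality_test",
]


@dataclass
class ScalingCurve:
    """Across-ordering increment moments of an information scaling curve."""

    mu: np.ndarray           # increment means, rad^-2, index N-1 -> size N
    sigma2: np.ndarray       # increment variances, (rad^-2)^2
    n_orderings: int
    ordering_policy: str     # {random, greedy, fixed}
    delta_theta: float       # radians
    n_trials: int | None = None
    label: str = ""
    bias_corrected: bool = True

    @property
    def n_max(self) -> int:
        return len(self.mu)

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(1, self.n_max + 1)

    @property
    def cum_mean(self) -> np.ndarray:
        """<I_N> = sum_{n<=N} mu_n (independent increments)."""
        return np.cumsum(self.mu)

    @property
    def cum_var(self) -> np.ndarray:
        """var(I_N) = sum_{n<=N} sigma2_n."""
        return np.cumsum(self.sigma2)

    @property
    def mean_increment(self) -> float:
        return float(self.mu.mean())

    @property
    def total_info(self) -> float:
        return float(self.mu.sum())

    def full_estimate(self) -> InfoEstimate:
        """Full-population estimate with across-ordering variance."""
        return InfoEstimate(
            value=self.total_info,
            variance=float(self.sigma2.sum()),
            n_neurons=self.n_max,
            n_trials=self.n_trials if self.n_trials is not None else self.n_max + 4,
            delta_theta=self.delta_theta,
            bias_corrected=self.bias_corrected,
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "N": self.sizes,
                "mu": self.mu,
                "sigma2": self.sigma2,
                "cum_mean": self.cum_mean,
                "cum_var": self.cum_var,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_csv(cls, path, delta_theta: float = np.deg2rad(45.0)) -> "ScalingCurve":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(
            mu=df["mu"].to_numpy(),
            sigma2=df["sigma2"].to_numpy(),
            n_orderings=0,
            ordering_policy="fixed",
            delta_theta=delta_theta,
        )


def ordering_prefix_infos(
    f_prime: np.ndarray,
    sigma: np.ndarray,
    ordering: np.ndarray,
    T: int | None = None,
    delta_theta: float | None = None,
    bias_corrected: bool = True,
) -> np.ndarray:
    """Information of every prefix of ``ordering`` (one Cholesky solve).

    Returns I_1 .. I_N along the ordering, bias-corrected when requested
    (which needs ``T`` and ``delta_theta``).
    """
    idx = np.asarray(ordering, dtype=int)
    sp = sigma[np.ix_(idx, idx)]
    L = np.linalg.cholesky(sp)
    y = solve_triangular(L, f_prime[idx], lower=True)
    naive = np.cumsum(y**2)
    if not bias_corrected:
        return naive
    if T is None or delta_theta is None:
        raise ValueError("bias correction needs T and delta_theta")
    k = np.arange(1, idx.size + 1)
    factor = (2 * T - k - 3) / (2 * T - 2)
    subtract = 2.0 * k / (T * delta_theta**2)
    return naive * factor - subtract


def increment_curve_from_moments(
    f_prime: np.ndarray,
    sigma: np.ndarray,
    T: int | None,
    delta_theta: float,
    n_orderings: int = 10_000,
    seed: int = 0,
    bias_corrected: bool = True,
    orderings: Sequence[Sequence[int]] | None = None,
    label: str = "",
) -> ScalingCurve:
    """Increment-moment curve from explicit discrimination moments.

    Orderings are permutations sampled without replacement within an ordering
    and with replacement across orderings; an explicit list of orderings can
    be supplied instead (e.g., for exhaustive enumeration on tiny problems).
    """
    n = f_prime.size
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x0DD5]))
    if orderings is None:
        iterator = (rng.permutation(n) for _ in range(n_orderings))
        count = n_orderings
    else:
        iterator = (np.asarray(o, dtype=int) for o in orderings)
        count = len(orderings)
    s = np.zeros(n)
    s2 = np.zeros(n)
    for ordering in iterator:
        infos = ordering_prefix_infos(
            f_prime, sigma, ordering, T=T, delta_theta=delta_theta,
            bias_corrected=bias_corrected,
        )
        inc = np.diff(infos, prepend=0.0)
        s += inc
        s2 += inc**2
    mu = s / count
    var = (s2 - count * mu**2) / max(count - 1, 1)
    return ScalingCurve(
        mu=mu,
        sigma2=np.maximum(var, 0.0),
        n_orderings=count,
        ordering_policy="random" if orderings is None else "fixed",
        delta_theta=delta_theta,
        n_trials=T,
        label=label,
        bias_corrected=bias_corrected,
    )


def increment_curve(
    ds: TrialDataset,
    n_orderings: int = 10_000,
    seed: int = 0,
    n_max: int | None = None,
    bias_corrected: bool = True,
    label: str = "",
) -> ScalingCurve:
    """Bootstrap over random neuron orderings on a two-condition dataset.

    Requires T per condition >= N_max + 4 so the bias correction is defined
    (with margin) at every population size.
    """
    T = ds.n_trials
    n = ds.n_neurons if n_max is None else int(n_max)
    if T < n + 4:
        raise ValueError(
            f"too few trials for N_max={n}: T >= N_max + 4 required "
            f"(maximum admissible N_max is {T - 4})"
        )
    f_hat, s_hat = empirical_moments(ds, np.arange(n) if n_max is not None else None)
    return increment_curve_from_moments(
        f_hat,
        s_hat,
        T=T,
        delta_theta=ds.delta_theta,
        n_orderings=n_orderings,
        seed=seed,
        bias_corrected=bias_corrected,
        label=label,
    )


def _greedy_gains(
    f_prime: np.ndarray,
    sigma: np.ndarray,
    selected: list[int],
    candidates: np.ndarray,
) -> np.ndarray:
    """Naive-information gain of adding each candidate to the selected set.

    I_{S+j} - I_S = (f_j - s_jS^T Sigma_S^-1 f_S)^2 / (s_jj - s_jS^T Sigma_S^-1 s_jS).
    """
    if not selected:
        return f_prime[candidates] ** 2 / np.diag(sigma)[candidates]
    S = np.asarray(selected, dtype=int)
    L = np.linalg.cholesky(sigma[np.ix_(S, S)])
    rhs = np.concatenate([f_prime[S, None], sigma[np.ix_(S, candidates)]], axis=1)
    y = solve_triangular(L, rhs, lower=True)
    u, V = y[:, 0], y[:, 1:]
    num = (f_prime[candidates] - u @ V) ** 2
    den = np.diag(sigma)[candidates] - np.einsum("ij,ij->j", V, V)
    return num / np.maximum(den, np.finfo(float).tiny)


def greedy_ordering(
    datasets: TrialDataset | Sequence[TrialDataset],
    objective: str = "single",
) -> np.ndarray:
    """Order neurons by incrementally adding the largest information increase.

    ``objective="single"`` maximizes the (naive) information gain for one
    discrimination; ``"average"`` maximizes the mean gain across several
    discriminations sharing the same neuron set.  Candidate ranking uses the
    naive (not bias-corrected) information; ties break to the lowest index.
    """
    if isinstance(datasets, TrialDataset):
        datasets = [datasets]
    if objective not in ("single", "average"):
        raise ValueError("objective must be 'single' or 'average'")
    if objective == "single" and len(datasets) != 1:
        raise ValueError("objective 'single' takes exactly one discrimination")
    n_set = {ds.n_neurons for ds in datasets}
    if len(n_set) != 1:
        raise ValueError("all discriminations must share the neuron set")
    n = n_set.pop()
    moments = [empirical_moments(ds) for ds in datasets]
    selected: list[int] = []
    remaining = np.arange(n)
    while remaining.size:
        gains = np.mean(
            [_greedy_gains(f, s, selected, remaining) for f, s in moments], axis=0
        )
        best = remaining[int(np.argmax(gains))]  # argmax returns first max: lowest index
        selected.append(int(best))
        remaining = remaining[remaining != best]
    return np.asarray(selected, dtype=int)


def save_ordering(ordering: Sequence[int], path) -> None:
    """Write a neuron ordering as one 0-based index per line."""
    with open(path, "w") as fh:
        fh.writelines(f"{int(i)}\n" for i in ordering)


def load_ordering(path) -> np.ndarray:
    """Read a neuron ordering written by :func:`save_ordering`."""
    with open(path) as fh:
        idx = np.array([int(line) for line in fh if line.strip()], dtype=int)
    if len(np.unique(idx)) != len(idx):
        raise ValueError("ordering file contains duplicate indices")
    return idx


@dataclass
class FixedOrderCurve:
    """Scaling curve for one fixed neuron ordering with parametric bootstrap.

    No bias correction is applied (an N-dependent correction would fake an
    information drop at large N); uncertainty comes from re-sampling Gaussian
    increments with the estimator's mean and variance and re-summing.
    """

    ordering: np.ndarray
    point: np.ndarray         # naive information at each prefix size
    boot_curves: np.ndarray   # (n_boot, N)
    delta_theta: float
    label: str = ""

    @property
    def n_max(self) -> int:
        return self.point.size

    @property
    def boot_mean(self) -> np.ndarray:
        return self.boot_curves.mean(axis=0)

    @property
    def boot_sd(self) -> np.ndarray:
        return self.boot_curves.std(axis=0, ddof=1)


def fixed_order_curve(
    ds: TrialDataset,
    ordering: Sequence[int],
    n_boot: int = 1000,
    seed: int = 0,
) -> FixedOrderCurve:
    """Information scaling along a fixed ordering with bootstrap uncertainty."""
    ordering = np.asarray(ordering, dtype=int)
    T = ds.n_trials
    dtheta = ds.delta_theta
    f_hat, s_hat = empirical_moments(ds)
    naive = ordering_prefix_infos(f_hat, s_hat, ordering, bias_corrected=False)
    k = np.arange(1, ordering.size + 1)
    # estimator variance of the naive prefix estimates (analytic backend)
    var = np.empty_like(naive)
    for i, kk in enumerate(k):
        factor, subtract = _bc_constants(int(kk), T, dtheta)
        bc = naive[i] * factor - subtract
        var[i] = _analytic_variance(bc, int(kk), T, dtheta) / factor**2
    inc_mean = np.diff(naive, prepend=0.0)
    inc_var = np.maximum(np.diff(var, prepend=0.0), 0.0)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF1B0]))
    draws = inc_mean + np.sqrt(inc_var) * rng.standard_normal((n_boot, ordering.size))
    return FixedOrderCurve(
        ordering=ordering,
        point=naive,
        boot_curves=np.cumsum(draws, axis=1),
        delta_theta=dtheta,
    )


def capture_size(
    curve: FixedOrderCurve | ScalingCurve | np.ndarray,
    fraction: float = 0.9,
) -> tuple[int, tuple[int, int] | None]:
    """Smallest population size capturing ``fraction`` of the full information.

    Returns (size, ci) where ``size`` is the bootstrap median when bootstrap
    curves are available (FixedOrderCurve) and the point value otherwise, and
    ``ci`` is the bootstrap 95% interval or None.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")

    def _size(cum: np.ndarray) -> int:
        target = fraction * cum[-1]
        return int(np.argmax(cum >= target) + 1)

    if isinstance(curve, FixedOrderCurve):
        sizes = np.array([_size(c) for c in curve.boot_curves])
        lo, hi = np.percentile(sizes, [2.5, 97.5])
        return int(np.median(sizes)), (int(lo), int(hi))
    cum = curve.cum_mean if isinstance(curve, ScalingCurve) else np.asarray(curve, float)
    return _size(cum), None


def info_difference_test(estA: InfoEstimate, estB: InfoEstimate) -> float:
    """Probability that A - B < 0 under Gaussian estimate distributions.

    This is the probability of the one-sided null "A <= B"; swapping the
    arguments maps p to 1 - p.  With both variances zero and equal values the
    degenerate case returns 0.5 by convention.
    """
    diff = estA.value - estB.value
    s2 = estA.variance + estB.variance
    if s2 == 0.0:
        return 0.5 if diff == 0.0 else (0.0 if diff > 0 else 1.0)
    return float(norm.cdf(-diff / np.sqrt(s2)))


def threshold_equality_test(
    estimates: Sequence[InfoEstimate],
    n_boot: int = 100_000,
    seed: int = 0,
) -> float:
    """Bootstrap test that K information estimates share a common mean.

    Draws independent bootstrap sample sets of TS_H1 = sum_k (I_k - mu_k)^2
    and TS_H0 = sum_k (I_k - mu_bar)^2 with I_k ~ N(mu_k, sigma_k^2), and
    reports the two-sided tail probability 2*min(p, 1-p) of
    p = pr(TS_H1 - TS_H0 < 0).  Because the discrimination threshold is a
    monotone function of information, equality of thresholds is tested
    directly on the information estimates.  Degenerate zero-variance,
    equal-mean input returns 0.5 by convention.
    """
    if len(estimates) < 2:
        raise ValueError("at least two estimates are required")
    mu = np.array([e.value for e in estimates])
    sd = np.sqrt([e.variance for e in estimates])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7E57]))
    draws_h1 = mu + sd * rng.standard_normal((n_boot, mu.size))
    draws_h0 = mu + sd * rng.standard_normal((n_boot, mu.size))
    ts_h1 = ((draws_h1 - mu) ** 2).sum(axis=1)
    ts_h0 = ((draws_h0 - mu.mean()) ** 2).sum(axis=1)
    diff = ts_h1 - ts_h0
    if np.all(diff == 0.0):
        return 0.5
    p = float(np.mean(diff < 0.0))
    return 2.0 * min(p, 1.0 - p)
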