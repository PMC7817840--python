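"""Information-scaling models and Bayesian fits to increment curves.

Three nested models describe how linearly decodable information grows with
population size N:

* ``unlim``  : I_N = c N                       (one parameter, c)
* ``lim``    : I_N = 1 / (1/(cN) + 1/I_inf)    (c, I_inf)
* ``limexp`` : like lim but with an initially supralinear non-limiting part
               I_{0,N} = c (N + tau (exp(-N/tau) - 1))   (c, I_inf, tau)

The likelihood treats the measured increment means mu_n as independent
Gaussians around the model-predicted increments with the measured increment
variances - legitimate because information increments are uncorrelated
across N.  Parameters carry weakly informative half-line-truncated Cauchy
priors centered on empirical scales, and are sampled by univariate
stepping-out/shrinkage slice sampling over four chains.  Model comparison
uses WAIC on the deviance scale (smaller is better); convergence is
monitored with the Gelman-Rubin potential scale reduction factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm

from .scaling import ScalingCurve

__all__ = [
    "ScalingModelSpec",
    "MCMCConfig",
    "PosteriorFit",
    "model_total_info",
    "model_increment",
    "log_likelihood",
    "log_prior",
    "fit_posterior",
    "psrf",
    "waic",
    "derived_posteriors",
    "posterior_summary",
    "inverse_scaling_fit",
]

_FAMILIES = {"unlim": ("c",), "lim": ("c", "i_inf"), "limexp": ("c", "i_inf", "tau")}


@dataclass(frozen=True)
class ScalingModelSpec:
    """A point in parameter space of one scaling-model family."""

    family: str
    c: float
    i_inf: float = np.inf
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.c < 0 or self.tau < 0 or not (self.i_inf > 0 or np.isinf(self.i_inf)):
            raise ValueError("parameters must be nonnegative (i_inf positive)")

    @property
    def params(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in _FAMILIES[self.family])


def _i0(spec: ScalingModelSpec, N: np.ndarray) -> np.ndarray:
    """Non-limiting information component I_{0,N}."""
    N = np.asarray(N, dtype=float)
    if spec.family == "limexp" and spec.tau > 0:
        return spec.c * (N + spec.tau * np.expm1(-N / spec.tau))
    return spec.c * N


def model_total_info(spec: ScalingModelSpec, N) -> np.ndarray | float:
    """Model information I_N at population size(s) N (rad^-2)."""
    scalar = np.isscalar(N)
    i0 = _i0(spec, np.atleast_1d(N))
    if spec.family == "unlim" or np.isinf(spec.i_inf):
        out = i0
    else:
        out = np.where(i0 > 0, i0 * spec.i_inf / (i0 + spec.i_inf), 0.0)
    return float(out[0]) if scalar else out


def model_increment(spec: ScalingModelSpec, N) -> np.ndarray | float:
    """Predicted information increase Delta I_N = I_N - I_{N-1} (I_0 = 0)."""
    scalar = np.isscalar(N)
    Narr = np.atleast_1d(np.asarray(N, dtype=float))
    if np.any(Narr < 1):
        raise ValueError("N must be >= 1")
    out = model_total_info(spec, Narr) - model_total_info(spec, Narr - 1.0)
    return float(out[0]) if scalar else out


def _floored_sigma2(sigma2: np.ndarray) -> np.ndarray:
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 < 0):
        raise ValueError("increment variances must be nonnegative")
    floor = 1e-12 * max(1.0, float(sigma2.max(initial=0.0)))
    out = np.maximum(sigma2, floor)
    if np.any(out <= 0):
        raise ValueError("nonpositive increment variance after flooring")
    return out


def log_likelihood(curve: ScalingCurve, spec: ScalingModelSpec) -> tuple[float, np.ndarray]:
    """Gaussian increment likelihood: total and pointwise log-densities."""
    sigma2 = _floored_sigma2(curve.sigma2)
    pred = model_increment(spec, curve.sizes)
    pointwise = norm.logpdf(curve.mu, loc=pred, scale=np.sqrt(sigma2))
    return float(pointwise.sum()), pointwise


@dataclass(frozen=True)
class _Scales:
    """Empirical scales that anchor the priors and slice widths."""

    mu_mean: float   # <mu_n>, average increment
    i_hat: float     # <I_N>, full-population information estimate
    n_max: int

    @classmethod
    def from_curves(cls, curves: Sequence[ScalingCurve]) -> "_Scales":
        return cls(
            mu_mean=float(np.mean([c.mean_increment for c in curves])),
            i_hat=float(np.mean([c.total_info for c in curves])),
            n_max=int(max(c.n_max for c in curves)),
        )


def _truncated_cauchy_logpdf(x: float, loc: float, scale: float) -> float:
    # Cauchy density renormalized to [0, inf); closed form avoids slow
    # scipy.stats dispatch in the sampler's inner loop
    if x < 0:
        return -np.inf
    z = (x - loc) / scale
    log_norm = np.log(0.5 + np.arctan(loc / scale) / np.pi)  # pr(X >= 0)
    return float(-np.log(np.pi * scale) - np.log1p(z * z) - log_norm)


def _prior_params(scales: _Scales) -> dict[str, tuple[float, float]]:
    return {
        "c": (scales.mu_mean, 10.0 * (scales.mu_mean + 0.5)),
        "i_inf": (scales.i_hat, 10.0 * max(1.0, scales.i_hat)),
        "tau": (0.0, float(scales.n_max)),
    }


def log_prior(spec: ScalingModelSpec, scales: _Scales) -> float:
    """Half-line-truncated Cauchy (Student-t, df=1) priors on the parameters.

    Locations and scales follow the empirical increment mean for c, the
    empirical full-population information for I_inf, and the population size
    for tau; the "variance" convention of St1 is read as squared scale.
    """
    pp = _prior_params(scales)
    total = 0.0
    for name in _FAMILIES[spec.family]:
        loc, scale = pp[name]
        total += _truncated_cauchy_logpdf(getattr(spec, name), loc, scale)
    return total


def _slice_widths(scales: _Scales) -> dict[str, float]:
    return {
        "c": (scales.mu_mean + 0.5) / 2.0,
        "i_inf": max(1.0, scales.i_hat) / 5.0,
        "tau": 10.0,
    }


@dataclass
class MCMCConfig:
    """Slice-sampling settings: raw iterations per chain after burn-in."""

    n_chains: int = 4
    n_iter: int = 10_000
    burn_in: int = 100
    thin: int = 10
    max_stepout: int = 100

    @classmethod
    def paper(cls) -> "MCMCConfig":
        return cls(n_iter=100_000)

    @classmethod
    def test(cls, n_iter: int = 10_000) -> "MCMCConfig":
        return cls(n_iter=n_iter)

    @property
    def n_kept(self) -> int:
        return self.n_iter // self.thin


@dataclass
class PosteriorFit:
    """Posterior samples of a scaling-model fit with diagnostics.

    ``samples[name]`` has shape (n_chains, n_kept); the pointwise
    log-likelihood matrix stacks all kept samples (rows) against all data
    points of all fitted curves (columns).
    """

    family: str
    samples: dict[str, np.ndarray]
    pointwise_loglik: np.ndarray
    curves: list[ScalingCurve] = field(repr=False, default_factory=list)
    scales: _Scales | None = None
    seed: int | None = None
    ml_init: dict[str, float] = field(default_factory=dict)

    @property
    def param_names(self) -> tuple[str, ...]:
        return _FAMILIES[self.family]

    @property
    def n_chains(self) -> int:
        return next(iter(self.samples.values())).shape[0]

    def flat(self, name: str) -> np.ndarray:
        return self.samples[name].reshape(-1)

    @property
    def psrf(self) -> dict[str, float]:
        return psrf(self)

    @property
    def waic(self) -> float:
        return waic(self)

    def spec_at(self, point: dict[str, float] | None = None) -> ScalingModelSpec:
        """Model spec at the posterior median (or a supplied point)."""
        if point is None:
            point = {k: float(np.median(self.flat(k))) for k in self.param_names}
        return ScalingModelSpec(family=self.family, **point)

    def to_frame(self):
        import pandas as pd

        nc, nk = next(iter(self.samples.values())).shape
        data = {"chain": np.repeat(np.arange(nc), nk)}
        for k in self.param_names:
            data[k] = self.samples[k].reshape(-1)
        return pd.DataFrame(data)


def _neg_log_lik(theta: np.ndarray, family: str, curves: Sequence[ScalingCurve]) -> float:
    try:
        spec = ScalingModelSpec(family, *np.maximum(theta, 0.0))
    except ValueError:
        return np.inf
    total = 0.0
    for curve in curves:
        ll, _ = log_likelihood(curve, spec)
        total += ll
    return -total if np.isfinite(total) else np.inf


def _ml_fit(family: str, curves: Sequence[ScalingCurve], scales: _Scales) -> np.ndarray:
    names = _FAMILIES[family]
    c0 = max(scales.mu_mean, 1e-3)
    i0 = max(scales.i_hat, 1.0)
    starts = [[c0, 2.0 * i0, 1.0][: len(names)]]
    starts.append([c0, 20.0 * i0, 10.0][: len(names)])
    starts.append([0.5 * c0, 0.5 * i0, 0.1][: len(names)])
    bounds = [(1e-10, None)] * len(names)
    best, best_val = None, np.inf
    for x0 in starts:
        res = minimize(
            _neg_log_lik, np.asarray(x0, float), args=(family, curves),
            method="L-BFGS-B", bounds=bounds,
        )
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    if best is None or not np.isfinite(best_val):
        raise RuntimeError("maximum-likelihood initialization failed (non-finite objective)")
    return np.maximum(best, 1e-10)


class _LogPosterior:
    """Fast pooled log-posterior for the slice sampler's inner loop.

    Prior normalizers, inverse variances, and the Gaussian log-normalization
    constant are precomputed once per fit.
    """

    def __init__(self, family: str, curves: Sequence[ScalingCurve], scales: _Scales):
        self.family = family
        self.names = _FAMILIES[family]
        self.curves = []
        for c in curves:
            sigma2 = _floored_sigma2(c.sigma2)
            self.curves.append(
                (
                    c.sizes.astype(float),
                    c.sizes.astype(float) - 1.0,
                    c.mu,
                    1.0 / sigma2,
                    -0.5 * float(np.log(2.0 * np.pi * sigma2).sum()),
                )
            )
        pp = _prior_params(scales)
        # (loc, scale, -log(pi*scale) - log pr(X>=0)) per parameter
        self.prior = [
            (loc, scale, -np.log(np.pi * scale) - np.log(0.5 + np.arctan(loc / scale) / np.pi))
            for loc, scale in (pp[n] for n in self.names)
        ]

    def __call__(self, theta: np.ndarray) -> float:
        total = 0.0
        for val, (loc, scale, const) in zip(theta, self.prior):
            if val < 0:
                return -np.inf
            z = (val - loc) / scale
            total += const - np.log1p(z * z)
        c = theta[0]
        i_inf = theta[1] if len(theta) > 1 else np.inf
        tau = theta[2] if len(theta) > 2 else 0.0
        limexp = self.family == "limexp" and tau > 0
        limited = not np.isinf(i_inf)
        for sizes, sizes0, mu, inv_s2, const in self.curves:
            if limexp:
                i0_hi = c * (sizes + tau * np.expm1(-sizes / tau))
                i0_lo = c * (sizes0 + tau * np.expm1(-sizes0 / tau))
            else:
                i0_hi = c * sizes
                i0_lo = c * sizes0
            if limited:
                # x*I/(x+I) is 0 at x=0 and denominators stay positive for I>0
                den_hi = i0_hi + i_inf
                den_lo = i0_lo + i_inf
                if i_inf <= 0 or den_hi.min() <= 0:
                    return -np.inf
                pred = i_inf * (i0_hi / den_hi - i0_lo / den_lo)
            else:
                pred = i0_hi - i0_lo
            resid = mu - pred
            total += const - 0.5 * float(np.dot(resid * resid, inv_s2))
        return float(total)


def _slice_update(
    logpost, x: np.ndarray, j: int, width: float, rng: np.random.Generator,
    lp_x: float, max_stepout: int,
) -> tuple[np.ndarray, float]:
    """One slice move along coordinate j: doubling + shrinkage (Neal 2003).

    Interval doubling (rather than fixed-width stepping out) reaches the
    heavy upper tail of weakly identified parameters - notably I_inf when
    the data carry no sign of saturation - in logarithmically many
    evaluations; shrinkage then uses the doubling-consistency back-test.
    """
    log_y = lp_x + np.log(rng.random())

    def f(xj: float) -> float:
        prop = x.copy()
        prop[j] = xj
        return logpost(prop)

    u = rng.random()
    L = x[j] - width * u
    R = L + width
    f_L, f_R = f(L), f(R)
    k = max_stepout
    while k > 0 and (f_L > log_y or f_R > log_y):
        if rng.random() < 0.5:
            L -= R - L
            f_L = f(L)
        else:
            R += R - L
            f_R = f(R)
        k -= 1

    def acceptable(x1: float) -> bool:
        # back-test: would the doubling procedure started from x1 reach the
        # whole interval (L, R)?  Reject if a rejected midpoint separates
        # x and x1 (Neal 2003, Fig. 6).
        lh, rh = L, R
        d = False
        while rh - lh > 1.1 * width:
            m = 0.5 * (lh + rh)
            if (x[j] < m) != (x1 < m):
                d = True
            if x1 < m:
                rh = m
            else:
                lh = m
            if d and f(lh) <= log_y and f(rh) <= log_y:
                return False
        return True

    lbar, rbar = L, R
    while True:
        xj = lbar + rng.random() * (rbar - lbar)
        prop = x.copy()
        prop[j] = xj
        lp = logpost(prop)
        if lp > log_y and acceptable(xj):
            return prop, lp
        if xj < x[j]:
            lbar = xj
        else:
            rbar = xj


def fit_posterior(
    curves: ScalingCurve | Sequence[ScalingCurve],
    family: str = "lim",
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
) -> PosteriorFit:
    """Slice-sample the scaling-model posterior (pooled over curves).

    Multiple curves share a single parameter vector; their likelihoods
    multiply.  Chains start at the maximum-likelihood fit; sampling is
    deterministic given ``seed``.
    """
    if isinstance(curves, ScalingCurve):
        curves = [curves]
    curves = list(curves)
    if len({round(c.delta_theta, 12) for c in curves}) != 1:
        raise ValueError("pooled curves must share delta_theta")
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    mcmc = mcmc or MCMCConfig()
    if mcmc.n_iter < 1000:
        raise ValueError("at least 1000 iterations are required")
    scales = _Scales.from_curves(curves)
    names = _FAMILIES[family]
    widths = np.array([_slice_widths(scales)[n] for n in names])
    logpost = _LogPosterior(family, curves, scales)
    x0 = _ml_fit(family, curves, scales)
    lp0 = logpost(x0)
    if not np.isfinite(lp0):
        raise RuntimeError(
            f"log-posterior not finite at ML init {dict(zip(names, x0))} (lp={lp0})"
        )

    kept = np.empty((mcmc.n_chains, mcmc.n_kept, len(names)))
    for chain in range(mcmc.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x511CE, chain]))
        x = x0.copy()
        lp = lp0
        k = 0
        for it in range(mcmc.burn_in + mcmc.n_iter):
            for j in range(len(names)):
                x, lp = _slice_update(logpost, x, j, widths[j], rng, lp, mcmc.max_stepout)
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == mcmc.thin - 1:
                kept[chain, k] = x
                k += 1
    samples = {n: kept[:, :, i].copy() for i, n in enumerate(names)}

    pointwise = _pointwise_loglik(family, kept.reshape(-1, len(names)), curves)
    return PosteriorFit(
        family=family,
        samples=samples,
        pointwise_loglik=pointwise,
        curves=curves,
        scales=scales,
        seed=int(seed),
        ml_init=dict(zip(names, map(float, x0))),
    )


def _pointwise_loglik(
    family: str, theta: np.ndarray, curves: Sequence[ScalingCurve], block: int = 2048
) -> np.ndarray:
    """(samples x data points) log-density matrix, computed in blocks."""
    cols = []
    for curve in curves:
        sizes = curve.sizes.astype(float)
        sigma2 = _floored_sigma2(curve.sigma2)
        mu = curve.mu
        out = np.empty((theta.shape[0], sizes.size))
        for lo in range(0, theta.shape[0], block):
            th = theta[lo : lo + block]
            c = th[:, 0:1]
            i_inf = th[:, 1:2] if th.shape[1] > 1 else np.full((th.shape[0], 1), np.inf)
            tau = th[:, 2:3] if th.shape[1] > 2 else np.zeros((th.shape[0], 1))

            def i0(n):
                base = c * n
                if family == "limexp":
                    with np.errstate(divide="ignore", invalid="ignore"):
                        extra = np.where(
                            tau > 0, c * tau * np.expm1(-n / np.where(tau > 0, tau, 1.0)), 0.0
                        )
                    return base + extra
                return base

            def total(n):
                v = i0(n)
                with np.errstate(invalid="ignore", divide="ignore"):
                    lim = np.where(v > 0, v * i_inf / (v + i_inf), 0.0)
                return np.where(np.isinf(i_inf), v, lim)

            pred = total(sizes[None, :]) - total(sizes[None, :] - 1.0)
            out[lo : lo + block] = (
                -0.5 * np.log(2.0 * np.pi * sigma2)[None, :]
                - 0.5 * (mu[None, :] - pred) ** 2 / sigma2[None, :]
            )
        cols.append(out)
    return np.concatenate(cols, axis=1)


def psrf(fit: PosteriorFit) -> dict[str, float]:
    """Gelman-Rubin potential scale reduction factor per parameter.

    Values are clamped at 1.0 from below; > 1.1 indicates poor mixing and
    triggers a warning.
    """
    out = {}
    for name, arr in fit.samples.items():
        m, n = arr.shape
        if m < 2:
            raise ValueError("PSRF needs at least two chains")
        w = arr.var(axis=1, ddof=1).mean()
        b_over_n = arr.mean(axis=1).var(ddof=1)
        if w == 0:
            out[name] = 1.0
            continue
        v_hat = (n - 1) / n * w + b_over_n
        out[name] = float(np.sqrt(max(v_hat / w, 1.0)))
    for name, r in out.items():
        if r > 1.1:
            import warnings

            warnings.warn(
                f"PSRF for {name!r} is {r:.3f} (> 1.1): chains may not have converged",
                RuntimeWarning,
                stacklevel=2,
            )
    return out


def waic(fit: PosteriorFit) -> float:
    """Watanabe-Akaike criterion on the deviance scale, -2(lppd - p_waic).

    Smaller is better; comparable only across fits to the same curve(s).
    Can be negative when pointwise densities exceed one.
    """
    ll = fit.pointwise_loglik
    s = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(s)))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic)


def derived_posteriors(fit: PosteriorFit, fraction: float = 0.95) -> dict[str, np.ndarray]:
    """Posterior sample vectors of I_inf and N_f (population size reaching
    ``fraction`` of asymptotic information).

    Setting I_N = fraction * I_inf in the lim model gives
    N_f = (fraction / (1 - fraction)) * I_inf / c  (N_95 = 19 I_inf / c).
    """
    if fit.family == "unlim":
        raise ValueError("N_f is undefined for the unlim family (I_inf = inf)")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    c = fit.flat("c")
    i_inf = fit.flat("i_inf")
    n_f = (fraction / (1.0 - fraction)) * i_inf / np.maximum(c, np.finfo(float).tiny)
    return {"i_inf": i_inf, "c": c, "n_f": n_f}


def posterior_summary(samples: np.ndarray) -> dict[str, float]:
    """Median with 50% and 90% credible intervals."""
    q = np.percentile(samples, [5, 25, 50, 75, 95])
    return {
        "median": float(q[2]),
        "ci50": (float(q[1]), float(q[3])),
        "ci90": (float(q[0]), float(q[4])),
    }


def inverse_scaling_fit(curve: ScalingCurve) -> dict[str, float]:
    """Weighted linear regression of 1/I_N on 1/N.

    Under the lim model 1/I_N = (1/c)(1/N) + 1/I_inf, so the intercept
    estimates the inverse asymptotic information and its one-sided positivity
    p-value tests for limited information.  Moments of 1/I_N use the delta
    method: <1/I_N> ~= 1/<I_N>, var(1/I_N) ~= var(I_N)/<I_N>^4.  Sizes with
    nonpositive <I_N> (possible at small N after bias correction) are dropped.
    """
    import statsmodels.api as sm

    cum = curve.cum_mean
    var = curve.cum_var
    sizes = curve.sizes
    mask = cum > 0
    if mask.sum() < 3:
        raise ValueError("fewer than 3 usable points for the inverse-information fit")
    y = 1.0 / cum[mask]
    x = 1.0 / sizes[mask]
    vy = var[mask] / cum[mask] ** 4
    if np.all(vy <= 0):
        w = np.ones_like(y)
    else:
        w = 1.0 / np.maximum(vy, 1e-12 * vy[vy > 0].min())
        w = w / w.mean()
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = res.params
    t_int = res.tvalues[0]
    from scipy.stats import t as t_dist

    p_one_sided = float(t_dist.sf(t_int, res.df_resid))
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "intercept_se": float(res.bse[0]),
        "r_squared": float(res.rsquared),
        "intercept_pvalue": p_one_sided,
        "n_points": int(mask.sum()),
    }
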