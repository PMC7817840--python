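"""Per-neuron tuning-curve fits and direction/orientation classification.

Three nested models are fit to each neuron's trial responses by nonlinear
least squares:

* direction   f1(t) = a + b1 exp( k cos(t - t_pref)) + b2 exp(-k cos(t - t_pref))
* orientation f2(t) = a + b  exp( k cos(2 (t - t_pref)))
* constant    f3(t) = a

(the two von Mises lobes of f1 share the concentration k with opposite-sign
cosine arguments).  Models are compared by nested F-tests with Bonferroni
correction: a neuron is "direction"-tuned if f1 significantly beats f2, else
"orientation"-tuned if f2 beats f3, else "untuned".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

__all__ = ["TuningFit", "fit_tuning", "classify_neuron", "coefficient_of_variation"]

_N_PARAMS = {"direction": 5, "orientation": 4, "constant": 1}


@dataclass
class TuningFit:
    """One fitted tuning model with its residual sum of squares."""

    family: str
    params: dict[str, float]
    rss: float
    n_params: int
    r_squared: float
    converged: bool = True

    def predict(self, theta_deg: np.ndarray) -> np.ndarray:
        t = np.deg2rad(np.asarray(theta_deg, dtype=float))
        p = self.params
        if self.family == "direction":
            cd = np.cos(t - p["theta_pref"])
            return p["a"] + p["b1"] * np.exp(p["kappa"] * cd) + p["b2"] * np.exp(-p["kappa"] * cd)
        if self.family == "orientation":
            return p["a"] + p["b"] * np.exp(p["kappa"] * np.cos(2.0 * (t - p["theta_pref"])))
        return np.full_like(t, p["a"])


def _flatten(conditions_deg, responses) -> tuple[np.ndarray, np.ndarray]:
    theta, y = [], []
    for cond, resp in zip(conditions_deg, responses):
        resp = np.asarray(resp, dtype=float).ravel()
        theta.append(np.full(resp.size, cond, dtype=float))
        y.append(resp)
    return np.concatenate(theta), np.concatenate(y)


def _fit_family(family: str, theta_rad: np.ndarray, y: np.ndarray) -> TuningFit:
    grand = float(y.mean())
    tss = float(((y - grand) ** 2).sum())
    if family == "constant":
        rss = tss
        return TuningFit(
            family="constant",
            params={"a": grand},
            rss=rss,
            n_params=1,
            r_squared=0.0 if tss > 0 else 1.0,
        )
    spread = float(y.std()) or 1.0
    period_mult = 1.0 if family == "direction" else 2.0

    def resid(p):
        if family == "direction":
            a, b1, b2, k, pref = p
            cd = np.cos(theta_rad - pref)
            pred = a + b1 * np.exp(k * cd) + b2 * np.exp(-k * cd)
        else:
            a, b, k, pref = p
            pred = a + b * np.exp(k * np.cos(2.0 * (theta_rad - pref)))
        return pred - y

    best = None
    # multi-start over preferred angles spanning the circle; ties keep the
    # first (lowest-index) start
    for pref0 in np.arange(8) * (2.0 * np.pi / 8.0) / period_mult:
        if family == "direction":
            x0 = [grand, 0.5 * spread, 0.1 * spread, 1.5, pref0]
            lb = [-np.inf, 0.0, 0.0, 1e-3, -2.0 * np.pi]
            ub = [np.inf, np.inf, np.inf, 25.0, 4.0 * np.pi]
        else:
            x0 = [grand, 0.5 * spread, 1.5, pref0]
            lb = [-np.inf, 0.0, 1e-3, -2.0 * np.pi]
            ub = [np.inf, np.inf, 25.0, 4.0 * np.pi]
        try:
            res = least_squares(resid, x0, bounds=(lb, ub), method="trf", max_nfev=2000)
        except Exception:
            continue
        rss = float(2.0 * res.cost)
        if best is None or rss < best[0] - 1e-12:
            best = (rss, res)
    if best is None:
        return TuningFit(family, {"a": grand}, tss, _N_PARAMS[family], 0.0, converged=False)
    rss, res = best
    names = (
        ("a", "b1", "b2", "kappa", "theta_pref")
        if family == "direction"
        else ("a", "b", "kappa", "theta_pref")
    )
    params = dict(zip(names, map(float, res.x)))
    params["theta_pref"] = float(np.rad2deg(params["theta_pref"]) % 360.0)
    params["theta_pref"] = float(np.deg2rad(params["theta_pref"]))  # canonical [0, 2pi)
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return TuningFit(
        family=family,
        params=params,
        rss=rss,
        n_params=_N_PARAMS[family],
        r_squared=r2,
        converged=bool(res.success),
    )


def fit_tuning(conditions_deg: Sequence[float], responses: Sequence[np.ndarray]) -> dict[str, TuningFit]:
    """Fit the three nested tuning models to one neuron's trial responses.

    ``responses[k]`` holds the trials at ``conditions_deg[k]``.  The constant
    fit is the grand mean (analytic); the von Mises fits use multi-start
    trust-region least squares.  Returns {"direction", "orientation",
    "constant"} fits; non-convergence is flagged, keeping the best-found
    parameters.
    """
    if len(conditions_deg) < 2:
        raise ValueError("at least two stimulus conditions are required")
    theta_deg, y = _flatten(conditions_deg, responses)
    theta_rad = np.deg2rad(theta_deg)
    fits = {fam: _fit_family(fam, theta_rad, y) for fam in ("direction", "orientation", "constant")}
    # enforce nesting up to optimizer tolerance: a richer model can always
    # reproduce a simpler one, so flag violations
    tol = 1e-6 * max(1.0, fits["constant"].rss)
    if fits["direction"].rss > fits["orientation"].rss + tol:
        fits["direction"].converged = False
    if fits["orientation"].rss > fits["constant"].rss + tol:
        fits["orientation"].converged = False
    return fits


def _nested_f_pvalue(
    rss_r: float, rss_f: float, df_r: int, df_f: int, n_obs: int, tol: float = 0.0
) -> float:
    """P-value of the F-test comparing a restricted to a fuller model.

    ``tol`` absorbs optimizer round-off: improvements below it are treated
    as no improvement (degenerate perfectly-fit data would otherwise produce
    spurious huge F statistics from ~1e-30 residuals).
    """
    dp = df_f - df_r
    dof = n_obs - df_f
    if dof <= 0:
        raise ValueError("more parameters than observations")
    rss_f = max(rss_f, 0.0)
    if rss_r - rss_f <= tol:
        return 1.0
    if rss_f <= tol:
        return 0.0
    stat = (rss_r - rss_f) / dp / (rss_f / dof)
    return float(f_dist.sf(stat, dp, dof))


def classify_neuron(
    fits: dict[str, TuningFit],
    n_obs: int,
    alpha: float = 0.05,
    n_tests: int = 1,
) -> str:
    """Label a neuron as direction-tuned, orientation-tuned, or untuned.

    Nested F-tests at Bonferroni-corrected level alpha/n_tests: "direction"
    if the direction model significantly beats the orientation model, else
    "orientation" if the orientation model beats the constant model, else
    "untuned".  ``n_tests`` is the Bonferroni denominator (typically the
    number of neurons times the tests per neuron).
    """
    alpha_c = alpha / max(n_tests, 1)
    # round-off floor on the scale of the data's total sum of squares
    grand = fits["constant"].params.get("a", 0.0)
    tol = 1e-9 * max(fits["constant"].rss, n_obs * grand**2, 1e-9)
    p_dir = _nested_f_pvalue(
        fits["orientation"].rss, fits["direction"].rss,
        fits["orientation"].n_params, fits["direction"].n_params, n_obs, tol=tol,
    )
    if p_dir < alpha_c:
        return "direction"
    p_ori = _nested_f_pvalue(
        fits["constant"].rss, fits["orientation"].rss,
        fits["constant"].n_params, fits["orientation"].n_params, n_obs, tol=tol,
    )
    if p_ori < alpha_c:
        return "orientation"
    return "untuned"


def coefficient_of_variation(
    responses: Sequence[np.ndarray],
    mode: str = "average",
    mean_floor: float = 1e-6,
) -> float:
    """Trial-to-trial coefficient of variation (relative standard deviation).

    Computed per condition from the trials at that condition, then averaged
    over conditions whose mean exceeds ``mean_floor``; ``mode="preferred"``
    instead uses only the condition with the largest mean response.  Returns
    NaN (with a warning) if no condition has positive mean.
    """
    means = np.array([np.mean(r) for r in responses])
    sds = np.array([np.std(r, ddof=1) for r in responses])
    ok = means > mean_floor
    if not ok.any():
        import warnings

        warnings.warn("all condition means at or below floor; CV undefined", RuntimeWarning)
        return float("nan")
    if mode == "preferred":
        k = int(np.argmax(means))
        return float(sds[k] / means[k])
    if mode != "average":
        raise ValueError("mode must be 'average' or 'preferred'")
    return float(np.mean(sds[ok] / means[ok]))
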