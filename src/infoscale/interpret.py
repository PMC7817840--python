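"""Cross-fit interpretation: the c-I_inf scaling relation, population-size
predictions, and retinotopic-scale arithmetic.

Across discriminations, sessions, and stimulus contrasts, the per-neuron
information c and the asymptotic information I_inf co-vary.  A log-log
regression log10(c) = beta0 + beta1 log10(I_inf) summarizes that relation; a
slope of exactly one would make N_95 = 19 I_inf / c independent of I_inf,
while the empirically shallower slope makes the required population size grow
weakly with the total information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScalingRelation",
    "fit_scaling_relation",
    "n95_from_relation",
    "captured_fraction",
    "cortical_area",
]

# cortical magnification defaults for mouse V1 (degrees of visual space per mm)
AZIMUTH_DEG_PER_MM = 63.0
ELEVATION_DEG_PER_MM = 40.0


@dataclass(frozen=True)
class ScalingRelation:
    """OLS fit of log10(c) on log10(I_inf) with a slope-1 F-test."""

    beta0: float          # intercept, log10 units
    beta1: float          # slope, dimensionless
    beta1_se: float       # OLS standard error of the slope
    f_stat: float         # F statistic for H0: beta1 = 1
    p_value: float
    r_squared: float
    n_points: int


def fit_scaling_relation(points) -> ScalingRelation:
    """Fit log10(c) = beta0 + beta1 log10(I_inf) to (c, I_inf) pairs.

    Ordinary least squares on posterior medians (no error weighting); the
    returned F-test compares against the fixed-slope model beta1 = 1.
    Requires at least three strictly positive points.
    """
    import statsmodels.api as sm
    from scipy.stats import f as f_dist

    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an iterable of (c, i_inf) pairs")
    if pts.shape[0] < 3:
        raise ValueError("at least three points are required")
    if np.any(pts <= 0):
        raise ValueError("all c and I_inf values must be positive")
    y = np.log10(pts[:, 0])
    x = np.log10(pts[:, 1])
    res = sm.OLS(y, sm.add_constant(x)).fit()
    beta0, beta1 = res.params
    rss_full = float(res.ssr)
    # restricted model: slope fixed at 1 -> intercept-only fit on y - x
    r = y - x
    rss_restricted = float(((r - r.mean()) ** 2).sum())
    dof = pts.shape[0] - 2
    if rss_full == 0.0:
        f_stat = 0.0 if rss_restricted == 0.0 else np.inf
        p = 1.0 if rss_restricted == 0.0 else 0.0
    else:
        f_stat = max(rss_restricted - rss_full, 0.0) / (rss_full / dof)
        p = float(f_dist.sf(f_stat, 1, dof))
    return ScalingRelation(
        beta0=float(beta0),
        beta1=float(beta1),
        beta1_se=float(res.bse[1]),
        f_stat=float(f_stat),
        p_value=p,
        r_squared=float(res.rsquared),
        n_points=int(pts.shape[0]),
    )


def n95_from_relation(
    i_inf: float,
    relation: ScalingRelation | tuple[float, float],
    round_to: int | None = None,
) -> float:
    """Population size reaching 95% of I_inf, via the fitted c-I_inf relation.

    Substituting c = 10^beta0 * I_inf^beta1 into N_95 = 19 I_inf / c gives
    N_95 = 0.95 I_inf^(1 - beta1) / (0.05 * 10^beta0).  ``round_to`` rounds
    to the nearest integer (0) or nearest 10^round_to (e.g. 3 for thousands).
    """
    if i_inf <= 0:
        raise ValueError("i_inf must be positive")
    beta0, beta1 = (
        (relation.beta0, relation.beta1)
        if isinstance(relation, ScalingRelation)
        else relation
    )
    n95 = 0.95 * i_inf ** (1.0 - beta1) / (0.05 * 10.0**beta0)
    if round_to is not None:
        unit = 10.0**round_to
        n95 = round(n95 / unit) * unit
    return float(n95)


def captured_fraction(alpha: float, beta1: float) -> float:
    """Fraction of high-contrast asymptotic information captured at N_95^lo.

    With I_inf^hi = alpha * I_inf^lo and c scaling as I_inf^beta1, a
    population sized to capture 95% of the low asymptotic information
    captures 0.95 / (0.95 + 0.05 alpha^(1 - beta1)) of the high one; equals
    0.95 at alpha = 1 and is independent of the absolute information levels.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return float(0.95 / (0.95 + 0.05 * alpha ** (1.0 - beta1)))


def cortical_area(
    circle_radius_deg: float | None = None,
    rect_deg: tuple[float, float] | None = None,
    azimuth_deg_per_mm: float = AZIMUTH_DEG_PER_MM,
    elevation_deg_per_mm: float = ELEVATION_DEG_PER_MM,
) -> float:
    """Retinotopic cortical area (mm^2) of a visual-field extent.

    A circle of radius r degrees maps to an ellipse with semi-axes
    (r / azimuth factor, r / elevation factor); a rectangle of w x h degrees
    maps to (w / azimuth) * (h / elevation).  Exactly one extent must be
    given.
    """
    if (circle_radius_deg is None) == (rect_deg is None):
        raise ValueError("specify exactly one of circle_radius_deg or rect_deg")
    if circle_radius_deg is not None:
        if circle_radius_deg < 0:
            raise ValueError("extent must be nonnegative")
        return float(
            np.pi * (circle_radius_deg / azimuth_deg_per_mm) * (circle_radius_deg / elevation_deg_per_mm)
        )
    w, h = rect_deg
    if w < 0 or h < 0:
        raise ValueError("extent must be nonnegative")
    return float((w / azimuth_deg_per_mm) * (h / elevation_deg_per_mm))
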