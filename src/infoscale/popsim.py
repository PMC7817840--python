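"""Synthetic neural populations with known tuning, noise covariance, and
asymptotic information.

A ground-truth population is defined by per-neuron tuning curves (mixtures of
von Mises shapes for direction- and orientation-tuned neurons, constants for
untuned ones), a non-limiting noise covariance ``Sigma0``, and an asymptotic
information level ``I_inf``.  The full noise covariance for a discrimination
between two stimulus angles is

    Sigma = Sigma0 + f' f'^T / I_inf,

where ``f'`` is the finite-difference change of the mean response per radian.
The rank-one term is the differential-correlation component: it alone bounds
the linearly decodable information at ``I_inf``, however many neurons are
added.  Because the linear Fisher information depends only on the first two
moments of the response distribution, trials are drawn from a multivariate
Gaussian around the tuning curves (optionally rectified at zero to mimic
nonnegative deconvolved-calcium activity).

Angles are degrees at every public boundary and radians internally;
information is always in rad^-2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "PopulationConfig",
    "PopulationGroundTruth",
    "TrialDataset",
    "make_population",
    "sample_trials",
    "closed_form_info",
    "shuffle_trials",
]

_EIG_FLOOR_REL = 1e-6  # eigenvalue flooring for nearest-PD repair


@dataclass(frozen=True)
class PopulationConfig:
    """Generator settings for a synthetic population.

    Tuning-family fractions follow the mixture observed in mouse V1 layer 2/3
    (18% direction-tuned, 48% orientation-tuned, 34% untuned on average).
    Amplitude/width/baseline distributions are log-normals with defaults that
    put per-neuron information in the O(1e-2 .. 1e-1) rad^-2 regime.
    """

    n_neurons: int = 200
    frac_direction: float = 0.18
    frac_orientation: float = 0.48
    i_inf: float = np.inf          # asymptotic information, rad^-2 (inf = unlimited)
    theta1_deg: float = 135.0      # discrimination pair, degrees
    theta2_deg: float = 180.0
    # tuning parameter distributions (log-normal log-mean / log-sd)
    baseline_mu: float = np.log(0.4)
    baseline_sigma: float = 0.4
    amplitude_mu: float = np.log(0.2)
    amplitude_sigma: float = 0.5
    kappa_mu: float = np.log(0.7)
    kappa_sigma: float = 0.4
    # noise model
    sigma0_kind: str = "limited_range"  # {limited_range, diagonal, lowrank}
    cv: float = 1.0                # trial-to-trial coefficient of variation
    rho_max: float = 0.25          # limited-range: peak pairwise correlation
    corr_length_deg: float = 40.0  # limited-range: decay scale in preferred angle
    lowrank_dim: int = 3           # lowrank: number of shared factors
    lowrank_strength: float = 0.5  # lowrank: shared / private variance ratio
    rectify: bool = False          # clip sampled activity at zero


@dataclass(frozen=True)
class PopulationGroundTruth:
    """A generative population with closed-form information.

    ``tuning`` maps parameter names to length-n arrays; ``family`` holds the
    per-neuron label in {"direction", "orientation", "untuned"}.
    """

    n_neurons: int
    family: np.ndarray
    tuning: dict[str, np.ndarray]
    sigma0: np.ndarray
    i_inf: float
    theta1: float  # radians
    theta2: float  # radians
    config: PopulationConfig | None = field(default=None, compare=False)
    seed: int | None = field(default=None, compare=False)

    @property
    def delta_theta(self) -> float:
        """Signed stimulus difference theta2 - theta1 (radians)."""
        return self.theta2 - self.theta1

    def mean_response(self, theta: float) -> np.ndarray:
        """Tuning-curve value f(theta) for every neuron (theta in radians)."""
        return tuning_mean(self.family, self.tuning, theta)

    @property
    def f_prime(self) -> np.ndarray:
        """Mean-rate change per radian, (f(theta2) - f(theta1)) / dtheta."""
        return (self.mean_response(self.theta2) - self.mean_response(self.theta1)) / self.delta_theta

    @property
    def sigma(self) -> np.ndarray:
        """Full noise covariance Sigma0 + f'f'^T / I_inf."""
        if np.isinf(self.i_inf):
            return self.sigma0.copy()
        fp = self.f_prime
        return self.sigma0 + np.outer(fp, fp) / self.i_inf


@dataclass
class TrialDataset:
    """Trial-by-neuron responses for a set of stimulus conditions.

    ``conditions`` are angles in degrees; ``responses[k]`` is the (T x N)
    activity matrix for condition k.  Trial counts are equal across
    conditions and there are no missing entries.
    """

    conditions: np.ndarray                  # degrees, shape (K,)
    responses: list[np.ndarray]             # each (T, N)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.conditions = np.asarray(self.conditions, dtype=float)
        if len(self.responses) != len(self.conditions):
            raise ValueError("one response matrix per condition is required")
        shapes = {r.shape for r in self.responses}
        if len({s[0] for s in shapes}) != 1:
            raise ValueError("all conditions must have the same trial count")
        if len({s[1] for s in shapes}) != 1:
            raise ValueError("all conditions must have the same neuron count")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_trials(self) -> int:
        return self.responses[0].shape[0]

    @property
    def n_neurons(self) -> int:
        return self.responses[0].shape[1]

    def condition_index(self, theta_deg: float) -> int:
        match = np.flatnonzero(np.isclose(self.conditions % 360.0, theta_deg % 360.0))
        if match.size == 0:
            raise KeyError(f"condition {theta_deg} deg not present in dataset")
        return int(match[0])

    def select_pair(self, theta1_deg: float, theta2_deg: float) -> "TrialDataset":
        """Two-condition dataset for one discrimination."""
        i, j = self.condition_index(theta1_deg), self.condition_index(theta2_deg)
        return TrialDataset(
            conditions=self.conditions[[i, j]],
            responses=[self.responses[i], self.responses[j]],
            provenance=dict(self.provenance),
        )

    @property
    def delta_theta(self) -> float:
        """Circular stimulus difference of a two-condition dataset (radians)."""
        if self.n_conditions != 2:
            raise ValueError("delta_theta is defined for two-condition datasets")
        d = (self.conditions[1] - self.conditions[0] + 180.0) % 360.0 - 180.0
        return float(np.deg2rad(abs(d)))

    # --- serialization -------------------------------------------------

    def to_frame(self):
        """Long-format table: one row per trial, condition_deg + neuron_* columns."""
        import pandas as pd

        blocks = []
        for cond, resp in zip(self.conditions, self.responses):
            df = pd.DataFrame(resp, columns=[f"neuron_{i}" for i in range(self.n_neurons)])
            df.insert(0, "condition_deg", cond)
            blocks.append(df)
        return pd.concat(blocks, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialDataset":
        import pandas as pd

        df = pd.read_csv(path)
        conds = np.unique(df["condition_deg"].to_numpy())
        cols = [c for c in df.columns if c.startswith("neuron_")]
        cols.sort(key=lambda c: int(c.split("_")[1]))
        responses = [
            df.loc[df["condition_deg"] == c, cols].to_numpy(dtype=float) for c in conds
        ]
        return cls(conditions=conds, responses=responses)

    def to_npz(self, path) -> None:
        """Named-array container with provenance (runtime format)."""
        import json

        np.savez(
            path,
            conditions=self.conditions,
            provenance=np.array(json.dumps(self.provenance, default=str)),
            **{f"responses_{k}": r for k, r in enumerate(self.responses)},
        )

    @classmethod
    def from_npz(cls, path) -> "TrialDataset":
        import json

        with np.load(path, allow_pickle=False) as z:
            conds = z["conditions"]
            responses = [z[f"responses_{k}"] for k in range(len(conds))]
            prov = json.loads(str(z["provenance"]))
        return cls(conditions=conds, responses=responses, provenance=prov)


# --- tuning curves ------------------------------------------------------


def tuning_mean(family: np.ndarray, tuning: dict[str, np.ndarray], theta: float) -> np.ndarray:
    """Evaluate the per-neuron mean response at stimulus angle theta (radians)."""
    a = tuning["a"]
    b1 = tuning["b1"]
    b2 = tuning["b2"]
    kappa = tuning["kappa"]
    pref = tuning["theta_pref"]
    out = np.array(a, dtype=float, copy=True)
    is_dir = family == "direction"
    is_ori = family == "orientation"
    cd = np.cos(theta - pref[is_dir])
    out[is_dir] += b1[is_dir] * np.exp(kappa[is_dir] * cd) + b2[is_dir] * np.exp(-kappa[is_dir] * cd)
    out[is_ori] += b1[is_ori] * np.exp(kappa[is_ori] * np.cos(2.0 * (theta - pref[is_ori])))
    return out


def tuning_deriv(family: np.ndarray, tuning: dict[str, np.ndarray], theta: float) -> np.ndarray:
    """Analytic derivative df/dtheta of the tuning curves at theta (radians)."""
    b1 = tuning["b1"]
    b2 = tuning["b2"]
    kappa = tuning["kappa"]
    pref = tuning["theta_pref"]
    out = np.zeros_like(b1, dtype=float)
    is_dir = family == "direction"
    is_ori = family == "orientation"
    d = theta - pref[is_dir]
    k = kappa[is_dir]
    out[is_dir] = k * np.sin(d) * (
        -b1[is_dir] * np.exp(k * np.cos(d)) + b2[is_dir] * np.exp(-k * np.cos(d))
    )
    d2 = 2.0 * (theta - pref[is_ori])
    k2 = kappa[is_ori]
    out[is_ori] = -2.0 * b1[is_ori] * k2 * np.sin(d2) * np.exp(k2 * np.cos(d2))
    return out


def _limited_range_corr(pref: np.ndarray, rho_max: float, length_rad: float) -> np.ndarray:
    """Correlations decaying with circular distance between preferred angles."""
    d = np.abs(pref[:, None] - pref[None, :])
    d = np.minimum(d, 2.0 * np.pi - d)
    r = rho_max * np.exp(-d / length_rad)
    np.fill_diagonal(r, 1.0)
    return r


def _nearest_pd(mat: np.ndarray, floor_rel: float = _EIG_FLOOR_REL) -> np.ndarray:
    """Symmetrize and floor eigenvalues at floor_rel * max eigenvalue."""
    sym = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(sym)
    floor = floor_rel * w.max()
    if w.min() < floor:
        w = np.maximum(w, floor)
        sym = (v * w) @ v.T
        sym = 0.5 * (sym + sym.T)
    return sym


def make_population(config: PopulationConfig, seed: int) -> PopulationGroundTruth:
    """Draw a ground-truth population from the generator settings.

    Deterministic in ``(config, seed)``.  Raises ``ValueError`` if the
    requested base covariance is not positive definite after repair (naming
    the offending eigenvalue).
    """
    if config.n_neurons < 2:
        raise ValueError("n_neurons must be >= 2")
    if not (config.i_inf > 0):
        raise ValueError("i_inf must be positive (np.inf for unlimited)")
    fu = 1.0 - config.frac_direction - config.frac_orientation
    if config.frac_direction < 0 or config.frac_orientation < 0 or fu < -1e-12:
        raise ValueError("tuning-family fractions must be nonnegative and sum to <= 1")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    n = config.n_neurons

    u = rng.random(n)
    family = np.where(
        u < config.frac_direction,
        "direction",
        np.where(u < config.frac_direction + config.frac_orientation, "orientation", "untuned"),
    ).astype(object)
    family = np.asarray(family, dtype="U11")

    a = rng.lognormal(config.baseline_mu, config.baseline_sigma, n)
    b1 = rng.lognormal(config.amplitude_mu, config.amplitude_sigma, n)
    b2 = b1 * rng.uniform(0.0, 0.5, n)  # secondary (anti-preferred) lobe
    kappa = rng.lognormal(config.kappa_mu, config.kappa_sigma, n)
    pref = rng.uniform(0.0, 2.0 * np.pi, n)
    untuned = family == "untuned"
    b1 = np.where(untuned, 0.0, b1)
    b2 = np.where(untuned | (family == "orientation"), 0.0, b2)
    tuning = {"a": a, "b1": b1, "b2": b2, "kappa": kappa, "theta_pref": pref}

    theta1 = float(np.deg2rad(config.theta1_deg))
    theta2 = float(np.deg2rad(config.theta2_deg))
    mean_mid = 0.5 * (
        tuning_mean(family, tuning, theta1) + tuning_mean(family, tuning, theta2)
    )
    var = (config.cv * np.maximum(mean_mid, 0.05)) ** 2

    if config.sigma0_kind == "diagonal":
        sigma0 = np.diag(var)
    elif config.sigma0_kind == "limited_range":
        corr = _limited_range_corr(pref, config.rho_max, np.deg2rad(config.corr_length_deg))
        sd = np.sqrt(var)
        sigma0 = _nearest_pd(corr * np.outer(sd, sd))
    elif config.sigma0_kind == "lowrank":
        load = rng.standard_normal((n, config.lowrank_dim))
        shared = load @ load.T
        shared *= config.lowrank_strength * var.mean() / np.trace(shared) * n
        sigma0 = _nearest_pd(shared + np.diag(var))
    else:
        raise ValueError(f"unknown sigma0_kind: {config.sigma0_kind!r}")

    w = np.linalg.eigvalsh(sigma0)
    if w.min() <= 0:
        raise ValueError(
            f"base covariance is not positive definite (smallest eigenvalue {w.min():.3e})"
        )

    return PopulationGroundTruth(
        n_neurons=n,
        family=family,
        tuning=tuning,
        sigma0=sigma0,
        i_inf=float(config.i_inf),
        theta1=theta1,
        theta2=theta2,
        config=config,
        seed=int(seed),
    )


def sample_trials(gt: PopulationGroundTruth, T: int, seed: int) -> TrialDataset:
    """Sample a two-condition trial dataset (T trials per condition).

    Multivariate Gaussian around the tuning means with the full covariance
    Sigma = Sigma0 + f'f'^T/I_inf shared across the two conditions; optional
    rectification at zero when the generator config requests it.
    """
    if T < 2:
        raise ValueError("T must be >= 2 (sample covariance undefined otherwise)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7A1A15]))
    chol = np.linalg.cholesky(gt.sigma)
    rectify = bool(gt.config.rectify) if gt.config is not None else False
    responses = []
    for theta in (gt.theta1, gt.theta2):
        mean = gt.mean_response(theta)
        x = mean + rng.standard_normal((T, gt.n_neurons)) @ chol.T
        if rectify:
            x = np.maximum(x, 0.0)
        responses.append(x)
    return TrialDataset(
        conditions=np.rad2deg([gt.theta1, gt.theta2]),
        responses=responses,
        provenance={"seed": int(seed), "T": int(T), "generator_seed": gt.seed},
    )


def sample_session(
    gt: PopulationGroundTruth,
    conditions_deg: Sequence[float],
    T: int,
    seed: int,
) -> TrialDataset:
    """Sample a multi-condition session (T trials per condition).

    Each condition theta is drawn around the tuning means with covariance
    Sigma0 + g(theta) g(theta)^T / I_inf, where g is the analytic local
    derivative of the tuning curves, so that every discrimination extracted
    from the session carries (approximately) limited information.  With
    I_inf = inf the noise is simply Sigma0 for every condition.
    """
    if T < 2:
        raise ValueError("T must be >= 2 (sample covariance undefined otherwise)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E5510]))
    rectify = bool(gt.config.rectify) if gt.config is not None else False
    responses = []
    for theta_deg in conditions_deg:
        theta = float(np.deg2rad(theta_deg))
        mean = gt.mean_response(theta)
        cov = gt.sigma0
        if not np.isinf(gt.i_inf):
            g = tuning_deriv(gt.family, gt.tuning, theta)
            cov = cov + np.outer(g, g) / gt.i_inf
        x = mean + rng.standard_normal((T, gt.n_neurons)) @ np.linalg.cholesky(cov).T
        if rectify:
            x = np.maximum(x, 0.0)
        responses.append(x)
    return TrialDataset(
        conditions=np.asarray(conditions_deg, dtype=float),
        responses=responses,
        provenance={"seed": int(seed), "T": int(T), "generator_seed": gt.seed},
    )


def closed_form_info(gt: PopulationGroundTruth, subset: Sequence[int] | None = None) -> float:
    """Exact linear Fisher information of a neuron subset (rad^-2).

    Uses the Sherman–Morrison reduction of the rank-one covariance
    decomposition: 1/I = 1/I0 + 1/I_inf with I0 = f'^T Sigma0^-1 f' restricted
    to the subset.  Equals the direct evaluation f'^T Sigma^-1 f'.
    """
    if subset is None:
        idx = np.arange(gt.n_neurons)
    else:
        idx = np.asarray(subset, dtype=int)
        if idx.size == 0:
            raise ValueError("subset must be nonempty")
        if idx.min() < 0 or idx.max() >= gt.n_neurons:
            raise ValueError("subset indices out of range")
    fp = gt.f_prime[idx]
    s0 = gt.sigma0[np.ix_(idx, idx)]
    try:
        c, low = cho_factor(s0)
    except np.linalg.LinAlgError as err:
        raise ValueError("restricted base covariance is singular") from err
    i0 = float(fp @ cho_solve((c, low), fp))
    if np.isinf(gt.i_inf):
        return i0
    if i0 == 0.0:
        return 0.0
    return 1.0 / (1.0 / i0 + 1.0 / gt.i_inf)


def shuffle_trials(ds: TrialDataset, seed: int) -> TrialDataset:
    """Destroy noise correlations by permuting trials independently per neuron.

    Within every condition, each neuron's column is permuted with its own
    random permutation, preserving all per-neuron marginals while breaking
    cross-neuron trial pairing.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5F0FF1E]))
    shuffled = []
    for resp in ds.responses:
        out = np.empty_like(resp)
        T = resp.shape[0]
        for j in range(resp.shape[1]):
            out[:, j] = resp[rng.permutation(T), j]
        shuffled.append(out)
    prov = dict(ds.provenance)
    prov["shuffled_seed"] = int(seed)
    return TrialDataset(conditions=ds.conditions.copy(), responses=shuffled, provenance=prov)
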