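"""Cross-validated decomposition of noise, signal alignment, and information
across principal noise dimensions.

Trials are split into random halves (stratified by condition).  The training
half defines the principal dimensions Q of the pooled noise covariance; the
test half provides independent moments (f'_test, Sigma_test) from which three
per-dimension quantities follow:

* noise variance          q_n^T Sigma_test q_n
* signal alignment        cos^2(alpha_n) = (q_n^T f'_test)^2 / (f'_test^T f'_test)
* cumulative information  I_n = f'^T Q_{1:n} (Q_{1:n}^T Sigma_test Q_{1:n})^-1 Q_{1:n}^T f'

Because Q is a complete orthonormal basis, the alignments sum to one and the
full-dimension cumulative information equals the information computed from the
test moments directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from .popsim import TrialDataset
from .fisher import empirical_moments

__all__ = ["PCASplit", "SubspaceSummary", "split_pca", "subspace_summary", "fraction_to_threshold"]


@dataclass
class PCASplit:
    """Train eigenbasis and test moments of one random trial split."""

    q_train: np.ndarray         # (N, N) orthonormal, eigenvalue-descending
    eigvals_train: np.ndarray   # (N,)
    f_prime_test: np.ndarray    # (N,)
    sigma_test: np.ndarray      # (N, N)


def split_pca(ds: TrialDataset, n_splits: int = 10, seed: int = 0) -> list[PCASplit]:
    """Random half-splits of trials with train-half principal dimensions.

    Splits are disjoint random halves of trials within each condition; an odd
    trial count drops one random trial.  Requires T >= 2 (N + 2) so both
    halves support covariance estimation.
    """
    if ds.n_conditions != 2:
        raise ValueError("a two-condition dataset is required")
    N = ds.n_neurons
    T = ds.n_trials
    if T < 2 * (N + 2):
        raise ValueError(f"need T >= 2(N+2) = {2 * (N + 2)} trials per condition, got {T}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x59117]))
    half = T // 2
    splits = []
    for _ in range(n_splits):
        train_resp, test_resp = [], []
        for resp in ds.responses:
            perm = rng.permutation(T)
            train_resp.append(resp[perm[:half]])
            test_resp.append(resp[perm[half : 2 * half]])
        train = TrialDataset(conditions=ds.conditions, responses=train_resp)
        test = TrialDataset(conditions=ds.conditions, responses=test_resp)
        _, sigma_train = empirical_moments(train)
        f_test, sigma_test = empirical_moments(test)
        w, v = np.linalg.eigh(sigma_train)
        order = np.argsort(w)[::-1]
        splits.append(
            PCASplit(
                q_train=v[:, order],
                eigvals_train=w[order],
                f_prime_test=f_test,
                sigma_test=sigma_test,
            )
        )
    return splits


@dataclass
class SubspaceSummary:
    """Per-split and across-split subspace decomposition.

    Arrays are (n_splits, N), dimensions ordered by descending train
    eigenvalue.
    """

    var_test: np.ndarray    # per-dimension test noise variance
    cos2: np.ndarray        # per-dimension squared signal alignment
    cum_info: np.ndarray    # cumulative information over leading dimensions

    @property
    def n_splits(self) -> int:
        return self.var_test.shape[0]

    @property
    def n_dims(self) -> int:
        return self.var_test.shape[1]

    @property
    def mean_var(self) -> np.ndarray:
        return self.var_test.mean(axis=0)

    @property
    def mean_cos2(self) -> np.ndarray:
        return self.cos2.mean(axis=0)

    @property
    def mean_cum_info(self) -> np.ndarray:
        return self.cum_info.mean(axis=0)

    def to_frame(self):
        import pandas as pd

        rows = []
        for s in range(self.n_splits):
            rows.append(
                pd.DataFrame(
                    {
                        "dim": np.arange(1, self.n_dims + 1),
                        "var_test": self.var_test[s],
                        "cos2": self.cos2[s],
                        "cum_info": self.cum_info[s],
                        "split": s,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def subspace_summary(splits: list[PCASplit]) -> SubspaceSummary:
    """Per-dimension noise, alignment, and cumulative information per split.

    The cumulative information over the leading n dimensions is computed from
    the projected test moments via a single Cholesky factorization (prefix
    blocks of the factor correspond to prefix dimension sets).
    """
    var_rows, cos_rows, info_rows = [], [], []
    for sp in splits:
        Q = sp.q_train
        B = Q.T @ sp.sigma_test @ Q
        B = 0.5 * (B + B.T)
        g = Q.T @ sp.f_prime_test
        var_rows.append(np.diag(B).copy())
        denom = sp.f_prime_test @ sp.f_prime_test
        if denom == 0:
            raise ValueError("test f' is zero; alignment undefined")
        cos_rows.append(g**2 / denom)
        try:
            L = np.linalg.cholesky(B)
        except np.linalg.LinAlgError as err:
            raise ValueError("projected test covariance is singular") from err
        y = solve_triangular(L, g, lower=True)
        info_rows.append(np.cumsum(y**2))
    return SubspaceSummary(
        var_test=np.asarray(var_rows),
        cos2=np.asarray(cos_rows),
        cum_info=np.asarray(info_rows),
    )


def fraction_to_threshold(summary: SubspaceSummary, level: float = 0.9) -> dict:
    """Fractions of dimensions needed to reach ``level`` of each total.

    Thresholds the across-split mean curves (per-split fractions are also
    returned).  For each of noise variance, cumulative signal alignment, and
    cumulative information, the result is the smallest n whose cumulative
    quantity reaches ``level`` times its total, divided by the number of
    dimensions.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    N = summary.n_dims

    def frac(cum: np.ndarray) -> float:
        return float((np.argmax(cum >= level * cum[-1]) + 1) / N)

    per_split = {
        "variance": np.array([frac(np.cumsum(v)) for v in summary.var_test]),
        "alignment": np.array([frac(np.cumsum(c)) for c in summary.cos2]),
        "information": np.array([frac(ci) for ci in summary.cum_info]),
    }
    return {
        "variance": frac(np.cumsum(summary.mean_var)),
        "alignment": frac(np.cumsum(summary.mean_cos2)),
        "information": frac(summary.mean_cum_info),
        "per_split": per_split,
    }
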