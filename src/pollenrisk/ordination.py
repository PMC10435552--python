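"""Redundancy analysis (RDA) with a Monte Carlo permutation test.

RDA is the PCA of the fitted values of a multivariate linear regression:
response matrix Y (here nests x pesticide concentrations) is regressed on
a constraint matrix X (nests x pollen-taxa proportions); the covariance of
the fitted values is eigendecomposed, and each eigenvalue is expressed as
a fraction of the total pretreated variance of Y.

Pretreatment: Y columns are centered, and by default also standardized -
residue concentrations span three orders of magnitude, so unstandardized
axes would be dominated by the most concentrated substance.  X is centered
(ordination is translation invariant in the constraints) and may have more
columns than n - 1; the projection rank handles the deficiency.

Significance is assessed with an unrestricted Monte Carlo test: whole rows
of Y are permuted, the pseudo-F recomputed, and
p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RDAResult", "rda_fit", "rda_permutation_test"]


@dataclass(frozen=True)
class RDAResult:
    """Constrained ordination axes and the associated permutation test."""

    axis_eigenvalues: tuple[float, ...]     # variances of constrained axes
    variance_explained: tuple[float, ...]   # eigenvalue / total Y variance
    total_variance: float
    site_scores: pd.DataFrame               # nests, axes 1..k
    response_scores: pd.DataFrame           # substances, correlation scaling
    predictor_scores: pd.DataFrame          # taxa, correlation scaling
    rank: int
    pseudo_F: float | None = None
    permutation_p: float | None = None
    n_permutations: int | None = None


def _pretreat_y(Y: pd.DataFrame, scale: bool) -> pd.DataFrame:
    Yc = Y.astype(float)
    sd = Yc.std(ddof=1)
    dead = sd.index[sd == 0].tolist()
    if dead:
        raise ValueError(
            f"response column(s) constant after pretreatment: {', '.join(map(str, dead))}")
    Yc = Yc - Yc.mean()
    if scale:
        Yc = Yc / sd
    return Yc


def _fitted(Yc: np.ndarray, Xc: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    return Xc @ beta


def rda_fit(Y: pd.DataFrame, X: pd.DataFrame, scale_y: bool = True,
            n_axes: int = 2) -> RDAResult:
    """Fit the constrained ordination of ``Y`` on ``X`` (rows = same nests).

    Eigenvalues are variances (sum of squares / (n - 1)) of the fitted
    values along each axis; their sum plus the residual variance equals the
    total pretreated variance of ``Y`` exactly.  Scores for axes 1..k use
    correlation ("scaling 2") conventions: response and predictor scores
    are correlations of the original columns with the site scores.
    """
    if list(Y.index) != list(X.index):
        raise ValueError("Y and X must be indexed by the same nests, same order")
    n = len(Y)
    if n < 3:
        raise ValueError("RDA needs at least 3 nests")
    Yc = _pretreat_y(Y, scale_y)
    Xc = (X.astype(float) - X.astype(float).mean()).to_numpy()
    Ycv = Yc.to_numpy()

    fitted = _fitted(Ycv, Xc)
    rank = int(np.linalg.matrix_rank(Xc))
    total = float((Ycv**2).sum() / (n - 1))

    # eigendecomposition of the fitted-value covariance via SVD
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = min(n_axes, int((eig > 1e-12 * max(total, 1.0)).sum()))
    axes = [f"RDA{i + 1}" for i in range(keep)]

    site = u[:, :keep] * s[:keep]               # sample scores on fitted axes
    site_df = pd.DataFrame(site, index=Y.index, columns=axes)

    def _corr_scores(cols: pd.DataFrame) -> pd.DataFrame:
        vals = cols.to_numpy(dtype=float)
        out = np.zeros((vals.shape[1], keep))
        for j in range(keep):
            sj = site[:, j]
            for i in range(vals.shape[1]):
                vi = vals[:, i]
                if vi.std() == 0 or sj.std() == 0:
                    out[i, j] = 0.0
                else:
                    out[i, j] = np.corrcoef(vi, sj)[0, 1]
        return pd.DataFrame(out, index=cols.columns, columns=axes)

    return RDAResult(
        axis_eigenvalues=tuple(float(v) for v in eig[:keep]),
        variance_explained=tuple(float(v / total) for v in eig[:keep]),
        total_variance=total,
        site_scores=site_df,
        response_scores=_corr_scores(Y),
        predictor_scores=_corr_scores(X),
        rank=rank,
    )


def _basis(Xc: np.ndarray, rank: int) -> np.ndarray:
    """Orthonormal basis of the column space of the centered constraints."""
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    return u[:, :rank]


def _pseudo_f(Ycv: np.ndarray, Q: np.ndarray, rank: int) -> float:
    n = len(Ycv)
    ss_fit = float(((Q.T @ Ycv) ** 2).sum())
    ss_res = float((Ycv**2).sum()) - ss_fit
    df_res = n - 1 - rank
    if df_res <= 0 or ss_res <= 1e-12 * ss_fit:
        return np.inf
    return (ss_fit / rank) / (ss_res / df_res)


def rda_permutation_test(Y: pd.DataFrame, X: pd.DataFrame, n_perm: int = 499,
                         seed: int | None = None,
                         scale_y: bool = True) -> RDAResult:
    """RDA plus the unrestricted Monte Carlo test of the constraint.

    ``pseudo_F = (constrained SS / rank) / (residual SS / (n - 1 - rank))``;
    rows of the pretreated ``Y`` are permuted wholesale.  With the same
    seed the returned p is identical across runs, and it is always a
    multiple of ``1 / (n_perm + 1)``.
    """
    base = rda_fit(Y, X, scale_y=scale_y)
    Yc = _pretreat_y(Y, scale_y).to_numpy()
    Xc = (X.astype(float) - X.astype(float).mean()).to_numpy()
    rank = base.rank
    Q = _basis(Xc, rank)
    f_obs = _pseudo_f(Yc, Q, rank)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_perm = _pseudo_f(Yc[rng.permutation(len(Yc))], Q, rank)
        if f_perm >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return RDAResult(
        axis_eigenvalues=base.axis_eigenvalues,
        variance_explained=base.variance_explained,
        total_variance=base.total_variance,
        site_scores=base.site_scores,
        response_scores=base.response_scores,
        predictor_scores=base.predictor_scores,
        rank=base.rank,
        pseudo_F=float(f_obs),
        permutation_p=float(p),
        n_permutations=n_perm,
    )
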