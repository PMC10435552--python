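"""Landscape composition: standardization, factor analysis, ORC extraction.

Landscape structure around each nest is quantified inside circular buffers
(500 m and 1000 m radius) as the area fractions of 13 discrete cover types
plus two normalized linear-feature densities (field borders; borders
between fields and natural habitat).  Oilseed-rape coverage (ORC) is the
experimental gradient and is kept out of the factor analysis; the
remaining elements are standardized and reduced to two factors (FA1, FA2).

Extraction is principal-component based (eigendecomposition of the
correlation matrix) with varimax rotation - a deterministic default that
also works on the rank-deficient 12-sites-by-13-variables case where
maximum-likelihood factor analysis is ill-posed.  Unrotated loadings are
available via ``rotation="none"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "COVER_ELEMENTS",
    "LINEAR_ELEMENTS",
    "ORC_ELEMENT",
    "FactorModel",
    "standardize",
    "fit_factor_model",
    "orc_extract",
    "landscape_matrix",
    "landscape_predictors",
]

#: The 13 discrete, non-overlapping cover types (fractions of buffer area).
COVER_ELEMENTS = (
    "oilseed_rape",
    "cereals",
    "nonflowering_crops",
    "flowering_crops",
    "meadows",
    "forests",
    "bushes",
    "orchards",
    "vegetation_by_water",
    "vegetation_by_infrastructure",
    "water",
    "concrete",
    "buildings",
)

#: Linear fragmentation features (normalized length densities).
LINEAR_ELEMENTS = ("field_borders", "natural_borders")

ORC_ELEMENT = "oilseed_rape"


@dataclass(frozen=True)
class FactorModel:
    """Two-factor summary of landscape composition for one buffer radius."""

    loadings: pd.DataFrame       # elements x factors
    scores: pd.DataFrame         # sites x factors, standardized units
    variance_explained: tuple[float, ...]  # fraction of total variance each
    buffer_m: int
    rotation: str


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Columns to sample mean 0, sample SD 1 (ddof=1).

    Raises ``ValueError`` naming any constant column, for which a z-score
    is undefined.
    """
    m = matrix.astype(float)
    if len(m) < 2:
        raise ValueError("standardization needs at least 2 rows")
    sd = m.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant column(s): {', '.join(map(str, constant))}")
    return (m - m.mean()) / sd


def _varimax(loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Varimax rotation matrix for a p x k loading matrix (Kaiser, unnormalized)."""
    p, k = loadings.shape
    rot = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam**3 - lam @ np.diag((lam**2).sum(axis=0)) / p))
        rot = u @ vt
        new_var = s.sum()
        if new_var < var * (1 + tol):
            break
        var = new_var
    return rot


def fit_factor_model(matrix: pd.DataFrame, n_factors: int = 2,
                     rotation: str = "varimax", buffer_m: int = 0) -> FactorModel:
    """Factor analysis of a sites x elements matrix (ORC already excluded).

    Principal-component extraction: loadings are eigenvectors of the
    correlation matrix scaled by the root eigenvalues; ``variance_explained``
    is the per-factor sum of squared loadings over the number of variables.
    Scores are computed by the regression method (pseudo-inverse of the
    correlation matrix, which tolerates rank deficiency) and have mean 0.
    Sign convention: each factor is oriented so that its largest-|loading|
    element loads positively.
    """
    if rotation not in ("varimax", "none"):
        raise ValueError("rotation must be 'varimax' or 'none'")
    n, p = matrix.shape
    if n < n_factors + 1:
        raise ValueError(f"need at least {n_factors + 1} rows, got {n}")
    if p < n_factors:
        raise ValueError(f"need at least {n_factors} columns, got {p}")
    z = standardize(matrix)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    if not np.isfinite(corr).all():
        raise ValueError("singular correlation matrix; prune collinear columns")
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1][:n_factors]
    if eigval[order].min() <= 1e-12:
        raise ValueError("correlation matrix is rank deficient below the "
                         "requested number of factors; prune columns")
    load = eigvec[:, order] * np.sqrt(eigval[order])

    if rotation == "varimax":
        load = load @ _varimax(load)
    # order factors by explained variance, then fix signs
    ssq = (load**2).sum(axis=0)
    load = load[:, np.argsort(ssq)[::-1]]
    for j in range(n_factors):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] = -load[:, j]

    ssq = (load**2).sum(axis=0)
    var_explained = tuple(float(v) for v in ssq / p)
    scores = z.to_numpy() @ np.linalg.pinv(corr) @ load

    names = [f"FA{j + 1}" for j in range(n_factors)]
    return FactorModel(
        loadings=pd.DataFrame(load, index=matrix.columns, columns=names),
        scores=pd.DataFrame(scores, index=matrix.index, columns=names),
        variance_explained=var_explained,
        buffer_m=buffer_m,
        rotation=rotation,
    )


def landscape_matrix(landscape: pd.DataFrame, buffer_m: int,
                     include_linear: bool = True) -> pd.DataFrame:
    """Sites x elements wide matrix for one buffer, ORC column excluded."""
    sel = landscape[landscape["buffer_m"] == buffer_m]
    if sel.empty:
        raise KeyError(f"no landscape rows for buffer {buffer_m} m")
    wide = sel.pivot(index="site_id", columns="element", values="value")
    elements = [e for e in COVER_ELEMENTS if e != ORC_ELEMENT]
    if include_linear:
        elements += list(LINEAR_ELEMENTS)
    cols = [e for e in elements if e in wide.columns]
    out = wide[cols].fillna(0.0)
    out.columns.name = None
    return out


def orc_extract(landscape: pd.DataFrame, site: str, buffer_m: int) -> float:
    """Oilseed-rape coverage of one site/buffer as a fraction in [0, 1]."""
    sel = landscape[(landscape["site_id"] == site)
                    & (landscape["buffer_m"] == buffer_m)]
    if sel.empty:
        raise KeyError(f"no landscape rows for site {site!r}, buffer {buffer_m} m")
    orc = float(sel["orc"].iloc[0])
    if not 0.0 <= orc <= 1.0:
        raise ValueError(f"ORC {orc} outside [0, 1] for site {site!r}")
    return orc


def landscape_predictors(landscape: pd.DataFrame, buffer_m: int,
                         rotation: str = "varimax") -> pd.DataFrame:
    """Per-site ORC, FA1, FA2 and LDI for one buffer - the regression set."""
    from .diversity import ldi  # local import avoids a module cycle

    mat = landscape_matrix(landscape, buffer_m)
    model = fit_factor_model(mat, n_factors=2, rotation=rotation,
                             buffer_m=buffer_m)
    sites = list(mat.index)
    out = pd.DataFrame({
        "site_id": sites,
        "orc": [orc_extract(landscape, s, buffer_m) for s in sites],
        "fa1": model.scores["FA1"].to_numpy(),
        "fa2": model.scores["FA2"].to_numpy(),
        "ldi": [ldi(landscape, s, buffer_m) for s in sites],
    })
    return out
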