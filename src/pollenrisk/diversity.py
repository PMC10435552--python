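"""Shannon diversity, effective numbers of species, and taxa filtering.

The central quantity is the pollen effective number of species (PENS), the
Hill number of order 1 of a nest's pollen composition::

    H' = -sum_i p_i ln p_i        (Shannon-Wiener index, natural log)
    PENS = exp(H')

computed on proportions renormalized to sum exactly 1 (printed percentage
tables deviate from 100 by rounding).  The same index over the shares of
the seven bee-relevant landscape elements in a buffer is the Landscape
Diversity Index (LDI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Bundle

__all__ = [
    "DiversityResult",
    "shannon_index",
    "pens",
    "ldi",
    "prevalence_filter",
    "composition_summary",
    "nest_diversity",
    "BEE_FORAGE_ELEMENTS",
]

#: The seven landscape elements treated as potential bee foraging habitat;
#: only their shares (renormalized among themselves) enter the LDI.
BEE_FORAGE_ELEMENTS = (
    "vegetation_by_water",
    "vegetation_by_infrastructure",
    "bushes",
    "forests",
    "meadows",
    "orchards",
    "flowering_crops",
)


@dataclass(frozen=True)
class DiversityResult:
    """Diversity of one unit (a nest's pollen or a site's landscape)."""

    unit_id: str
    shannon_h: float        # nats
    effective_number: float  # exp(shannon_h), in [1, richness]
    richness: int           # categories with positive share


def _shares(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("shares must be a 1-D vector")
    if (v < 0).any():
        raise ValueError("shares must be nonnegative")
    total = v.sum()
    if total <= 0:
        raise ValueError("shares must contain at least one positive entry")
    return v / total


def shannon_index(shares) -> float:
    """Shannon-Wiener index (natural log) of a nonnegative share vector.

    Shares are renormalized to sum 1; zero entries contribute nothing.
    Raises ``ValueError`` on all-zero or negative input.
    """
    p = _shares(shares)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def pens(shares) -> float:
    """Effective number of species ``exp(H')`` (Hill number, order 1)."""
    return float(np.exp(shannon_index(shares)))


def richness(shares) -> int:
    """Number of categories with a strictly positive share."""
    v = np.asarray(shares, dtype=float)
    return int((v > 0).sum())


def ldi(landscape: pd.DataFrame, site: str, buffer_m: int,
        elements=BEE_FORAGE_ELEMENTS) -> float:
    """Landscape Diversity Index of one site/buffer.

    Shannon index of the shares of ``elements`` renormalized among
    themselves; an element absent from the table counts as 0.  Raises
    ``ValueError``, naming the site, when all seven shares are zero.
    """
    sel = landscape[(landscape["site_id"] == site)
                    & (landscape["buffer_m"] == buffer_m)]
    if sel.empty:
        raise KeyError(f"no landscape rows for site {site!r}, buffer {buffer_m} m")
    by_el = sel.set_index("element")["value"]
    v = np.array([float(by_el.get(e, 0.0)) for e in elements])
    if v.sum() <= 0:
        raise ValueError(f"site {site!r}: all bee-forage elements are zero")
    return shannon_index(v)


def prevalence_filter(pollen: pd.DataFrame, threshold_pct: float) -> list[str]:
    """Taxa whose maximum per-nest proportion strictly exceeds the threshold.

    Used to restrict ordination to non-rare pollen types.  Ordering is the
    taxon's first appearance in the table (stable).  Raising the threshold
    can only shrink the result.
    """
    if threshold_pct <= 0:
        raise ValueError("threshold must be > 0 percent")
    maxima = pollen.groupby("taxon", sort=False)["proportion_pct"].max()
    return [t for t in dict.fromkeys(pollen["taxon"]) if maxima[t] > threshold_pct]


def composition_summary(table: pd.DataFrame, key: str, value: str) -> pd.DataFrame:
    """Min/max/median per row label, over units where the label is present.

    Works for the pollen long table (``key='taxon'``) and the residue long
    table (``key='substance'``).  The median convention is the arithmetic
    mean of the central pair for even counts; a single-value row has
    min = max = median.
    """
    grouped = table.groupby(key, sort=False)[value]
    out = grouped.agg(n_present="count", min="min", max="max", median="median")
    if (out["n_present"] == 0).any():
        raise ValueError("summary requested for a label with no present values")
    return out.reset_index()


def nest_diversity(bundle: Bundle) -> pd.DataFrame:
    """Per-nest Shannon index, PENS and richness as a tidy table."""
    rows = []
    for nid, grp in bundle.pollen.groupby("nest_id", sort=False):
        v = grp["proportion_pct"].to_numpy()
        h = shannon_index(v)
        rows.append(DiversityResult(nid, h, float(np.exp(h)), richness(v)))
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df.set_index("unit_id").reindex(bundle.nest_ids).reset_index()
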