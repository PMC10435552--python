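"""Toxic-unit Pesticide Risk Index and residue summaries.

For each nest, every detected active substance contributes one toxic unit
(TU): the larval dose implied by the residue concentration and the mean
provision mass, scaled by the substance's oral acute 48-h honeybee LD50::

    TU_s = concentration_s [ng/g] x provision mass [g] / LD50_s [ng/bee]
    Risk Index = sum of TU_s over detected substances

Non-detections contribute zero.  Published LD50 values printed as a lower
bound ("> x") enter as exactly x, which makes the corresponding TU - and
hence the index - an upper bound on the value under any true LD50; such
terms are flagged.

The index is an additive hazard-exposure score, not a mortality
prediction: no honeybee-to-*Osmia* sensitivity scaling and no mixture
interactions are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Bundle

__all__ = [
    "RiskIndexResult",
    "resolve_ld50",
    "pesticide_risk_index",
    "risk_index_table",
    "detection_summary",
    "substance_median",
]


@dataclass(frozen=True)
class RiskIndexResult:
    """Per-nest toxic units and their sum."""

    nest_id: str
    toxic_units: dict[str, float]          # substance -> TU, detected only
    risk_index: float                      # sum of toxic units
    n_substances: int
    upper_bound_substances: tuple[str, ...] = ()  # TUs that are upper bounds


def resolve_ld50(ld50_ug_bee: float, lower_bound: bool = False) -> tuple[float, bool]:
    """Convert a catalog LD50 [ug/bee] to ng/bee for the TU denominator.

    When the published value is a lower bound ("> x"), the bound x itself is
    used - the conservative choice, making the TU an upper bound - and the
    returned flag is True.
    """
    if not ld50_ug_bee > 0:
        raise ValueError("LD50 must be positive")
    return float(ld50_ug_bee) * 1000.0, bool(lower_bound)


def pesticide_risk_index(residues: pd.DataFrame, nest_id: str,
                         provision_mass_mg: float,
                         catalog: pd.DataFrame) -> RiskIndexResult:
    """Toxic-unit Risk Index for one nest.

    ``residues`` is the long detected-only table; rows of other nests are
    ignored.  Every detected substance must appear in ``catalog``.
    """
    if not provision_mass_mg > 0:
        raise ValueError("provision mass must be positive")
    mass_g = provision_mass_mg / 1000.0
    cat = catalog.set_index("substance")
    tus: dict[str, float] = {}
    bounded: list[str] = []
    sel = residues[residues["nest_id"] == nest_id]
    for _, row in sel.iterrows():
        s = row["substance"]
        if s not in cat.index:
            raise KeyError(f"detected substance {s!r} missing from catalog")
        ld50_ng, is_bound = resolve_ld50(cat.at[s, "ld50_ug_bee"],
                                         cat.at[s, "ld50_bound"] == "greater_than")
        tus[s] = float(row["concentration_ng_g"]) * mass_g / ld50_ng
        if is_bound:
            bounded.append(s)
    return RiskIndexResult(nest_id, tus, float(sum(tus.values())),
                           len(tus), tuple(bounded))


def risk_index_table(bundle: Bundle) -> pd.DataFrame:
    """Risk Index for every nest of a bundle, as a tidy table."""
    rows = []
    for _, r in bundle.nests.iterrows():
        res = pesticide_risk_index(bundle.residues, r["nest_id"],
                                   r["provision_mass_mg"], bundle.substances)
        rows.append({"nest_id": res.nest_id, "risk_index": res.risk_index,
                     "n_substances": res.n_substances})
    return pd.DataFrame(rows)


def detection_summary(bundle: Bundle, substance: str) -> tuple[int, float]:
    """(number of nests detected, percent of nests detected)."""
    if substance not in set(bundle.substances["substance"]):
        raise KeyError(f"unknown substance {substance!r}")
    n = int((bundle.residues["substance"] == substance).sum())
    return n, 100.0 * n / len(bundle.nest_ids)


def substance_median(bundle: Bundle, substance: str) -> float:
    """Median concentration [ng/g] over nests where the substance was detected.

    Central-pair mean for even counts.  Raises ``ValueError`` when the
    substance was never detected (a median over nothing is undefined).
    """
    vals = bundle.residues.loc[bundle.residues["substance"] == substance,
                               "concentration_ng_g"]
    if vals.empty:
        if substance not in set(bundle.substances["substance"]):
            raise KeyError(f"unknown substance {substance!r}")
        raise ValueError(f"{substance!r} has no detections; median undefined")
    return float(np.median(vals))
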