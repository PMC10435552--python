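"""Data model, validation and CSV I/O for pollen-provision analyses.

The pipeline consumes five tabular inputs, all comma-separated UTF-8 text
with a mandatory header row:

``pollen.csv``
    Long table ``nest_id,taxon,proportion_pct`` of per-nest pollen-type
    proportions in percent of identified grains.  Printed source tables
    carry rounding, so per-nest sums are validated to 100 +/- 0.5 and all
    downstream math renormalizes to fractions summing to exactly 1.
``residues.csv``
    Long table ``nest_id,substance,concentration_ng_g`` with one row per
    *detected* (nest, substance) pair.  A pair absent from the table (or a
    row with an empty concentration cell) means *not detected*; it is never
    coerced to a zero concentration.
``substances.csv``
    Catalog ``substance,classes,loq_ng_g,ld50_ug_bee,ld50_bound`` with the
    assay limit of quantification and the oral acute 48-h honeybee LD50.
    ``ld50_bound`` is ``exact`` or ``greater_than`` (the published value is
    a lower bound, printed "> x").  ``classes`` is a ``;``-separated subset
    of {I, H, F, N, A} (insecticide/herbicide/fungicide/nematicide/acaricide).
``nests.csv``
    Per-nest scalars ``nest_id,provision_mass_mg,energetic_value_kj_g``.
``landscape.csv``
    Long table ``site_id,buffer_m,element,value,orc`` of landscape-element
    proportions per circular buffer (500 or 1000 m radius) plus the
    oilseed-rape coverage (ORC) of that buffer as a fraction.

Nest and site identifiers share one namespace (one nest per site).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "NestRecord",
    "Bundle",
    "read_dataset",
    "write_dataset",
    "load_builtin_fixtures",
    "POLLEN_COLUMNS",
    "RESIDUE_COLUMNS",
    "SUBSTANCE_COLUMNS",
    "NEST_COLUMNS",
    "LANDSCAPE_COLUMNS",
    "GARBLED_TAXA",
]

POLLEN_COLUMNS = ["nest_id", "taxon", "proportion_pct"]
RESIDUE_COLUMNS = ["nest_id", "substance", "concentration_ng_g"]
SUBSTANCE_COLUMNS = ["substance", "classes", "loq_ng_g", "ld50_ug_bee", "ld50_bound"]
NEST_COLUMNS = ["nest_id", "provision_mass_mg", "energetic_value_kj_g"]
LANDSCAPE_COLUMNS = ["site_id", "buffer_m", "element", "value", "orc"]

#: Source-table rows whose printed min/max columns are inconsistent with the
#: per-nest cells; transcribed as printed, flagged for the record.
GARBLED_TAXA = ("Eleagnus sp.", "Caprifoliaceae/Lonicera")

_CLASS_CODES = frozenset("IHFNA")
_POLLEN_SUM_TOL = 0.5

# Unicode dash variants occasionally found in extracted tables.
_DASH_TABLE = str.maketrans({"‐": "-", "‑": "-", "‒": "-",
                             "–": "-", "—": "-", "−": "-"})


class SchemaError(ValueError):
    """A file's header does not match the documented schema."""


class ValidationError(ValueError):
    """A table violates a type invariant; the message lists offending rows."""


@dataclass(frozen=True)
class NestRecord:
    """Per-nest scalars: mean larval provision mass and energy density."""

    nest_id: str
    provision_mass_mg: float
    energetic_value_kj_g: float


@dataclass(frozen=True)
class Bundle:
    """Validated bundle of the five analysis tables.

    ``landscape`` is optional: the landscape table of the original study is
    not published, so fixture bundles carry ``None`` there and
    landscape-dependent stages are skipped for them.
    """

    pollen: pd.DataFrame
    residues: pd.DataFrame
    substances: pd.DataFrame
    nests: pd.DataFrame
    landscape: pd.DataFrame | None = None

    # -- accessors ---------------------------------------------------------

    @property
    def nest_ids(self) -> list[str]:
        return list(self.nests["nest_id"])

    def nest(self, nest_id: str) -> NestRecord:
        row = self.nests.loc[self.nests["nest_id"] == nest_id]
        if row.empty:
            raise KeyError(f"unknown nest {nest_id!r}")
        r = row.iloc[0]
        return NestRecord(r["nest_id"], float(r["provision_mass_mg"]),
                          float(r["energetic_value_kj_g"]))

    def pollen_matrix(self) -> pd.DataFrame:
        """Nests x taxa matrix of percentages, absent taxa as 0.

        Row order follows ``nests.csv``; column order is first appearance in
        the long table (stable, matters for prevalence filtering).
        """
        taxa = list(dict.fromkeys(self.pollen["taxon"]))
        wide = (self.pollen.pivot(index="nest_id", columns="taxon",
                                  values="proportion_pct")
                .reindex(index=self.nest_ids, columns=taxa)
                .fillna(0.0))
        wide.columns.name = None
        return wide

    def residue_matrix(self, fill: float = 0.0) -> pd.DataFrame:
        """Nests x substances concentrations with non-detects as ``fill``.

        Columns cover every substance with at least one detection, in
        catalog order.
        """
        detected = [s for s in self.substances["substance"]
                    if s in set(self.residues["substance"])]
        wide = (self.residues.pivot(index="nest_id", columns="substance",
                                    values="concentration_ng_g")
                .reindex(index=self.nest_ids, columns=detected)
                .fillna(fill))
        wide.columns.name = None
        return wide

    def is_detected(self, nest_id: str, substance: str) -> bool:
        m = ((self.residues["nest_id"] == nest_id)
             & (self.residues["substance"] == substance))
        return bool(m.any())


# ---------------------------------------------------------------------------
# reading


def _require_columns(df: pd.DataFrame, expected: list[str], name: str) -> pd.DataFrame:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{name}: missing column(s) {', '.join(missing)}; "
            f"expected header {','.join(expected)}")
    return df[expected]

def _normalize_labels(df: pd.DataFrame) -> pd.DataFrame:
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].astype(str).str.translate(_DASH_TABLE).str.strip()
    return df


def _read_csv(path: str | Path, expected: list[str], name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{name} table not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{name}: file {path} is empty") from None
    df = _require_columns(df, expected, name)
    return _normalize_labels(df)


def _to_float(df: pd.DataFrame, cols: Iterable[str], name: str,
              allow_empty: Iterable[str] = ()) -> pd.DataFrame:
    for col in cols:
        blank = df[col] == ""
        if blank.any() and col not in allow_empty:
            raise ValidationError(f"{name}: empty values in column {col!r}")
        try:
            out = pd.to_numeric(df[col].where(~blank, other=np.nan))
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{name}: non-numeric value in {col!r}: {exc}")
        df[col] = out.astype(float)
    return df


def read_dataset(
    pollen: str | Path,
    residues: str | Path,
    substances: str | Path,
    nests: str | Path,
    landscape: str | Path | None = None,
) -> Bundle:
    """Read and validate the five CSV tables into a :class:`Bundle`.

    Raises :class:`SchemaError` when a header does not match, and
    :class:`ValidationError` (listing the offending rows) when a type
    invariant fails.  No partial bundle is ever returned.
    """
    pol = _to_float(_read_csv(pollen, POLLEN_COLUMNS, "pollen"),
                    ["proportion_pct"], "pollen")
    res = _to_float(_read_csv(residues, RESIDUE_COLUMNS, "residues"),
                    ["concentration_ng_g"], "residues",
                    allow_empty=["concentration_ng_g"])
    # empty concentration cell = not detected; drop the row
    res = res.dropna(subset=["concentration_ng_g"]).reset_index(drop=True)
    sub = _to_float(_read_csv(substances, SUBSTANCE_COLUMNS, "substances"),
                    ["loq_ng_g", "ld50_ug_bee"], "substances")
    nst = _to_float(_read_csv(nests, NEST_COLUMNS, "nests"),
                    ["provision_mass_mg", "energetic_value_kj_g"], "nests")
    lnd = None
    if landscape is not None:
        lnd = _to_float(_read_csv(landscape, LANDSCAPE_COLUMNS, "landscape"),
                        ["buffer_m", "value", "orc"], "landscape")
    bundle = Bundle(pol, res, sub, nst, lnd)
    validate_bundle(bundle)
    return bundle


def validate_bundle(bundle: Bundle) -> None:
    """Check every type invariant; raise :class:`ValidationError` if any fails."""
    problems: list[str] = []
    pol, res, sub, nst = bundle.pollen, bundle.residues, bundle.substances, bundle.nests

    bad = pol[(pol["proportion_pct"] < 0) | (pol["proportion_pct"] > 100)]
    for _, r in bad.iterrows():
        problems.append(f"pollen: {r.nest_id}/{r.taxon} proportion "
                        f"{r.proportion_pct} outside [0, 100]")
    dup = pol.duplicated(subset=["nest_id", "taxon"])
    for _, r in pol[dup].iterrows():
        problems.append(f"pollen: duplicate taxon {r.taxon!r} in nest {r.nest_id}")
    sums = pol.groupby("nest_id")["proportion_pct"].sum()
    for nid, s in sums.items():
        if abs(s - 100.0) > _POLLEN_SUM_TOL:
            problems.append(f"pollen: nest {nid} proportions sum to {s:.2f}, "
                            f"outside 100 +/- {_POLLEN_SUM_TOL}")

    bad = res[res["concentration_ng_g"] <= 0]
    for _, r in bad.iterrows():
        problems.append(f"residues: {r.nest_id}/{r.substance} detected "
                        f"concentration {r.concentration_ng_g} is not > 0")
    dup = res.duplicated(subset=["nest_id", "substance"])
    for _, r in res[dup].iterrows():
        problems.append(f"residues: duplicate pair {r.nest_id}/{r.substance}")

    for _, r in sub.iterrows():
        if not r["loq_ng_g"] > 0:
            problems.append(f"substances: {r.substance} LOQ {r.loq_ng_g} is not > 0")
        if not r["ld50_ug_bee"] > 0:
            problems.append(f"substances: {r.substance} LD50 {r.ld50_ug_bee} is not > 0")
        if r["ld50_bound"] not in ("exact", "greater_than"):
            problems.append(f"substances: {r.substance} ld50_bound "
                            f"{r.ld50_bound!r} not in {{exact, greater_than}}")
        codes = set(filter(None, str(r["classes"]).split(";")))
        if not codes <= _CLASS_CODES:
            problems.append(f"substances: {r.substance} classes {r.classes!r} "
                            f"outside {{I, H, F, N, A}}")
    if sub["substance"].duplicated().any():
        problems.append("substances: duplicate substance labels")

    for _, r in nst.iterrows():
        if not r["provision_mass_mg"] > 0:
            problems.append(f"nests: {r.nest_id} provision_mass_mg not > 0")
        if not r["energetic_value_kj_g"] > 0:
            problems.append(f"nests: {r.nest_id} energetic_value_kj_g not > 0")
    if nst["nest_id"].duplicated().any():
        problems.append("nests: duplicate nest_id")

    known_nests = set(nst["nest_id"])
    for name, df in (("pollen", pol), ("residues", res)):
        unknown = sorted(set(df["nest_id"]) - known_nests)
        if unknown:
            problems.append(f"{name}: nest_id(s) {unknown} absent from nests table")
    unknown = sorted(set(res["substance"]) - set(sub["substance"]))
    if unknown:
        problems.append(f"residues: substance(s) {unknown} absent from catalog")

    if bundle.landscape is not None:
        lnd = bundle.landscape
        bad = lnd[(lnd["orc"] < 0) | (lnd["orc"] > 1)]
        for _, r in bad.iterrows():
            problems.append(f"landscape: {r.site_id}/{int(r.buffer_m)} m "
                            f"ORC {r.orc} outside [0, 1]")
        from .landscape import COVER_ELEMENTS  # avoid cycle at import time
        cover = lnd[lnd["element"].isin(COVER_ELEMENTS)]
        csums = cover.groupby(["site_id", "buffer_m"])["value"].sum()
        for (sid, buf), s in csums.items():
            if s > 1 + 1e-4:  # absorbs 6-decimal write precision
                problems.append(f"landscape: {sid}/{int(buf)} m cover fractions "
                                f"sum to {s:.4f} > 1")

    if problems:
        raise ValidationError("invalid bundle:\n  " + "\n  ".join(problems))


# ---------------------------------------------------------------------------
# writing

_FORMATS = {
    "proportion_pct": "%.2f", "concentration_ng_g": "%.2f",
    "loq_ng_g": "%.2f", "ld50_ug_bee": "%.2f",
    "provision_mass_mg": "%.2f", "energetic_value_kj_g": "%.2f",
}


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col, fmt in _FORMATS.items():
        if col in out.columns:
            out[col] = out[col].map(lambda v: fmt % v)
    out.to_csv(path, index=False, lineterminator="\n")


def write_dataset(bundle: Bundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle to ``directory`` in the canonical CSV dialect.

    Round-trip contract: ``write_dataset`` then :func:`read_dataset` on the
    canonical files reproduces the bundle, and re-writing is byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "pollen": directory / "pollen.csv",
        "residues": directory / "residues.csv",
        "substances": directory / "substances.csv",
        "nests": directory / "nests.csv",
    }
    _write_csv(bundle.pollen, paths["pollen"])
    _write_csv(bundle.residues, paths["residues"])
    _write_csv(bundle.substances, paths["substances"])
    _write_csv(bundle.nests, paths["nests"])
    if bundle.landscape is not None:
        paths["landscape"] = directory / "landscape.csv"
        lnd = bundle.landscape.copy()
        lnd["buffer_m"] = lnd["buffer_m"].astype(int)
        lnd["value"] = lnd["value"].map(lambda v: "%.6f" % v)
        lnd["orc"] = lnd["orc"].map(lambda v: "%.6f" % v)
        lnd.to_csv(paths["landscape"], index=False, lineterminator="\n")
    return paths


def load_builtin_fixtures() -> Bundle:
    """Load the transcription of the study's two printed tables.

    The bundle covers the twelve nests A1-A12: pollen-type proportions,
    detected pesticide concentrations with the substance catalog (LOQ and
    honeybee oral 48-h LD50), provision masses and energetic values.  The
    landscape table was never published, so ``bundle.landscape`` is None.
    """
    root = resources.files("pollenrisk") / "fixtures"
    with resources.as_file(root) as d:
        return read_dataset(d / "pollen.csv", d / "residues.csv",
                            d / "substances.csv", d / "nests.csv")
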