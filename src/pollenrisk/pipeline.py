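"""End-to-end orchestration and reporting.

``run_reproduction`` recomputes every derived quantity that the packaged
study tables support: per-nest diversity (PENS) and toxic-unit Risk Index,
per-taxon and per-substance summaries, the RMA regressions of the Risk
Index and of energetic value on PENS, the simple regression of the Risk
Index on the *Brassica napus* share, and the constrained ordination (RDA)
of residues on the prevalent pollen taxa.  The landscape table of the
study is unpublished, so landscape-dependent regressions are skipped there
with an explicit notice.

``run_full_analysis`` runs the complete workflow - including the
per-buffer backward-eliminated regressions of PENS, Risk Index and
energetic value on {ORC, FA1, FA2, LDI} - on a user-supplied or generated
five-table bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .data import Bundle, load_builtin_fixtures, read_dataset
from .diversity import composition_summary, nest_diversity, prevalence_filter
from .inference import (RegressionResult, RMAResult, backward_eliminate,
                        rma_regression, simple_regression)
from .landscape import landscape_predictors, standardize
from .ordination import RDAResult, rda_permutation_test
from .risk import detection_summary, risk_index_table, substance_median

__all__ = ["AnalysisReport", "run_reproduction", "run_full_analysis",
           "save_report", "load_report", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: Mapping[str, Any] = {
    "buffers": [500, 1000],
    "alpha": 0.05,
    "prevalence_threshold_pct": 1.0,
    "n_permutations": 499,
    "seed": 42,
    "scale_y": True,
    "rotation": "varimax",
    "sections": ["diversity", "risk", "models"],
}


@dataclass
class AnalysisReport:
    """Structured result of a pipeline run."""

    per_nest: pd.DataFrame
    per_taxon: pd.DataFrame
    per_substance: pd.DataFrame
    models: dict[str, Any] = field(default_factory=dict)
    notices: tuple[str, ...] = ()
    provenance: dict[str, Any] = field(default_factory=dict)

    def as_dict(self) -> dict[str, Any]:
        """Pure-python representation (used for serialization and equality)."""
        return {
            "per_nest": self.per_nest.to_dict(orient="list"),
            "per_taxon": self.per_taxon.to_dict(orient="list"),
            "per_substance": self.per_substance.to_dict(orient="list"),
            "models": {k: _model_to_dict(v) for k, v in self.models.items()},
            "notices": list(self.notices),
            "provenance": self.provenance,
        }


def _model_to_dict(model: Any) -> dict[str, Any]:
    if isinstance(model, dict):
        return model
    out: dict[str, Any] = {"kind": type(model).__name__}
    for f in dataclasses.fields(model):
        v = getattr(model, f.name)
        if isinstance(v, pd.DataFrame):
            v = {"index": list(map(str, v.index)),
                 "columns": list(map(str, v.columns)),
                 "data": [[float(x) for x in row] for row in v.to_numpy()]}
        elif isinstance(v, tuple):
            v = _tuples_to_lists(v)
        out[f.name] = v
    return out


def _tuples_to_lists(v):
    if isinstance(v, tuple):
        return [_tuples_to_lists(x) for x in v]
    return v


def _config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps({k: config[k] for k in sorted(config)},
                   default=str).encode()).hexdigest()[:16]


def _per_nest_table(bundle: Bundle) -> pd.DataFrame:
    div = nest_diversity(bundle).rename(columns={"unit_id": "nest_id",
                                                 "effective_number": "pens"})
    return (div.merge(risk_index_table(bundle), on="nest_id")
               .merge(bundle.nests, on="nest_id"))


def _per_substance_table(bundle: Bundle) -> pd.DataFrame:
    rows = []
    for s in bundle.substances["substance"]:
        n, pct = detection_summary(bundle, s)
        if n == 0:
            continue
        vals = bundle.residues.loc[bundle.residues["substance"] == s,
                                   "concentration_ng_g"]
        rows.append({"substance": s, "n_detected": n, "pct_detected": pct,
                     "min": float(vals.min()), "max": float(vals.max()),
                     "median": substance_median(bundle, s)})
    return pd.DataFrame(rows)


def _fixture_models(bundle: Bundle, per_nest: pd.DataFrame,
                    threshold_pct: float, n_perm: int, seed: int,
                    scale_y: bool) -> dict[str, Any]:
    pens = per_nest["pens"].to_numpy()
    risk = per_nest["risk_index"].to_numpy()
    energy = per_nest["energetic_value_kj_g"].to_numpy()
    models: dict[str, Any] = {
        "rma_risk_on_pens": rma_regression(pens, risk),
        "rma_energy_on_pens": rma_regression(pens, energy),
    }
    wide = bundle.pollen_matrix()
    bn = wide["Brassica napus"].to_numpy() if "Brassica napus" in wide else None
    if bn is not None:
        models["simple_risk_on_bnapus"] = simple_regression(
            bn, risk, response="risk_index", predictor="bnapus_pct")
    taxa = prevalence_filter(bundle.pollen, threshold_pct)
    X = wide[taxa] / 100.0
    Y = bundle.residue_matrix(fill=0.0)
    models["rda_residues_on_taxa"] = rda_permutation_test(
        Y, X, n_perm=n_perm, seed=seed, scale_y=scale_y)
    return models


def run_reproduction(n_perm: int = 499, seed: int = 42,
                     prevalence_threshold_pct: float = 1.0,
                     scale_y: bool = True) -> AnalysisReport:
    """Recompute the study's derived numbers from the packaged tables."""
    bundle = load_builtin_fixtures()
    per_nest = _per_nest_table(bundle)
    per_taxon = composition_summary(bundle.pollen, "taxon", "proportion_pct")
    per_sub = _per_substance_table(bundle)
    models = _fixture_models(bundle, per_nest, prevalence_threshold_pct,
                             n_perm, seed, scale_y)
    config = {"n_permutations": n_perm, "seed": seed,
              "prevalence_threshold_pct": prevalence_threshold_pct,
              "scale_y": scale_y}
    return AnalysisReport(
        per_nest=per_nest, per_taxon=per_taxon, per_substance=per_sub,
        models=models,
        notices=("landscape-dependent regressions skipped: "
                 "requires landscape table",),
        provenance={"source": "builtin fixtures", "version": __version__,
                    "seed": seed, "config_hash": _config_hash(config)},
    )


def run_full_analysis(bundle: Bundle | None = None,
                      config: Mapping[str, Any] | None = None,
                      tables: Mapping[str, str] | None = None) -> AnalysisReport:
    """Complete workflow on a five-table bundle.

    ``config`` overrides :data:`DEFAULT_CONFIG`; unknown keys raise with
    the list of valid keys.  Requires the landscape table and at least 5
    sites for the regression stack.
    """
    cfg = dict(DEFAULT_CONFIG)
    for key, value in (config or {}).items():
        if key not in DEFAULT_CONFIG:
            raise KeyError(f"unknown config key {key!r}; valid keys: "
                           f"{', '.join(sorted(DEFAULT_CONFIG))}")
        cfg[key] = value
    if bundle is None:
        if tables is None:
            raise ValueError("provide a bundle or a mapping of table paths")
        missing = [t for t in ("pollen", "residues", "substances", "nests")
                   if t not in tables]
        if missing:
            raise ValueError(f"missing table(s): {', '.join(missing)}")
        bundle = read_dataset(tables["pollen"], tables["residues"],
                              tables["substances"], tables["nests"],
                              tables.get("landscape"))

    sections = set(cfg["sections"])
    per_nest = _per_nest_table(bundle)
    per_taxon = composition_summary(bundle.pollen, "taxon", "proportion_pct")
    per_sub = _per_substance_table(bundle)

    models: dict[str, Any] = {}
    notices: list[str] = []
    if "models" in sections:
        models.update(_fixture_models(
            bundle, per_nest, cfg["prevalence_threshold_pct"],
            cfg["n_permutations"], cfg["seed"], cfg["scale_y"]))
        if bundle.landscape is None:
            notices.append("landscape-dependent regressions skipped: "
                           "requires landscape table")
        else:
            if len(per_nest) < 5:
                raise ValueError("landscape regressions need at least 5 sites")
            for buffer_m in cfg["buffers"]:
                pred = landscape_predictors(bundle.landscape, buffer_m,
                                            rotation=cfg["rotation"])
                merged = per_nest.merge(pred, left_on="nest_id",
                                        right_on="site_id")
                X = standardize(merged[["orc", "fa1", "fa2", "ldi"]])
                for resp, col in (("pens", "pens"),
                                  ("risk_index", "risk_index"),
                                  ("energy", "energetic_value_kj_g")):
                    models[f"backward_{resp}_{buffer_m}m"] = backward_eliminate(
                        merged[col].to_numpy(), X, alpha=cfg["alpha"],
                        response=resp)

    return AnalysisReport(
        per_nest=per_nest, per_taxon=per_taxon, per_substance=per_sub,
        models=models, notices=tuple(notices),
        provenance={"source": "user tables", "version": __version__,
                    "seed": cfg["seed"], "config_hash": _config_hash(cfg)},
    )


# ---------------------------------------------------------------------------
# serialization

def save_report(report: AnalysisReport, directory: str | Path) -> Path:
    """Write the report as a CSV set plus ``report.json`` and a text summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    report.per_nest.to_csv(directory / "per_nest.csv", index=False)
    report.per_taxon.to_csv(directory / "per_taxon.csv", index=False)
    report.per_substance.to_csv(directory / "per_substance.csv", index=False)
    with open(directory / "report.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=1, default=str)
    (directory / "summary.txt").write_text(format_summary(report))
    return directory


def load_report(directory: str | Path) -> AnalysisReport:
    """Read a saved report; models come back as plain dictionaries."""
    directory = Path(directory)
    with open(directory / "report.json") as fh:
        doc = json.load(fh)
    return AnalysisReport(
        per_nest=pd.DataFrame(doc["per_nest"]),
        per_taxon=pd.DataFrame(doc["per_taxon"]),
        per_substance=pd.DataFrame(doc["per_substance"]),
        models=doc["models"],
        notices=tuple(doc["notices"]),
        provenance=doc["provenance"],
    )


def format_summary(report: AnalysisReport) -> str:
    """Human-readable summary at tabular precision (2 dp; risk as x10^-3)."""
    lines = ["Pollen provision analysis", "=" * 25, "", "Per nest:"]
    for _, r in report.per_nest.iterrows():
        lines.append(
            f"  {r.nest_id:>4s}  PENS {r.pens:5.2f}  richness {int(r.richness):2d}  "
            f"risk {1000 * r.risk_index:7.3f} x10^-3  "
            f"energy {r.energetic_value_kj_g:5.2f} kJ/g")
    lines += ["", "Detected substances:"]
    for _, r in report.per_substance.iterrows():
        lines.append(
            f"  {r.substance:<16s} {int(r.n_detected):2d}/{len(report.per_nest)} nests "
            f"({r.pct_detected:5.2f}%)  median {r['median']:6.2f} ng/g")
    if report.models:
        lines += ["", "Models:"]
        for name, m in report.models.items():
            if isinstance(m, RMAResult):
                lines.append(f"  {name}: slope {m.slope:+.4g}, r {m.r:+.3f}, "
                             f"p {m.p_value:.3g}")
            elif isinstance(m, RegressionResult):
                terms = ", ".join(f"{t} (beta {b:+.3g}, p {p:.3g})"
                                  for t, b, p in m.terms) or "intercept only"
                lines.append(f"  {name}: {terms}; R2 {m.r_squared:.2f}, "
                             f"model p {m.model_p:.3g}")
            elif isinstance(m, RDAResult):
                ve = ", ".join(f"{100 * v:.1f}%" for v in m.variance_explained)
                lines.append(f"  {name}: axes explain {ve}; "
                             f"p {m.permutation_p}")
    for n in report.notices:
        lines.append(f"note: {n}")
    return "\n".join(lines) + "\n"
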