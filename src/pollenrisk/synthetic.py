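"""Synthetic study generator with known ground truth.

The landscape table of the original field study was never published, so
this module emulates the whole study design: sites on an oilseed-rape
coverage (ORC) gradient, buffers described by 13 cover types plus two
linear features, nest pollen compositions, left-censored pesticide
residues, provision masses and energetic values.  All latent effect sizes
are configurable and recorded, giving every pipeline stage a test bed
with known truth.

Generative model (one global seed, all draws from one generator):

* **Landscape** - non-crop cover shares per site are Dirichlet draws; the
  ORC gradient is imposed (evenly spaced over ``orc_range``) and the rest
  renormalized to ``1 - ORC``.  Linear-feature densities follow the
  arable/natural character of the buffer.  A "naturalness" latent score is
  the standardized share of woods, meadows, bushes and water-side
  vegetation.
* **Pollen** - each nest's expected composition tilts toward *Brassica
  napus* with ORC and toward tree taxa with naturalness.  The expected
  diversity is controlled through a tempering exponent solved so that the
  effective number of species of the mean composition equals a linear
  target ``pens_base + effect_pens_ldi * z(LDI) + noise``; the realized
  composition is a Dirichlet draw around that mean whose total
  concentration ``grain_count`` mimics the number of pollen grains scored.
* **Residues** - per-substance Bernoulli detection with probability
  increasing in ORC; concentrations lognormal (heavy right tail);
  draws below the assay LOQ are censored to *not detected*.
* **Energetics** - energetic value is linear in z(LDI) with Gaussian
  noise; provision masses are uniform over ``mass_range``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data import Bundle, load_builtin_fixtures, validate_bundle
from .diversity import ldi as _ldi_of
from .landscape import COVER_ELEMENTS, LINEAR_ELEMENTS, ORC_ELEMENT

__all__ = ["SyntheticConfig", "SyntheticBundle", "generate_dataset",
           "ground_truth", "DEFAULT_TAXA", "DEFAULT_RESIDUE_PARAMS"]

#: The 28 pollen taxa of the study region (fixture namespace).
DEFAULT_TAXA = (
    "Brassica napus", "Acer sp.", "Achillea typ", "Aesculus sp.",
    "Caprifoliaceae/Lonicera", "Carex sp.", "Caryophyllaceae",
    "Centaurea cyanus", "Chenopodiaceae", "Cornus sp.", "Eleagnus sp.",
    "Hypericum sp.", "Juglans sp.", "Lamium sp.", "Malus sp.",
    "Papaver sp.", "Pinus sp.", "Plantago sp.", "Poaceae", "Prunus sp.",
    "Pyrus sp.", "Quercus sp.", "Ranunculus sp.", "Rubus sp.", "Rumex sp.",
    "Salix sp.", "Trifolium repens", "Viola tricolor",
)

_TREE_TAXA = frozenset({
    "Acer sp.", "Quercus sp.", "Salix sp.", "Prunus sp.", "Juglans sp.",
    "Aesculus sp.", "Pinus sp.", "Malus sp.", "Pyrus sp.", "Cornus sp.",
    "Eleagnus sp.",
})

# Baseline taxon propensities: the crop dominates, a handful of taxa are
# common, the rest rare - mirrors the observed provision structure.
_TAXON_BASE = {
    "Brassica napus": 8.0, "Poaceae": 2.0, "Ranunculus sp.": 2.0,
    "Quercus sp.": 2.0, "Acer sp.": 1.5, "Rubus sp.": 1.2,
    "Hypericum sp.": 1.2, "Rumex sp.": 0.8, "Prunus sp.": 0.8,
}
_TAXON_RARE = 0.3

#: substance -> (detection prob at mean ORC, increase per unit ORC,
#:               log-mean ln(ng/g), log-SD, LOQ ng/g)
DEFAULT_RESIDUE_PARAMS: Mapping[str, tuple[float, float, float, float, float]] = (
    MappingProxyType({
        "acetamiprid":    (0.75, 0.5, -1.27, 1.0, 0.10),
        "azoxystrobin":   (0.58, 0.5, 2.36, 1.3, 1.00),
        "boscalid":       (0.58, 0.5, 2.42, 1.0, 0.01),
        "chlorothalonil": (0.10, 0.3, 0.77, 1.0, 1.00),
        "difenoconazole": (0.17, 0.3, 3.15, 1.0, 0.01),
        "fluopyram":      (0.50, 0.5, 2.01, 1.0, 1.00),
        "fluxapyroxad":   (0.33, 0.5, 0.95, 1.0, 1.00),
        "picoxystrobin":  (0.10, 0.3, 1.31, 1.0, 0.10),
        "tebuconazole":   (0.42, 0.5, 2.79, 1.0, 1.00),
        "dimethoate":     (0.58, 0.5, 1.47, 1.0, 1.00),
        "omethoate":      (0.50, 0.5, 1.16, 1.0, 5.00),
        "prosulfocarb":   (0.10, 0.3, 3.27, 1.0, 1.00),
    }))

# Dirichlet propensities for the 12 non-crop cover types.
_COVER_BASE = {
    "cereals": 8.0, "nonflowering_crops": 5.0, "flowering_crops": 1.5,
    "meadows": 3.0, "forests": 4.0, "bushes": 1.0, "orchards": 1.0,
    "vegetation_by_water": 0.8, "vegetation_by_infrastructure": 0.8,
    "water": 0.5, "concrete": 1.0, "buildings": 1.0,
}
_NATURAL_ELEMENTS = ("meadows", "forests", "bushes", "vegetation_by_water")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for :func:`generate_dataset`.

    Defaults reproduce the design the fixtures come from: 12 sites on a
    6-65 % ORC gradient, the 28-taxon pollen pool, provision masses in the
    observed 212-255 mg range, negative diversity-vs-landscape-diversity
    effect and positive energy effect.
    """

    n_sites: int = 12
    orc_range: tuple[float, float] = (0.06, 0.65)
    taxa_pool: tuple[str, ...] = DEFAULT_TAXA
    effect_pens_ldi: float = -0.8     # PENS units per SD of LDI
    pens_base: float = 4.5
    pens_noise_sd: float = 0.5
    effect_energy_ldi: float = 0.35   # kJ/g per SD of LDI
    energy_base: float = 18.0
    energy_noise_sd: float = 0.30
    orc_tilt: float = 1.2             # log-propensity of B. napus per z(ORC)
    naturalness_tilt: float = 0.8     # log-propensity of tree taxa per z
    grain_count: float = 300.0        # Dirichlet total concentration
    mass_range: tuple[float, float] = (212.0, 255.0)
    residue_params: Mapping[str, tuple[float, float, float, float, float]] = (
        field(default_factory=lambda: DEFAULT_RESIDUE_PARAMS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ValueError("need at least 3 sites")
        lo, hi = self.orc_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("orc_range must be an ordered pair inside [0, 1]")
        if not self.grain_count > 0:
            raise ValueError("Dirichlet concentration (grain_count) must be > 0")
        if not self.mass_range[0] < self.mass_range[1]:
            raise ValueError("mass_range must be ordered")
        if len(self.taxa_pool) < 3:
            raise ValueError("taxa pool too small")
        for s, (p, slope, mu, sd, loq) in self.residue_params.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{s}: detection probability {p} outside [0, 1]")
            if sd <= 0 or loq <= 0:
                raise ValueError(f"{s}: log-SD and LOQ must be positive")
        for sd in (self.pens_noise_sd, self.energy_noise_sd):
            if sd < 0:
                raise ValueError("noise SDs must be nonnegative")


@dataclass(frozen=True)
class SyntheticBundle(Bundle):
    """A generated bundle carrying its latent ground truth."""

    truth: Mapping[str, object] = field(default_factory=dict, compare=False)


def ground_truth(bundle: Bundle) -> Mapping[str, object]:
    """Latent parameter record of a generated bundle (read-only).

    Raises ``TypeError`` for bundles that did not come out of
    :func:`generate_dataset`.
    """
    if not isinstance(bundle, SyntheticBundle):
        raise TypeError("ground truth is only available for generated bundles")
    return bundle.truth


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _temper_to_pens(mean: np.ndarray, target: float) -> np.ndarray:
    """Exponent-temper ``mean`` so its effective number of species = target."""
    def pens_of(t: float) -> float:
        w = mean**t
        p = w / w.sum()
        p = p[p > 1e-300]
        return float(np.exp(-(p * np.log(p)).sum()))

    lo, hi = 1e-4, 60.0
    target = min(max(target, pens_of(hi) + 1e-6), pens_of(lo) - 1e-6)
    t = brentq(lambda t: pens_of(t) - target, lo, hi, xtol=1e-10)
    w = mean**t
    return w / w.sum()


def _gen_landscape(cfg: SyntheticConfig, rng: np.random.Generator):
    sites = [f"A{i + 1}" for i in range(cfg.n_sites)]
    orc500 = np.linspace(cfg.orc_range[0], cfg.orc_range[1], cfg.n_sites)
    rows = []
    shares500 = {}
    noncrop = [e for e in COVER_ELEMENTS if e != ORC_ELEMENT]
    alpha = np.array([_COVER_BASE[e] for e in noncrop])
    for i, site in enumerate(sites):
        base = rng.dirichlet(alpha)
        for buffer_m in (500, 1000):
            if buffer_m == 500:
                shares = base
                orc = orc500[i]
            else:
                # the wider buffer resembles the inner one with fresh detail
                shares = 0.7 * base + 0.3 * rng.dirichlet(alpha)
                shares = shares / shares.sum()
                orc = float(np.clip(orc500[i] * rng.uniform(0.8, 1.2), 0.0, 0.95))
            cover = dict(zip(noncrop, (1.0 - orc) * shares))
            cover[ORC_ELEMENT] = orc
            arable = cover["cereals"] + cover["nonflowering_crops"] + orc
            natural = sum(cover[e] for e in _NATURAL_ELEMENTS)
            linear = {
                "field_borders": float(np.clip(
                    0.25 + 0.6 * arable + rng.normal(0, 0.05), 0.0, 1.0)),
                "natural_borders": float(np.clip(
                    0.15 + 0.8 * natural + rng.normal(0, 0.05), 0.0, 1.0)),
            }
            for el in COVER_ELEMENTS:
                rows.append((site, buffer_m, el, cover[el], orc))
            for el in LINEAR_ELEMENTS:
                rows.append((site, buffer_m, el, linear[el], orc))
            if buffer_m == 500:
                shares500[site] = cover
    df = pd.DataFrame(rows, columns=["site_id", "buffer_m", "element",
                                     "value", "orc"])
    naturalness = np.array([sum(shares500[s][e] for e in _NATURAL_ELEMENTS)
                            for s in sites])
    return sites, orc500, df, naturalness


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticBundle:
    """Generate a full five-table bundle plus its ground-truth record.

    The same config (including its seed) always produces the identical
    bundle.  Every generated bundle passes the data-model validation.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    sites, orc, land_df, naturalness = _gen_landscape(cfg, rng)
    ldi = np.array([_ldi_of(land_df, s, 500) for s in sites])
    ldi_z, orc_z, nat_z = _zscore(ldi), _zscore(orc), _zscore(naturalness)

    # --- pollen ----------------------------------------------------------
    taxa = list(cfg.taxa_pool)
    base_w = np.array([_TAXON_BASE.get(t, _TAXON_RARE) for t in taxa])
    target_pens = (cfg.pens_base + cfg.effect_pens_ldi * ldi_z
                   + rng.normal(0, cfg.pens_noise_sd, cfg.n_sites))
    target_pens = np.clip(target_pens, 1.3, len(taxa) - 0.5)
    pollen_rows = []
    for i, site in enumerate(sites):
        tilt = np.where(
            np.array(taxa) == "Brassica napus", cfg.orc_tilt * orc_z[i], 0.0)
        tilt = tilt + np.array(
            [cfg.naturalness_tilt * nat_z[i] if t in _TREE_TAXA else 0.0
             for t in taxa])
        mean = base_w * np.exp(tilt)
        mean = mean * np.exp(rng.normal(0, 0.02, len(taxa)))  # break ties
        mean = _temper_to_pens(mean / mean.sum(), target_pens[i])
        comp = rng.dirichlet(cfg.grain_count * mean)
        pct = np.round(100.0 * comp, 2)
        for t, v in zip(taxa, pct):
            if v > 0:
                pollen_rows.append((site, t, float(v)))
    pollen_df = pd.DataFrame(pollen_rows,
                             columns=["nest_id", "taxon", "proportion_pct"])

    # --- residues (catalog from the packaged study tables) ---------------
    catalog = load_builtin_fixtures().substances
    catalog = catalog[catalog["substance"].isin(cfg.residue_params)].reset_index(drop=True)
    mean_orc = orc.mean()
    residue_rows = []
    for i, site in enumerate(sites):
        for s, (p_base, p_slope, mu, sd, loq) in cfg.residue_params.items():
            p = float(np.clip(p_base + p_slope * (orc[i] - mean_orc), 0.02, 0.98))
            if rng.random() < p:
                c = float(np.round(rng.lognormal(mu, sd), 2))
                if c >= loq:  # below-LOQ draws are censored to not detected
                    residue_rows.append((site, s, c))
    residues_df = pd.DataFrame(residue_rows,
                               columns=["nest_id", "substance",
                                        "concentration_ng_g"])

    # --- per-nest scalars -------------------------------------------------
    energy = np.round(cfg.energy_base + cfg.effect_energy_ldi * ldi_z
                      + rng.normal(0, cfg.energy_noise_sd, cfg.n_sites), 2)
    mass = np.round(rng.uniform(*cfg.mass_range, cfg.n_sites), 2)
    nests_df = pd.DataFrame({"nest_id": sites,
                             "provision_mass_mg": mass,
                             "energetic_value_kj_g": energy})

    truth = MappingProxyType({
        "config": cfg,
        "effect_pens_ldi": cfg.effect_pens_ldi,
        "effect_energy_ldi": cfg.effect_energy_ldi,
        "sites": tuple(sites),
        "orc": tuple(map(float, orc)),
        "ldi": tuple(map(float, ldi)),
        "ldi_z": tuple(map(float, ldi_z)),
        "naturalness_z": tuple(map(float, nat_z)),
        "target_pens": tuple(map(float, target_pens)),
    })
    bundle = SyntheticBundle(pollen_df, residues_df, catalog, nests_df,
                             land_df, truth=truth)
    validate_bundle(bundle)
    return bundle
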