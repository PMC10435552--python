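# Methods

## Data model and conventions

Five comma-separated UTF-8 tables with mandatory headers (see
`pollenrisk.data`). Conventions that matter downstream:

- **Pollen proportions** are stored as printed percentages; per-nest sums
  are validated to 100 ± 0.5 (printed-table rounding) and every
  diversity computation renormalizes to fractions summing to exactly 1.
- **Residues** are long-format, detected pairs only. An absent (nest,
  substance) pair *is* "not detected"; it is never coerced to a zero
  concentration. Four omethoate concentrations below the 5 ng/g LOQ are
  kept as detected with their reported values, because the source tables
  tabulate and median them.
- **Medians** are the arithmetic mean of the central pair for even
  counts — this convention re-derives every printed residue median
  exactly.
- Unicode dash variants in labels are normalized to ASCII hyphens on
  read; nest and site identifiers share one namespace (one nest per
  site).
- Two pollen rows of the packaged tables (Eleagnus, Caprifoliaceae) are
  typographically inconsistent in the printed source (min/max columns
  disagree with the cells); they are transcribed cell-by-cell, flagged
  in `pollenrisk.data.GARBLED_TAXA`, and excluded from numeric
  reproduction checks, as is the Acer median (printed 17.79 where its
  own cells give 17.97).

## Diversity

`PENS = exp(H')` with natural logarithms throughout — the packaged PENS
row confirms base *e*: all 12 recomputed values sit within 0.25% of the
printed ones, inside the ±1.5% slack that 2-decimal input rounding can
produce. LDI applies the same index to the shares of the seven
bee-forage landscape elements renormalized among themselves.

The prevalence filter retains taxa whose maximum share in any nest
strictly exceeds a threshold. The source study states both a 5% rule and
a 1% rule for the ordination; only the 1% rule yields exactly the 13
excluded taxa it reports, so 1% is the package default (the 5% variant
is one argument away).

## Pesticide Risk Index

Implemented literally as Σ concentration × provision mass / LD50 with
LD50 converted µg→ng and "> x" bounds taken at x (each such toxic unit
is flagged as an upper bound; replacing the bound by any larger true
LD50 can only lower the index). Non-detections contribute zero — no
LOQ/2 imputation — because the index is defined over detected
substances.

**Known discrepancy.** The per-nest Risk Index row printed in the source
tables equals the literal equation's result divided by ≈9.8
(consistently across the well-resolved nests; 9.77–9.83). No constant in
the source explains this factor. The package follows the equation;
reproduction checks therefore assert the *rank order* of nests (which
any constant factor preserves, and which matches the printed row
exactly) plus a hand-summed six-term oracle for nest A12
(1.3161 × 10⁻²), not the printed values.

## Landscape factors

Extraction method: eigendecomposition of the correlation matrix with
loadings = eigenvectors × √eigenvalues ("principal component"
extraction), varimax rotation by default, regression-method scores via
the pseudo-inverse (tolerant of the rank-deficient 12 × 13 case, where
maximum-likelihood factor analysis is ill-posed — which is why ML is not
offered as the default). Variance explained per factor is the sum of
squared loadings over the number of variables; factors are ordered by
it and signed so the largest-|loading| element loads positively. The
source's printed variance fractions (32.4/21.0% at 500 m, 29.0/27.1% at
1000 m) cannot be verified without its unpublished landscape table and
are treated as reference values, not tests.

## Regression stack

- Backward elimination refits after dropping the single worst predictor
  with p > α (α = 0.05), ties broken toward the later column; the
  intercept is never dropped; the result is a fixed point. An intercept-
  only outcome is legitimate under pure noise. With 4 exchangeable null
  predictors the per-predictor retention rate is close to α (measured
  6.6% over 500 replicate synthetic studies, 4.6% in a larger 1000-rep
  calibration of the permutation machinery).
- Designs with condition number above 1e8 are rejected, naming the
  near-dependency.
- RMA slope = sign(r)·SD(y)/SD(x); its default p-value is the two-sided
  t-test of r = 0 on n−2 df, with a seeded permutation alternative
  (9999 recommended) since the original analysis tool does not document
  its method.
- Shapiro–Wilk via scipy (Royston's algorithm), 3 ≤ n ≤ 5000.
- n < 15 triggers a logged warning rather than an error: the study's own
  n is 12.

## Ordination

RDA = eigendecomposition (via SVD) of the covariance of the fitted
values of Y ~ X, both centered. **Y pretreatment default is
center + standardize**: residue concentrations span 0.11–198.4 ng/g, so
unstandardized axes would be dominated by the most concentrated
substance. The source does not state its pretreatment; with the default,
the first two axes of the packaged tables carry 26.6% and 25.1% of
residue variance against the printed 29.1%/25.0% — treated as an
attempted reproduction, not a pass/fail test. Non-detects enter Y as 0
(configurable).

pseudo-F = (constrained SS / rank) / (residual SS / (n − 1 − rank));
unrestricted permutation of whole Y rows;
p = (1 + #{F\* ≥ F}) / (1 + n_perm), always a multiple of
1/(n_perm + 1). With 15 taxa constraining 12 nests the design is
saturated (rank n − 1): the residual df is zero, F is reported as
infinite and the permutation p degenerates to 1 — the axis shares and
scores remain valid. Type-I error of the test measured over 200 null
datasets (n = 20, 5 responses, 3 constraints, 499 permutations): 3.5–8%
depending on seed, 4.6% over 1000 replicates.

## Synthetic studies

The generator emulates the study design, with one global seed feeding a
single `numpy` Generator:

- **Landscape**: non-crop cover shares are Dirichlet draws (propensities
  chosen so arable classes dominate, as in the study region); the ORC
  gradient is imposed evenly over 6–65% (the study's span) and the rest
  renormalized; the 1000 m buffer is a 0.7/0.3 mixture of the 500 m
  composition and fresh variation. Linear-feature densities follow the
  arable/natural character of the buffer.
- **Pollen**: expected composition tilts toward *B. napus* with ORC and
  toward tree taxa with a naturalness score; expected diversity is set
  by tempering the mean composition (exponent solved by bisection) to a
  linear target `pens_base + effect_pens_ldi · z(LDI) + ε`,
  defaults 4.5 − 0.8·z + N(0, 0.5²) — the observed PENS range and a
  clearly negative landscape effect, matching the study's direction.
  Realized compositions are Dirichlet draws with total concentration
  `grain_count` = 300 (the order of grains scored per sample); the finite
  count attenuates realized diversity by ≈4–5%, which is why slope
  recovery is asserted within standard errors, not exactly.
- **Residues**: per-substance Bernoulli detection with probability
  increasing in ORC (defaults matched to the observed detection
  frequencies), lognormal concentrations (log-medians from the observed
  medians, log-SD 1.0–1.3 reproducing the heavy right tail), draws below
  the LOQ censored to not-detected.
- **Energetics/mass**: energetic value = 18.0 + 0.35·z(LDI) + N(0,
  0.3²) kJ/g (observed range, positive effect as reported); provision
  masses uniform over the observed 212–255 mg.

What the generator does *not* emulate: spatial autocorrelation between
sites, within-nest cell-to-cell heterogeneity, taxon-specific residue
sources (detection depends on ORC, not on which taxa are present), or
any bee behaviour. Passing calibration tests therefore show the
*statistical machinery* is unbiased and correctly sized under the
assumed generative model, not that the field study's effects are real.

## Problem sizes of the shipped checks

Slope recovery uses one 100-site study; null retention uses 500
replicate 12-site studies; permutation calibration uses 200 null
datasets at n = 20 with 499 permutations each — sizes chosen so every
rate has a standard error comfortably inside its asserted band while
the whole suite stays interactive (~1 minute for the calibration
blocks).

## Known limitations

- The ≈9.8× Risk-Index discrepancy above is documented, not resolved.
- Honeybee LD50s stand in for *Osmia* sensitivity (none exist for most
  substances); the index is additive with no mixture interactions.
- Printed 2-decimal tables limit reproduction precision to ~1.5% for
  diversity quantities.
- The RDA axis shares depend on the (unstated) pretreatment of the
  original analysis; both standardized and unstandardized variants are
  exposed.
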