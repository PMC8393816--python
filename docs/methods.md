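# Methods

## Data model and processing order

Measurements are long (tidy) records of
`(sample_id, compartment, group, bio_replicate, tech_replicate, analyte,
intensity)` in counts per second, one row per SRM transition per injection.
Processing follows the order standard for spiked-standard shotgun panels:

1. per injection, each analyte is divided by the internal standard of its
   (class, linkage) group, giving dimensionless lipid/standard ratios;
2. the ratios are averaged over the technical replicates of each biological
   sample (`collapse_technical`).

Ratios are formed first and then averaged; because the collapse is a plain
arithmetic mean of ratios, normalizing and collapsing commute exactly (a
regression test asserts this).  A zero analyte signal is kept as ratio 0 — a
zero SRM signal is informative — whereas a zero or missing *standard*
invalidates the whole class for that injection, since no ratio in the class
is interpretable.  Protein-amount adjustment is assumed done at the wet-lab
stage; an optional per-sample `scale` column is applied to analyte (not
standard) intensities before normalization if present.

## Differential statistics

For one contrast (treated vs. control) in one compartment, per species:

- fold change `FC = mean(treated ratios) / mean(control ratios)`, computed by
  scaling each treated replicate by the control mean (control ≡ 1);
- `SEM = SD(scaled treated) / sqrt(n_treated)` — the error bar on the fold
  change as displayed;
- p from a classical pooled-variance two-tailed Student t-test on the raw
  (unscaled) per-replicate ratios.  Pooled variance rather than Welch because
  the design is balanced (n = 7 vs. 7), where the two are near-identical.
  Tests run on the raw ratio scale by design; no log transform is applied.
- no multiple-testing correction in the primary analysis (each species is
  reported marginally, as is conventional for these targeted panels); a
  Benjamini–Hochberg column is carried in the volcano export as
  supplementary information only.

Degenerate inputs: identical constant groups give p = 1 (flagged
`degenerate`); a zero control mean makes the species `not_evaluable`.

### Classification

With `avg_sem` the mean SEM over the analysis set (whole panel for the
panel-wide view, one class for per-class views, always per compartment):

- `significant_up/down` if p ≤ α (default 0.05), direction from
  sign(FC − 1); significance is p-only, the effect does not also need to
  clear the guide line;
- else `trend_up/down` if |FC − 1| > avg_sem;
- else `unchanged`.

The partition is exhaustive and exclusive; label counts always sum to the
analysis-set size.  The trend rule deliberately uses the *average* SEM of
the set as a single guide line (the dashed vertical lines of the volcano
plots), not each species' own SEM.  Consequence worth knowing: when all
species share a similar measurement CV, a null species' fold change
fluctuates by about √2 × its own SEM (both groups contribute), so an
appreciable fraction of nulls will cross the average-SEM line by chance.
The rule separates signal from noise well only when per-species SEMs are
heterogeneous enough that the average sits far above the typical species'
SEM — which is how real panels spanning two orders of magnitude in abundance
behave, but not how a homogeneous-CV simulation behaves.

### Volcano export

Effect coordinate log2(FC) (0 at no change), −log10(p) with p = 0 clamped to
the smallest positive float (flagged), the label, and the ±avg_sem guide
value.  Fold-change and label columns round-trip through the TSV export.

## Composition analyses

- **mol%**: `100 × ratio / Σ ratios over the same (sample, class, linkage)`.
  Sums are exactly 100 per sample and class whenever the class sum is
  positive; a zero class sum flags the whole class not-evaluable for that
  sample.  The same differential machinery runs unchanged on mol% tables.
  Carnitines are treated as one class-group so the partition covers the
  panel.
- **Double-bond ratios** (e.g. `PCae X:4/X:6`): per biological replicate,
  Σ ratios over the numerator double-bond set divided by Σ over the
  denominator set; linkage `ax` pools aa+ae.  The per-replicate ratios are
  then contrasted like any other variable and reported as % of the control
  mean ± SEM with a Student-t p.  Ratios are formed per replicate and then
  averaged (not ratio of group means) — this is what makes the reported SEM
  on the ratio meaningful.  Replicates with a zero denominator are excluded
  with a warning; if none remain the ratio is not-evaluable.
- **Aggregates**: summed-signal fold change per double-bond count or per
  chain-length bin (defaults: ≤ 33 short, 34–39 mid, ≥ 40 long on summed
  carbons, configurable).
- **Carnitine panel**: Ceven = Σ even chains ≥ 4, Codd = Σ odd chains ≥ 5,
  CX = Σ all acyl-carnitines (chain ≥ 2).  C2 is excluded from Ceven and C3
  from Codd because each is the denominator of its own ratio (the panel
  would otherwise be partially degenerate); C0 (free carnitine) is never
  counted as an acyl-carnitine.  These set conventions are configurable in
  code and flagged here as an interpretation.

## Compartment comparison

The shift test counts species labeled up (trend or significant) and down per
compartment and applies a two-sided Fisher exact test to the 2×2 table.  The
two-sided p is the minimum-likelihood definition — the sum of hypergeometric
point probabilities (margins fixed) not exceeding that of the observed
table — with a relative tie tolerance of 1e-12, which is wide enough to
absorb floating-point noise in true ties yet narrower than the smallest
genuine probability gap for tables with n ≤ 40.  The implementation is
verified exhaustively against an integer-arithmetic enumeration oracle for
all tables with n ≤ 40 and spot-checked against an independent library
implementation.  The Venn partition assigns every changed species to exactly
one cell (exclusive-to-A/B by direction, shared same direction, shared
opposite).

## Synthetic data generator

The generator emulates the study layout: 2 compartments × 2 groups ×
n = 7 biological replicates × 3 technical replicates over a 226-analyte
panel (dense per-class composition grids — PCaa 49, PCae 49, lyso-PC 20,
PEaa 35, PEae 35, lyso-PE 9, PG 10, carnitines 19 — a plausible
reconstruction, since the original appendix species list is not public).

- **Baselines**: per-analyte abundances log-uniform over 10³–10⁵ cps;
  standards spiked at 10⁴ cps.
- **Noise**: multiplicative log-normal, mean exactly 1.  Biological CV 0.15
  drawn once per (sample, analyte) and shared by the sample's technical
  replicates; technical CV 0.05 independent per injection.  The defaults are
  typical mid-range values for cultured-cell SRM panels.
- **Standards**: technical CV 0.01 (the spiked amount is constant, and a
  matrix-effect QC that resolves 1–3% changes presupposes ~1% repeatability
  of standard signals), plus a per-(standard, compartment, group)
  multiplicative matrix-effect shift for non-reference groups, normal with
  E|shift| = 0.012 so the QC metric averages ~1.2%.
- **Planted effects**: fold changes keyed by (compartment, selector), where
  a selector is an exact analyte name, a class+linkage token (`PEaa`,
  `lyso-PC`, `carnitine`), or a class restricted to a double-bond count
  (`PCae X:4`).  Overlapping selectors compose multiplicatively; a selector
  matching nothing is an error.  The expectation of a planted species equals
  the reference expectation times the planted fold change exactly.
- **Determinism**: a single integer seed feeds named `SeedSequence` children
  in a fixed order (baselines, biological, technical, standards, matrix);
  identical seeds give bit-identical tables.

What the generator does **not** emulate: abundance-dependent (heterogeneous)
per-species CVs, missingness/dropout, drift or batch structure, isotope
patterns, and ionization physics.  Tests passing on this generator therefore
demonstrate the correctness of the arithmetic and the calibration of the
statistics under idealized noise — not the trend rule's practical
false-positive rate on real, variance-heterogeneous panels (see the
classification note above).

## Problem sizes used in the checks

The calibration suite uses 10 simulated panels of 1,000 null species
(10,000 species-contrasts) for the α-level check; recovery uses 200 species
with 50 planted 1.3-fold effects at the default design; the Fisher sweep is
exhaustive over all 2×2 tables with n ≤ 40; the matrix-QC level is averaged
over 25–100 simulated datasets.  The full suite runs in well under a minute
on one CPU.

## Known limitations

- Sum-composition resolution only: individual sn-1/sn-2 fatty acids are not
  assigned, so ω3/ω6 attribution rests on the double-bond-count proxy.
- No isotope correction, adduct handling, or isobaric-mass deconvolution.
- Two compartments per shift test; no multi-compartment omnibus test.
- The trend classification inherits the average-SEM caveat described above.
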