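# Methods

## Partition coefficients from dilution series

A dilution series loads increasing amounts of protein into replicate
two-phase systems and measures a concentration-proportional signal
(fluorescence after o-phthaldialdehyde derivatisation, in the assay the
packaged panels come from) in both phases. Since K = [top]/[bottom] does
not depend on load, top-phase signal is linear in bottom-phase signal with
slope K. `estimate_k` fits that line by ordinary least squares.

* **Intercept** — included by default. The slope definition of K is
  agnostic about an intercept, and a free intercept absorbs instrument
  background that would otherwise bias K; `force_zero_intercept=True`
  restores the strict proportionality model, which on noise-free
  proportional data returns the exact ratio.
* **Weighting** — unweighted by default; no weighting scheme is part of
  the measurement convention the package models.
* **Replicates** — `average_k` takes the arithmetic mean and reports the
  maximum relative deviation; deviations above 3% (the reproducibility
  typical of the assay) raise a `ReproducibilityWarning` rather than an
  error, because a noisy replicate is a data-quality observation, not an
  invalid input.
* The standard deviations attached to the packaged K values are stored as
  published and never recomputed.

## The SIA signature distance

For variant *i* with partition coefficients K_ij in systems j = 1…n and a
reference protein with K_0j, the signature is

    d_i0 = sqrt( Σ_j [ (log K_ij − log K_0j) / log K_0j ]² · s_j / s_max )

The relative-difference-of-logs form makes d independent of the logarithm
base; dividing s_j by s_max makes it independent of any common rescaling
of the standard deviations. Both invariances are property-tested.

Two aspects of the published formulation are ambiguous, so both are
explicit `SignatureConfig` fields rather than hidden choices:

* **`apply_sqrt`** (default on): the distance is described as a normalised
  Euclidean distance, which implies the radical; the printed expression's
  doubled summation sign is treated as typographical.
* **`sd_source`** (default `panel_mean`): "the normalised standard
  deviation in system j" is one value per system, so the default takes the
  panel mean of the relative standard deviation sd/K in each system, then
  normalises by the maximum across systems. `reference_row` and
  `mutant_row` implement the other defensible readings.

Under no configuration do the recomputed distances match the published
signature columns digit-for-digit (e.g. the nuclease I18L row recomputes
to 4.19 under the default, 2.1–2.7 under other readings, versus the
published 2.41); the constants behind the published column are not
recoverable. Downstream regressions therefore consume the **published**
signature columns, which is also what the published fits consumed. The
signature engine is still fully exercised: the zero-distance reference,
the invariances and the ranking behaviour are exact properties.

## Structure–stability regressions

`fit_ols` is ordinary least squares (statsmodels under the hood, verified
in tests against a hand-rolled normal-equations solve) reporting the
diagnostics conventionally quoted with such fits: coefficients ± SE, N,
r², residual SD = sqrt(RSS/(n−p)) and F = (r²/(p−1))/((1−r²)/(n−p)).
`loo_outlier_scan` fits all leave-one-out subsets and returns the one with
maximal r², with deterministic tie-breaking by row order — the
single-outlier removal these 4–14-point panels need.

`reproduce_equation` re-runs the six published regressions of the packaged
panels:

| id | fit | rows |
|----|-----|------|
| E2 | log K₃ ~ log K₁ + log K₂ (decimal logs) | all 15 variants minus L37I |
| E3 | ΔG_H2O ~ signature + C_m | best 8 of the 9 nuclease rows (LOO scan) |
| E4 | ΔΔG ~ signature + T_m | the 5 lysozyme mutants |
| E5 | ΔG_H2O ~ polar SASA + signature | nuclease minus L108V, L108I, I18L |
| E6 | ΔG_H2O ~ apolar SASA + signature | nuclease minus I18L, I72M, T82V, L108V |
| E7 | ΔΔG ~ polar SASA + signature | lysozyme mutants minus T115A/S117A |

Decimal logarithms are used for E2 because the published intercept matches
the decimal-log reconstruction (slopes are base-invariant). The E3 row set
is not hard-coded: the published fit states N = 8 without naming the
excluded variant, so the implementation scans and reports it (the scan
excludes I72M). The lysozyme reference C54T/C97A joins the "WT" row of the
lysozyme surface-area table, documented as a fixture-level alias; its ΔΔG
is stored as absent, not zero.

### Reproducibility limits

Re-fitting the published two-decimal tables reproduces E2, E4 and E7
essentially exactly (r² = 0.9424, 0.9995, 0.9869 versus published 0.9424,
0.9995, 0.9886), including every E2/E4 coefficient and standard error —
with one exception: the published E2 slope on the NaCl system is −0.4 ±
0.20 while the refit gives +0.44 ± 0.21 with every other number identical,
so the published minus sign is treated as a typo.

E3, E5 and E6 are **not** recoverable from the published tables, and the
corresponding acceptance-level tests are deliberately left failing:

* E3: exhaustive enumeration of all nine 8-row subsets tops out at
  r² = 0.9863, below the published 0.9953. C_m is published to one decimal
  (±0.05 M), which alone propagates ≈ ±0.3 kcal/mol of rounding noise
  through the ≈6.2 kcal·mol⁻¹·M⁻¹ slope — enough to cap r² near the
  observed value. The published fit evidently used unrounded source data.
* E5/E6: with the published outlier sets the refits give r² = 0.77 and
  0.87; brute force over *all* row subsets of the stated size reaches at
  most 0.88 (E5) and 0.96 (E6), and no subset's coefficients match the
  published ones. No selection of the published rows can produce the
  published statistics.
* The F ≡ (r²/(p−1))/((1−r²)/(n−p)) identity recovers five of the six
  published F values within 2% from the published (r², N); the E4 value
  (1846) corresponds to an unrounded r² ≈ 0.99946 and cannot be recovered
  from the 4-decimal 0.9995 (which implies F = 1999).

`siakit reproduce` reports all six comparisons and exits nonzero because
of these documented mismatches; its tolerance is |Δr²| ≤ 0.02, since the
published diagnostics carry four decimals but the inputs only two.

## Solvent-accessible surface area

The Shrake–Rupley engine places a deterministic golden-spiral lattice of
`n_quadrature_points` (default 960) on each atom's sphere of radius
r_vdW + r_probe and counts the points falling outside every other atom's
expanded sphere; the atom's area is the accessible fraction of
4π(r + probe)². A k-d tree prunes the neighbour search. There is no random
number generator anywhere in the engine, so results are bit-stable.

* **Probe radius** 1.4 Å — the universal water-probe convention. (The
  prose the package follows describes a 1.4 Å *diameter*; that is treated
  as an erratum, and the probe is configurable.)
* **Radii** — a Bondi-derived table (C 1.70, N 1.55, O 1.52, S 1.80,
  H 1.20, P 1.80, Se 1.90 Å), named `bondi` and swappable.
* **Polarity** — N and O polar, C apolar, S polar by default (a
  convention, configurable), hydrogens inherit the class of the nearest
  heavy atom within 1.4 Å (an unbonded hydrogen is an error). Polar +
  apolar equals total exactly by construction.
* **Validation** — against closed-form oracles: an isolated sphere
  (4π(r+p)², within 0.5% at 960 points), the two-sphere spherical-cap
  formula (0.5%), 960-vs-3840-point convergence (1%), and rigid-motion
  invariance (0.1%).

PDB input goes through Biopython's parser; waters are always excluded,
HETATM records optionally included, multi-model files select a 1-based
model index. The packaged SASA tables derive from predicted structural
models that are not shipped, so they are regression *inputs*, never
validation targets for this engine. (Their published unit header reads
kcal/mol/Å²; the values are areas and are stored as Å².)

## Synthetic data

The generators are pure functions of their parameters and seed; the seed
is recorded in every output.

* `gen_dilution_series` — bottom signals proportional to the load-volume
  grid 0–75 µL in 15 µL steps (six points, the practical protocol); top =
  K·bottom·(1+ε), ε ~ N(0, rel_noise) with rel_noise defaulting to 0.01,
  the ~1% reproducibility observed in practice.
* `gen_mutant_panel` — log₁₀K₁, log₁₀K₂ uniform over the measured panel
  range K ∈ [0.25, 1.75] (rejecting reference K within 0.02 of 1, which
  would sit on the log K₀ = 0 singularity); log₁₀K₃ from the planted
  linear model (default (−0.17, 0.44, 0.78), the refit cross-system
  relationship) plus N(0, 0.02) structural noise; recorded sd columns at
  3% of K (mid-range of the measured sd/K); a ΔG-like response from the
  planted model (default (0.56, −0.12, 6.2) with 0.14 residual SD, the
  nuclease stability relationship) applied to the *computed* signatures
  and a C_m-like covariate uniform on [0.3, 1.0]. An optional planted
  outlier row offsets one response for leave-one-out tests. Ground truth
  is returned for recovery tests.
* `gen_toy_structure` — single atom, pair, linear chain or helix-like
  arrangement as valid PDB text, with an analytic reference area where a
  closed form exists and a 10×-refined quadrature value otherwise.

What the generators do **not** emulate: phase-volume effects, derivatisation
chemistry, heteroscedastic per-system noise, correlations between the
stability covariate and the partition profile, or any physical relation
between a structure and its partition behaviour. Passing recovery tests
therefore demonstrate the estimators' statistical correctness under the
assumed linear models, not the validity of those models for real proteins.

## Problem sizes

The default test and reproduction runs use the packaged 9- and 6-variant
panels, 50-variant synthetic panels for coefficient recovery, 6-point
dilution series, and toy structures of ≤ 12 atoms at 960–9600 quadrature
points; the whole suite completes in a few seconds.

## Known limitations

* The signature's s_j convention is a documented choice, not a
  reconstruction; published signature columns are treated as data.
* The SASA engine is numerical Shrake–Rupley only; no analytic
  Lee–Richards slicing, no per-residue breakdown.
* No robust or weighted regression; outlier handling is leave-one-out
  exclusion, matching the practice the package reproduces.
* Structure prediction is out of scope; structures are inputs.
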