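# Methods

This note documents the models, parameter choices and numerical conventions
behind vacuoquant, and what the synthetic-data tests do and do not establish
about real data.

## The measurement problem

CLN3 disease severity spans a spectrum determined by the residual function of
the two *CLN3* alleles.  The package quantifies lysosomal storage in blood
lymphocytes along three routes that probe the same biology at different
resolutions: manual smear counts of vacuolated lymphocytes, flow-cytometric
fractions of LAMP-1⁺ perforin⁻ ("affected") cells per lymphocyte subset, and
per-cell LAMP-1 image statistics from imaging flow cytometry.  A longitudinal
mixed model then asks whether these outcomes separate severity classes and
whether they drift with age within a patient (they should not, if the marker
reflects genotype-determined storage rather than progression).

## Severity classes and genotype rule

Six ordered strata: control < carrier < retina_only < protracted <
delayed_classical < classical.  The genotype rule is total and symmetric over
allele categories {truncating, mild_missense, particularly_mild_missense}:
two truncating → classical; truncating + mild missense → delayed classical;
two particularly mild missense → retina_only; every other combination with a
missense allele → protracted.  A truncating + particularly-mild pair is not
covered by the published strata definitions; it is mapped to protracted ("at
least one mild missense allele"), the mildest stratum consistent with one
functional-ish allele.

## Synthetic cohort generator

Per patient: random intercept `b0 ~ N(0, σ_int)` and random age slope
`b1 ~ N(0, σ_slope)` on the logit scale, drawn once.  Per sample at age `a`:

    p_true = expit(logit(m_class) + b0 + (b1 + β_age) · a)

Each of 3 observers applies an extra logit shift `N(0, σ_obs)` and counts
`Binomial(100, p_obs)` vacuolated cells, then draws vacuoles-per-cell values
for `min(20, n_vacuolated)` cells from a class-specific discrete distribution.
When all three SDs are zero, the generator collapses to its analytic
expectation and emits exact rounded expected counts instead of binomial
draws, so zero-noise recovery tests can assert exact equality.

Defaults (all overridable via `CohortConfig`):

| parameter | default | rationale |
|---|---|---|
| class means `m` | control 2 %, carrier 3 %, retina_only 3 %, protracted 8 %, delayed_classical 15 %, classical 30 % | published medians/ranges per stratum; carriers slightly above controls; delayed classical interpolated |
| vacuoles/cell | control 1–5 (mode 2), protracted 3–12 (mode 8), classical 6–18 (mode 10) | published ranges and medians; rendered as a `1/(1+|k−mode|)` pmf, which reproduces the median with hard range limits without a parametric assumption |
| σ_int | 0.25 logit | gives a classical between-patient spread of roughly 15–50 %, consistent with the published 11–69 % patient range |
| σ_slope | 0.01 logit/yr | small within-patient drift; the marker is empirically stable over follow-up |
| σ_obs | 0.15 logit | free choice: no inter-observer agreement statistics are published; 0.15 makes observer noise comparable to binomial counting noise at p = 0.3 |
| β_age | 0 | the null age effect is part of the study conditions |
| ages | uniform 4–25 yr, 2–5 samples/patient | diagnosis + follow-up sampling of a pediatric-onset disease |

## Synthetic flow generator

Intensities live on an arbitrary log scale.  Surface markers are Gaussian
with negative mode N(0.8, 0.2) and positive mode N(3.2, 0.2) — 12 SD of
separation, so 1-D thresholds recover subsets essentially perfectly; this is
deliberate, since the aim is to test the gating logic, not to model spectral
spillover.  Subset mix: 40 % CD4-T, 25 % CD8-T, 15 % B, 10 % NK, 10 % other.

The affected fraction of subset `s` in class `c` is a mixture weight

    π(c, s) = expit(logit(0.02) + shift[c][s] + offset)

where 0.02 is the baseline false-positive rate, `shift` rises with severity
in the T compartments (classical 4.0, delayed 3.2, protracted 2.5, carrier
0.3) and is largest in the B compartment for retina_only (4.5), emulating the
B-cell-dominant signature of the mildest phenotype.  `offset` lets the
pipeline inject patient-level random effects for longitudinal structure.
Affected cells draw LAMP-1 from N(3.4, 0.2); unaffected from N(1.0, 0.3).
NK cells draw LAMP-1 and perforin as `3.2 + e + ε` with shared
`e ~ N(0, 0.25)`: the strong correlation reflects that both markers report
the same cytotoxic-granule compartment, and it is what makes a single NK
population usable as a dual-marker positive control.  5 % of CD8-T cells are
rendered cytotoxically activated (both markers high, *not* affected),
exercising the perforin-exclusion rule.

## Synthetic cell images

64×64 8-bit frames.  CD4 channel: disk of intensity 180 (radius ≈ 0.32 ×
image size, jittered center) on background 20.  LAMP-1 channel: diffuse
cytoplasmic baseline rising with class (control 40 → classical 70) plus
`n_vacuoles` rings of intensity 200 (radius 3 px, width 1.5 px) — vacuoles
appear as annuli because LAMP-1 sits on the vacuole membrane, not in the
lumen.  Rings are placed by rejection sampling with a minimum center
separation of 1.8 radii; impossible placements raise an error.  Gaussian
noise (SD 6) is added after the ground-truth mean is recorded, then rounded
and clipped to 0–255.  What the images do **not** emulate: focus variation,
nucleus exclusion, irregular cell outlines, background gradients, or camera
noise statistics — segmentation fidelity on these images bounds algorithmic
correctness, not real-world robustness.

## Otsu thresholding and segmentation

`otsu_threshold` returns the level `t ∈ 1..255` maximizing between-class
variance of the 256-bin histogram with classes `< t` / `≥ t`; ties break to
the lowest maximizing level (the classical formulation is ambiguous at
ties).  The test suite and acceptance script verify exact agreement with an
exhaustive brute-force argmax.  Segmentation uses the CD4 channel only
(LAMP-1 never influences the mask, preventing circularity), keeps the
largest 8-connected component and fills holes — single-cell frames contain
one cell; debris and dark vacuole interiors must not fragment the mask.

## Sliding-threshold curves

For each level `k` in 0..255, `pct_at_level[k]` is the percentage of masked
pixels with LAMP-1 `≥ k` ("equal or above" taken literally).  "Cell surface"
is interpreted as the 2-D masked area of the projected image.  The identity
`Σ_{k=1..255} pct[k]/100 = mean_lamp1` holds exactly for integer images
(each pixel of intensity v is counted at exactly v levels ≥ 1) and is
asserted per cell to 1e-9.  Population bands (median, 25–75, 2.5–97.5) and
the per-class mean-LAMP-1 deciles use the linear-interpolation quantile
definition; band shapes depend on this choice, so it is fixed and documented
rather than configurable.

## Gating conventions

Subset precedence: CD20⁺ → B; else CD3⁺ → T (CD4⁺ → T4, CD8⁺ → T8,
double-positive to the larger standardized excess above threshold with ties
to T4, double-negative T → other); else CD56⁺ → NK; else other.  Thresholds
are 1-D (no bivariate polygon gates) and default to an Otsu split of each
channel's intensity histogram — one shared thresholding primitive across the
package.  No compensation or doublet discrimination is modelled; real FCS
users must supply compensated, pre-cleaned event tables (CSV with channels
CD3, CD4, CD8, CD20, CD56, LAMP1, PERFORIN).

The NK-anchored LAMP-1/perforin gates use the *lower* order-statistic
quantile (`numpy` `method="lower"`) at the configured level (default 0.05):
this guarantees at least 95 % of NK events are positive on each marker by
construction, which is the gate's defining property as a positive control.
With fewer than `min_nk` (default 50) NK events the anchor is considered
unreliable and the caller must supply manual gates.

## Severity model

`outcome ~ age + class` (treatment coding, control as reference) with random
intercept per patient; a random age slope is added when it lowers the AIC.
AICs are compared between ML fits (REML likelihoods are not comparable
across fixed-effect-identical models with different random structures in the
usual AIC sense; ML comparison then REML refit is the standard
reconciliation), and the selected structure is refit under REML for the
reported estimates.  P-values are Wald t with between-within df: class
contrasts use `n_patients − n_classes`, the age slope uses `n_obs −
n_patients − 1`.  Outcomes are modelled on the raw percentage scale by
default (adequate for mid-range percentages; a logit option exists for
boundary-heavy outcomes).  Degenerate designs degrade explicitly: no
repeated measures → random intercept only, with a warning; zero residual
variance → fixed-effects-only least squares, flagged in
`chosen_random_structure`.  The trend report labels an outcome "stable" when
the age-slope confidence interval contains zero.

## Problem sizes used in tests and the acceptance script

Chosen to be study-like while keeping runs desk-scale: the parameter-recovery
Monte Carlo uses 200 cohorts of 20 patients per class × 3 samples; gating
checks use 10 000-event samples; imaging checks use 200–500 generated cells;
the acceptance script's smear cohort uses 12/8/12 patients per class.  At
these sizes the binomial/Gaussian sampling noise is the dominant uncertainty
and the recovery tolerances (2 SE coverage, 3 binomial SEs, Jaccard ≥ 0.9)
follow from the generator's own noise model, not from fitted constants.

## Known limitations

* Gates are 1-D thresholds; real workflows often draw 2-D polygon gates.
* The flow generator is spillover-free and the image generator
  morphologically idealized (see above); passing tests demonstrate correct
  algorithms and calibrated statistics under the stated noise model, not
  instrument-level realism.
* Exact published p-values are not reproducible: they derive from
  non-deposited patient data and an unstated contrast/df convention.  The
  package reproduces the *structure* of the findings (severity separation,
  null age effect) on matched synthetic conditions.
* FCS binary I/O is not implemented; event tables travel as CSV.
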