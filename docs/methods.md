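# Methods

## Model and assumptions

The package estimates the causal effect θ of a maternal circulating
exposure X (25(OH)D on the natural-log scale; calcium in SD units) on
offspring birth weight Y, using genetic variants as instruments. The
working model behind every estimator is linear and homogeneous:

    β_yj = θ · E_j + α_j + ε_j,     ε_j ~ N(0, σ_j²)

where `E_j` is instrument j's per-allele effect on the exposure, `β_yj`
its effect on the outcome, and `α_j` a direct (horizontally pleiotropic)
path to the outcome. A valid instrument has `α_j = 0`; the four estimators
differ in what they tolerate:

| estimator       | consistent when                                      |
|-----------------|------------------------------------------------------|
| pooled Wald / IVW | all `α_j = 0` (no unbalanced pleiotropy)           |
| MR-Egger slope  | `α_j` independent of `E_j` (InSIDE), any mean α      |
| weighted median | < 50% of inverse-variance weight on `α_j ≠ 0` SNPs   |

Randomised supplementation trials are handled with the same algebra:
randomised arm is the instrument, the arm difference in the biomarker is
`E`, the arm difference in birth weight is `β_y`, and each trial
contributes one Wald ratio. Pooling, Cochran's Q, I² and leave-one-out run
through one shared implementation for both evidence streams, so any
discrepancy between the genetic and trial estimates is a property of the
data, not of divergent code paths.

## Harmonisation

Effects are re-expressed per exposure-raising allele on a shared strand
before estimation: exact allele match kept; swapped alleles sign-flipped
(frequency complemented); opposite-strand pairs complemented first.
Palindromic SNPs (A/T, C/G) are strand-ambiguous and are either dropped
(default) or inferred from allele frequencies when both sides sit outside
the ambiguity band `eaf ∈ [0.42, 0.58]` (configurable); inside the band,
or with a missing frequency, the SNP is dropped with a recorded reason.
Harmonisation is idempotent, orientation-invariant, and partitions the
rsid intersection into kept and dropped — all three properties are tested.

## Uncertainty conventions

- **Wald ratio SE**: first-order rule `σ_j / |E_j|` (exposure uncertainty
  ignored), matching the convention of summary-data MR at large exposure
  GWAS sizes; a full delta-method variant (`full_delta=True`) adds the
  `β_y² σ_E² / E⁴` term.
- **Fixed-effect covariance**: IVW, Egger and multivariable IVW report
  `cov = (X'WX)⁻¹` with the residual variance pinned at 1 (a
  "fixed-effect" SE); a multiplicative option rescales by the weighted
  mean squared residual. The fixed convention makes multivariable IVW with
  one exposure coincide exactly with univariable IVW.
- **Reference distributions**: IVW uses t with `J − 1` df, Egger t with
  `J − 2`; the plain pooled Wald ratio defaults to normal CIs with a t
  option. Two-sided p-values always come from the same reference as the
  CI. At small J the t reference is deliberately conservative: with an
  exactly normal pivot, the t(6) CI at J = 7 covers ~98.6% rather than
  95% — which is why the calibration experiments score coverage with the
  normal reference (the exact pivot) and report the t figure alongside.
- **Weighted-median SE**: parametric bootstrap — each ratio resampled from
  `N(β_j, se_j)`, the weighted median recomputed, SD taken across
  `n_boot = 1,000` draws by default; the seed is required in pipeline
  runs. With normalised weights the 50th percentile always lies inside
  `[ρ_1, ρ_J]`, so the boundary clamp in the interpolation is a pure
  numerical guard.

## Unit scaling

All transforms are multiplicative `ScaleSpec`s carrying provenance
strings, composable, and exactly linear (the z-score and p-value are
invariant):

- per-10% conversion of per-ln-unit effects uses `ln(1.1) ≈ 0.0953`;
- a 10% rise from the gestational 25(OH)D distribution (median 61.8,
  quartiles 46.1 / 81.6 nmol/l) is 6.2 / 4.6 / 8.2 nmol/l;
- the calcium SD is `(10.5 − 8.5)/4 = 0.5 mg/dl` by the
  reference-range-over-four rule;
- SD-standardised birth weight converts back to grams through an explicit
  cohort SD (the documented example is 476 g) — there is no hidden
  default;
- pounds→kg uses 0.454.

## Synthetic data: what it emulates, and what it does not

`simulate_two_sample` draws `E_j` as folded normals (default mean 0.06,
SD 0.03 on the log-nmol/l scale, matching the spread of published
25(OH)D instruments), allele frequencies uniform on (0.1, 0.9), and
per-SNP SEs by the unit-variance GWAS rule `1/√(2p(1−p)n)` with default
sample sizes 79,366 (exposure) and 190,406 (outcome). Observed effects
add mean-zero normal noise at those SEs; the outcome file is emitted with
random allele flips and an optional share of palindromic SNPs so
harmonisation is always exercised. `invalid_fraction` is a share of IVW
weight: the invalid set is filled in random order under a hard cap at the
target, so a nominal 40% can never cross the weighted median's 50%
breakdown line, while selection stays essentially independent of
instrument strength (needed for InSIDE experiments). Directional
pleiotropy draws `α_j ~ N(μ_α, σ_α)` for invalid SNPs; InSIDE violation
adds `γ · E_j`.

`simulate_rcts` simulates individual participants per trial (sizes
uniform over 16–1,134 by default, 24 trials), with biomarker uptake in
treated compliers and a linear biomarker→birth-weight effect θ
(birth-weight residual SD 476 g); both intention-to-treat and
per-protocol arm summaries are emitted, and compliance can be confounded
with outcome potential to demonstrate per-protocol bias.

`simulate_mother_child` draws maternal genotypes at Hardy–Weinberg
equilibrium, transmits one maternal allele at random and draws the
paternal allele from the population, yielding the maternal–fetal dosage
correlation of ≈ 0.5 that makes fetal-genotype adjustment necessary;
birth weight is linear in dosages, gestational age (130 g/week) and
child sex (120 g), residual SD 450 g, with confounders drawn
independently of genotype.

None of the generators model linkage disequilibrium between instruments
(selection assumes independent SNPs), assortative mating, selection into
the cohort, reporting error in recalled birth weight, or non-linear or
trimester-specific exposure effects. Passing calibration on these
generators therefore shows the estimators implement their definitions
correctly and behave as theory predicts under the stated violations — it
does not certify robustness to biases the generators do not produce.

## Calibration experiment sizes

The standard runs use 1,000 replicates for IVW coverage (J = 7,
θ = 0.05), 200 for the Egger/InSIDE experiment (J = 50, θ = 0.5, 90% of
weight pleiotropic with μ_α = 0.01), 300 for weighted-median recovery
(J = 10, θ = 0.5, 40% invalid weight), and 100–200 for the trial and
cohort experiments — sizes at which Monte-Carlo error is comfortably
inside the tolerances being checked while the whole battery runs in
seconds. Weighted-median consistency is asymptotic in per-ratio
precision, so that experiment uses large GWAS sizes (5×10⁵ / 2×10⁶);
with one-sided pleiotropy the estimator sits at an upper quantile of the
valid ratios, displaced from θ in proportion to their sampling spread,
and at the default study-sized GWAS that displacement is still visible.

## Design choices where the design was open

- Column mapping at ingestion is explicit; no header sniffing.
- Missing fetal genotypes are handled complete-case within SNP, with
  per-SNP counts reported.
- Covariate sets are explicit configuration everywhere (gestational age
  and child sex for cohort associations; none by default for the
  allele-score screen).
- Multivariable adjustment is implemented in full; a "partial" design
  (only instruments with second-trait effects available) is expressed by
  subsetting the instrument list in configuration.
- Trial risk-of-bias indicators (intention-to-treat, loss to follow-up,
  range-reported-as-CI) are carried as inert metadata for subgrouping;
  no quantitative bias adjustment is attempted.
- The pipeline refuses to run any analysis whose instrument-count
  requirement fails pre-flight, and removes partial outputs on stage
  failure; reruns with identical configuration and seeds are
  byte-identical.

## Known limitations

- The Egger intercept's estimand is the weighted-least-squares projection
  of the pleiotropy vector, which differs slightly from the arithmetic
  mean α when instrument selection and weights are correlated.
- Bootstrap SEs for the weighted median ignore the (small) exposure-side
  sampling error, consistent with the first-order ratio SE.
- The trial-IV stage consumes published arm-level summaries only; it
  cannot reconstruct compliance-adjusted estimates a trial did not
  report, and the intention-to-treat flag is informational.
- No LD-aware modelling: supplying correlated instruments will understate
  SEs in all estimators.
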