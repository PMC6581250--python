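# mrtri

Two-sample mendelian randomisation (MR) with randomised-trial
instrumental-variable triangulation, built for the question of whether
maternal circulating biomarkers — 25-hydroxyvitamin D (25(OH)D) and calcium
— causally affect offspring birth weight. The package is aimed at
epidemiologists and biostatisticians who work from GWAS summary statistics
and published trial summaries rather than individual-level data, and who
want every estimator, unit conversion and sensitivity analysis to be
scriptable, seeded and testable without access to cohort data.

## The statistical core

Given per-SNP associations with an exposure (effect `E_j`, from one GWAS
sample) and with an outcome (effect `β_yj`, SE `σ_j`, from another),
harmonised to the exposure-raising alleles:

- **Wald ratio** per instrument: `β_j = β_yj / E_j`, with first-order SE
  `σ_j / |E_j|`; ratios are pooled by fixed-effect inverse-variance
  meta-analysis (`w_j = se_j⁻²`), with Cochran's Q, I² and leave-one-out
  diagnostics.
- **IVW**: `β_IVW = Σ E_j² σ_j⁻² β_j / Σ E_j² σ_j⁻²` — the weighted
  regression of `β_yj` on `E_j` through the origin, algebraically identical
  to the pooled Wald ratio; fixed-effect SEs, t-reference CIs.
- **MR-Egger**: the same weighted regression with a free intercept `β_0`;
  the slope is a pleiotropy-adjusted effect under the InSIDE assumption and
  a non-zero intercept indicates directional horizontal pleiotropy.
- **Weighted median**: per-SNP ratios sorted with normalised weights; the
  percentile of ratio `j` is `ρ_j = 100(S_j − w_j/2)` and the estimate
  interpolates at the 50th percentile; consistent while < 50% of the weight
  comes from invalid instruments; bootstrap SE.
- **Multivariable IVW**: weighted regression of `β_yj` on several exposure
  columns jointly (no intercept), giving direct effects adjusted for a
  second genetically proxied trait.
- **Trials as instruments**: for supplementation RCTs reporting arm-level
  mean differences, randomisation is the instrument: the per-trial ratio is
  the birth-weight difference over the biomarker difference, pooled and
  diagnosed with exactly the same fixed-effect machinery.
- **Common reporting scale**: auditable multiplicative transforms — e.g.
  a 10% rise from a gestational 25(OH)D median of 61.8 nmol/l is 6.2 nmol/l,
  the calcium reference range 8.5–10.5 mg/dl gives an SD of 0.5 mg/dl, and
  ln-scale GWAS effects convert per-10% via ln(1.1).

Individual-level stages (fetal-genotype-adjusted maternal associations,
allele-score-versus-confounder screens) and seed-deterministic synthetic
generators for all three input classes (GWAS summaries, trial summaries,
mother–child panels with the Mendelian maternal–fetal dosage correlation of
≈ 0.5) round out the pipeline.

## Worked example

The numbered scripts under `analysis/` run the full walkthrough on
synthetic data shaped like the real study (7 instruments per exposure,
GWAS of 79k/190k, 24 vitamin-D-type and 6 calcium-type trials):

```bash
python analysis/01_simulate_inputs.py
python analysis/02_mr_analysis.py
python analysis/03_rct_iv.py
python analysis/04_triangulate.py
python analysis/05_sensitivity.py
```

The triangulation step prints (generated with the seeds fixed in the
scripts):

```
25(OH)D    MR      ivw                  0.39 g (   -1.86 to     2.65)
25(OH)D    MR      weighted-median      0.12 g (   -2.18 to     2.41)
calcium    MR      ivw                -13.71 g (  -29.24 to     1.82)  << CIs disjoint from RCT-IV
calcium    MR      weighted-median    -14.37 g (  -31.12 to     2.38)  << CIs disjoint from RCT-IV
25(OH)D    RCT-IV  rct-iv               3.91 g (   -0.31 to     8.14)
calcium    RCT-IV  rct-iv             150.56 g (  118.21 to   182.92)  << CIs disjoint from MR
```

Reading it: the vitamin-D stream was generated with a null genetic effect
and a weak positive trial effect — both estimates are small and their CIs
overlap, so the streams are concordant. The calcium stream was generated
with a weak inverse genetic effect but a strong positive trial effect — the
disjoint-CI flags mark the discordance, the signature that at least one
evidence stream is biased. All effects are in grams of birth weight per
10% higher 25(OH)D or per 1 SD higher calcium.

The same machinery is scriptable through the CLI (`mrtri simulate`,
`mrtri mr --config run.yaml`, `mrtri rct-iv`, `mrtri triangulate`,
`mrtri report`) or directly from Python:

```python
from mrtri import harmonise, ivw, read_snp_summaries
from mrtri.datasets import vitd_instruments   # bundled published instruments

exposure = vitd_instruments()
outcome = read_snp_summaries("my_outcome_gwas.tsv", trait="birth_weight")
result = ivw(harmonise(exposure, outcome, "infer-by-eaf"))
```

## Layout

- `src/mrtri/` — the library: `summary_io` (ingestion + harmonisation),
  `estimators`, `mvmr`, `rct`, `scaling`, `cohort`, `simulate`,
  `calibration`, `pipeline`, `cli`, `datasets`.
- `analysis/` — the numbered walkthrough scripts (thin drivers over the
  library; all computation lives in `src/`).
- `tests/` — pytest suite including property-based tests and the
  acceptance checks.
- `docs/methods.md` — modelling assumptions, parameter choices, numerical
  conventions and known limitations.
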