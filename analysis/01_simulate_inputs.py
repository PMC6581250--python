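#!/usr/bin/env python
"""Materialise the demo inputs for the analysis walkthrough.

Two exposure streams mirror the study design:

* a vitamin-D-like exposure — 7 instruments on the natural-log nmol/l
  scale, a true causal effect of zero on (SD-standardised) birth weight,
  and 24 supplementation trials in which the biomarker does shift birth
  weight (0.96 g per nmol/l, i.e. ~5.9 g per 10% after scaling by 6.2);
* a calcium-like exposure — 7 instruments on the SD scale, a weak inverse
  causal effect (-0.042 SD of birth weight per SD, ~-20 g), and 6 trials
  simulated with a strong positive effect (356 g per mg/dl, ~178 g per
  0.5 mg/dl SD), reproducing the discordance pattern between evidence
  streams.

Outputs land in results/demo_data/ as TSVs readable by the ingestion
modules. All seeds fixed; rerunning reproduces the files byte for byte.
"""

from pathlib import Path

from mrtri.rct import write_rct_records
from mrtri.simulate import RctSimConfig, TwoSampleConfig, simulate_rcts, simulate_two_sample
from mrtri.summary_io import write_snp_summaries

OUT = Path("results/demo_data")
OUT.mkdir(parents=True, exist_ok=True)

# vitamin-D stream: null genetic effect, positive trial effect
vd_exp, vd_out, _ = simulate_two_sample(TwoSampleConfig(
    n_snps=7, theta=0.0, palindromic_fraction=0.25,
    exposure_label="25(OH)D", exposure_unit="ln nmol/l",
    outcome_unit="SD", seed=1001,
))
write_snp_summaries(vd_exp, OUT / "vitd_exposure_gwas.tsv")
write_snp_summaries(vd_out, OUT / "vitd_outcome_gwas.tsv")

vd_itt, _, _ = simulate_rcts(RctSimConfig(
    n_trials=24, n_range=(16, 1134), biomarker_shift=25.0, biomarker_sd=15.0,
    theta=0.96, outcome_sd=476.0, seed=1002,
))
write_rct_records(vd_itt, OUT / "vitd_trials.tsv")

# calcium stream: weak inverse genetic effect, strong positive trial effect
ca_exp, ca_out, _ = simulate_two_sample(TwoSampleConfig(
    n_snps=7, theta=-0.042, exposure_beta_mean=0.1, exposure_beta_sd=0.04,
    n_exposure=61_275, palindromic_fraction=0.25,
    exposure_label="calcium", exposure_unit="SD",
    outcome_unit="SD", seed=2001,
))
write_snp_summaries(ca_exp, OUT / "calcium_exposure_gwas.tsv")
write_snp_summaries(ca_out, OUT / "calcium_outcome_gwas.tsv")

ca_itt, _, _ = simulate_rcts(RctSimConfig(
    n_trials=6, n_range=(23, 274), biomarker_shift=0.9, biomarker_sd=0.4,
    theta=356.0, outcome_sd=476.0, seed=2002,
))
write_rct_records(ca_itt, OUT / "calcium_trials.tsv")

print(f"wrote demo GWAS summaries and trial tables to {OUT}/")
print(f"  vitamin D: {len(vd_exp)} instruments, {len(vd_itt)} trials")
print(f"  calcium:   {len(ca_exp)} instruments, {len(ca_itt)} trials")
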