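#!/usr/bin/env python
"""Individual-level sensitivity checks on a simulated mother-child cohort.

1. Fetal-genotype adjustment: regenerate maternal SNP-birth-weight
   associations conditioning on the fetal dosage at the same SNP, and
   compare with the marginal associations. Under a purely maternal effect
   the two agree; a fetal pathway would pull them apart.
2. Allele-score screen: regress observed confounders on the weighted
   allele score; valid instruments show null associations.

Tables land in results/sensitivity/.
"""

from pathlib import Path

import pandas as pd

from mrtri.cohort import allele_score_screen, conditional_maternal_association
from mrtri.simulate import CohortSimConfig, simulate_mother_child

OUT = Path("results/sensitivity")
OUT.mkdir(parents=True, exist_ok=True)

panel, truth = simulate_mother_child(CohortSimConfig(
    n_pairs=5223, eaf=(0.3, 0.5, 0.7), maternal_effect=40.0, fetal_effect=0.0,
    seed=3001,
))

rows = []
for snp in truth.rsids:
    adj = conditional_maternal_association(panel, snp, ["gestational_age", "child_sex"])
    raw = conditional_maternal_association(panel, snp, ["gestational_age", "child_sex"],
                                           adjust_fetal=False)
    rows.append({"rsid": snp, "beta_adjusted": adj.beta, "se_adjusted": adj.se,
                 "beta_marginal": raw.beta, "se_marginal": raw.se, "n": adj.n})
fetal = pd.DataFrame(rows)
fetal.to_csv(OUT / "fetal_adjustment.tsv", sep="\t", index=False)

print("fetal-genotype adjustment (true maternal effect 40 g/allele, no fetal effect):")
for _, r in fetal.iterrows():
    print(f"  {r['rsid']}: adjusted {r['beta_adjusted']:6.2f} g "
          f"vs marginal {r['beta_marginal']:6.2f} g (SE ~{r['se_adjusted']:.1f})")

weights = {snp: 0.05 for snp in truth.rsids}
screen = allele_score_screen(
    panel, weights, ["height", "education_years", "deprivation", "smoking"]
)
screen.to_csv(OUT / "allele_score_screen.tsv", sep="\t", index=False)
print("\nallele-score vs confounder screen (all confounders independent of genotype):")
for _, r in screen.iterrows():
    print(f"  {r['confounder']:16s} beta {r['beta']:8.3f}  p {r['pval']:.3f}")
print("  (under the null ~5% of tests fall below 0.05 by chance;"
      " judge the table as a whole)")
print(f"\nwrote {OUT}/fetal_adjustment.tsv and {OUT}/allele_score_screen.tsv")
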