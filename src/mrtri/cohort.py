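"""Individual-level mother-child analyses.

Two stages need person-level data rather than GWAS summaries:

1. *Fetal-genotype adjustment.* A mother transmits each allele to her child
   with probability 1/2, so maternal and fetal dosages at a SNP correlate at
   about 0.5. If the fetal genotype affects birth weight directly, the
   marginal maternal SNP-birth-weight association is contaminated.
   :func:`conditional_maternal_association` regresses birth weight on the
   maternal dosage *conditional on* the fetal dosage at the same SNP (plus
   covariates such as gestational age and child sex), and returns the
   adjusted association as a ``SnpSummary`` so the downstream MR estimators
   run unchanged on the fetal-adjusted path.

2. *Allele-score confounder screen.* A weighted allele score (weights = the
   instruments' exposure effects) should be unrelated to observed
   confounders if the instruments are valid; :func:`allele_score_screen`
   regresses each named confounder on the score and tabulates the
   associations.

Regressions are ordinary least squares via statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import CollinearityError, SchemaError, ValidationError
from .summary_io import SnpSummary

MATERNAL_PREFIX = "m_"
FETAL_PREFIX = "f_"


@dataclass
class CohortPanel:
    """One row per mother-child pair: dosages, birth weight, covariates.

    Dosage columns are named ``m_<rsid>`` (maternal) and ``f_<rsid>``
    (fetal); fetal dosages may be missing pair-wise. Birth weight is in
    grams.
    """

    data: pd.DataFrame
    snps: list[str] = field(init=False)

    def __post_init__(self):
        if "birth_weight" not in self.data.columns:
            raise SchemaError("panel must have a 'birth_weight' column")
        self.snps = [
            c[len(MATERNAL_PREFIX):]
            for c in self.data.columns
            if c.startswith(MATERNAL_PREFIX)
        ]
        if not self.snps:
            raise SchemaError(f"panel has no '{MATERNAL_PREFIX}<rsid>' dosage columns")
        dose_cols = [c for c in self.data.columns
                     if c.startswith((MATERNAL_PREFIX, FETAL_PREFIX))]
        doses = self.data[dose_cols]
        if ((doses < 0) | (doses > 2)).any().any():
            raise ValidationError("dosages must lie in [0, 2]")
        if (self.data["birth_weight"] <= 0).any():
            raise ValidationError("birth weights must be positive")

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def read(cls, path: str | Path) -> "CohortPanel":
        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        return cls(pd.read_csv(path, sep=sep))

    def write(self, path: str | Path) -> None:
        self.data.to_csv(Path(path), sep="\t", index=False)


def conditional_maternal_association(
    panel: CohortPanel,
    snp: str,
    covariate_names: Sequence[str] = (),
    *,
    adjust_fetal: bool = True,
    min_complete: int = 30,
    collinearity_tol: float = 1e-10,
) -> SnpSummary:
    """Maternal per-allele effect on birth weight, adjusted for fetal genotype.

    Least-squares coefficient of the maternal dosage on birth weight (grams
    per allele), with the fetal dosage at the same SNP plus any named
    covariates in the model. With ``adjust_fetal=False`` this reduces to a
    plain covariate-adjusted regression. Complete cases only, within SNP.
    """
    m_col, f_col = MATERNAL_PREFIX + snp, FETAL_PREFIX + snp
    if m_col not in panel.data.columns:
        raise SchemaError(f"no maternal dosage column {m_col!r}")
    cols = [m_col, "birth_weight", *covariate_names]
    if adjust_fetal:
        if f_col not in panel.data.columns:
            raise SchemaError(f"no fetal dosage column {f_col!r}")
        cols.append(f_col)
    missing = [c for c in cols if c not in panel.data.columns]
    if missing:
        raise SchemaError(f"panel missing column(s): {missing}")

    sub = panel.data[cols].dropna()
    n = len(sub)
    if n < min_complete:
        raise ValidationError(
            f"{snp}: only {n} complete mother-child pairs (need >= {min_complete})"
        )
    if float(np.var(sub[m_col])) == 0.0:
        raise ValidationError(f"{snp}: maternal dosage has zero variance")
    if adjust_fetal:
        r = np.corrcoef(sub[m_col], sub[f_col])[0, 1]
        if abs(r) > 1 - collinearity_tol:
            raise CollinearityError(
                f"{snp}: maternal and fetal dosages are collinear (r = {r:.6f})"
            )

    predictors = [m_col] + ([f_col] if adjust_fetal else []) + list(covariate_names)
    X = sm.add_constant(sub[predictors].astype(float))
    fit = sm.OLS(sub["birth_weight"].astype(float), X).fit()
    return SnpSummary(
        rsid=snp,
        effect_allele="A",  # synthetic orientation: dosage counts the exposure-raising allele
        other_allele="G",
        beta=float(fit.params[m_col]),
        se=float(fit.bse[m_col]),
        pval=float(min(max(fit.pvalues[m_col], np.nextafter(0, 1)), 1.0)),
        n=n,
        trait="birth_weight",
        unit="g",
    )


def weighted_allele_score(panel: CohortPanel, weights: Mapping[str, float],
                          *, who: str = "maternal") -> pd.Series:
    """Per-person score: sum over SNPs of exposure-effect weight x dosage."""
    prefix = MATERNAL_PREFIX if who == "maternal" else FETAL_PREFIX
    missing = [s for s in weights if prefix + s not in panel.data.columns]
    if missing:
        raise SchemaError(f"panel lacks dosage columns for: {missing}")
    if all(w == 0 for w in weights.values()):
        raise ValidationError("all-zero allele-score weights")
    score = sum(w * panel.data[prefix + s] for s, w in weights.items())
    return pd.Series(score, name="allele_score")


def allele_score_screen(
    panel: CohortPanel,
    weights: Mapping[str, float],
    confounder_names: Sequence[str],
) -> pd.DataFrame:
    """Regress each confounder on the weighted allele score.

    Valid instruments should show null associations throughout; any strong
    association flags a pathway from genotype to the confounder. Returns a
    tidy table (confounder, beta, se, pval, n).
    """
    if len(confounder_names) < 2:
        raise ValidationError("screen expects at least 2 confounders")
    missing = [c for c in confounder_names if c not in panel.data.columns]
    if missing:
        raise SchemaError(f"panel missing confounder column(s): {missing}")
    score = weighted_allele_score(panel, weights)
    rows = []
    for name in confounder_names:
        sub = pd.DataFrame({"y": panel.data[name], "score": score}).dropna()
        X = sm.add_constant(sub["score"].astype(float))
        fit = sm.OLS(sub["y"].astype(float), X).fit()
        rows.append(
            {
                "confounder": name,
                "beta": float(fit.params["score"]),
                "se": float(fit.bse["score"]),
                "pval": float(fit.pvalues["score"]),
                "n": len(sub),
            }
        )
    return pd.DataFrame(rows)
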