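"""Multivariable IVW mendelian randomisation.

Adjusts the causal effect of a primary exposure for one or more additional
genetically proxied traits (e.g. maternal height alongside 25(OH)D, or
educational attainment alongside calcium) by regressing the SNP-outcome
effects on all exposure-effect columns jointly, weighted by the inverse
outcome variance, with no intercept. Coefficient k is the direct effect of
exposure k holding the others fixed.

With a single exposure this reduces exactly to the univariable IVW
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .estimators import MrResult, _interval
from .exceptions import CollinearityError, ValidationError


@dataclass(frozen=True)
class MultiExposureRecord:
    rsid: str
    beta_exp: tuple[float, ...]       # one per exposure
    se_exp: tuple[float, ...]
    beta_out: float
    se_out: float

    def __post_init__(self):
        if len(self.beta_exp) != len(self.se_exp):
            raise ValidationError(f"{self.rsid}: beta_exp and se_exp lengths differ")
        if not self.se_out > 0:
            raise ValidationError(f"{self.rsid}: outcome SE must be > 0")


@dataclass
class MultiExposureSet:
    records: list[MultiExposureRecord]
    exposure_labels: list[str]
    outcome_label: str = ""
    outcome_unit: str = ""
    exposure_units: list[str] = field(default_factory=list)

    def __post_init__(self):
        k = len(self.exposure_labels)
        for r in self.records:
            if len(r.beta_exp) != k:
                raise ValidationError(
                    f"{r.rsid}: expected {k} exposure betas, got {len(r.beta_exp)}"
                )


def mvmr_ivw(
    mset: MultiExposureSet, *, level: float = 0.95
) -> list[MrResult]:
    """Multivariable IVW: one direct-effect estimate per exposure.

    Weighted (``se_out**-2``) least squares of the outcome effects on the
    exposure-effect matrix with no intercept; fixed-effect covariance
    ``(X'WX)**-1``; CIs via t with df = n - K.
    """
    n, k = len(mset.records), len(mset.exposure_labels)
    if n < k + 1:
        raise ValidationError(
            f"multivariable IVW needs at least {k + 1} instruments for {k} exposures, got {n}"
        )
    X = np.array([r.beta_exp for r in mset.records], dtype=float)
    y = np.array([r.beta_out for r in mset.records], dtype=float)
    w = np.array([r.se_out ** -2 for r in mset.records], dtype=float)

    xtwx = X.T @ (w[:, None] * X)
    rank = np.linalg.matrix_rank(xtwx)
    if rank < k:
        # name the offending exposures: columns whose removal restores full rank
        offenders = []
        for j in range(k):
            sub = np.delete(np.delete(xtwx, j, axis=0), j, axis=1)
            if np.linalg.matrix_rank(sub) == k - 1:
                offenders.append(mset.exposure_labels[j])
        raise CollinearityError(
            f"exposure-effect matrix is rank deficient (rank {rank} < {k}); "
            f"collinear exposures involve: {offenders or mset.exposure_labels}"
        )
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    cov = np.linalg.inv(xtwx)
    df = n - k
    out: list[MrResult] = []
    for j, lab in enumerate(mset.exposure_labels):
        se = float(np.sqrt(cov[j, j]))
        lo, hi, p = _interval(float(coef[j]), se, level, df)
        unit_in = mset.exposure_units[j] if j < len(mset.exposure_units) else ""
        out.append(
            MrResult(
                method="mvmr-ivw", beta=float(coef[j]), se=se, ci_low=lo,
                ci_high=hi, pval=p, n_instruments=n, ci_df=df, level=level,
                label=lab, units=f"{mset.outcome_unit} per {unit_in}".strip(),
            )
        )
    return out


def from_columns(
    rsids: Sequence[str],
    beta_exp: np.ndarray,
    se_exp: np.ndarray,
    beta_out: Sequence[float],
    se_out: Sequence[float],
    exposure_labels: Sequence[str],
    **labels,
) -> MultiExposureSet:
    """Build a MultiExposureSet from array-like columns (instruments x exposures)."""
    beta_exp = np.atleast_2d(np.asarray(beta_exp, dtype=float))
    se_exp = np.atleast_2d(np.asarray(se_exp, dtype=float))
    records = [
        MultiExposureRecord(
            rsid=str(rsids[i]),
            beta_exp=tuple(beta_exp[i]),
            se_exp=tuple(se_exp[i]),
            beta_out=float(beta_out[i]),
            se_out=float(se_out[i]),
        )
        for i in range(len(rsids))
    ]
    return MultiExposureSet(records=records, exposure_labels=list(exposure_labels), **labels)
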