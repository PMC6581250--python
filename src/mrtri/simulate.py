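"""Synthetic data with the statistical structure the analyses assume.

Three generators mirror the three input classes of the study design:

* :func:`simulate_two_sample` — GWAS summary statistics for an exposure and
  an outcome under the linear instrumental-variable model
  ``beta_out_j = theta * E_j + alpha_j + noise``, where ``theta`` is the
  causal effect and ``alpha_j`` a per-SNP pleiotropic effect (zero for
  valid instruments). Pleiotropy can respect or violate the InSIDE
  condition (``alpha`` independent of, or correlated with, ``E``).
* :func:`simulate_rcts` — two-arm supplementation trials in which
  randomisation shifts a biomarker in compliers and the biomarker shifts
  birth weight by ``theta`` grams per unit; arm-level summaries are emitted
  both as-randomised (intention-to-treat) and per-protocol so compliance
  bias can be demonstrated.
* :func:`simulate_mother_child` — individual-level mother-child panels with
  Mendelian transmission (one maternal allele passed on, the other parental
  allele drawn from the population), giving the characteristic maternal-
  fetal dosage correlation of about 0.5.

All generators take an explicit seed, are bit-reproducible, and return a
truth record carrying everything needed to score an estimator against the
generating parameters.

Default configurations are sized to the study the package emulates: seven
instruments per exposure, exposure GWAS of ~79,000 and an outcome GWAS of
~190,000 (the implied per-SNP standard errors follow the usual
``1 / sqrt(2 p (1-p) n)`` rule for a unit-variance trait), 24 vitamin-D-type
trials of 16-1,134 participants, and cohort panels of 5,223 pairs with a
birth-weight residual SD giving a total SD near 476 g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import CohortPanel, FETAL_PREFIX, MATERNAL_PREFIX
from .exceptions import ConfigError
from .rct import RctRecord, parse_rct_record
from .summary_io import SnpSummary

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]


def gwas_se(eaf: np.ndarray, n: float) -> np.ndarray:
    """Per-allele SE for a unit-variance trait: ``1 / sqrt(2 p (1-p) n)``."""
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


# ---------------------------------------------------------------------------
# two-sample GWAS summaries


@dataclass
class TwoSampleConfig:
    """Generating model for paired exposure/outcome GWAS summary tables."""

    n_snps: int = 7
    theta: float = 0.0                       # outcome units per exposure unit
    exposure_beta_mean: float = 0.06         # |E_j| location (log-nmol/l per allele)
    exposure_beta_sd: float = 0.03
    pleiotropy_mean: float = 0.0             # alpha location for invalid SNPs
    pleiotropy_sd: float = 0.0
    inside_violation: bool = False           # alpha correlated with E_j
    inside_gamma: float = 0.0                # alpha_j = gamma*E_j + noise when violating
    invalid_fraction: float = 0.0            # share of IVW weight carried by alpha != 0 SNPs
    n_exposure: int = 79_366
    n_outcome: int = 190_406
    eaf_range: tuple[float, float] = (0.1, 0.9)
    palindromic_fraction: float = 0.0
    exposure_label: str = "exposure"
    outcome_label: str = "birth_weight"
    exposure_unit: str = "ln-unit"
    outcome_unit: str = "SD"
    seed: int | None = None

    def validate(self) -> None:
        if self.n_snps < 2:
            raise ConfigError(f"need at least 2 SNPs, got {self.n_snps}")
        if not (0.0 <= self.invalid_fraction < 1.0):
            raise ConfigError(f"invalid_fraction must be in [0, 1), got {self.invalid_fraction}")
        if self.exposure_beta_sd <= 0:
            raise ConfigError("exposure_beta_sd must be > 0")


@dataclass
class TwoSampleTruth:
    theta: float
    exposure_effects: np.ndarray       # true E_j
    pleiotropy: np.ndarray             # alpha_j
    valid: np.ndarray                  # bool per SNP
    rsids: list[str]


def simulate_two_sample(
    config: TwoSampleConfig,
) -> tuple[list[SnpSummary], list[SnpSummary], TwoSampleTruth]:
    """Generate exposure and outcome summary lists plus the generating truth.

    The outcome list is emitted with random allele-orientation flips (and,
    optionally, palindromic allele pairs) so that harmonisation is
    genuinely exercised before estimation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    j = config.n_snps
    rsids = [f"rs{100000 + i}" for i in range(j)]

    eaf = rng.uniform(*config.eaf_range, size=j)
    e_true = np.abs(rng.normal(config.exposure_beta_mean, config.exposure_beta_sd, size=j))
    e_true = np.maximum(e_true, 1e-4)   # keep instruments non-degenerate

    se_exp = gwas_se(eaf, config.n_exposure)
    se_out = gwas_se(eaf, config.n_outcome)

    # invalid_fraction is a share of IVW weight (w_j ~ E_j^2 / se_out^2). The
    # invalid set is filled in random order under a hard cap at the target, so
    # a nominal 40% can never cross the weighted median's 50% breakdown line,
    # while keeping instrument selection essentially independent of strength
    # (required for pleiotropy experiments under the InSIDE condition).
    valid = np.ones(j, dtype=bool)
    if config.invalid_fraction > 0:
        w = e_true ** 2 / se_out ** 2
        w = w / w.sum()
        share = 0.0
        for i in rng.permutation(j):
            if share + w[i] <= config.invalid_fraction + 1e-12:
                valid[i] = False
                share += w[i]
        if valid.all():
            raise ConfigError(
                f"invalid_fraction {config.invalid_fraction} is infeasible at "
                f"J = {config.n_snps}: every single instrument carries more weight"
            )
    alpha = np.zeros(j)
    n_invalid = int((~valid).sum())
    if n_invalid:
        idx = ~valid
        noise = rng.normal(config.pleiotropy_mean, max(config.pleiotropy_sd, 1e-12), idx.sum())
        if config.inside_violation:
            alpha[idx] = config.inside_gamma * e_true[idx] + noise
        else:
            alpha[idx] = noise

    beta_exp_obs = e_true + rng.normal(0.0, se_exp)
    beta_out_obs = config.theta * e_true + alpha + rng.normal(0.0, se_out)

    n_palin = round(config.palindromic_fraction * j)
    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=j)
    pairs = [_NONPALINDROMIC_PAIRS[k] for k in pair_idx]
    if n_palin:
        for i in rng.choice(j, size=n_palin, replace=False):
            pairs[i] = _PALINDROMIC_PAIRS[rng.integers(0, len(_PALINDROMIC_PAIRS))]

    exposure, outcome = [], []
    flip = rng.random(j) < 0.5          # report outcome for the other allele
    for i in range(j):
        ea, oa = pairs[i]
        exposure.append(
            SnpSummary(
                rsid=rsids[i], effect_allele=ea, other_allele=oa,
                beta=float(beta_exp_obs[i]), se=float(se_exp[i]), eaf=float(eaf[i]),
                n=config.n_exposure, trait=config.exposure_label,
                unit=config.exposure_unit,
            )
        )
        if flip[i]:
            out = SnpSummary(
                rsid=rsids[i], effect_allele=oa, other_allele=ea,
                beta=float(-beta_out_obs[i]), se=float(se_out[i]),
                eaf=float(1.0 - eaf[i]), n=config.n_outcome,
                trait=config.outcome_label, unit=config.outcome_unit,
            )
        else:
            out = SnpSummary(
                rsid=rsids[i], effect_allele=ea, other_allele=oa,
                beta=float(beta_out_obs[i]), se=float(se_out[i]),
                eaf=float(eaf[i]), n=config.n_outcome,
                trait=config.outcome_label, unit=config.outcome_unit,
            )
        outcome.append(out)

    truth = TwoSampleTruth(
        theta=config.theta, exposure_effects=e_true, pleiotropy=alpha,
        valid=valid, rsids=rsids,
    )
    return exposure, outcome, truth


# ---------------------------------------------------------------------------
# supplementation trials


@dataclass
class RctSimConfig:
    """Generating model for two-arm supplementation trials."""

    n_trials: int = 24
    n_range: tuple[int, int] = (16, 1134)    # randomised per trial
    biomarker_shift: float = 25.0            # mean uptake in treated compliers (units)
    biomarker_sd: float = 15.0               # individual biomarker SD (units)
    compliance: float = 1.0                  # fraction of treated who take supplement
    confounded_compliance: bool = False      # compliers differ in outcome potential
    compliance_confounding_g: float = 0.0    # grams added to compliers' BW potential
    attrition: float = 0.0                   # fraction lost to follow-up
    differential_attrition: float = 0.0      # extra attrition in control arm
    theta: float = 1.0                       # g of birth weight per biomarker unit
    outcome_sd: float = 476.0                # g
    baseline_bw: float = 3227.0              # g
    seed: int | None = None

    def validate(self) -> None:
        for name in ("compliance", "attrition", "differential_attrition"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_range[0] < 4:
            raise ConfigError("smallest trial must randomise at least 4 participants")


@dataclass
class RctTruth:
    theta: float
    compliance: float
    achieved_shift: list[float]   # realised biomarker arm difference per trial


def _arm_summary(values: np.ndarray) -> tuple[float, float]:
    return float(np.mean(values)), float(np.var(values, ddof=1) / len(values))


def simulate_rcts(
    config: RctSimConfig,
) -> tuple[list[RctRecord], list[RctRecord], RctTruth]:
    """Simulate trials; returns (as-randomised records, per-protocol records, truth).

    As-randomised records compare everyone by arm (intention to treat);
    per-protocol records drop treated non-compliers, which biases the
    contrast when compliance is confounded with outcome potential.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    itt_records, pp_records, shifts = [], [], []
    for t in range(config.n_trials):
        n = int(rng.integers(config.n_range[0], config.n_range[1] + 1))
        n_treat = n // 2
        n_ctrl = n - n_treat
        arm = np.concatenate([np.ones(n_treat, bool), np.zeros(n_ctrl, bool)])

        u = rng.normal(size=n)            # latent outcome potential
        if config.confounded_compliance:
            # compliers are the high-potential fraction of the treated arm
            threshold = np.quantile(u, 1.0 - config.compliance)
            complier = u >= threshold
        else:
            complier = rng.random(n) < config.compliance
        took = arm & complier

        biomarker = rng.normal(0.0, config.biomarker_sd, size=n)
        biomarker[took] += config.biomarker_shift
        bw = (
            config.baseline_bw
            + config.theta * biomarker
            + config.compliance_confounding_g * u
            + rng.normal(0.0, config.outcome_sd, size=n)
        )

        lost = rng.random(n) < (
            config.attrition + np.where(arm, 0.0, config.differential_attrition)
        )
        keep = ~lost
        if (keep & arm).sum() < 2 or (keep & ~arm).sum() < 2:
            raise ConfigError(
                f"trial {t}: attrition leaves fewer than 2 participants in an arm"
            )

        def record(mask_treat, mask_ctrl, trial_id):
            m_bt, v_bt = _arm_summary(biomarker[mask_treat])
            m_bc, v_bc = _arm_summary(biomarker[mask_ctrl])
            m_wt, v_wt = _arm_summary(bw[mask_treat])
            m_wc, v_wc = _arm_summary(bw[mask_ctrl])
            d_b, se_b = m_bt - m_bc, math.sqrt(v_bt + v_bc)
            d_w, se_w = m_wt - m_wc, math.sqrt(v_wt + v_wc)
            z = 1.959963984540054
            return parse_rct_record(
                {
                    "trial_id": trial_id,
                    "n_randomised": n,
                    "exposure_diff": d_b,
                    "exposure_ci_low": d_b - z * se_b,
                    "exposure_ci_high": d_b + z * se_b,
                    "outcome_diff": d_w,
                    "outcome_ci_low": d_w - z * se_w,
                    "outcome_ci_high": d_w + z * se_w,
                    "intention_to_treat": "yes" if trial_id.endswith("itt") else "no",
                    "loss_to_followup_pct": 100.0 * lost.mean(),
                }
            )

        itt = record(keep & arm, keep & ~arm, f"trial{t:02d}-itt")
        pp = record(keep & took, keep & ~arm, f"trial{t:02d}-pp")
        itt_records.append(itt)
        pp_records.append(pp)
        shifts.append(itt.exposure_diff)
    return itt_records, pp_records, RctTruth(
        theta=config.theta, compliance=config.compliance, achieved_shift=shifts
    )


# ---------------------------------------------------------------------------
# mother-child cohort panels


@dataclass
class CohortSimConfig:
    """Generating model for individual-level mother-child panels."""

    n_pairs: int = 5223
    eaf: Sequence[float] = (0.3, 0.5, 0.7)   # one per SNP
    maternal_effect: float | Sequence[float] = 0.0   # g per maternal allele
    fetal_effect: float | Sequence[float] = 0.0      # g per fetal allele
    missing_fetal_fraction: float = 0.0
    bw_mean: float = 3500.0
    bw_sd: float = 450.0                     # residual SD, g
    gestage_effect: float = 130.0            # g per week
    sex_effect: float = 120.0                # g, male vs female
    seed: int | None = None

    def validate(self) -> None:
        if self.n_pairs < 30:
            raise ConfigError(f"need at least 30 pairs, got {self.n_pairs}")
        for p in self.eaf:
            if not (0.0 < p < 1.0):
                raise ConfigError(f"allele frequency must be in (0, 1), got {p}")
        if not (0.0 <= self.missing_fetal_fraction < 1.0):
            raise ConfigError("missing_fetal_fraction must be in [0, 1)")


@dataclass
class CohortTruth:
    maternal_effects: np.ndarray
    fetal_effects: np.ndarray
    rsids: list[str]


def _broadcast(value, k: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(k, float(arr))
    if arr.shape != (k,):
        raise ConfigError(f"expected scalar or length-{k} effects, got shape {arr.shape}")
    return arr


def simulate_mother_child(config: CohortSimConfig) -> tuple[CohortPanel, CohortTruth]:
    """Simulate mother-child pairs with Mendelian allele transmission.

    Maternal genotypes are Hardy-Weinberg draws; one maternal allele is
    transmitted at random and the paternal allele drawn from the
    population, so corr(maternal, fetal dosage) is ~0.5 at any frequency.
    Birth weight is linear in dosages, gestational age and child sex, with
    confounders (height, education, deprivation, smoking) drawn
    independently of genotype.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, k = config.n_pairs, len(config.eaf)
    rsids = [f"rs{200000 + i}" for i in range(k)]
    m_eff = _broadcast(config.maternal_effect, k)
    f_eff = _broadcast(config.fetal_effect, k)

    import pandas as pd

    cols: dict[str, np.ndarray] = {}
    m_dose = np.empty((n, k))
    f_dose = np.empty((n, k))
    for i, p in enumerate(config.eaf):
        a1 = rng.random(n) < p
        a2 = rng.random(n) < p
        transmitted = np.where(rng.random(n) < 0.5, a1, a2)
        paternal = rng.random(n) < p
        m_dose[:, i] = a1.astype(float) + a2.astype(float)
        f_dose[:, i] = transmitted.astype(float) + paternal.astype(float)

    gestage = rng.normal(39.8, 1.3, size=n)
    sex = (rng.random(n) < 0.5).astype(float)
    bw = (
        config.bw_mean
        + config.gestage_effect * (gestage - 39.8)
        + config.sex_effect * (sex - 0.5)
        + m_dose @ m_eff
        + f_dose @ f_eff
        + rng.normal(0.0, config.bw_sd, size=n)
    )
    bw = np.maximum(bw, 300.0)   # physical floor; essentially never binds

    for i, rsid in enumerate(rsids):
        cols[MATERNAL_PREFIX + rsid] = m_dose[:, i]
    fetal = f_dose.copy()
    if config.missing_fetal_fraction:
        miss = rng.random((n, k)) < config.missing_fetal_fraction
        fetal = np.where(miss, np.nan, fetal)
    for i, rsid in enumerate(rsids):
        cols[FETAL_PREFIX + rsid] = fetal[:, i]

    frame = pd.DataFrame(
        {
            "pair_id": [f"p{i:05d}" for i in range(n)],
            **cols,
            "birth_weight": bw,
            "gestational_age": gestage,
            "child_sex": sex,
            "height": rng.normal(164.5, 6.7, size=n),
            "education_years": rng.normal(13.0, 2.5, size=n),
            "deprivation": rng.normal(0.0, 3.0, size=n),
            "smoking": (rng.random(n) < 0.15).astype(float),
        }
    )
    return CohortPanel(frame), CohortTruth(
        maternal_effects=m_eff, fetal_effects=f_eff, rsids=rsids
    )
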