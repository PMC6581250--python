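"""Seeded calibration experiments for the estimator suite.

These experiments generate data with :mod:`mrtri.simulate`, run the full
ingestion-harmonisation-estimation path, and score the results against the
generating truth. They back both the test suite and the reproducibility
script, so each returns plain numbers rather than asserting anything.

Replicate counts are arguments with defaults chosen so the standard runs
finish in seconds on one CPU while leaving Monte-Carlo error well inside
the tolerances being checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import conditional_maternal_association
from .estimators import ivw, mr_egger, weighted_median
from .simulate import (
    CohortSimConfig,
    TwoSampleConfig,
    simulate_mother_child,
    simulate_two_sample,
)
from .summary_io import harmonise


def _spawn(seed: int, k: int) -> list[int]:
    """Derive k independent child seeds below 2**31 from one master seed."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(k) % (2 ** 31)]


def ivw_coverage(
    n_reps: int = 1000, theta: float = 0.05, seed: int = 0,
    n_snps: int = 7, ci: str = "normal",
) -> float:
    """Fraction of replicates whose IVW 95% CI covers the true effect.

    All instruments valid; the full simulate -> harmonise -> estimate path
    runs per replicate. The check uses the normal-reference CI, which is the
    exact pivot here: with J instruments the t(J-1) reference is conservative
    by construction (~98.6% at J = 7), a deliberate reporting choice rather
    than a calibration property.
    """
    covered = 0
    for s in _spawn(seed, n_reps):
        exposure, outcome, truth = simulate_two_sample(
            TwoSampleConfig(n_snps=n_snps, theta=theta, seed=s)
        )
        res = ivw(harmonise(exposure, outcome), ci=ci)  # type: ignore[arg-type]
        covered += res.ci_low <= truth.theta <= res.ci_high
    return covered / n_reps


@dataclass
class PleiotropyRun:
    """Average behaviour of Egger and IVW under directional pleiotropy."""

    egger_slope_mean: float
    egger_intercept_mean: float
    ivw_mean: float
    predicted_ivw_bias: float    # analytic: sum(w E alpha) / sum(w E^2), averaged
    mean_pleiotropy: float
    theta: float


def egger_under_inside(
    n_reps: int = 200, n_snps: int = 50, theta: float = 0.5,
    pleiotropy_mean: float = 0.01, pleiotropy_sd: float = 0.005,
    invalid_fraction: float = 0.9, seed: int = 0,
) -> PleiotropyRun:
    """Directional pleiotropy with the InSIDE condition holding.

    The Egger slope should stay centred on theta and its intercept on the
    mean pleiotropic effect, while IVW shifts by the weighted mean of
    ``alpha_j / E_j`` — returned as the analytic prediction for comparison.
    """
    slopes, intercepts, ivws, predicted, alphas = [], [], [], [], []
    for s in _spawn(seed, n_reps):
        exposure, outcome, truth = simulate_two_sample(
            TwoSampleConfig(
                n_snps=n_snps, theta=theta, invalid_fraction=invalid_fraction,
                pleiotropy_mean=pleiotropy_mean, pleiotropy_sd=pleiotropy_sd,
                inside_violation=False, seed=s,
            )
        )
        hset = harmonise(exposure, outcome)
        res = mr_egger(hset)
        slopes.append(res.slope.beta)
        intercepts.append(res.intercept.beta)
        ivws.append(ivw(hset).beta)
        w = np.array([r.se_out ** -2 for r in hset.records])
        e = truth.exposure_effects
        predicted.append(float(np.sum(w * e * truth.pleiotropy) / np.sum(w * e ** 2)))
        alphas.append(float(truth.pleiotropy.mean()))
    return PleiotropyRun(
        egger_slope_mean=float(np.mean(slopes)),
        egger_intercept_mean=float(np.mean(intercepts)),
        ivw_mean=float(np.mean(ivws)),
        predicted_ivw_bias=float(np.mean(predicted)),
        mean_pleiotropy=float(np.mean(alphas)),
        theta=theta,
    )


def weighted_median_recovery(
    n_reps: int = 300, n_snps: int = 10, theta: float = 0.5,
    invalid_fraction: float = 0.4, pleiotropy_mean: float = 0.05,
    pleiotropy_sd: float = 0.01, seed: int = 0, n_boot: int = 200,
    n_exposure: int = 500_000, n_outcome: int = 2_000_000,
) -> float:
    """Mean weighted-median estimate with a given share of invalid weight.

    Below 50% invalid weight the estimator stays consistent for theta; at
    or above it, it breaks down. Consistency is asymptotic in per-ratio
    precision, so the default GWAS sizes are large: with one-sided
    pleiotropy the weighted median sits at an upper quantile of the valid
    ratios, displaced from theta by an amount proportional to their
    sampling spread.
    """
    betas = []
    for s in _spawn(seed, n_reps):
        exposure, outcome, _ = simulate_two_sample(
            TwoSampleConfig(
                n_snps=n_snps, theta=theta, invalid_fraction=invalid_fraction,
                pleiotropy_mean=pleiotropy_mean, pleiotropy_sd=pleiotropy_sd,
                n_exposure=n_exposure, n_outcome=n_outcome,
                seed=s,
            )
        )
        hset = harmonise(exposure, outcome)
        betas.append(weighted_median(hset, n_boot=n_boot, seed=s).beta)
    return float(np.mean(betas))


def maternal_fetal_correlation(
    n_pairs: int = 10_000, eaf: float = 0.3, seed: int = 0
) -> float:
    """Observed corr(maternal, fetal dosage) under Mendelian transmission."""
    panel, truth = simulate_mother_child(
        CohortSimConfig(n_pairs=n_pairs, eaf=(eaf,), seed=seed)
    )
    m = panel.data["m_" + truth.rsids[0]]
    f = panel.data["f_" + truth.rsids[0]]
    return float(np.corrcoef(m, f)[0, 1])


@dataclass
class FetalAdjustmentRun:
    adjusted_mean: float        # maternal beta after conditioning on fetal dosage
    unadjusted_mean: float      # marginal maternal beta (~ fetal_effect / 2)
    adjusted_mc_se: float
    fetal_effect: float


def fetal_adjustment_zeroing(
    n_reps: int = 100, n_pairs: int = 2000, fetal_effect: float = 40.0,
    seed: int = 0,
) -> FetalAdjustmentRun:
    """Pure fetal effect: conditioning on fetal genotype zeroes the maternal
    estimate, while the marginal estimate sits near half the fetal effect."""
    adjusted, unadjusted = [], []
    for s in _spawn(seed, n_reps):
        panel, truth = simulate_mother_child(
            CohortSimConfig(n_pairs=n_pairs, fetal_effect=fetal_effect, seed=s)
        )
        snp = truth.rsids[0]
        adjusted.append(conditional_maternal_association(panel, snp, []).beta)
        unadjusted.append(
            conditional_maternal_association(panel, snp, [], adjust_fetal=False).beta
        )
    return FetalAdjustmentRun(
        adjusted_mean=float(np.mean(adjusted)),
        unadjusted_mean=float(np.mean(unadjusted)),
        adjusted_mc_se=float(np.std(adjusted, ddof=1) / np.sqrt(len(adjusted))),
        fetal_effect=fetal_effect,
    )
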