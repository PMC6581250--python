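"""Two-sample MR estimators and heterogeneity diagnostics.

All estimators consume a :class:`~mrtri.summary_io.HarmonisedSet` whose
records carry, per instrument j, the effect on the exposure ``E_j`` (with SE)
and the effect on the outcome ``beta_out`` with SE ``sigma_j``.

Four estimators are provided, differing in which instrumental-variable
assumptions they need:

``wald-pool``
    per-SNP Wald ratios ``beta_out / beta_exp`` pooled by fixed-effect
    inverse-variance meta-analysis; assumes no unbalanced horizontal
    pleiotropy.
``ivw``
    weighted regression of outcome effects on exposure effects through the
    origin, weights ``sigma_j**-2``; the point estimate is algebraically
    identical to the pooled Wald ratio, the SE is the fixed-effect
    regression SE and CIs use a t reference with n-1 df.
``egger-slope``
    the same regression with a free intercept; the slope is a
    pleiotropy-robust causal estimate under the InSIDE assumption
    (instrument strength independent of direct effects), and a non-zero
    intercept is evidence of directional pleiotropy.
``weighted-median``
    the weighted 50th percentile of the per-SNP ratios; consistent when
    less than half the weight comes from invalid instruments. Its SE comes
    from a seeded parametric bootstrap.

The per-SNP ratio SE uses the first-order rule (outcome SE divided by the
exposure effect, exposure uncertainty ignored); a full delta-method variant
that propagates the exposure SE is available behind ``full_delta=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .exceptions import CollinearityError, DegenerateInstrumentError, ValidationError
from .summary_io import HarmonisedRecord, HarmonisedSet

Method = Literal["wald-pool", "ivw", "egger-slope", "weighted-median"]
CiPolicy = Literal["normal", "t"]


@dataclass(frozen=True)
class RatioEstimate:
    """A per-instrument causal-effect estimate (outcome units per exposure unit)."""

    id: str
    ratio: float
    se: float

    def __post_init__(self):
        if not self.se > 0:
            raise ValidationError(f"{self.id}: ratio SE must be > 0, got {self.se}")

    @property
    def weight(self) -> float:
        """Inverse-variance weight, exactly ``se**-2``."""
        return self.se ** -2


@dataclass(frozen=True)
class MrResult:
    """A causal-effect estimate with its uncertainty and provenance tag."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_instruments: int
    ci_df: float | None = None  # None -> normal reference
    level: float = 0.95
    label: str = ""
    units: str = ""

    def __post_init__(self):
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValidationError(
                f"{self.method}: CI ({self.ci_low}, {self.ci_high}) does not bracket beta {self.beta}"
            )


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger fit: pleiotropy-adjusted slope plus the intercept test."""

    slope: MrResult
    intercept: MrResult


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q and I-squared across per-instrument estimates."""

    q: float
    df: int
    i2: float
    per_unit: tuple[tuple[str, float], ...]
    degenerate: bool = False

    @property
    def pval(self) -> float:
        if self.df < 1:
            return 1.0
        return float(stats.chi2.sf(self.q, self.df))


@dataclass(frozen=True)
class LeaveOneOutRow:
    excluded_id: str
    result: MrResult | None
    infeasible_reason: str | None = None


@dataclass(frozen=True)
class LeaveOneOutResult:
    baseline: MrResult
    rows: tuple[LeaveOneOutRow, ...]


def _interval(beta: float, se: float, level: float, df: float | None):
    """Two-sided CI and p-value from a normal (df None) or t reference."""
    alpha = 1.0 - level
    if df is None:
        crit = stats.norm.ppf(1 - alpha / 2)
        p = 2 * stats.norm.sf(abs(beta) / se)
    else:
        crit = stats.t.ppf(1 - alpha / 2, df)
        p = 2 * stats.t.sf(abs(beta) / se, df)
    return beta - crit * se, beta + crit * se, float(p)


def wald_ratio(record: HarmonisedRecord, *, full_delta: bool = False) -> RatioEstimate:
    """Per-SNP causal estimate: outcome effect divided by exposure effect.

    SE is ``se_out / |beta_exp|`` by default; with ``full_delta=True`` the
    exposure effect's own uncertainty is propagated as well.
    """
    if record.beta_exp == 0:
        raise DegenerateInstrumentError(
            f"{record.rsid}: exposure effect is zero, Wald ratio undefined"
        )
    ratio = record.beta_out / record.beta_exp
    if full_delta:
        se = math.sqrt(
            record.se_out ** 2 / record.beta_exp ** 2
            + record.beta_out ** 2 * record.se_exp ** 2 / record.beta_exp ** 4
        )
    else:
        se = record.se_out / abs(record.beta_exp)
    return RatioEstimate(id=record.rsid, ratio=ratio, se=se)


def pool_fixed(
    estimates: Sequence[RatioEstimate],
    *,
    level: float = 0.95,
    ci: CiPolicy = "normal",
    method_tag: str = "wald-pool",
) -> MrResult:
    """Fixed-effect inverse-variance meta-analysis of per-unit ratios.

    ``beta = sum(w_j b_j) / sum(w_j)`` with ``w_j = se_j**-2`` and
    ``se = sum(w_j)**-0.5``. Order-invariant. CIs are normal by default
    (``ci='t'`` switches to a t reference with n-1 df).
    """
    if not estimates:
        raise ValidationError("cannot pool an empty list of estimates")
    w = np.array([e.weight for e in estimates], dtype=float)
    b = np.array([e.ratio for e in estimates], dtype=float)
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    df = len(estimates) - 1 if ci == "t" and len(estimates) > 1 else None
    lo, hi, p = _interval(beta, se, level, df)
    return MrResult(
        method=method_tag, beta=beta, se=se, ci_low=lo, ci_high=hi,
        pval=p, n_instruments=len(estimates), ci_df=df, level=level,
    )


def _design(hset: HarmonisedSet):
    E = np.array([r.beta_exp for r in hset.records], dtype=float)
    y = np.array([r.beta_out for r in hset.records], dtype=float)
    w = np.array([r.se_out ** -2 for r in hset.records], dtype=float)
    return E, y, w


def ivw(hset: HarmonisedSet, *, level: float = 0.95, ci: CiPolicy = "t") -> MrResult:
    """Inverse variance-weighted estimator: regression through the origin.

    ``beta = sum(E_j**2 sigma_j**-2 b_j) / sum(E_j**2 sigma_j**-2)`` where
    ``b_j`` is the per-SNP ratio — identical to the pooled Wald ratio. The
    SE is the fixed-effect one, ``(sum E_j**2 sigma_j**-2)**-0.5``, and the
    CI uses a t reference with n-1 df by default.
    """
    n = len(hset.records)
    if n < 2:
        raise ValidationError(f"IVW needs at least 2 instruments, got {n}")
    E, y, w = _design(hset)
    if np.any(E == 0):
        raise DegenerateInstrumentError("IVW: an instrument has zero exposure effect")
    sw = float(np.sum(w * E ** 2))
    beta = float(np.sum(w * E * y) / sw)
    se = sw ** -0.5
    df = n - 1 if ci == "t" else None
    lo, hi, p = _interval(beta, se, level, df)
    return MrResult(
        method="ivw", beta=beta, se=se, ci_low=lo, ci_high=hi, pval=p,
        n_instruments=n, ci_df=df, level=level,
        label=hset.exposure_label,
        units=f"{hset.outcome_unit} per {hset.exposure_unit}".strip(),
    )


def mr_egger(
    hset: HarmonisedSet,
    *,
    level: float = 0.95,
    se_method: Literal["fixed", "multiplicative"] = "fixed",
) -> EggerResult:
    """Weighted regression of outcome effects on exposure effects, free intercept.

    The slope estimates the causal effect under InSIDE; the intercept
    estimates the average directional pleiotropic effect. CIs use a t
    reference with n-2 df. With ``se_method='fixed'`` the covariance is
    ``(X'WX)**-1`` (residual variance forced to 1, matching the fixed-effect
    IVW convention); ``'multiplicative'`` scales it by the weighted mean
    squared residual.
    """
    n = len(hset.records)
    if n < 3:
        raise ValidationError(f"MR-Egger needs at least 3 instruments, got {n}")
    E, y, w = _design(hset)
    if np.ptp(E) == 0:
        raise CollinearityError("MR-Egger: no variation in exposure effects")
    X = np.column_stack([np.ones_like(E), E])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    cov = np.linalg.inv(xtwx)
    if se_method == "multiplicative":
        resid = y - X @ coef
        scale = float(np.sum(w * resid ** 2) / (n - 2))
        cov = cov * scale
    df = n - 2
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    lo_s, hi_s, p_s = _interval(float(coef[1]), se_slope, level, df)
    lo_i, hi_i, p_i = _interval(float(coef[0]), se_int, level, df)
    units = f"{hset.outcome_unit} per {hset.exposure_unit}".strip()
    slope = MrResult(
        method="egger-slope", beta=float(coef[1]), se=se_slope, ci_low=lo_s,
        ci_high=hi_s, pval=p_s, n_instruments=n, ci_df=df, level=level,
        label=hset.exposure_label, units=units,
    )
    intercept = MrResult(
        method="egger-intercept", beta=float(coef[0]), se=se_int, ci_low=lo_i,
        ci_high=hi_i, pval=p_i, n_instruments=n, ci_df=df, level=level,
        label=hset.exposure_label, units=hset.outcome_unit,
    )
    return EggerResult(slope=slope, intercept=intercept)


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> tuple[float, bool]:
    """Weighted 50th percentile of ratios by linear interpolation.

    Weights are normalised to sum 1; with cumulative weight ``S_j`` the j-th
    sorted ratio sits at percentile ``p_j = 100 (S_j - w_j / 2)`` and the
    estimate is the ratio interpolated at percentile 50. Returns the point
    estimate and a flag marking boundary clamping (percentile 50 outside
    [p_1, p_J], where the extreme ratio is returned).
    """
    order = np.argsort(ratios)
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    s = np.cumsum(w)
    p = 100.0 * (s - w / 2.0)
    if 50.0 < p[0]:
        return float(r[0]), True
    if 50.0 > p[-1]:
        return float(r[-1]), True
    return float(np.interp(50.0, p, r)), False


def weighted_median(
    hset: HarmonisedSet,
    n_boot: int = 1000,
    seed: int | None = None,
    *,
    level: float = 0.95,
    full_delta: bool = False,
) -> MrResult:
    """Weighted-median estimator with parametric-bootstrap SE.

    Robust to up to (but not including) 50% of the weight coming from
    invalid instruments. The SE resamples each per-SNP ratio from
    ``Normal(ratio_j, se_j)`` and takes the SD of the recomputed weighted
    medians over ``n_boot`` seeded draws.
    """
    n = len(hset.records)
    if n < 3:
        raise ValidationError(f"weighted median needs at least 3 instruments, got {n}")
    if n_boot < 2:
        raise ValidationError(f"n_boot must be at least 2, got {n_boot}")
    est = [wald_ratio(r, full_delta=full_delta) for r in hset.records]
    ratios = np.array([e.ratio for e in est])
    ses = np.array([e.se for e in est])
    weights = ses ** -2
    beta, _clamped = weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    draws = rng.normal(ratios, ses, size=(n_boot, n))
    boot = np.empty(n_boot)
    for i in range(n_boot):
        boot[i], _ = weighted_median_point(draws[i], weights)
    se = float(np.std(boot, ddof=1))
    lo, hi, p = _interval(beta, se, level, None)
    return MrResult(
        method="weighted-median", beta=beta, se=se, ci_low=lo, ci_high=hi,
        pval=p, n_instruments=n, ci_df=None, level=level,
        label=hset.exposure_label,
        units=f"{hset.outcome_unit} per {hset.exposure_unit}".strip(),
    )


def heterogeneity(
    estimates: Sequence[RatioEstimate], pooled: MrResult
) -> HeterogeneityResult:
    """Cochran's Q against the pooled estimate, with I-squared.

    ``Q = sum w_j (b_j - b_pool)**2``; ``I2 = max(0, (Q - df) / Q) * 100``.
    A single estimate yields Q = 0 with a degenerate flag.
    """
    if len(estimates) == 1:
        return HeterogeneityResult(
            q=0.0, df=0, i2=0.0,
            per_unit=((estimates[0].id, 0.0),), degenerate=True,
        )
    contribs = [(e.id, e.weight * (e.ratio - pooled.beta) ** 2) for e in estimates]
    q = float(sum(c for _, c in contribs))
    df = len(estimates) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, i2=i2, per_unit=tuple(contribs))


def estimate(hset: HarmonisedSet, method: Method, **settings) -> MrResult:
    """Dispatch to one of the four estimators by tag."""
    if method == "wald-pool":
        est = [wald_ratio(r, full_delta=settings.pop("full_delta", False))
               for r in hset.records]
        return pool_fixed(est, **settings)
    if method == "ivw":
        return ivw(hset, **settings)
    if method == "egger-slope":
        return mr_egger(hset, **settings).slope
    if method == "weighted-median":
        return weighted_median(hset, **settings)
    raise ValueError(f"unknown method {method!r}")


_MIN_N = {"wald-pool": 1, "ivw": 2, "egger-slope": 3, "weighted-median": 3}


def leave_one_out(
    hset: HarmonisedSet, method: Method = "ivw", **settings
) -> LeaveOneOutResult:
    """Re-estimate excluding each instrument in turn to find influential SNPs.

    A row whose exclusion makes the method infeasible (too few instruments)
    is flagged rather than silently skipped.
    """
    baseline = estimate(hset, method, **dict(settings))
    rows = []
    for rec in hset.records:
        remaining = replace_records(hset, [r for r in hset.records if r.rsid != rec.rsid])
        if len(remaining.records) < _MIN_N[method]:
            rows.append(LeaveOneOutRow(rec.rsid, None, "too few instruments after removal"))
            continue
        rows.append(LeaveOneOutRow(rec.rsid, estimate(remaining, method, **dict(settings))))
    return LeaveOneOutResult(baseline=baseline, rows=tuple(rows))


def replace_records(hset: HarmonisedSet, records: list[HarmonisedRecord]) -> HarmonisedSet:
    return HarmonisedSet(
        records=records,
        exposure_label=hset.exposure_label,
        outcome_label=hset.outcome_label,
        exposure_unit=hset.exposure_unit,
        outcome_unit=hset.outcome_unit,
        dropped=list(hset.dropped),
    )
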