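"""Instrumental-variable analysis applied to supplementation trials.

Randomisation to supplement versus control is itself a valid instrument for
the biomarker it shifts: the per-trial Wald ratio is the arm difference in
birth weight divided by the arm difference in the biomarker (circulating
25(OH)D in nmol/l, or calcium in mg/dl). Per-trial ratios are pooled with
exactly the same fixed-effect machinery as the genetic instruments
(:func:`mrtri.estimators.pool_fixed`, :func:`mrtri.estimators.heterogeneity`,
:func:`mrtri.estimators.leave_one_out` on ratio lists), so the two evidence
streams share one implementation of pooling and diagnostics.

Arm-difference SEs are derived from reported 95% CIs as
``(hi - lo) / (2 * z)``; trials that published a range rather than a CI are
carried with a ``range_as_ci`` flag. Risk-of-bias indicators
(intention-to-treat, loss to follow-up) are inert metadata usable for
subgrouping; no quantitative bias adjustment is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .estimators import RatioEstimate
from .exceptions import DegenerateInstrumentError, SchemaError, ValidationError


@dataclass(frozen=True)
class RctRecord:
    """One trial's arm-level contrasts: biomarker shift and birth-weight shift."""

    trial_id: str
    n_randomised: int
    exposure_diff: float          # treatment - control, biomarker units
    exposure_ci: tuple[float, float]
    outcome_diff: float           # treatment - control, grams
    outcome_ci: tuple[float, float]
    se_exposure: float
    se_outcome: float
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, point, (lo, hi) in (
            ("exposure", self.exposure_diff, self.exposure_ci),
            ("outcome", self.outcome_diff, self.outcome_ci),
        ):
            if not (lo <= point <= hi):
                raise ValidationError(
                    f"{self.trial_id}: {name} CI ({lo}, {hi}) does not bracket {point}"
                )
        if not (self.se_exposure > 0 and self.se_outcome > 0):
            raise ValidationError(f"{self.trial_id}: derived SEs must be > 0")


_REQUIRED = [
    "trial_id", "n_randomised",
    "exposure_diff", "exposure_ci_low", "exposure_ci_high",
    "outcome_diff", "outcome_ci_low", "outcome_ci_high",
]
_FLAGS = ["intention_to_treat", "loss_to_followup_pct", "range_as_ci"]


def se_from_ci(lo: float, hi: float, ci_level: float = 0.95) -> float:
    """Normal-theory SE from a two-sided CI: ``(hi - lo) / (2 z)``."""
    if hi <= lo:
        raise ValidationError(f"inverted CI bounds ({lo}, {hi})")
    z = stats.norm.ppf(1 - (1 - ci_level) / 2)
    return (hi - lo) / (2 * z)


def parse_rct_record(raw: Mapping, ci_level: float = 0.95) -> RctRecord:
    """Build an RctRecord from one raw trial-summary row.

    ``raw`` maps the canonical column names (``trial_id``, ``n_randomised``,
    ``exposure_diff`` with ``exposure_ci_low``/``_high``, likewise
    ``outcome_*``) to values; flag columns are carried through as metadata.
    """
    missing = [c for c in _REQUIRED if c not in raw or pd.isna(raw[c])]
    if missing:
        raise ValidationError(f"trial row rejected, missing field(s): {missing}")
    exp_ci = (float(raw["exposure_ci_low"]), float(raw["exposure_ci_high"]))
    out_ci = (float(raw["outcome_ci_low"]), float(raw["outcome_ci_high"]))
    return RctRecord(
        trial_id=str(raw["trial_id"]),
        n_randomised=int(raw["n_randomised"]),
        exposure_diff=float(raw["exposure_diff"]),
        exposure_ci=exp_ci,
        outcome_diff=float(raw["outcome_diff"]),
        outcome_ci=out_ci,
        se_exposure=se_from_ci(*exp_ci, ci_level),
        se_outcome=se_from_ci(*out_ci, ci_level),
        flags={k: raw[k] for k in _FLAGS if k in raw and not pd.isna(raw[k])},
    )


def read_rct_records(path: str | Path, ci_level: float = 0.95) -> list[RctRecord]:
    """Read a TSV of trial summaries (one row per trial) into RctRecords."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep)
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(f"trial table missing column(s): {missing}")
    return [parse_rct_record(row, ci_level) for row in frame.to_dict("records")]


def write_rct_records(records: Sequence[RctRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "trial_id": r.trial_id,
            "n_randomised": r.n_randomised,
            "exposure_diff": r.exposure_diff,
            "exposure_ci_low": r.exposure_ci[0],
            "exposure_ci_high": r.exposure_ci[1],
            "outcome_diff": r.outcome_diff,
            "outcome_ci_low": r.outcome_ci[0],
            "outcome_ci_high": r.outcome_ci[1],
        }
        row.update({k: r.flags[k] for k in _FLAGS if k in r.flags})
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def rct_ratio(record: RctRecord, *, full_delta: bool = False) -> RatioEstimate:
    """Per-trial Wald ratio: birth-weight difference over biomarker difference.

    First-order SE (outcome SE over |exposure difference|) by default, for
    symmetry with the genetic Wald ratio; ``full_delta=True`` also
    propagates the exposure-difference uncertainty.
    """
    if record.exposure_diff == 0:
        raise DegenerateInstrumentError(
            f"{record.trial_id}: zero biomarker difference, trial ratio undefined"
        )
    ratio = record.outcome_diff / record.exposure_diff
    if full_delta:
        se = (
            record.se_outcome ** 2 / record.exposure_diff ** 2
            + record.outcome_diff ** 2 * record.se_exposure ** 2 / record.exposure_diff ** 4
        ) ** 0.5
    else:
        se = record.se_outcome / abs(record.exposure_diff)
    return RatioEstimate(id=record.trial_id, ratio=ratio, se=se)
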