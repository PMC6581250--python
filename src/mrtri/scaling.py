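"""Unit transforms placing MR and trial estimates on a common reporting scale.

The analyses report effects on birth weight in grams, per a 10% increase in
circulating 25(OH)D and per 1 SD increase in circulating calcium. Getting
there requires a handful of multiplicative transforms, each captured as an
auditable :class:`ScaleSpec` rather than a constant buried in code:

``percent-of-reference``
    factor = reference * pct / 100 — e.g. a 10% rise from a gestational
    median of 61.8 nmol/l is 6.18 nmol/l (6.2 at one decimal), which is the
    factor that converts trial ratios in grams per nmol/l to grams per 10%.
``range-to-sd``
    factor = (hi - lo) / 4 — the usual reference-range-to-SD rule; the
    healthy calcium range 8.5-10.5 mg/dl gives an SD of 0.5 mg/dl.
``ln-relative``
    factor = ln(1 + pct/100) — converts effects per natural-log unit of the
    biomarker to effects per relative increase (10% -> ln(1.1)).
``sd-to-unit``
    factor = the supplied SD in target units — e.g. birth weight SD 476 g
    converts effects in SD units back to grams.
``absolute``
    an arbitrary supplied factor (e.g. pounds to kilograms, 0.454).

Rescaling multiplies the point estimate, SE and both CI bounds by the
factor; p-values (and hence z-scores) are invariant. Specs compose:
applying two in sequence equals one spec with the product factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

from .estimators import MrResult, RatioEstimate
from .exceptions import UnitMismatchError, ValidationError

Mode = Literal["percent-of-reference", "range-to-sd", "ln-relative", "sd-to-unit", "absolute"]


@dataclass(frozen=True)
class ScaleSpec:
    mode: Mode
    factor: float
    unit_in: str = ""
    unit_out: str = ""
    provenance: str = ""

    def __post_init__(self):
        if not self.factor > 0:
            raise ValidationError(f"scale factor must be > 0, got {self.factor}")

    def compose(self, other: "ScaleSpec") -> "ScaleSpec":
        """Spec applying ``self`` then ``other`` (factors multiply)."""
        if self.unit_out and other.unit_in and self.unit_out != other.unit_in:
            raise UnitMismatchError(
                f"cannot compose: {self.unit_out!r} != {other.unit_in!r}"
            )
        return ScaleSpec(
            mode="absolute",
            factor=self.factor * other.factor,
            unit_in=self.unit_in,
            unit_out=other.unit_out,
            provenance=f"({self.provenance}) then ({other.provenance})",
        )


def make_scale_spec(mode: Mode, *, unit_in: str = "", unit_out: str = "",
                    provenance: str = "", **params) -> ScaleSpec:
    """Construct a ScaleSpec, computing the factor from mode-specific params.

    percent-of-reference: ``reference``, ``pct`` -> reference * pct / 100
    range-to-sd:          ``lo``, ``hi``        -> (hi - lo) / 4
    ln-relative:          ``pct``               -> ln(1 + pct/100)
    sd-to-unit:           ``sd``                -> sd
    absolute:             ``factor``            -> factor
    """
    if mode == "percent-of-reference":
        reference, pct = float(params["reference"]), float(params["pct"])
        if pct <= -100:
            raise ValidationError(f"pct must exceed -100, got {pct}")
        factor = reference * pct / 100.0
    elif mode == "range-to-sd":
        lo, hi = float(params["lo"]), float(params["hi"])
        if hi <= lo:
            raise ValidationError(f"range-to-sd requires hi > lo, got ({lo}, {hi})")
        factor = (hi - lo) / 4.0
    elif mode == "ln-relative":
        pct = float(params["pct"])
        if pct <= -100:
            raise ValidationError(f"pct must exceed -100, got {pct}")
        factor = math.log1p(pct / 100.0)
    elif mode == "sd-to-unit":
        factor = float(params["sd"])
    elif mode == "absolute":
        factor = float(params["factor"])
    else:
        raise ValueError(f"unknown scale mode {mode!r}")
    return ScaleSpec(mode=mode, factor=factor, unit_in=unit_in,
                     unit_out=unit_out, provenance=provenance)


def rescale_effect(estimate, spec: ScaleSpec, *, check_units: bool = True):
    """Multiply an estimate's beta/SE/CI by the spec factor, relabelling units.

    Works on :class:`MrResult` (CI bounds included) and
    :class:`RatioEstimate`. The p-value is untouched — rescaling is exactly
    linear, so the z-score beta/se is invariant.
    """
    f = spec.factor
    if isinstance(estimate, MrResult):
        if check_units and spec.unit_in and estimate.units and spec.unit_in not in estimate.units:
            raise UnitMismatchError(
                f"spec expects {spec.unit_in!r} but estimate is in {estimate.units!r}"
            )
        return replace(
            estimate,
            beta=estimate.beta * f,
            se=estimate.se * f,
            ci_low=estimate.ci_low * f,
            ci_high=estimate.ci_high * f,
            units=spec.unit_out or estimate.units,
        )
    if isinstance(estimate, RatioEstimate):
        return RatioEstimate(id=estimate.id, ratio=estimate.ratio * f, se=estimate.se * f)
    raise TypeError(f"cannot rescale {type(estimate).__name__}")
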