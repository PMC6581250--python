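"""Reading, validation and harmonisation of GWAS summary statistics.

Two-sample mendelian randomisation combines per-SNP effect estimates on an
exposure (here maternal circulating 25(OH)D or calcium) with per-SNP effects
on an outcome (offspring birth weight) taken from a different sample. Before
any estimator runs, the two summary tables must be *harmonised*: every effect
re-expressed per copy of the exposure-raising allele, on a common strand.

The harmonisation rules implemented here are the field-standard ones:

* exact allele match -> keep as is;
* effect/other alleles swapped -> flip the outcome beta's sign and complement
  its allele frequency;
* alleles reported on the opposite strand -> complement, then apply the two
  rules above;
* palindromic SNPs (A/T or C/G), where strand cannot be resolved from the
  alleles, are either dropped or strand-inferred from the effect-allele
  frequencies, with an ambiguity band around 0.5 inside which inference is
  refused;
* finally, any SNP whose exposure beta is negative has both alleles swapped
  (betas sign-flipped, frequency complemented) so that ``beta_exp >= 0``
  always holds — effects are "per exposure-raising allele".

Anything that cannot be resolved is routed to the ``dropped`` list with a
reason, never silently kept or discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .exceptions import (
    HarmonisationError,
    RowParseError,
    SchemaError,
    ValidationError,
)

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default effect-allele-frequency band inside which a palindromic SNP's
#: strand cannot be inferred (both frequencies too close to 0.5)
DEFAULT_AMBIGUITY_BAND = (0.42, 0.58)

PalindromePolicy = Literal["drop", "infer-by-eaf"]


@dataclass(frozen=True)
class SnpSummary:
    """One SNP's association with one trait from a GWAS summary table.

    ``beta`` is the per-allele effect in the trait's units (natural-log
    nmol/l for 25(OH)D, SD units for calcium, SD or grams for birth weight);
    ``se`` its standard error; ``eaf`` the effect-allele frequency when
    reported.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pval: float | None = None
    n: float | None = None
    trait: str = ""
    unit: str = ""

    def __post_init__(self):
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.rsid}: effect allele {self.effect_allele!r} not one of A/C/G/T"
            )
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.rsid}: other allele {self.other_allele!r} not one of A/C/G/T"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: effect and other allele are identical")
        if not self.se > 0:
            raise ValidationError(f"{self.rsid}: standard error must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValidationError(f"{self.rsid}: eaf must be in (0, 1), got {self.eaf}")
        if self.pval is not None and not (0.0 < self.pval <= 1.0):
            raise ValidationError(f"{self.rsid}: p-value must be in (0, 1], got {self.pval}")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G SNPs, whose strand is ambiguous."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele

    def flipped(self) -> "SnpSummary":
        """Return the same association expressed for the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )

    def complemented(self) -> "SnpSummary":
        """Return the same association expressed on the opposite strand."""
        return replace(
            self,
            effect_allele=_COMPLEMENT[self.effect_allele],
            other_allele=_COMPLEMENT[self.other_allele],
        )


@dataclass(frozen=True)
class HarmonisedRecord:
    """Aligned exposure/outcome effect pair for one instrument.

    ``beta_exp`` >= 0 by construction (oriented to the raising allele).
    """

    rsid: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf: float | None = None
    effect_allele: str = ""
    other_allele: str = ""


@dataclass
class HarmonisedSet:
    """A harmonised instrument set ready for the MR estimators."""

    records: list[HarmonisedRecord]
    exposure_label: str = ""
    outcome_label: str = ""
    exposure_unit: str = ""
    outcome_unit: str = ""
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rsid": r.rsid,
                    "effect_allele": r.effect_allele,
                    "other_allele": r.other_allele,
                    "beta_exp": r.beta_exp,
                    "se_exp": r.se_exp,
                    "beta_out": r.beta_out,
                    "se_out": r.se_out,
                    "eaf": r.eaf,
                }
                for r in self.records
            ]
        )

    def subset(self, rsids: Iterable[str]) -> "HarmonisedSet":
        """Restrict to the given instruments (e.g. synthesis vs metabolism SNPs)."""
        keep = set(rsids)
        missing = keep - {r.rsid for r in self.records}
        if missing:
            raise KeyError(f"rsids not in harmonised set: {sorted(missing)}")
        return HarmonisedSet(
            records=[r for r in self.records if r.rsid in keep],
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
            exposure_unit=self.exposure_unit,
            outcome_unit=self.outcome_unit,
            dropped=list(self.dropped),
        )

    def write(self, path: str | Path) -> None:
        """Serialise to TSV plus a sibling dropped-SNP log."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        log = path.with_suffix(path.suffix + ".dropped.tsv")
        pd.DataFrame(self.dropped, columns=["rsid", "reason"]).to_csv(
            log, sep="\t", index=False
        )


#: canonical field order for summary tables written by this package
_FIELDS = ["rsid", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]
_NUMERIC_FIELDS = {"eaf", "beta", "se", "pval", "n"}
_OPTIONAL_FIELDS = {"eaf", "pval", "n"}


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_snp_summaries(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    *,
    delimiter: str | None = None,
    trait: str = "",
    unit: str = "",
) -> list[SnpSummary]:
    """Read a delimited summary-statistics table into ``SnpSummary`` records.

    Parameters
    ----------
    path
        TSV or CSV file with a header row. The delimiter follows the file
        extension (``.csv`` -> comma, otherwise tab) unless overridden.
    column_map
        Mapping from ``SnpSummary`` field name to the column name in the
        file. Mapping is explicit — no header sniffing — so ingestion is
        deterministic across dialects. Defaults to the identity mapping for
        the canonical field names.
    trait, unit
        Labels stamped on every record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    column_map = dict(column_map) if column_map else {f: f for f in _FIELDS}

    frame = pd.read_csv(path, sep=_delimiter_for(path, delimiter), dtype=str)
    for fieldname, column in column_map.items():
        if fieldname in _OPTIONAL_FIELDS:
            continue
        if column not in frame.columns:
            raise SchemaError(f"mapped column {column!r} (field {fieldname!r}) not in header")

    out: list[SnpSummary] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # header is line 1
        values: dict[str, object] = {}
        row_map = dict(zip(frame.columns, row))
        for fieldname, column in column_map.items():
            raw = row_map.get(column)
            if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
                if fieldname in _OPTIONAL_FIELDS:
                    values[fieldname] = None
                    continue
                raise RowParseError(f"missing value for {fieldname!r}", line=i)
            raw = str(raw).strip()
            if fieldname in _NUMERIC_FIELDS:
                try:
                    values[fieldname] = float(raw)
                except ValueError:
                    raise RowParseError(
                        f"unparseable numeric {raw!r} for {fieldname!r}", line=i
                    ) from None
            else:
                values[fieldname] = raw
        values["effect_allele"] = str(values["effect_allele"]).upper()
        values["other_allele"] = str(values["other_allele"]).upper()
        out.append(SnpSummary(trait=trait, unit=unit, **values))  # type: ignore[arg-type]
    return out


def write_snp_summaries(records: Sequence[SnpSummary], path: str | Path,
                        *, delimiter: str | None = None) -> None:
    """Write records to a delimited file that :func:`read_snp_summaries` round-trips."""
    path = Path(path)
    frame = pd.DataFrame(
        [{f: getattr(r, f) for f in _FIELDS} for r in records], columns=_FIELDS
    )
    frame.to_csv(path, sep=_delimiter_for(path, delimiter), index=False)


def _check_unique(records: Sequence[SnpSummary], which: str) -> dict[str, SnpSummary]:
    index: dict[str, SnpSummary] = {}
    for r in records:
        if r.rsid in index:
            raise HarmonisationError(f"duplicate rsid {r.rsid!r} in {which} list")
        index[r.rsid] = r
    return index


def _align_outcome(
    exp: SnpSummary,
    out: SnpSummary,
    policy: PalindromePolicy,
    band: tuple[float, float],
) -> tuple[SnpSummary | None, str | None]:
    """Re-express the outcome association on the exposure's allele pair.

    Returns ``(aligned_outcome, None)`` or ``(None, drop_reason)``.
    """
    pair = (exp.effect_allele, exp.other_allele)

    if exp.is_palindromic:
        if not out.is_palindromic or {out.effect_allele, out.other_allele} != set(pair):
            return None, "allele mismatch"
        if policy == "drop":
            return None, "palindromic"
        if exp.eaf is None or out.eaf is None:
            return None, "palindromic with missing eaf"
        lo, hi = band
        if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
            return None, "ambiguous palindrome"
        # orient labels first, then use frequency agreement to infer strand
        if (out.effect_allele, out.other_allele) != pair:
            out = out.flipped()
        same_side = (exp.eaf - 0.5) * (out.eaf - 0.5) > 0
        return (out if same_side else out.flipped()), None

    for candidate in (out, out.complemented()):
        if (candidate.effect_allele, candidate.other_allele) == pair:
            return candidate, None
        if (candidate.other_allele, candidate.effect_allele) == pair:
            return candidate.flipped(), None
    return None, "allele mismatch"


def harmonise(
    exposure: Sequence[SnpSummary],
    outcome: Sequence[SnpSummary],
    palindrome_policy: PalindromePolicy = "drop",
    *,
    ambiguity_band: tuple[float, float] = DEFAULT_AMBIGUITY_BAND,
) -> HarmonisedSet:
    """Align exposure and outcome summaries to the exposure-raising alleles.

    Only SNPs present in both lists are considered; every such SNP lands in
    either ``records`` or ``dropped`` (with a reason), so the two partition
    the rsid intersection. The operation is idempotent: harmonising an
    already harmonised pair changes nothing.
    """
    if not exposure or not outcome:
        raise HarmonisationError("exposure and outcome lists must both be non-empty")
    exp_index = _check_unique(exposure, "exposure")
    out_index = _check_unique(outcome, "outcome")

    shared = [r.rsid for r in exposure if r.rsid in out_index]
    if not shared:
        raise HarmonisationError("no rsids shared between exposure and outcome")

    records: list[HarmonisedRecord] = []
    dropped: list[tuple[str, str]] = []
    for rsid in shared:
        exp, out = exp_index[rsid], out_index[rsid]
        # orient the exposure to its raising allele first
        if exp.beta < 0:
            exp = exp.flipped()
        aligned, reason = _align_outcome(exp, out, palindrome_policy, ambiguity_band)
        if aligned is None:
            dropped.append((rsid, reason or "unresolved"))
            continue
        records.append(
            HarmonisedRecord(
                rsid=rsid,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=aligned.beta,
                se_out=aligned.se,
                eaf=exp.eaf,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
            )
        )

    first_exp, first_out = exposure[0], outcome[0]
    return HarmonisedSet(
        records=records,
        dropped=dropped,
        exposure_label=first_exp.trait,
        outcome_label=first_out.trait,
        exposure_unit=first_exp.unit,
        outcome_unit=first_out.unit,
    )


def harmonised_to_summaries(hset: HarmonisedSet) -> tuple[list[SnpSummary], list[SnpSummary]]:
    """Re-express a HarmonisedSet as (exposure, outcome) summary lists.

    Useful for checking idempotence and for writing harmonised data back out
    in the ingestion schema.
    """
    exposure = [
        SnpSummary(
            rsid=r.rsid,
            effect_allele=r.effect_allele or "A",
            other_allele=r.other_allele or "G",
            beta=r.beta_exp,
            se=r.se_exp,
            eaf=r.eaf,
            trait=hset.exposure_label,
            unit=hset.exposure_unit,
        )
        for r in hset.records
    ]
    outcome = [
        SnpSummary(
            rsid=r.rsid,
            effect_allele=r.effect_allele or "A",
            other_allele=r.other_allele or "G",
            beta=r.beta_out,
            se=r.se_out,
            eaf=r.eaf,
            trait=hset.outcome_label,
            unit=hset.outcome_unit,
        )
        for r in hset.records
    ]
    return exposure, outcome
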