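"""End-to-end orchestration: MR arm, RCT arm, triangulation report.

A run is described by a :class:`RunConfig` (loadable from a YAML file) that
names the input tables, the estimator settings, the unit-scaling specs and
the analyses to execute. All numeric scaling constants enter through the
configuration with provenance strings — none are buried in code. Outputs
are tidy TSVs plus a plain-text log of input digests and settings; a rerun
with the same configuration and seeds is byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import estimators as est
from . import rct as rct_mod
from . import summary_io
from .exceptions import ConfigError
from .scaling import ScaleSpec, make_scale_spec, rescale_effect

KNOWN_ANALYSES = (
    "wald-pool", "ivw", "egger", "weighted-median", "heterogeneity", "leave-one-out",
)

RESULT_COLUMNS = [
    "method", "exposure", "outcome", "n_units", "beta", "se",
    "ci_low", "ci_high", "pval", "q", "i2", "units", "subset",
]


@dataclass
class RunConfig:
    exposure_path: str
    outcome_path: str
    out_dir: str
    exposure_label: str = "exposure"
    outcome_label: str = "birth_weight"
    exposure_unit: str = ""
    outcome_unit: str = ""
    exposure_columns: dict | None = None
    outcome_columns: dict | None = None
    analyses: list[str] = dc_field(default_factory=lambda: ["wald-pool", "ivw"])
    palindrome_policy: str = "drop"
    ci_policy_pool: str = "normal"
    n_boot: int = 1000
    seed: int | None = None
    loo_method: str = "ivw"
    scale: dict | None = None          # make_scale_spec kwargs incl. mode
    subsets: dict[str, list[str]] = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for p in (self.exposure_path, self.outcome_path):
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        unknown = set(self.analyses) - set(KNOWN_ANALYSES)
        if unknown:
            raise ConfigError(f"unknown analyses: {sorted(unknown)}")
        if "weighted-median" in self.analyses and self.seed is None:
            raise ConfigError("weighted-median requires an explicit seed in pipeline runs")


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def result_row(r: est.MrResult, *, exposure: str, outcome: str, units: str = "",
               q: float | None = None, i2: float | None = None,
               subset: str = "all") -> dict:
    return {
        "method": r.method, "exposure": exposure, "outcome": outcome,
        "n_units": r.n_instruments, "beta": r.beta, "se": r.se,
        "ci_low": r.ci_low, "ci_high": r.ci_high, "pval": r.pval,
        "q": q, "i2": i2, "units": units or r.units, "subset": subset,
    }


def _min_snps(analysis: str, loo_method: str) -> int:
    need = {"wald-pool": 1, "ivw": 2, "egger": 3, "weighted-median": 3,
            "heterogeneity": 1}
    if analysis == "leave-one-out":
        return est._MIN_N[loo_method] + 1
    return need[analysis]


def _run_estimators_on(
    hset: summary_io.HarmonisedSet, config: RunConfig, subset_name: str,
    spec: ScaleSpec | None,
) -> tuple[list[dict], pd.DataFrame | None]:
    """All requested analyses on one instrument set; returns result rows + LOO table."""
    rows: list[dict] = []
    het = None
    ratios = [est.wald_ratio(r) for r in hset.records]
    if "heterogeneity" in config.analyses or "wald-pool" in config.analyses:
        pooled = est.pool_fixed(ratios, ci=config.ci_policy_pool)
        het = est.heterogeneity(ratios, pooled)

    def add(r: est.MrResult, rescale: bool = True):
        # the Egger intercept is in outcome units, not per exposure unit,
        # so the exposure-scale spec must not touch it
        if spec is not None and rescale:
            r = rescale_effect(r, spec, check_units=False)
        rows.append(
            result_row(
                r, exposure=config.exposure_label, outcome=config.outcome_label,
                q=het.q if het else None, i2=het.i2 if het else None,
                subset=subset_name,
            )
        )

    for analysis in config.analyses:
        if analysis == "wald-pool":
            add(est.pool_fixed(ratios, ci=config.ci_policy_pool))
        elif analysis == "ivw":
            add(est.ivw(hset))
        elif analysis == "egger":
            egger = est.mr_egger(hset)
            add(egger.slope)
            add(egger.intercept, rescale=False)
        elif analysis == "weighted-median":
            add(est.weighted_median(hset, n_boot=config.n_boot, seed=config.seed))

    loo_frame = None
    if "leave-one-out" in config.analyses:
        loo = est.leave_one_out(hset, method=config.loo_method, )
        loo_rows = []
        for row in loo.rows:
            r = row.result
            if r is not None and spec is not None:
                r = rescale_effect(r, spec, check_units=False)
            loo_rows.append(
                {
                    "excluded": row.excluded_id,
                    "subset": subset_name,
                    "beta": r.beta if r else None,
                    "se": r.se if r else None,
                    "ci_low": r.ci_low if r else None,
                    "ci_high": r.ci_high if r else None,
                    "pval": r.pval if r else None,
                    "note": row.infeasible_reason or "",
                }
            )
        loo_frame = pd.DataFrame(loo_rows)
    return rows, loo_frame


def run_mr_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Harmonise, estimate, and write tidy result tables.

    Pre-flight validation covers every requested analysis before anything
    is written; on a stage failure, partial outputs are removed.
    """
    config.validate()
    exposure = summary_io.read_snp_summaries(
        config.exposure_path, config.exposure_columns,
        trait=config.exposure_label, unit=config.exposure_unit,
    )
    outcome = summary_io.read_snp_summaries(
        config.outcome_path, config.outcome_columns,
        trait=config.outcome_label, unit=config.outcome_unit,
    )
    hset = summary_io.harmonise(exposure, outcome, config.palindrome_policy)  # type: ignore[arg-type]

    sets: dict[str, summary_io.HarmonisedSet] = {"all": hset}
    for name, rsids in config.subsets.items():
        sets[name] = hset.subset(rsids)
    for name, s in sets.items():
        for analysis in config.analyses:
            need = _min_snps(analysis, config.loo_method)
            if len(s.records) < need:
                raise ConfigError(
                    f"analysis {analysis!r} needs >= {need} instruments but "
                    f"subset {name!r} has {len(s.records)}"
                )

    spec = None
    if config.scale:
        params = dict(config.scale)
        spec = make_scale_spec(params.pop("mode"), **params)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        all_rows: list[dict] = []
        loo_frames: list[pd.DataFrame] = []
        for name, s in sets.items():
            rows, loo = _run_estimators_on(s, config, name, spec)
            all_rows.extend(rows)
            if loo is not None:
                loo_frames.append(loo)

        results = pd.DataFrame(all_rows, columns=RESULT_COLUMNS)
        path = out_dir / "mr_results.tsv"
        results.to_csv(path, sep="\t", index=False)
        written.append(path)

        hpath = out_dir / "harmonised.tsv"
        hset.write(hpath)
        written.extend([hpath, hpath.with_suffix(hpath.suffix + ".dropped.tsv")])

        out: dict[str, pd.DataFrame] = {"results": results}
        if loo_frames:
            loo_all = pd.concat(loo_frames, ignore_index=True)
            lpath = out_dir / "leave_one_out.tsv"
            loo_all.to_csv(lpath, sep="\t", index=False)
            written.append(lpath)
            out["leave_one_out"] = loo_all

        log = out_dir / "run_log.txt"
        settings = {k: v for k, v in asdict(config).items()}
        lines = [
            "mrtri MR analysis run",
            f"exposure_digest_sha256_16: {_digest(config.exposure_path)}",
            f"outcome_digest_sha256_16: {_digest(config.outcome_path)}",
            f"n_harmonised: {len(hset.records)}",
            f"n_dropped: {len(hset.dropped)}",
            "settings:",
        ] + [f"  {k}: {settings[k]}" for k in sorted(settings)]
        if spec is not None:
            lines.append(f"scale: factor={spec.factor!r} provenance={spec.provenance!r}")
        log.write_text("\n".join(lines) + "\n")
        written.append(log)
        return out
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def run_rct_analysis(
    records: Sequence[rct_mod.RctRecord],
    *,
    exposure_label: str,
    scale: ScaleSpec | None = None,
    ci_policy: str = "normal",
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-trial Wald ratios, fixed-effect pool, heterogeneity, leave-one-out.

    Reuses the same pooling/Q/I2 code paths as the genetic analysis.
    """
    ratios = [rct_mod.rct_ratio(r) for r in records]
    pooled = est.pool_fixed(ratios, ci=ci_policy, method_tag="rct-iv")
    het = est.heterogeneity(ratios, pooled)
    if scale is not None:
        pooled_scaled = rescale_effect(pooled, scale, check_units=False)
        ratios_scaled = [rescale_effect(r, scale, check_units=False) for r in ratios]
    else:
        pooled_scaled, ratios_scaled = pooled, ratios

    per_trial = pd.DataFrame(
        [
            {
                "trial_id": r.id, "ratio": r.ratio, "se": r.se,
                "q_contribution": dict(het.per_unit).get(r0.id),
            }
            for r, r0 in zip(ratios_scaled, ratios)
        ]
    )
    pooled_frame = pd.DataFrame(
        [
            result_row(
                pooled_scaled, exposure=exposure_label, outcome="birth_weight",
                units=scale.unit_out if scale else "", q=het.q, i2=het.i2,
            )
        ],
        columns=RESULT_COLUMNS,
    )
    out = {"per_trial": per_trial, "pooled": pooled_frame}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        per_trial.to_csv(out_dir / "rct_per_trial.tsv", sep="\t", index=False)
        pooled_frame.to_csv(out_dir / "rct_pooled.tsv", sep="\t", index=False)
    return out


def run_triangulation(
    mr_results: pd.DataFrame, rct_results: pd.DataFrame
) -> pd.DataFrame:
    """Merge MR and RCT-IV estimates into a forest-style triangulation table.

    Both inputs use the tidy result schema and must already be on the
    common reporting scale. For every exposure, any pair of evidence
    streams whose CIs are disjoint gets a discordance flag — the signature
    of bias in at least one stream.
    """
    frames = []
    for stream, frame in (("MR", mr_results), ("RCT-IV", rct_results)):
        if frame is None or frame.empty:
            continue
        f = frame.copy()
        f.insert(0, "stream", stream)
        frames.append(f)
    if not frames:
        raise ConfigError("triangulation needs at least one result stream")
    merged = pd.concat(frames, ignore_index=True)

    units_by_exposure = merged.groupby("exposure")["units"].nunique()
    mixed = units_by_exposure[units_by_exposure > 1]
    if not mixed.empty:
        raise ConfigError(
            f"unit mismatch after rescaling for exposure(s): {list(mixed.index)}"
        )

    flags = []
    for _, row in merged.iterrows():
        others = merged[(merged["exposure"] == row["exposure"])
                        & (merged["stream"] != row["stream"])]
        disjoint = [
            o["stream"]
            for _, o in others.iterrows()
            if o["ci_low"] > row["ci_high"] or o["ci_high"] < row["ci_low"]
        ]
        flags.append(";".join(sorted(set(disjoint))))
    merged["discordant_with"] = flags
    return merged
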