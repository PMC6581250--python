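"""Bundled reference data.

``vitd_instruments.tsv`` carries the published discovery-GWAS associations
of the seven circulating-25(OH)D instruments (per-allele effects in natural
log nmol/l with 95% CIs, effect-allele frequencies and sample sizes, as
reported by the source GWAS); the standard errors were back-derived from
the printed CIs as ``(hi - lo) / (2 * 1.96)``. These are the
instrument-exposure inputs of the vitamin D analysis and double as a
real-data fixture for ingestion and scaling.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .summary_io import SnpSummary, read_snp_summaries


def _data_path(name: str):
    return resources.files("mrtri.data").joinpath(name)


def vitd_instruments_frame() -> pd.DataFrame:
    """The bundled 25(OH)D instrument table as a DataFrame."""
    with resources.as_file(_data_path("vitd_instruments.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def vitd_instruments() -> list[SnpSummary]:
    """The bundled 25(OH)D instrument-exposure associations as SnpSummary records."""
    with resources.as_file(_data_path("vitd_instruments.tsv")) as p:
        return read_snp_summaries(
            p, trait="25(OH)D", unit="ln nmol/l",
        )
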