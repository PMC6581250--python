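import numpy as np
import pytest

from mrtri.summary_io import HarmonisedRecord, HarmonisedSet


def make_harmonised(
    beta_exp, beta_out, se_out, se_exp=None, eaf=None,
    exposure_unit="ln-unit", outcome_unit="SD",
) -> HarmonisedSet:
    """Build a HarmonisedSet directly from effect arrays (test helper)."""
    beta_exp = np.asarray(beta_exp, float)
    beta_out = np.asarray(beta_out, float)
    se_out = np.asarray(se_out, float)
    se_exp = np.full_like(beta_exp, 1e-3) if se_exp is None else np.asarray(se_exp, float)
    records = [
        HarmonisedRecord(
            rsid=f"rs{i}", beta_exp=float(beta_exp[i]), se_exp=float(se_exp[i]),
            beta_out=float(beta_out[i]), se_out=float(se_out[i]),
            eaf=None if eaf is None else float(eaf[i]),
            effect_allele="A", other_allele="G",
        )
        for i in range(len(beta_exp))
    ]
    return HarmonisedSet(
        records=records, exposure_label="exposure", outcome_label="birth_weight",
        exposure_unit=exposure_unit, outcome_unit=outcome_unit,
    )


@pytest.fixture
def hand_pool_set() -> HarmonisedSet:
    """Two instruments with unit exposure effects giving ratios 4 +/- 1 and 2 +/- 2."""
    return make_harmonised([1.0, 1.0], [4.0, 2.0], [1.0, 2.0])


def random_harmonised(rng: np.random.Generator, n: int = 8) -> HarmonisedSet:
    beta_exp = rng.uniform(0.01, 0.2, n)
    beta_out = rng.normal(0.0, 0.05, n)
    se_out = rng.uniform(0.005, 0.05, n)
    return make_harmonised(beta_exp, beta_out, se_out)
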