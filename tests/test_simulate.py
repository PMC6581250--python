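"""Generator structure: determinism, transmission, compliance, calibration."""

import numpy as np
import pytest

from mrtri.estimators import ivw, mr_egger, pool_fixed, wald_ratio, weighted_median
from mrtri.exceptions import ConfigError
from mrtri.rct import rct_ratio, read_rct_records, write_rct_records
from mrtri.simulate import (
    CohortSimConfig,
    RctSimConfig,
    TwoSampleConfig,
    simulate_mother_child,
    simulate_rcts,
    simulate_two_sample,
)
from mrtri.summary_io import harmonise, read_snp_summaries, write_snp_summaries


class TestTwoSample:
    def test_seed_determinism(self):
        a = simulate_two_sample(TwoSampleConfig(seed=11, palindromic_fraction=0.3))
        b = simulate_two_sample(TwoSampleConfig(seed=11, palindromic_fraction=0.3))
        assert a[0] == b[0] and a[1] == b[1]
        c = simulate_two_sample(TwoSampleConfig(seed=12, palindromic_fraction=0.3))
        assert a[0] != c[0]

    def test_round_trip_through_reader(self, tmp_path):
        exposure, outcome, _ = simulate_two_sample(TwoSampleConfig(seed=1))
        for name, records in (("exp", exposure), ("out", outcome)):
            p = tmp_path / f"{name}.tsv"
            write_snp_summaries(records, p)
            back = read_snp_summaries(p)
            assert [
                (r.rsid, r.effect_allele, r.beta, r.se) for r in back
            ] == [(r.rsid, r.effect_allele, r.beta, r.se) for r in records]

    def test_null_model_calibration_small(self):
        """theta = 0, valid instruments: IVW rejects at ~5% (64 reps here;
        the full 1,000-replicate calibration lives with the coverage check)."""
        hits = 0
        for seed in range(64):
            exposure, outcome, _ = simulate_two_sample(
                TwoSampleConfig(theta=0.0, seed=seed)
            )
            res = ivw(harmonise(exposure, outcome))
            hits += not (res.ci_low <= 0.0 <= res.ci_high)
        assert hits <= 9  # P(X > 9 | Binomial(64, 0.05)) < 0.002

    def test_directional_pleiotropy_recovered_by_egger_intercept(self):
        """With InSIDE holding, the Egger intercept is unbiased for its
        estimand — the intercept of the weighted fit to the noiseless
        pleiotropic signal — and detects the directional shift."""
        intercepts, oracle = [], []
        for seed in range(150):
            exposure, outcome, truth = simulate_two_sample(
                TwoSampleConfig(
                    n_snps=30, theta=0.3, invalid_fraction=0.5,
                    pleiotropy_mean=0.01, pleiotropy_sd=0.002, seed=seed,
                )
            )
            hset = harmonise(exposure, outcome)
            res = mr_egger(hset)
            intercepts.append(res.intercept.beta)
            # construction oracle: weighted fit to theta*E + alpha without noise
            e = truth.exposure_effects
            w = np.array([r.se_out ** -2 for r in hset.records])
            X = np.column_stack([np.ones_like(e), e])
            y0 = truth.theta * e + truth.pleiotropy
            b = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y0))
            oracle.append(b[0])
        bias = np.mean(intercepts) - np.mean(oracle)
        mc_se = np.std(intercepts, ddof=1) / np.sqrt(len(intercepts))
        assert abs(bias) < 4 * mc_se
        assert np.mean(intercepts) > 0  # directional pleiotropy flagged

    def test_infeasible_invalid_fraction(self):
        # a target weight share below half the smallest achievable weight
        # cannot be approached by any non-empty subset
        with pytest.raises(ConfigError, match="infeasible"):
            simulate_two_sample(
                TwoSampleConfig(n_snps=7, invalid_fraction=0.001, seed=0)
            )
        with pytest.raises(ConfigError):
            simulate_two_sample(TwoSampleConfig(n_snps=7, invalid_fraction=1.0))

    def test_truth_record_scores_estimators(self):
        exposure, outcome, truth = simulate_two_sample(
            TwoSampleConfig(n_snps=10, theta=0.4, invalid_fraction=0.3,
                            pleiotropy_mean=0.02, pleiotropy_sd=0.01, seed=5)
        )
        assert truth.theta == 0.4
        assert 1 <= (~truth.valid).sum() < 10
        assert np.all(truth.pleiotropy[truth.valid] == 0.0)
        assert np.all(truth.pleiotropy[~truth.valid] != 0.0)
        assert len(truth.rsids) == len(exposure) == len(outcome)

    def test_invalid_weight_share_tracks_target(self):
        """The realised IVW-weight share of invalid instruments stays close
        to the configured share, never crossing the 50% breakdown line when
        40% is requested."""
        from mrtri.simulate import gwas_se
        for seed in range(40):
            cfg = TwoSampleConfig(n_snps=10, theta=0.5, invalid_fraction=0.4,
                                  pleiotropy_mean=0.05, pleiotropy_sd=0.01,
                                  seed=seed)
            exposure, _, truth = simulate_two_sample(cfg)
            eaf = np.array([s.eaf for s in exposure])
            w = truth.exposure_effects ** 2 / gwas_se(eaf, cfg.n_outcome) ** 2
            share = w[~truth.valid].sum() / w.sum()
            assert 0.2 <= share < 0.5


class TestRcts:
    def test_determinism_and_both_summary_modes(self):
        a_itt, a_pp, _ = simulate_rcts(RctSimConfig(n_trials=4, seed=3))
        b_itt, b_pp, _ = simulate_rcts(RctSimConfig(n_trials=4, seed=3))
        assert [r.outcome_diff for r in a_itt] == [r.outcome_diff for r in b_itt]
        assert [r.trial_id for r in a_pp] == [f"trial{t:02d}-pp" for t in range(4)]

    def test_full_compliance_calibration(self):
        """Full compliance, no attrition: the pooled ratio covers theta in
        roughly 95% of replicates (40 here, bounded loosely)."""
        theta, covered = 1.0, 0
        for seed in range(40):
            itt, _, _ = simulate_rcts(
                RctSimConfig(n_trials=8, theta=theta, seed=seed,
                             n_range=(100, 400))
            )
            pooled = pool_fixed([rct_ratio(r) for r in itt])
            covered += pooled.ci_low <= theta <= pooled.ci_high
        assert covered >= 33  # P(X < 33 | Binomial(40, 0.95)) < 0.005

    def test_noncompliance_dilutes_biomarker_not_ratio(self):
        """Compliance 0.5 halves the achieved biomarker difference but the
        as-randomised ratio remains centred on theta (the instrument stays
        valid)."""
        theta = 1.0
        full_shift, half_shift, ratios = [], [], []
        for seed in range(60):
            full, _, tf = simulate_rcts(
                RctSimConfig(n_trials=4, theta=theta, compliance=1.0,
                             n_range=(400, 800), outcome_sd=100.0, seed=seed)
            )
            half, _, th = simulate_rcts(
                RctSimConfig(n_trials=4, theta=theta, compliance=0.5,
                             n_range=(400, 800), outcome_sd=100.0, seed=seed)
            )
            full_shift.append(np.mean(tf.achieved_shift))
            half_shift.append(np.mean(th.achieved_shift))
            ratios.append(pool_fixed([rct_ratio(r) for r in half]).beta)
        assert np.mean(half_shift) == pytest.approx(0.5 * np.mean(full_shift), rel=0.1)
        mc_se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert np.mean(ratios) == pytest.approx(theta, abs=4 * mc_se)

    def test_confounded_per_protocol_bias_direction(self):
        """Per-protocol summaries with compliance confounded towards high
        outcome potential overstate the ratio (constructed direction)."""
        theta = 1.0
        pp_betas = []
        for seed in range(40):
            _, pp, _ = simulate_rcts(
                RctSimConfig(n_trials=6, theta=theta, compliance=0.5,
                             confounded_compliance=True,
                             compliance_confounding_g=300.0,
                             n_range=(300, 600), outcome_sd=100.0, seed=seed)
            )
            pp_betas.append(pool_fixed([rct_ratio(r) for r in pp]).beta)
        assert np.mean(pp_betas) > theta + 2 * np.std(pp_betas, ddof=1) / np.sqrt(len(pp_betas))

    def test_attrition_guard(self):
        with pytest.raises(ConfigError, match="attrition|arm"):
            simulate_rcts(RctSimConfig(n_trials=2, n_range=(4, 6),
                                       attrition=0.95, seed=1))

    def test_round_trip_through_reader(self, tmp_path):
        itt, _, _ = simulate_rcts(RctSimConfig(n_trials=3, seed=9))
        p = tmp_path / "trials.tsv"
        write_rct_records(itt, p)
        back = read_rct_records(p)
        assert [r.trial_id for r in back] == [r.trial_id for r in itt]
        assert back[0].se_outcome == pytest.approx(itt[0].se_outcome, rel=1e-9)


class TestMotherChild:
    @pytest.mark.parametrize("freq", [0.15, 0.5, 0.85])
    def test_transmission_correlation_near_half(self, freq):
        panel, truth = simulate_mother_child(
            CohortSimConfig(n_pairs=10_000, eaf=(freq,), seed=21)
        )
        m = panel.data["m_" + truth.rsids[0]]
        f = panel.data["f_" + truth.rsids[0]]
        assert 0.45 <= np.corrcoef(m, f)[0, 1] <= 0.55

    def test_dosage_means_match_hardy_weinberg(self):
        panel, truth = simulate_mother_child(
            CohortSimConfig(n_pairs=10_000, eaf=(0.3, 0.6), seed=22)
        )
        for rsid, p in zip(truth.rsids, (0.3, 0.6)):
            assert panel.data["m_" + rsid].mean() == pytest.approx(2 * p, abs=0.03)
            assert panel.data["f_" + rsid].mean() == pytest.approx(2 * p, abs=0.03)

    def test_determinism(self):
        a, _ = simulate_mother_child(CohortSimConfig(n_pairs=100, seed=5))
        b, _ = simulate_mother_child(CohortSimConfig(n_pairs=100, seed=5))
        assert a.data.equals(b.data)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            simulate_mother_child(CohortSimConfig(n_pairs=10))
        with pytest.raises(ConfigError):
            simulate_mother_child(CohortSimConfig(eaf=(0.0,)))
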