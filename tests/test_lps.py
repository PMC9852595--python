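import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from rsomics.datamodel import BetaMatrix, SampleSheet, ValidationError, beta_to_m
from rsomics.lps import (
    LABEL_CLL,
    LABEL_DLBCL,
    LABEL_INTERMEDIATE,
    LpsModel,
    classify,
    compute_lps,
    fit_group_distributions,
    posterior,
    score_samples,
    select_scoring_cpgs,
    train_and_score,
)
from rsomics.simulate import SimulationConfig, simulate_methylation


def _model(weights, cpgs=None, **kw):
    cpgs = cpgs or [f"cg{i}" for i in range(len(weights))]
    defaults = dict(mu_cll=0.0, var_cll=1.0, mu_dlbcl=4.0, var_dlbcl=4.0)
    defaults.update(kw)
    return LpsModel(scoring_cpgs=cpgs, weights=np.asarray(weights, float), **defaults)


class TestComputeLps:
    def test_weighted_sum_arithmetic(self):
        b = BetaMatrix(pd.DataFrame([[0.5], [0.5]], index=["cg0", "cg1"], columns=["s"]))
        assert compute_lps(b, _model([2.0, -1.0]))["s"] == pytest.approx(0.5)

    def test_zero_weights_give_zero_score(self, beta_matrix):
        model = _model([0.0] * 8, cpgs=beta_matrix.feature_ids)
        assert (compute_lps(beta_matrix, model) == 0).all()

    def test_matches_elementwise_sum_oracle(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(0, 1, size=(100, 7))
        b = BetaMatrix(pd.DataFrame(vals, index=[f"cg{i}" for i in range(100)],
                                    columns=[f"s{i}" for i in range(7)]))
        w = rng.normal(size=100)
        scores = compute_lps(b, _model(w.tolist(), cpgs=b.feature_ids))
        for j, s in enumerate(b.sample_ids):
            assert scores[s] == pytest.approx(sum(w[i] * vals[i, j] for i in range(100)),
                                              rel=1e-12)

    def test_linearity_in_beta_profiles(self):
        rng = np.random.default_rng(4)
        w = rng.normal(size=10)
        s1, s2 = rng.uniform(0, 1, 10), rng.uniform(0, 1, 10)
        a = 0.3
        mix = a * s1 + (1 - a) * s2
        b = BetaMatrix(pd.DataFrame(np.column_stack([s1, s2, mix]),
                                    index=[f"cg{i}" for i in range(10)],
                                    columns=["x", "y", "mix"]))
        lps = compute_lps(b, _model(w.tolist(), cpgs=b.feature_ids))
        assert lps["mix"] == pytest.approx(a * lps["x"] + (1 - a) * lps["y"], rel=1e-10)

    def test_missing_scoring_cpg_rejected(self, beta_matrix):
        with pytest.raises(ValidationError, match="absent"):
            compute_lps(beta_matrix, _model([1.0], cpgs=["nope"]))


class TestPosterior:
    def test_midpoint_with_equal_variances_is_half(self):
        m = _model([1.0], mu_cll=0.0, var_cll=1.0, mu_dlbcl=2.0, var_dlbcl=1.0)
        p_cll, p_dlbcl = posterior(1.0, m)
        assert p_cll == pytest.approx(0.5)
        assert p_cll + p_dlbcl == 1.0

    def test_far_separation_saturates(self):
        m = _model([1.0], mu_cll=0.0, var_cll=1.0, mu_dlbcl=20.0, var_dlbcl=1.0)
        p_cll, _ = posterior(0.0, m)
        assert p_cll > 1 - 1e-12

    def test_matches_normal_density_oracle(self):
        m = _model([1.0])  # mu 0/var 1 vs mu 4/var 4
        p_cll, _ = posterior(2.0, m)
        oracle = norm.pdf(2, 0, 1) / (norm.pdf(2, 0, 1) + norm.pdf(2, 4, 2))
        assert p_cll == pytest.approx(oracle, rel=1e-12)
        assert oracle == pytest.approx(0.3086, abs=5e-5)

    def test_posteriors_sum_to_one_exactly(self):
        m = _model([1.0])
        for x in np.linspace(-50, 50, 21):
            p_cll, p_dlbcl = posterior(x, m)
            assert p_cll + p_dlbcl == 1.0


class TestClassify:
    @pytest.mark.parametrize(
        "p_cll,expected",
        [(0.99, LABEL_CLL), (0.5, LABEL_INTERMEDIATE), (0.02, LABEL_DLBCL), (0.98, LABEL_CLL)],
    )
    def test_threshold_rule_inclusive(self, p_cll, expected):
        assert classify(p_cll, 1 - p_cll, threshold=0.98) == expected


class TestGroupDistributions:
    def _sheet(self, groups):
        ids = [f"s{i}" for i in range(len(groups))]
        return ids, SampleSheet(pd.DataFrame({"sample_id": ids, "group": groups}))

    def test_hand_arithmetic(self):
        ids, sheet = self._sheet(["CLL"] * 3 + ["DLBCL"] * 3)
        lps = pd.Series([1.0, 2.0, 3.0, 10.0, 12.0, 14.0], index=ids)
        mu_c, var_c, mu_d, var_d = fit_group_distributions(lps, sheet)
        assert (mu_c, var_c) == (pytest.approx(2.0), pytest.approx(1.0))
        assert (mu_d, var_d) == (pytest.approx(12.0), pytest.approx(4.0))

    def test_zero_variance_rejected(self):
        ids, sheet = self._sheet(["CLL"] * 3 + ["DLBCL"] * 3)
        lps = pd.Series([5.0, 5.0, 5.0, 1.0, 2.0, 3.0], index=ids)
        with pytest.raises(ValidationError, match="variance"):
            fit_group_distributions(lps, sheet)

    def test_small_group_rejected(self):
        ids, sheet = self._sheet(["CLL"] * 2 + ["DLBCL"] * 4)
        lps = pd.Series(np.arange(6.0), index=ids)
        with pytest.raises(ValidationError, match=">=3"):
            fit_group_distributions(lps, sheet)

    def test_recovers_sampling_distribution(self):
        rng = np.random.default_rng(0)
        ids, sheet = self._sheet(["CLL"] * 200 + ["DLBCL"] * 200)
        lps = pd.Series(
            np.concatenate([rng.normal(5, 2, 200), rng.normal(-5, 2, 200)]), index=ids
        )
        mu_c, var_c, _, _ = fit_group_distributions(lps, sheet)
        assert mu_c == pytest.approx(5.0, abs=0.3)
        assert var_c == pytest.approx(4.0, rel=0.20)


class TestSelection:
    def test_recovers_planted_cpgs_and_excludes_ighv(self, planted_cpg_bundle):
        b = planted_cpg_bundle
        m = beta_to_m(b.beta)
        cpgs, weights, funnel = select_scoring_cpgs(m, b.beta, b.sheet)
        planted = set(b.truth.cll_dlbcl_cpgs)
        ighv = set(b.truth.ighv_cpgs)
        selected = set(cpgs)
        assert not (selected & ighv), "no IGHV-differential CpG may score"
        # every planted CpG that was not itself IGHV-differential is recovered
        assert len(planted - selected) <= 2
        assert len(weights) == len(cpgs)
        assert funnel["n_scoring"] == len(cpgs)

    def test_no_differential_cpgs_is_an_error(self):
        cfg = SimulationConfig(seed=2, n_cpgs=300, frac_cll_dlbcl_differential=0.0,
                               frac_ighv_differential=0.0, n_cll_u=5, n_cll_m=5,
                               n_dlbcl=8, n_rs_cll_like=3, n_rs_dlbcl_like=3,
                               n_promoter_genes=0, n_correlated_promoters=0)
        b = simulate_methylation(cfg)
        with pytest.raises(ValidationError, match="relax"):
            select_scoring_cpgs(beta_to_m(b.beta), b.beta, b.sheet)

    def test_zero_delta_cut_removes_nothing_at_step_three(self, planted_cpg_bundle):
        b = planted_cpg_bundle
        m = beta_to_m(b.beta)
        loose, _, funnel0 = select_scoring_cpgs(m, b.beta, b.sheet, delta_cut=0.0)
        assert len(loose) == funnel0["n_after_ighv_exclusion"]


class TestTrainAndScore:
    @pytest.fixture(scope="class")
    @staticmethod
    def cohort():
        cfg = SimulationConfig(seed=31, n_cpgs=3000, n_cll_u=40, n_cll_m=40,
                               n_dlbcl=60, n_rs_cll_like=30, n_rs_dlbcl_like=10,
                               delta_beta_effect=0.35,
                               n_promoter_genes=0, n_correlated_promoters=0)
        return simulate_methylation(cfg)

    def test_rs_subgroups_recovered(self, cohort):
        model, res = train_and_score(cohort.beta, beta_to_m(cohort.beta), cohort.sheet)
        truth = cohort.truth.rs_labels
        cll_true = [s for s, lab in truth.items() if lab == "CLL_derived"]
        dlb_true = [s for s, lab in truth.items() if lab == "DLBCL_like"]
        n_cll_ok = sum(res.loc[s, "label"] == LABEL_CLL for s in cll_true)
        n_dlb_ok = sum(res.loc[s, "label"] == LABEL_DLBCL for s in dlb_true)
        cross = sum(
            res.loc[s, "label"] not in (truth[s], LABEL_INTERMEDIATE) for s in res.index
        )
        assert n_cll_ok >= 27
        assert n_dlb_ok >= 8
        assert cross == 0

    def test_cll_centroid_sample_is_cll_derived(self, cohort):
        model, _ = train_and_score(cohort.beta, beta_to_m(cohort.beta), cohort.sheet)
        cll_ids = cohort.sheet.samples_in_group("CLL")
        centroid = cohort.beta.values[cll_ids].mean(axis=1)
        b = BetaMatrix(centroid.to_frame("centroid"))
        res = score_samples(b, model)
        assert res.loc["centroid", "label"] == LABEL_CLL

    def test_serialization_round_trip_scores_identically(self, cohort, tmp_path):
        model, res = train_and_score(cohort.beta, beta_to_m(cohort.beta), cohort.sheet)
        model.to_json(tmp_path / "model.json")
        reloaded = LpsModel.from_json(tmp_path / "model.json")
        rs = cohort.sheet.samples_in_group("RS")
        res2 = score_samples(BetaMatrix(cohort.beta.values[rs]), reloaded)
        pd.testing.assert_frame_equal(res, res2)

    def test_weight_rescaling_leaves_posteriors_unchanged(self, cohort):
        model, res = train_and_score(cohort.beta, beta_to_m(cohort.beta), cohort.sheet)
        scaled = LpsModel(
            scoring_cpgs=model.scoring_cpgs,
            weights=model.weights * 3.7,
            threshold=model.threshold,
        )
        ref = cohort.sheet.samples_in_group("CLL") + cohort.sheet.samples_in_group("DLBCL")
        lps_ref = compute_lps(BetaMatrix(cohort.beta.values[ref]), scaled)
        mu_c, var_c, mu_d, var_d = fit_group_distributions(
            lps_ref, cohort.sheet.subset(ref)
        )
        scaled.mu_cll, scaled.var_cll = mu_c, var_c
        scaled.mu_dlbcl, scaled.var_dlbcl = mu_d, var_d
        rs = cohort.sheet.samples_in_group("RS")
        res2 = score_samples(BetaMatrix(cohort.beta.values[rs]), scaled)
        np.testing.assert_allclose(res2["p_cll"], res["p_cll"], atol=1e-9)
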