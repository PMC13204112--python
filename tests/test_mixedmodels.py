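import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from mucocilia.mixedmodels import (
    association_lmm,
    adjusted_recovery_lmm,
    fit_group_lmm,
    fit_recovery_lmm,
    tukey_contrasts,
)
from mucocilia.preprocess import SampleMetadata

from conftest import paired_metadata, singleton_metadata


def two_group_fixture(rng, n=6, delta=0.8):
    ya = rng.normal(0, 1, n)
    yb = rng.normal(delta, 1, n)
    meta = singleton_metadata(
        [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)],
        ["Ctrl"] * n + ["nonECRS"] * n,
    )
    return pd.Series(np.r_[ya, yb], index=meta.sample_ids), meta, ya, yb


class TestGroupLmm:
    def test_collapses_to_pooled_t_with_singleton_patients(self, rng):
        scores, meta, ya, yb = two_group_fixture(rng)
        fit = fit_group_lmm(scores, meta)
        ct = tukey_contrasts(fit).table.iloc[0]
        t, p = stats.ttest_ind(ya, yb)
        assert abs(ct["t"]) == pytest.approx(abs(t), abs=1e-6)
        assert ct["p"] == pytest.approx(p, abs=1e-6)
        assert ct["df"] == pytest.approx(10.0, abs=1e-6)
        assert ct["estimate"] == pytest.approx(ya.mean() - yb.mean(), abs=1e-10)

    def test_translation_changes_only_group_means(self, rng):
        scores, meta, *_ = two_group_fixture(rng)
        f0 = fit_group_lmm(scores, meta)
        f1 = fit_group_lmm(scores + 10.0, meta)
        assert np.allclose(
            f1.fixed_effects["estimate"], f0.fixed_effects["estimate"] + 10.0
        )
        assert np.allclose(f1.fixed_effects["se"], f0.fixed_effects["se"])
        assert f1.sigma2_e == pytest.approx(f0.sigma2_e)

    def test_matches_statsmodels_mixedlm_on_paired_data(self, rng):
        n = 9
        meta = paired_metadata(n)
        u = rng.normal(0, 1.0, n)
        pre = u + rng.normal(0, 0.5, n)
        post = u + 1.2 + rng.normal(0, 0.5, n)
        scores = pd.Series(np.r_[pre, post], index=meta.sample_ids)
        fit = fit_group_lmm(scores, meta)
        df = pd.DataFrame({"y": np.r_[pre, post], "g": ["Pre"] * n + ["Post"] * n,
                           "pt": list(range(n)) * 2})
        ref = sm.MixedLM.from_formula(
            "y ~ C(g, Treatment('Pre'))", groups="pt", data=df
        ).fit(reml=True)
        assert fit.sigma2_u == pytest.approx(float(ref.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.sigma2_e == pytest.approx(float(ref.scale), rel=1e-3)
        assert fit.fixed_effects.loc["PreECRS", "estimate"] == pytest.approx(
            float(ref.params["Intercept"]), abs=1e-5
        )

    def test_paired_design_shrinks_contrast_se(self, rng):
        n = 12
        meta = paired_metadata(n)
        u = rng.normal(0, 2.0, n)  # strong within-patient correlation
        pre = u + rng.normal(0, 0.2, n)
        post = u + 1.0 + rng.normal(0, 0.2, n)
        scores = pd.Series(np.r_[pre, post], index=meta.sample_ids)
        ct = tukey_contrasts(fit_group_lmm(scores, meta)).table.iloc[0]
        # unpaired pooled-variance se would be dominated by the patient spread
        se_unpaired = np.sqrt(np.var(pre, ddof=1) / n + np.var(post, ddof=1) / n)
        assert ct["se"] < 0.5 * se_unpaired
        assert ct["paired"]

    def test_single_group_rejected(self, rng):
        meta = singleton_metadata(["a", "b"], ["Ctrl", "Ctrl"])
        with pytest.raises(ValueError, match="2 groups"):
            fit_group_lmm(pd.Series([1.0, 2.0], index=["a", "b"]), meta)


class TestTukey:
    def test_k2_adjusted_equals_unadjusted(self, rng):
        scores, meta, *_ = two_group_fixture(rng)
        ct = tukey_contrasts(fit_group_lmm(scores, meta)).table.iloc[0]
        assert ct["p_tukey"] == pytest.approx(ct["p"], abs=1e-9)

    def test_balanced_three_by_five_matches_closed_form(self, rng):
        y = np.r_[rng.normal(0, 1, 5), rng.normal(1, 1, 5), rng.normal(2, 1, 5)]
        meta = singleton_metadata(
            [f"s{i}" for i in range(15)], ["Ctrl"] * 5 + ["nonECRS"] * 5 + ["PreECRS"] * 5
        )
        ct = tukey_contrasts(fit_group_lmm(pd.Series(y, index=meta.sample_ids), meta)).table
        means = [y[:5].mean(), y[5:10].mean(), y[10:].mean()]
        mse = np.mean([np.var(y[i * 5:(i + 1) * 5], ddof=1) for i in range(3)])
        pairs = {("Ctrl", "nonECRS"): (0, 1), ("Ctrl", "PreECRS"): (0, 2),
                 ("nonECRS", "PreECRS"): (1, 2)}
        for _, row in ct.iterrows():
            i, j = pairs[(row["level_a"], row["level_b"])]
            q = abs(means[i] - means[j]) / np.sqrt(mse / 5)
            expected = stats.studentized_range.sf(q, 3, 12)
            assert row["p_tukey"] == pytest.approx(expected, rel=1e-6)
            assert row["df"] == pytest.approx(12.0, abs=1e-6)

    def test_adjustment_never_decreases_p_for_three_groups(self, rng):
        y = rng.normal(0, 1, 18)
        meta = singleton_metadata(
            [f"s{i}" for i in range(18)], ["Ctrl"] * 6 + ["nonECRS"] * 6 + ["PreECRS"] * 6
        )
        ct = tukey_contrasts(fit_group_lmm(pd.Series(y, index=meta.sample_ids), meta)).table
        assert np.all(ct["p_tukey"] >= ct["p"] - 1e-12)

    def test_familywise_error_controlled_under_null(self, rng):
        reps, k, n_per = 1000, 3, 5
        meta = singleton_metadata(
            [f"s{i}" for i in range(k * n_per)],
            ["Ctrl"] * n_per + ["nonECRS"] * n_per + ["PreECRS"] * n_per,
        )
        fwe = 0
        for _ in range(reps):
            y = pd.Series(rng.normal(0, 1, k * n_per), index=meta.sample_ids)
            ct = tukey_contrasts(fit_group_lmm(y, meta)).table
            fwe += (ct["p_tukey"] < 0.05).any()
        assert fwe / reps <= 0.07


class TestAssociation:
    def cross_sectional(self, rng, n=20, slope=0.0, noise=1.0):
        meta = singleton_metadata(
            [f"s{i}" for i in range(n)], ["Ctrl"] * (n // 2) + ["nonECRS"] * (n - n // 2)
        )
        x = pd.Series(rng.normal(0, 2, n), index=meta.sample_ids)
        y = slope * x + pd.Series(rng.normal(0, noise, n), index=meta.sample_ids)
        return y, x, meta

    def test_perfect_association_gives_rm_one(self, rng):
        y, x, meta = self.cross_sectional(rng, slope=1.0, noise=1e-8)
        res = association_lmm(y, x, meta)
        assert res.rm == pytest.approx(1.0, abs=1e-4)

    def test_one_obs_per_patient_matches_ols_slope_p(self, rng):
        y, x, meta = self.cross_sectional(rng, slope=0.4)
        res = association_lmm(y, x, meta)
        lr = stats.linregress(x.to_numpy(), y.to_numpy())
        assert res.slope == pytest.approx(lr.slope, abs=1e-6)
        assert res.p_lmm == pytest.approx(lr.pvalue, rel=1e-4)

    def test_r2_ordering_and_sign(self, rng):
        y, x, meta = self.cross_sectional(rng, slope=-0.5)
        res = association_lmm(y, x, meta)
        assert 0 <= res.r2_marginal <= res.r2_conditional <= 1
        assert res.rm < 0

    def test_null_association_rm_small(self, rng):
        rejections = 0
        for _ in range(100):
            y, x, meta = self.cross_sectional(rng, n=60, slope=0.0)
            res = association_lmm(y, x, meta)
            rejections += res.p_lmm < 0.05
        assert rejections / 100 <= 0.12

    def test_zero_variance_predictor_rejected(self, rng):
        y, x, meta = self.cross_sectional(rng)
        with pytest.raises(ValueError, match="variance"):
            association_lmm(y, x * 0, meta)


def recovery_fixture(rng, n_p=9, gamma=0.7, noise=0.0, tau=1.0):
    meta = paired_metadata(n_p)
    pats = [f"E{i:02d}" for i in range(n_p)]
    b = pd.Series(rng.normal(0, 2, n_p), index=pats)
    u = rng.normal(0, tau, n_p)
    pre = 5 + u + rng.normal(0, noise, n_p)
    post = pre + 0.5 + gamma * (b - b.mean()).to_numpy() + rng.normal(0, noise, n_p)
    scores = pd.Series(np.r_[pre, post], index=meta.sample_ids)
    return scores, meta, b


class TestRecovery:
    def test_noiseless_identifiability(self, rng):
        scores, meta, b = recovery_fixture(rng, gamma=0.7, noise=0.0)
        res = fit_recovery_lmm(scores, meta, b)
        assert res.beta_interaction == pytest.approx(0.7, abs=1e-8)
        assert res.p_interaction < 1e-10

    def test_interaction_equals_delta_regression_slope(self, rng):
        scores, meta, b = recovery_fixture(rng, gamma=0.3, noise=0.4)
        res = fit_recovery_lmm(scores, meta, b)
        pats = b.index
        delta = np.array([scores[f"{p}_Post"] - scores[f"{p}_Pre"] for p in pats])
        bc = (b - b.mean()).to_numpy()
        ols_slope = np.polyfit(bc, delta, 1)[0]
        assert res.beta_interaction == pytest.approx(ols_slope, abs=1e-8)

    def test_unpaired_patient_named_in_error(self, rng):
        scores, meta, b = recovery_fixture(rng)
        broken = scores.drop("E03_Post")
        with pytest.raises(ValueError, match="E03"):
            fit_recovery_lmm(broken, meta, b)

    def test_missing_baseline_named_in_error(self, rng):
        scores, meta, b = recovery_fixture(rng)
        with pytest.raises(ValueError, match="E05"):
            fit_recovery_lmm(scores, meta, b.drop("E05"))

    def test_collinear_covariate_is_rank_deficiency_error(self, rng):
        scores, meta, b = recovery_fixture(rng, noise=0.3)
        cov = pd.DataFrame({"dup": b.loc[sorted(b.index)]})
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            fit_recovery_lmm(scores, meta, b, covariates=cov)

    def test_zero_variance_covariate_dropped(self, rng):
        scores, meta, b = recovery_fixture(rng, noise=0.3)
        plain = fit_recovery_lmm(scores, meta, b)
        cov = pd.DataFrame({"flat": pd.Series(0.0, index=b.index)})
        with pytest.warns(UserWarning, match="flat"):
            adj = fit_recovery_lmm(scores, meta, b, covariates=cov)
        assert adj.dropped_covariates == ("flat",)
        assert adj.p_interaction == pytest.approx(plain.p_interaction, abs=1e-12)

    def test_independent_covariates_barely_move_p(self, rng):
        scores, meta, b = recovery_fixture(rng, n_p=20, gamma=0.2, noise=0.5)
        plain = fit_recovery_lmm(scores, meta, b)
        cov = pd.DataFrame(
            rng.normal(size=(20, 2)), index=b.index, columns=["c1", "c2"]
        )
        adj = fit_recovery_lmm(scores, meta, b, covariates=cov)
        # patient-level covariates are orthogonal to the within-patient
        # interaction estimate in the balanced design
        assert adj.beta_interaction == pytest.approx(plain.beta_interaction, abs=1e-8)
        assert abs(np.log10(adj.p_interaction) - np.log10(plain.p_interaction)) < 0.5

    def test_metadata_covariate_path(self, rng):
        scores, meta, b = recovery_fixture(rng, n_p=12, gamma=0.4, noise=0.3)
        tab = meta.table.copy()
        tab["blood_eos"] = rng.uniform(1, 12, len(tab))
        tab["jesrec"] = rng.uniform(11, 17, len(tab))
        meta2 = SampleMetadata(tab)
        res = adjusted_recovery_lmm(
            scores, meta2, b, covariate_names=("blood_eos", "jesrec")
        )
        assert set(res.covariate_estimates.index) == {"blood_eos", "jesrec"}
        assert 0 <= res.p_interaction <= 1


class TestVarianceComponents:
    def test_nonnegative_and_r2_ordering(self, rng):
        scores, meta, b = recovery_fixture(rng, gamma=0.3, noise=0.5, tau=1.5)
        res = fit_recovery_lmm(scores, meta, b)
        fit = res.fit
        assert fit.sigma2_u >= 0 and fit.sigma2_e > 0
        assert fit.n_groups <= fit.n_obs
        assert res.r2_marginal <= res.r2_conditional <= 1
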