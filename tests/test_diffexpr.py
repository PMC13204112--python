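import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mucocilia.diffexpr import (
    ALPHA_MIN,
    bh_adjust,
    call_degs,
    categorize_degs,
    estimate_dispersions,
    nb_wald,
    size_factors,
)

from conftest import make_counts


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = make_counts([[10, 10], [20, 20], [5, 5]])
        assert np.allclose(size_factors(cm).factors, [1.0, 1.0])

    def test_doubled_sample_hand_computation(self):
        cm = make_counts([[10, 20], [4, 8], [30, 60]])
        sf = size_factors(cm).factors
        # every ratio to the geometric-mean reference is 1/sqrt(2) vs sqrt(2)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_global_rescaling_leaves_factors_unchanged(self, rng):
        base = rng.integers(1, 200, size=(40, 5))
        sf1 = size_factors(make_counts(base)).factors
        sf2 = size_factors(make_counts(base * 3)).factors
        assert np.allclose(sf1, sf2)

    def test_geometric_mean_is_one(self, rng):
        cm = make_counts(rng.integers(1, 500, size=(50, 7)))
        sf = size_factors(cm).factors
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0, abs=1e-9)

    def test_no_all_positive_gene_is_an_error(self):
        cm = make_counts([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="nonzero"):
            size_factors(cm)


class TestEstimateDispersions:
    def test_poisson_gene_near_floor(self, rng):
        y = rng.poisson(100.0, size=(200, 50))
        cm = make_counts(y)
        disp = estimate_dispersions(cm, size_factors(cm))
        assert (disp.alpha < 0.01).mean() > 0.9

    def test_nb_dispersion_recovered(self, rng):
        alpha, mu, n = 0.2, 100.0, 200
        r = 1 / alpha
        y = rng.negative_binomial(r, r / (r + mu), size=(100, n))
        cm = make_counts(y)
        disp = estimate_dispersions(cm, size_factors(cm))
        assert 0.1 < disp.alpha.median() < 0.4

    def test_constant_normalized_counts_stay_at_floor(self):
        cm = make_counts([[7, 7, 7], [9, 9, 9]])
        disp = estimate_dispersions(cm, size_factors(cm))
        assert disp.alpha.iloc[0] == ALPHA_MIN

    def test_all_zero_gene_flagged(self):
        cm = make_counts([[0, 0, 0], [5, 9, 40], [3, 3, 4]])
        disp = estimate_dispersions(cm, size_factors(cm))
        assert disp.alpha.loc["g0"] == ALPHA_MIN
        assert "g0" in disp.flagged


def _two_group_fixture(rng, G=200, n_per=6, mu=100.0, alpha=0.05, spike=0, lfc=2.0):
    r = 1 / alpha
    mean = np.full((G, 2 * n_per), mu)
    mean[:spike, :n_per] *= 2.0**lfc
    y = rng.negative_binomial(r, r / (r + mean))
    cm = make_counts(y)
    groups = pd.Series(["A"] * n_per + ["B"] * n_per, index=cm.samples)
    return cm, groups


class TestNbWald:
    def test_matches_reference_glm_per_gene(self, rng):
        cm, groups = _two_group_fixture(rng, G=20)
        sf = size_factors(cm)
        disp = estimate_dispersions(cm, sf, groups)
        res = nb_wald(cm, sf, disp, groups, ("A", "B"))
        X = np.column_stack([np.ones(12), (groups == "A").to_numpy(float)])
        off = np.log(sf.factors.to_numpy())
        for i in range(0, 20, 3):
            fit = sm.GLM(
                cm.data.iloc[i].to_numpy(), X,
                family=sm.families.NegativeBinomial(alpha=disp.alpha.iloc[i]),
                offset=off,
            ).fit()
            assert res["log2fc"].iloc[i] == pytest.approx(fit.params[1] / np.log(2), abs=1e-6)
            assert res["se"].iloc[i] == pytest.approx(fit.bse[1] / np.log(2), rel=1e-4)

    def test_contrast_reversal_negates_log2fc(self, rng):
        cm, groups = _two_group_fixture(rng, G=50)
        sf = size_factors(cm)
        disp = estimate_dispersions(cm, sf, groups)
        ab = nb_wald(cm, sf, disp, groups, ("A", "B"))
        ba = nb_wald(cm, sf, disp, groups, ("B", "A"))
        assert np.allclose(ab["log2fc"], -ba["log2fc"], atol=1e-9)
        assert np.allclose(ab["pvalue"], ba["pvalue"], atol=1e-9)

    def test_all_zero_genes_excluded_from_bh(self, rng):
        cm, groups = _two_group_fixture(rng, G=30)
        cm.data.iloc[0] = 0
        sf = size_factors(cm)
        disp = estimate_dispersions(cm, sf, groups)
        res = nb_wald(cm, sf, disp, groups, ("A", "B"))
        assert not res["tested"].iloc[0]
        assert np.isnan(res["pvalue"].iloc[0]) and np.isnan(res["padj"].iloc[0])
        # BH recomputed over tested genes only reproduces padj
        manual = bh_adjust(res["pvalue"])
        assert np.allclose(res["padj"].dropna(), pd.Series(manual).dropna())

    def test_too_small_group_rejected(self, rng):
        cm, groups = _two_group_fixture(rng, G=10)
        groups.iloc[:5] = "B"
        with pytest.raises(ValueError, match="fewer than 2"):
            nb_wald(cm, size_factors(cm), estimate_dispersions(cm, size_factors(cm)), groups, ("A", "B"))


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.03])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], [0.02, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_monotone_and_dominates_p(self, rng):
        p = rng.uniform(0, 1, 100)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestCallDegs:
    @pytest.mark.parametrize(
        "padj, lfc, call",
        [
            (0.04, 1.2, "up"),
            (0.04, 1.0, "ns"),    # strict > on |lfc|
            (0.05, 3.0, "ns"),    # strict < on padj
            (0.04, -1.2, "down"),
            (0.04, -1.0, "ns"),
            (np.nan, 5.0, "ns"),
        ],
    )
    def test_strict_thresholds(self, padj, lfc, call):
        res = pd.DataFrame({"gene": ["g"], "padj": [padj], "log2fc": [lfc]})
        assert call_degs(res)["call"].iloc[0] == call

    def test_matches_brute_force_filter(self, rng):
        res = pd.DataFrame({
            "gene": [f"g{i}" for i in range(500)],
            "padj": rng.uniform(0, 0.2, 500),
            "log2fc": rng.normal(0, 1.5, 500),
        })
        out = call_degs(res)
        for _, r in out.iterrows():
            if r["padj"] < 0.05 and r["log2fc"] > 1:
                assert r["call"] == "up"
            elif r["padj"] < 0.05 and r["log2fc"] < -1:
                assert r["call"] == "down"
            else:
                assert r["call"] == "ns"


class TestCategorizeDegs:
    def results(self):
        return pd.DataFrame({
            "gene": ["FOXJ1", "DNASE1L3", "NOVELGENE"],
            "padj": [0.01, 0.01, 0.01],
            "log2fc": [2.0, -2.0, 3.0],
            "call": ["up", "down", "up"],
        })

    def test_lookup_and_glyphs(self, registry):
        cat = categorize_degs(self.results(), registry)
        foxj1 = cat[(cat["gene"] == "FOXJ1") & (cat["set"] == "cilia_master")]
        assert len(foxj1) == 1
        assert foxj1.iloc[0]["category"] == "master"
        assert foxj1.iloc[0]["subcategory"] == "Ciliogenesis Master Switch"
        assert foxj1.iloc[0]["glyph"] == "◯"
        dnase = cat[cat["gene"] == "DNASE1L3"]
        assert set(dnase["glyph"]) == {"▲"}

    def test_unregistered_gene_omitted(self, registry):
        cat = categorize_degs(self.results(), registry)
        assert "NOVELGENE" not in set(cat["gene"])

    def test_counts_match_join_oracle(self, registry):
        res = self.results()
        cat = categorize_degs(res, registry)
        expected = 0
        for _, r in res.iterrows():
            if r["call"] == "ns":
                continue
            for gs in registry.sets.values():
                if r["gene"] in gs.genes:
                    expected += 1
        assert len(cat) == expected
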