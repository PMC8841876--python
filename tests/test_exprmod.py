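import math

import numpy as np
import pandas as pd
import pytest

from famscan.errors import ConfigError, DataError
from famscan.exprmod import (
    apply_blacklist,
    center_batches,
    fit_models,
    gene_calls,
    hypergeom_enrich,
    log2_ratio,
    pca_variance,
    qpcr_normalize,
    time_trend,
)
from famscan.simpanel import simulate_expression
from famscan.types import ExpressionMatrix


def _design(reps=8):
    return pd.DataFrame({
        "genotype": ["a"] * 2 * reps + ["b"] * 2 * reps,
        "treatment": (["mock"] * reps + ["inf"] * reps) * 2,
    })


def _em(values, samples):
    return ExpressionMatrix(values=values, samples=samples)


class TestLog2Ratio:
    def test_row_mean_maps_to_zero(self):
        v = pd.DataFrame([[4.0, 4.0, 4.0]], index=["f"],
                         columns=["s1", "s2", "s3"])
        np.testing.assert_allclose(log2_ratio(v).to_numpy(), 0.0)

    def test_double_row_mean_is_one(self):
        v = pd.DataFrame([[2.0, 2.0, 8.0]], index=["f"],
                         columns=["s1", "s2", "s3"])
        r = log2_ratio(v)
        assert r.iloc[0, 2] == pytest.approx(np.log2(8.0 / 4.0))

    def test_geometric_identity(self):
        rng = np.random.default_rng(0)
        v = pd.DataFrame(rng.lognormal(3, 1, size=(20, 6)),
                         columns=[f"s{i}" for i in range(6)])
        r = log2_ratio(v)
        np.testing.assert_allclose((2.0 ** r).mean(axis=1), 1.0, atol=1e-12)

    def test_non_positive_rejected(self):
        v = pd.DataFrame([[1.0, -2.0]], index=["bad"], columns=["s1", "s2"])
        with pytest.raises(DataError, match="bad"):
            log2_ratio(v)


class TestPcaVariance:
    def test_single_direction(self):
        t = np.linspace(0, 1, 10)
        vals = pd.DataFrame(np.outer([1.0, 2.0, -1.0], t),
                            columns=[f"s{i}" for i in range(10)])
        frac, _, _ = pca_variance(vals)
        assert frac[0] == pytest.approx(1.0)

    def test_isotropic_gaussian(self):
        # spherical-covariance oracle: all three fractions near 1/3 (ordered
        # eigenvalue fluctuations shrink like sqrt(2/n))
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(size=(3, 3000)),
                            columns=[f"s{i}" for i in range(3000)])
        frac, _, _ = pca_variance(vals)
        np.testing.assert_allclose(frac[:3], 1 / 3, atol=0.05)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        vals = pd.DataFrame(rng.normal(size=(8, 12)),
                            columns=[f"s{i}" for i in range(12)])
        frac, scores, n_axes = pca_variance(vals)
        assert frac.sum() == pytest.approx(1.0)
        assert scores.shape[0] == 12

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(rng.normal(size=(5, 9)),
                            columns=[f"s{i}" for i in range(9)])
        f1, _, _ = pca_variance(vals)
        perm = rng.permutation(9)
        f2, _, _ = pca_variance(vals.iloc[:, perm])
        np.testing.assert_allclose(f1, f2, atol=1e-10)

    def test_needs_two_samples(self):
        with pytest.raises(DataError):
            pca_variance(pd.DataFrame({"s1": [1.0, 2.0]}))


class TestFitModels:
    def test_noiseless_genotype_effect(self):
        design = _design(4)
        effects = pd.DataFrame({"mu": [5.0] * 3, "beta_g": [2.0] * 3},
                               index=["f1", "f2", "f3"])
        em = simulate_expression(design, effects, sigma=0.0, seed=0)
        fits = fit_models(em, model="GxT")
        g = fits[fits["term"] == "G"]
        assert (g["q"] < 1e-10).all()
        other = fits[fits["term"] != "G"]
        assert not other["significant"].any()

    def test_matches_statsmodels_type1_anova(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(4)
        design = _design(5)
        y = rng.normal(size=len(design)) + 0.8 * (
            design["genotype"] == "b") + 0.5 * (
            (design["genotype"] == "b") & (design["treatment"] == "mock"))
        vals = pd.DataFrame([y.to_numpy()], index=["f"],
                            columns=[f"s{i}" for i in range(len(design))])
        meta = design.copy()
        meta.index = vals.columns
        fits = fit_models(_em(vals, meta), model="GxT")
        df = meta.assign(y=y.to_numpy())
        lm = ols("y ~ C(genotype) + C(treatment) + C(genotype):C(treatment)",
                 data=df).fit()
        anova = sm.stats.anova_lm(lm, typ=1)
        for term, key in [("G", "C(genotype)"), ("T", "C(treatment)"),
                          ("G:T", "C(genotype):C(treatment)")]:
            mine = fits.loc[fits["term"] == term].iloc[0]
            assert mine["F"] == pytest.approx(anova.loc[key, "F"], rel=1e-8)
            assert mine["p"] == pytest.approx(anova.loc[key, "PR(>F)"],
                                              rel=1e-8)

    def test_null_type_one_error(self):
        design = _design(8)
        n_feat = 2000
        effects = pd.DataFrame({"mu": np.zeros(n_feat)},
                               index=[f"f{i}" for i in range(n_feat)])
        em = simulate_expression(design, effects, sigma=1.0, seed=11)
        fits = fit_models(em, model="GxT")
        for term in ("G", "T", "G:T"):
            frac = (fits.loc[fits["term"] == term, "p"] < 0.05).mean()
            assert abs(frac - 0.05) < 0.02
            # BH keeps calls near zero under the global null
            assert fits.loc[fits["term"] == term, "significant"].mean() < 0.01

    def test_time_model_with_categorical_time(self):
        import itertools

        rows = [
            {"genotype": g, "treatment": t, "time": d}
            for g, t, d in itertools.product(
                ["a", "b"], ["mock", "inf"], [1.5, 2, 3, 8])
        ]
        design = pd.DataFrame(rows)
        effects = pd.DataFrame({"mu": [1.0], "beta_g": [3.0]}, index=["f"])
        em = simulate_expression(design, effects, sigma=0.1, seed=3)
        fits = fit_models(em, model="DGT")
        assert set(fits["term"]) == {"D", "G", "T"}
        assert fits.loc[fits["term"] == "G", "p"].iloc[0] < 1e-6

    def test_rank_deficient_design_rejected(self):
        design = pd.DataFrame({"genotype": ["a"] * 4,
                               "treatment": ["m", "m", "i", "i"]})
        vals = pd.DataFrame(np.ones((2, 4)),
                            columns=[f"s{i}" for i in range(4)])
        meta = design.copy()
        meta.index = vals.columns
        with pytest.raises(ConfigError):
            fit_models(_em(vals, meta), model="GxT")

    def test_batch_centering_removes_batch_shift(self):
        design = _design(4)
        design["batch"] = ["x"] * 8 + ["y"] * 8
        vals = np.zeros((1, 16))
        vals[0, 8:] = 100.0  # pure batch shift confounded with genotype
        v = pd.DataFrame(vals, index=["f"],
                         columns=[f"s{i}" for i in range(16)])
        meta = design.copy()
        meta.index = v.columns
        centered = center_batches(_em(v, meta))
        np.testing.assert_allclose(centered.values.to_numpy(), 0.0)


class TestGeneCalls:
    def test_any_spot_rule(self):
        fits = pd.DataFrame({
            "feature": ["sp1", "sp2", "sp3"],
            "term": ["G"] * 3,
            "ss": 1.0, "F": 1.0, "p": 0.5, "q": 0.5,
            "significant": [True, False, False],
        })
        fmap = pd.Series({"sp1": "geneA", "sp2": "geneA", "sp3": "geneB"})
        calls = gene_calls(fits, fmap)
        by_gene = calls.set_index("gene")
        assert bool(by_gene.loc["geneA", "significant"])
        assert not bool(by_gene.loc["geneB", "significant"])
        assert int(by_gene.loc["geneA", "n_spots_significant"]) == 1


class TestTimeTrend:
    def _em_times(self, y_rows, times):
        vals = pd.DataFrame(y_rows, columns=[f"s{i}" for i in
                                             range(len(times))])
        meta = pd.DataFrame({"genotype": "a", "treatment": "m",
                             "time": times}, index=vals.columns)
        return _em(vals, meta)

    def test_perfect_linear_r_one(self):
        times = [1.0, 2.0, 4.0, 8.0]
        em = self._em_times([[2 * t + 1 for t in times]], times)
        out = time_trend(em)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["slope"].iloc[0] == pytest.approx(2.0)

    def test_constant_expression_undefined(self):
        times = [1.0, 2.0, 3.0]
        out = time_trend(self._em_times([[5.0, 5.0, 5.0]], times))
        assert not out["defined"].iloc[0]
        assert np.isnan(out["r"].iloc[0])

    def test_r_squared_equals_regression_r2(self):
        rng = np.random.default_rng(5)
        times = np.linspace(0, 10, 12)
        y = 0.7 * times + rng.normal(0, 1, 12)
        out = time_trend(self._em_times([y], list(times)))
        # R^2 of the simple regression on time
        fit = np.polyfit(times, y, 1)
        resid = y - np.polyval(fit, times)
        r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert out["r"].iloc[0] ** 2 == pytest.approx(r2, abs=1e-12)

    def test_too_few_time_points(self):
        with pytest.raises(ConfigError):
            time_trend(self._em_times([[1.0, 2.0]], [0.0, 1.0]))


class TestHypergeomEnrich:
    def test_spec_example(self):
        universe = {f"g{i}" for i in range(100)}
        hits = {f"g{i}" for i in range(20)}
        cats = {"c": {f"g{i}" for i in range(15, 25)}}  # overlap 5, size 10
        out = hypergeom_enrich(hits, universe, cats)
        assert out.iloc[0]["p"] == pytest.approx(0.0254, abs=5e-4)

    def test_direct_summation_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            n_pop = int(rng.integers(20, 200))
            universe = {f"g{i}" for i in range(n_pop)}
            hits = set(rng.choice(sorted(universe),
                                  size=rng.integers(5, n_pop // 2),
                                  replace=False))
            cat = set(rng.choice(sorted(universe),
                                 size=rng.integers(4, n_pop // 2),
                                 replace=False))
            out = hypergeom_enrich(hits, universe, {"c": cat})
            overlap = len(cat & hits)
            if out.empty:
                assert len(cat) <= 3 or overlap <= 2
                continue
            # independent oracle: direct tail summation of the density
            k_max = min(len(cat), len(hits))
            tail = sum(
                math.comb(len(cat), k)
                * math.comb(n_pop - len(cat), len(hits) - k)
                for k in range(overlap, k_max + 1)
            ) / math.comb(n_pop, len(hits))
            assert out.iloc[0]["p"] == pytest.approx(tail, abs=1e-10)

    def test_size_filter_precedence(self):
        universe = {f"g{i}" for i in range(10)}
        cats = {"tiny": {"g0", "g1", "g2"}}
        out = hypergeom_enrich(set(universe), universe, cats)
        assert out.empty  # category size <= 3 excluded even at full overlap

    def test_overlap_filter(self):
        universe = {f"g{i}" for i in range(50)}
        cats = {"c": {f"g{i}" for i in range(10)}}
        hits = {"g0", "g1"} | {f"g{i}" for i in range(40, 45)}
        out = hypergeom_enrich(hits, universe, cats)
        assert out.empty  # overlap of 2 is excluded (needs > 2)

    def test_bonferroni_counts_tested_categories_only(self):
        universe = {f"g{i}" for i in range(30)}
        hits = {f"g{i}" for i in range(10)}
        cats = {
            "tested1": {f"g{i}" for i in range(6)},
            "tested2": {f"g{i}" for i in range(4, 10)},
            "skipped": {"g0", "g1"},
        }
        out = hypergeom_enrich(hits, universe, cats)
        assert len(out) == 2
        np.testing.assert_allclose(out["p_bonferroni"],
                                   np.minimum(out["p"] * 2, 1.0))

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(DataError):
            hypergeom_enrich({"x"}, {"a", "b"}, {})


class TestQpcrNormalize:
    def test_references_at_their_means(self):
        out = qpcr_normalize([10.0, 10.0], [4.0, 4.0], [7.0, 7.0])
        np.testing.assert_allclose(out, 5.0)

    def test_hand_example(self):
        # ref means both 4 -> denominator 2/4 + 6/4 = 2
        out = qpcr_normalize([10.0, 10.0], [2.0, 6.0], [6.0, 2.0])
        assert out[0] == pytest.approx(5.0)

    def test_homogeneity(self):
        rng = np.random.default_rng(7)
        qg = rng.uniform(1, 10, 6)
        r1 = rng.uniform(1, 10, 6)
        r2 = rng.uniform(1, 10, 6)
        base = qpcr_normalize(qg, r1, r2)
        scaled = qpcr_normalize(qg, 3 * r1, 3 * r2)
        np.testing.assert_allclose(base, scaled)  # means rescale too

    def test_zero_reference_rejected(self):
        with pytest.raises(DataError):
            qpcr_normalize([1.0], [0.0], [1.0])


class TestBlacklist:
    def test_features_dropped(self):
        vals = pd.DataFrame(np.ones((3, 2)), index=["a", "b", "c"],
                            columns=["s1", "s2"])
        meta = pd.DataFrame({"genotype": ["x", "y"],
                             "treatment": ["m", "m"]}, index=["s1", "s2"])
        em = apply_blacklist(_em(vals, meta), ["b"])
        assert list(em.values.index) == ["a", "c"]
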