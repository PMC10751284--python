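"""Partial-F inference: oracle equivalence, permutation calibration,
Pareto tail behavior, FWE dominance, and effect classification."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import litaffect as la
from litaffect import wordtest as wt


def _oracle_partial_f(y, X_full, dropped):
    """Normal-equations least squares, written independently of the package."""
    X_n = np.delete(X_full, dropped, axis=1)

    def rss(X):
        beta = np.linalg.inv(X.T @ X) @ X.T @ y
        r = y - X @ beta
        return r @ r

    n, k = X_full.shape
    p = len(dropped)
    return ((rss(X_n) - rss(X_full)) / p) / (rss(X_full) / (n - k))


class TestPartialF:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            X = np.column_stack([np.ones(30), rng.normal(size=(30, 4))])
            y = rng.normal(size=30)
            dropped = [2, 4]
            assert la.partial_f(y, X, dropped) == pytest.approx(
                _oracle_partial_f(y, X, dropped), abs=1e-8, rel=1e-8)

    def test_scale_invariance_of_y(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 3))])
        y = rng.normal(size=20)
        f1 = la.partial_f(y, X, [1])
        f2 = la.partial_f(1000.0 * y, X, [1])
        assert f1 == pytest.approx(f2, rel=1e-10)

    def test_orthogonal_dropped_column_gives_zero(self):
        n = 40
        X_rest = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
        extra = np.zeros(n)
        extra[::2] = 1.0
        extra -= X_rest @ np.linalg.lstsq(X_rest, extra, rcond=None)[0]
        y = X_rest @ np.array([2.0, 0.5])  # y in span of the kept columns
        X = np.column_stack([X_rest, extra])
        assert la.partial_f(y, X, [2]) == pytest.approx(0.0, abs=1e-18)

    def test_rank_deficient_design_names_columns(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            la.partial_f(np.random.default_rng(2).normal(size=10), X, [1])


class TestPermutationTest:
    def test_p_floor_from_inclusion_convention(self, effect_corpus):
        res = la.permutation_test(effect_corpus.rates, effect_corpus.authors,
                                  n_perm=200, seed=0)
        assert (res.p_perm("joint") >= 1 / 201).all()

    def test_reproducible_for_fixed_seed(self, small_null_corpus):
        c = small_null_corpus
        r1 = la.permutation_test(c.rates, c.authors, n_perm=100, seed=5)
        r2 = la.permutation_test(c.rates, c.authors, n_perm=100, seed=5)
        np.testing.assert_array_equal(r1.null["joint"], r2.null["joint"])
        np.testing.assert_array_equal(r1.f_obs["joint"], r2.f_obs["joint"])

    def test_single_sex_rejected(self):
        spec = la.EffectSpec(vocab_size=5, n_authors=20, sex_ratio=1.0, seed=0)
        c = la.generate_corpus(spec)
        with pytest.raises(ValueError, match="both sexes"):
            la.permutation_test(c.rates, c.authors, n_perm=10)

    def test_null_pvalues_uniform(self, small_null_corpus):
        """Under the all-null generator, joint-test permutation p-values are
        uniform across words (KS p > 0.01)."""
        c = small_null_corpus
        res = la.permutation_test(c.rates, c.authors, n_perm=500, seed=3)
        p = res.p_perm("joint")
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_tiny_case_matches_exhaustive_enumeration(self):
        """With 8 authors (4 per sex) the permutation p agrees with exact
        enumeration over all C(8,4) sex assignments within Monte-Carlo error."""
        rng = np.random.default_rng(7)
        authors = pd.DataFrame({
            "author_id": [f"a{i}" for i in range(8)],
            "sex": ["male"] * 4 + ["female"] * 4,
            "country": ["X"] * 8,
            "continent": ["Europe"] * 8,
            "year_median": [1800, 1850, 1900, 1950, 1820, 1870, 1920, 1970],
            "translated": ["original"] * 8,
        })
        rates = rng.random((8, 3)) * 100
        m = la.RateMatrix(rates, ["u", "v", "w"], authors["author_id"], np.ones(8))
        design = wt.build_design(authors)
        res = la.permutation_test(m, authors, n_perm=4000, seed=1)

        Y = stats.rankdata(rates, axis=0)
        period = design.period
        for j in range(3):
            f_all = []
            for male_idx in combinations(range(8), 4):
                s = np.full(8, -0.5)
                s[list(male_idx)] = 0.5
                X = np.column_stack([design.fixed, s, s * period])
                f_all.append(_oracle_partial_f(Y[:, j], X, [X.shape[1] - 2, X.shape[1] - 1]))
            f_all = np.array(f_all)
            f_obs = f_all[0]  # identity assignment is the observed labeling
            assert f_obs == pytest.approx(res.f_obs["joint"][j], rel=1e-6)
            p_exact = (f_all >= f_obs - 1e-12).mean()
            p_mc = res.p_perm("joint")[j]
            mc_se = np.sqrt(p_exact * (1 - p_exact) / 4000)
            assert abs(p_mc - p_exact) < 4 * mc_se + 1e-3


class TestParetoRefine:
    def test_large_empirical_p_returned_unchanged(self):
        rng = np.random.default_rng(0)
        null = rng.exponential(size=2000)
        obs = float(np.median(null))
        p = la.pareto_refine(null, obs)
        expected = ((null >= obs).sum() + 1) / 2001
        assert p == expected

    def test_monotone_nonincreasing_in_observed_statistic(self):
        rng = np.random.default_rng(1)
        null = rng.exponential(size=5000)
        grid = np.linspace(0, null.max() * 1.5, 60)
        ps = [la.pareto_refine(null, g) for g in grid]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_exponential_tail_extrapolation(self):
        """Exponential null has generalized-Pareto shape 0; the refined p at
        the analytic 1e-4 quantile should sit near 1e-4 even though the
        empirical resolution is only 1e-4."""
        rng = np.random.default_rng(2)
        ratios = []
        for _ in range(10):
            null = rng.exponential(size=10_000)
            obs = -np.log(1e-4)
            ratios.append(la.pareto_refine(null, obs) / 1e-4)
        assert 0.5 < np.median(ratios) < 2.0

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            la.pareto_refine(np.ones(1000), 2.0)


class TestFWE:
    def test_single_word_fwc_equals_pareto(self):
        rng = np.random.default_rng(3)
        null = rng.chisquare(2, size=(2000, 1)).astype(np.float32)
        res = wt.PermutationResult(
            words=np.array(["w"]), f_obs={"joint": np.array([9.0])},
            null={"joint": null}, coef=pd.DataFrame(), n=100, k=5, n_perm=2000)
        p_fwc = la.fwe_correct(res, "joint")
        p_pareto = la.pareto_refine(null[:, 0].astype(float), 9.0)
        assert p_fwc[0] == pytest.approx(p_pareto, rel=0.3)

    def test_fwc_dominates_per_word_p(self, effect_corpus):
        results = la.run_word_tests(effect_corpus.rates, effect_corpus.authors,
                                    n_perm=600, seed=2)
        assert (results["p_fwc"] >= results["p_pareto"] - 1e-15).all()
        assert ((results["p_fwc"] > 0) & (results["p_fwc"] <= 1)).all()
        assert (results["F"] >= 0).all()


class TestClassification:
    def test_injected_directions_and_classes_recovered(self, effect_corpus):
        results = la.run_word_tests(effect_corpus.rates, effect_corpus.authors,
                                    n_perm=1500, seed=4)
        truth = effect_corpus.truth
        words = list(effect_corpus.rates.words)
        by_word = results.set_index("word")
        male_word = words[3]     # d = +0.8
        female_word = words[7]   # d = -0.8
        inter_word = words[12]   # gap crosses zero at mid-period
        assert by_word.loc[male_word, "sex_sign"] == "male-preferred"
        assert by_word.loc[female_word, "sex_sign"] == "female-preferred"
        assert by_word.loc[male_word, "class"] in ("main-effect", "both")
        assert by_word.loc[inter_word, "class"] in ("interaction", "both")
        assert by_word.loc[inter_word, "p_fwc_interaction"] < 0.05

    def test_zero_coefficient_ties_to_female_with_warning(self):
        with pytest.warns(UserWarning, match="tie"):
            sign, _ = wt.classify_direction(
                np.array([0.0]), np.array([0.5]), np.array([0.5]))
        assert sign[0] == "female-preferred"


def test_country_level_alternative_model_runs(effect_corpus):
    results = la.run_word_tests(effect_corpus.rates, effect_corpus.authors,
                                n_perm=150, seed=5, geography="country")
    assert len(results) == effect_corpus.rates.n_words
    assert results["p_fwc"].between(0, 1).all()
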