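"""Affective scoring: Eq-style log-rank weighting, rank-sum contrasts,
timecourses, the sex-by-valence model, and category frequencies."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import litaffect as la
from litaffect import affect as aff

from conftest import male_mask


class TestAuthorAffectScore:
    def test_three_word_worked_example(self):
        # frequencies 10 > 5 > 1 -> ranks 3, 2, 1 -> weights log3, log2, 0
        score = la.author_affect_score([10.0, 5.0, 1.0], [8.0, 5.0, 2.0])
        expected = (8 * np.log(3) + 5 * np.log(2)) / (np.log(3) + np.log(2))
        assert score == pytest.approx(expected, abs=1e-12)
        assert score == pytest.approx(6.8394, abs=1e-3)

    def test_constant_ratings_return_the_constant_exactly(self):
        assert la.author_affect_score([9.0, 4.0, 2.0], [5.5, 5.5, 5.5]) == 5.5

    def test_word_order_invariance(self):
        f = np.array([10.0, 5.0, 1.0, 7.0])
        r = np.array([8.0, 5.0, 2.0, 6.0])
        perm = [2, 0, 3, 1]
        assert la.author_affect_score(f[perm], r[perm]) == pytest.approx(
            la.author_affect_score(f, r), abs=1e-12)

    def test_frequency_scaling_invariance(self):
        f = np.array([12.0, 3.0, 44.0, 7.0])
        r = np.array([1.0, 9.0, 4.0, 6.0])
        for c in (0.01, 3.0, 1e5):
            assert la.author_affect_score(c * f, r) == pytest.approx(
                la.author_affect_score(f, r), abs=1e-12)

    def test_tied_frequencies_reduce_to_unweighted_mean(self):
        r = np.array([2.0, 9.0, 4.0])
        assert la.author_affect_score([5.0, 5.0, 5.0], r) == pytest.approx(r.mean(), abs=1e-12)

    def test_unused_words_excluded_and_too_few_is_nan(self):
        with pytest.warns(UserWarning, match="fewer than two"):
            assert np.isnan(la.author_affect_score([3.0, 0.0, 0.0], [5.0, 1.0, 9.0]))


class TestSexMatchedRatings:
    def test_male_preferred_words_get_male_rater_ratings(self, tiny_norms):
        results = pd.DataFrame({
            "word": ["alpha", "beta"],
            "sex_sign": ["male-preferred", "female-preferred"],
        })
        out = la.sex_matched_ratings(results, tiny_norms)
        assert out["valence"]["male_preferred"].tolist() == [7.0]   # alpha, male raters
        assert out["valence"]["female_preferred"].tolist() == [2.0]  # beta, female raters
        assert out["n_matched"] == 2

    def test_words_absent_from_norms_counted(self, tiny_norms):
        results = pd.DataFrame({"word": ["alpha", "zzz"], "sex_sign": ["male-preferred"] * 2})
        out = la.sex_matched_ratings(results, tiny_norms)
        assert out["n_missing"] == 1

    def test_empty_intersection_is_an_error(self, tiny_norms):
        results = pd.DataFrame({"word": ["zzz"], "sex_sign": ["male-preferred"]})
        with pytest.raises(ValueError):
            la.sex_matched_ratings(results, tiny_norms)


def _enumeration_oracle(a, b):
    """Independent two-sided rank-sum p: full enumeration, 2*min-tail."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_obs = ranks[: len(a)].sum()
    ws = [ranks[list(idx)].sum() for idx in combinations(range(len(pooled)), len(a))]
    ws = np.array(ws)
    return min(1.0, 2 * min((ws <= w_obs + 1e-9).mean(), (ws >= w_obs - 1e-9).mean()))


class TestCompareGroups:
    def test_identical_samples(self):
        out = la.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["difference"] == 0.0
        assert out["p"] > 0.6

    def test_extreme_separation_matches_enumeration(self):
        out = la.compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert out["p"] == pytest.approx(_enumeration_oracle(
            np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])), abs=1e-12)
        assert out["p"] == pytest.approx(0.1, abs=1e-12)  # 2 * (1/20)

    def test_exactness_with_ties_all_small_splits(self):
        rng = np.random.default_rng(0)
        for _ in range(15):
            n = int(rng.integers(4, 11))
            n1 = int(rng.integers(2, n - 1))
            pooled = rng.integers(0, 4, size=n).astype(float)  # heavy ties
            if np.ptp(pooled) == 0:
                continue
            a, b = pooled[:n1], pooled[n1:]
            assert la.compare_groups(a, b)["p"] == pytest.approx(
                _enumeration_oracle(a, b), abs=1e-12)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=6), rng.normal(1, 1, size=5)
        o1, o2 = la.compare_groups(a, b), la.compare_groups(b, a)
        assert o1["difference"] == pytest.approx(-o2["difference"])
        assert o1["p"] == pytest.approx(o2["p"], abs=1e-12)

    def test_constant_pooled_sample_warns_p_one(self):
        with pytest.warns(UserWarning, match="constant"):
            out = la.compare_groups([2.0, 2.0], [2.0, 2.0])
        assert out["p"] == 1.0


class TestValenceArousalModel:
    @staticmethod
    def _simulate(n, beta_int, noise, seed):
        rng = np.random.default_rng(seed)
        sex = np.where(rng.random(n) < 0.6, 0.5, -0.5)
        val = rng.normal(5.5, 0.8, n)
        arо = 5.0 - 0.3 * sex - 0.55 * val + beta_int * sex * val + rng.normal(0, noise, n)
        return pd.DataFrame({
            "author_id": [f"a{i}" for i in range(n)],
            "sex": np.where(sex > 0, "male", "female"),
            "period": np.full(n, 1900),
            "valence_score": val,
            "arousal_score": arо,
        })

    def test_recovers_known_interaction(self):
        scores = self._simulate(1400, beta_int=0.4, noise=0.15, seed=2)
        model = la.valence_arousal_model(scores)
        beta = model["coefficients"].loc["sex:valence", "beta"]
        se = model["coefficients"].loc["sex:valence", "se"]
        assert abs(beta - 0.4) < 2 * se
        assert model["df_resid"] == 1396

    def test_noiseless_linear_data_adj_r2_one(self):
        scores = self._simulate(200, beta_int=0.4, noise=0.0, seed=3)
        model = la.valence_arousal_model(scores)
        assert model["adj_r2"] == pytest.approx(1.0, abs=1e-10)

    def test_single_sex_rejected(self):
        scores = self._simulate(100, 0.0, 0.1, 4)
        scores["sex"] = "male"
        with pytest.raises(ValueError):
            la.valence_arousal_model(scores)


class TestCategoryFrequencies:
    @staticmethod
    def _matrix_from_streams(streams):
        return la.compute_rates(streams)

    def test_pure_positive_author(self):
        m = self._matrix_from_streams({
            "a": ["joy", "glee", "joy"], "b": ["woe", "joy", "dread"],
            "c": ["joy", "woe"], "d": ["glee", "dread", "dread"]})
        authors = pd.DataFrame({"author_id": ["a", "b", "c", "d"],
                                "sex": ["male", "female", "male", "female"]})
        lex = la.CategoryLexicon.from_sets({"joy", "glee"}, {"woe", "dread"})
        table, _ = la.category_frequencies(m, authors, lex, seed=0)
        row = table.set_index("author_id")
        assert row.loc["a", "pos_pct"] == pytest.approx(100.0)
        assert row.loc["a", "neg_pct"] == pytest.approx(0.0)
        assert (table["pos_pct"] + table["neg_pct"] <= 100 + 1e-9).all()

    def test_counts_match_naive_token_scan(self):
        rng = np.random.default_rng(5)
        vocab = [f"t{i}" for i in range(12)]
        pos, neg = set(vocab[:4]), set(vocab[4:7])
        lex = la.CategoryLexicon.from_sets(pos, neg)
        for trial in range(20):
            streams = {f"a{i}": [vocab[j] for j in rng.integers(0, 12, size=rng.integers(20, 60))]
                       for i in range(4)}
            m = self._matrix_from_streams(streams)
            authors = pd.DataFrame({"author_id": list(streams),
                                    "sex": ["male", "female"] * 2})
            table, _ = la.category_frequencies(m, authors, lex, seed=0)
            for aid, toks in streams.items():
                expected_pos = 100 * sum(t in pos for t in toks) / len(toks)
                got = table.set_index("author_id").loc[aid, "pos_pct"]
                assert got == pytest.approx(expected_pos, abs=1e-9)

    def test_overlapping_lexicon_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            la.CategoryLexicon.from_sets({"joy"}, {"joy"})


class TestFullSentimentPath:
    def test_valence_gradient_recovered_through_scores(self):
        """Authors built to overuse high-valence words get higher valence
        scores (rank correlation between injected propensity and score)."""
        spec = la.EffectSpec(vocab_size=300, n_authors=500, seed=3)
        authors = la.generate_authors(spec)
        norms = la.generate_affective_norms(list(spec.words), seed=4)
        vm = norms["valence_m"].to_numpy()
        z = (vm - vm.mean()) / vm.std()
        rng = np.random.default_rng(5)
        loadings = rng.normal(0, 1.0, spec.n_authors)
        c = la.generate_rates(authors, spec, author_loadings=loadings, loading_scores=0.5 * z)
        scores = la.score_authors(c.rates, authors, norms)
        r = stats.spearmanr(loadings, scores["valence_score"]).statistic
        assert r > 0.8

    def test_timecourse_gap_closes_after_changepoint(self):
        """A valence gap present before 1900 and absent after shows up as a
        larger between-sex gap in early windows than late windows."""
        hits = 0
        for seed in range(4):
            spec = la.EffectSpec(vocab_size=200, n_authors=600, seed=70 + seed)
            authors = la.generate_authors(spec)
            norms = la.generate_affective_norms(list(spec.words), seed=71)
            vm = norms["valence_m"].to_numpy()
            z = (vm - vm.mean()) / vm.std()
            early = (authors["year_median"] < 1900).to_numpy()
            female = ~male_mask(authors)
            loadings = np.where(early & female, 0.8, 0.0)
            c = la.generate_rates(authors, spec, author_loadings=loadings,
                                  loading_scores=0.5 * z)
            scores = la.score_authors(c.rates, authors, norms)
            tc = la.affect.affect_timecourse(scores, "valence_score", n_boot=50, seed=seed)
            gap = tc.pivot_table(index="center", columns="sex", values="mean")
            gap = (gap["female"] - gap["male"]).dropna()
            early_gap = gap[gap.index < 1880].mean()
            late_gap = gap[gap.index > 1920].mean()
            hits += early_gap > late_gap
        assert hits >= 3

    def test_single_sex_window_skipped(self):
        scores = pd.DataFrame({
            "author_id": [f"a{i}" for i in range(12)],
            "sex": ["male"] * 6 + ["female"] * 6,
            "period": [1800] * 6 + [2000] * 6,
            "valence_score": np.linspace(4, 6, 12),
        })
        with pytest.warns(UserWarning, match="skipped"):
            tc = la.affect.affect_timecourse(scores, "valence_score",
                                             width=50, step=50, n_boot=20, seed=0)
        assert set(tc.loc[tc["center"] < 1900, "sex"]) == {"male"}
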