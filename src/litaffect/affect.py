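"""Affective characterization of words and authors.

Covers the sentiment side of the pipeline: sex-matched affective norms for
significant words, Wilcoxon rank-sum group contrasts, the log-rank-weighted
author affective score

    score = sum_w rating_w * log(rank_w) / sum_w log(rank_w)

(ranks ascending over the author's own word frequencies, so the most
frequent word carries the largest log-rank weight and the least frequent
used word carries zero), per-sex valence/arousal timecourses, the
arousal ~ sex * valence regression, and positive/negative category
frequencies.

Affective norms travel as a DataFrame with columns ``word, valence_m,
valence_f, arousal_m, arousal_f`` (ratings on a 1-9 scale from male and
female raters). A one-dimensional lexicon (e.g. happiness ratings) works
through the same operations with the arousal columns absent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .corpus import RateMatrix

NORM_COLUMNS = ["word", "valence_m", "valence_f", "arousal_m", "arousal_f"]


@dataclass(frozen=True)
class CategoryLexicon:
    """Disjoint positive and negative affect word sets."""

    positive: frozenset[str]
    negative: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.positive & self.negative
        if overlap:
            raise ValueError(f"positive/negative sets overlap: {sorted(overlap)[:5]}")

    @classmethod
    def from_sets(cls, positive, negative) -> "CategoryLexicon":
        return cls(frozenset(positive), frozenset(negative))


# ---------------------------------------------------------------------------
# Lexicon IO
# ---------------------------------------------------------------------------

def read_norms(path: str | Path) -> pd.DataFrame:
    norms = pd.read_csv(path, sep="\t", dtype={"word": str})
    missing = [c for c in NORM_COLUMNS[:3] if c not in norms.columns]
    if missing:
        raise ValueError(f"norms file {path} lacks columns {missing}")
    return norms


def write_norms(norms: pd.DataFrame, path: str | Path) -> None:
    norms.to_csv(path, sep="\t", index=False)


def read_category_lexicon(path: str | Path) -> CategoryLexicon:
    lex = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    bad = set(lex["category"]) - {"positive", "negative"}
    if bad:
        raise ValueError(f"unknown categories in {path}: {sorted(bad)}")
    return CategoryLexicon.from_sets(
        lex.loc[lex["category"] == "positive", "word"],
        lex.loc[lex["category"] == "negative", "word"],
    )


def write_category_lexicon(lexicon: CategoryLexicon, path: str | Path) -> None:
    rows = [{"word": w, "category": "positive"} for w in sorted(lexicon.positive)]
    rows += [{"word": w, "category": "negative"} for w in sorted(lexicon.negative)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sex-matched ratings for significant words
# ---------------------------------------------------------------------------

def sex_matched_ratings(
    results: pd.DataFrame,
    norms: pd.DataFrame,
    dimensions: Sequence[str] = ("valence", "arousal"),
) -> dict:
    """Assign rater-sex-matched ratings to significant words.

    Male-preferred words get male-rater ratings, female-preferred words get
    female-rater ratings. ``results`` is the per-word test table (needs
    ``word`` and ``sex_sign``; pass only significant rows). Returns, per
    dimension, the two rating samples plus bookkeeping counts.
    """
    normed = norms.set_index("word")
    words = results["word"].tolist()
    in_norms = [w for w in words if w in normed.index]
    if not in_norms:
        raise ValueError("no significant word appears in the norms lexicon")
    sub = results.set_index("word").loc[in_norms]
    out: dict = {
        "n_significant": len(words),
        "n_matched": len(in_norms),
        "n_missing": len(words) - len(in_norms),
    }
    male_words = sub.index[sub["sex_sign"] == "male-preferred"]
    female_words = sub.index[sub["sex_sign"] == "female-preferred"]
    for dim in dimensions:
        male_sample = normed.loc[male_words, f"{dim}_m"].to_numpy(dtype=float)
        female_sample = normed.loc[female_words, f"{dim}_f"].to_numpy(dtype=float)
        out[dim] = {"male_preferred": male_sample, "female_preferred": female_sample}
    return out


# ---------------------------------------------------------------------------
# Group comparison (Wilcoxon rank-sum)
# ---------------------------------------------------------------------------

def exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments.

    Handles ties (average ranks). Two-sided convention: twice the smaller
    tail probability of the first group's rank sum, capped at 1 (equality
    included in both tails).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n, n1 = len(pooled), len(a)
    w_obs = ranks[:n1].sum()
    total = comb(n, n1)
    le = ge = 0
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    return min(1.0, 2 * min(le, ge) / total)


def compare_groups(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = 0,
    exact_max_n: int = 20,
) -> dict:
    """Difference of means with a 95% bootstrap CI and a two-sided Wilcoxon
    rank-sum p-value (exact by enumeration when the combined sample is
    small, normal approximation with tie correction otherwise)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least two observations")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("constant pooled sample; rank-sum p set to 1", stacklevel=2)
        p = 1.0
        method = "degenerate"
    elif len(pooled) <= exact_max_n:
        p = exact_rank_sum_p(a, b)
        method = "exact-enumeration"
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
        method = "normal-approximation"
    rng = np.random.default_rng(seed)
    diffs = (
        a[rng.integers(0, len(a), size=(n_boot, len(a)))].mean(axis=1)
        - b[rng.integers(0, len(b), size=(n_boot, len(b)))].mean(axis=1)
    )
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return {
        "difference": float(a.mean() - b.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "p": p,
        "method": method,
        "n_a": len(a),
        "n_b": len(b),
    }


# ---------------------------------------------------------------------------
# Author affective score (log-rank-weighted mean rating)
# ---------------------------------------------------------------------------

def author_affect_score(frequencies: np.ndarray, ratings: np.ndarray) -> float:
    """Log-rank-weighted mean affective rating of one author's lexicon use.

    ``frequencies`` and ``ratings`` are aligned over lexicon words; words
    the author never uses (frequency 0) or without a rating are excluded.
    Ranks are ascending over the author's own frequencies with average
    ranks for ties, so tied-frequency input reduces to the unweighted mean
    and scaling all frequencies by a constant leaves the score unchanged.
    Returns NaN (with a warning) when fewer than two usable words remain.
    """
    f = np.asarray(frequencies, dtype=float)
    r = np.asarray(ratings, dtype=float)
    if f.shape != r.shape:
        raise ValueError("frequencies and ratings must align")
    used = (f > 0) & ~np.isnan(r)
    if used.sum() < 2:
        warnings.warn("fewer than two usable lexicon words; score is NaN", stacklevel=2)
        return float("nan")
    r_used = r[used]
    if np.all(r_used == r_used[0]):
        return float(r_used[0])  # weighted mean of a constant, exactly
    ranks = stats.rankdata(f[used])
    w = np.log(ranks)
    return float((r_used * w).sum() / w.sum())


def score_authors(
    matrix: RateMatrix,
    authors: pd.DataFrame,
    norms: pd.DataFrame,
    stoplist: Sequence[str] = (),
    dimensions: Sequence[str] = ("valence", "arousal"),
) -> pd.DataFrame:
    """Per-author affective scores over the norms lexicon, sex-matched:
    male authors are scored with male-rater ratings, female authors with
    female-rater ratings. Returns author_id, sex, period and one
    ``<dimension>_score`` column per dimension."""
    stop = set(stoplist)
    normed = norms[~norms["word"].isin(stop)].set_index("word")
    windex = matrix.word_index()
    shared = [w for w in normed.index if w in windex]
    if len(shared) < 2:
        raise ValueError("norms lexicon shares fewer than two words with the corpus")
    cols = [windex[w] for w in shared]
    freqs = matrix.rates[:, cols]
    rating_cols = {
        dim: {
            "male": normed.loc[shared, f"{dim}_m"].to_numpy(dtype=float),
            "female": normed.loc[shared, f"{dim}_f"].to_numpy(dtype=float),
        }
        for dim in dimensions
    }
    rows = []
    for i, row in enumerate(authors.itertuples(index=False)):
        entry = {"author_id": row.author_id, "sex": row.sex, "period": row.year_median}
        for dim in dimensions:
            entry[f"{dim}_score"] = author_affect_score(freqs[i], rating_cols[dim][row.sex])
        rows.append(entry)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Timecourses and the sex x valence model
# ---------------------------------------------------------------------------

def affect_timecourse(
    scores: pd.DataFrame,
    value: str = "valence_score",
    width: float = 50.0,
    step: float = 10.0,
    n_boot: int = 1000,
    min_n: int = 3,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-sex sliding-window mean of an affective score with 95% bootstrap
    CIs across authors. Windows where a sex has fewer than ``min_n``
    authors skip that sex with a warning."""
    from .semantic_map import window_centers  # shared window convention

    years = scores["period"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    skipped = 0
    for c in window_centers(years, width, step):
        inside = np.abs(years - c) <= width / 2
        for sex in ("male", "female"):
            vals = scores.loc[inside & (scores["sex"] == sex).to_numpy(), value].dropna().to_numpy()
            if len(vals) < min_n:
                skipped += 1
                continue
            boots = vals[rng.integers(0, len(vals), size=(n_boot, len(vals)))].mean(axis=1)
            lo, hi = np.percentile(boots, [2.5, 97.5])
            rows.append({"center": c, "sex": sex, "mean": float(vals.mean()),
                         "ci_low": float(lo), "ci_high": float(hi), "n": len(vals)})
    if skipped:
        warnings.warn(f"skipped {skipped} (window, sex) cells with fewer than {min_n} authors",
                      stacklevel=2)
    if not rows:
        raise ValueError("no window had enough authors")
    return pd.DataFrame(rows)


def valence_arousal_model(scores: pd.DataFrame) -> dict:
    """OLS fit of arousal ~ intercept + sex + valence + sex:valence.

    Sex is coded -0.5 (female) / +0.5 (male). Returns coefficient table
    (beta, SE, t, p) and adjusted R^2, plus the statsmodels results object
    under ``"fit"``.
    """
    data = scores.dropna(subset=["valence_score", "arousal_score"])
    if len(data) < 10:
        raise ValueError("need at least 10 authors with both scores")
    if len(set(data["sex"])) < 2:
        raise ValueError("both sexes must be present")
    sex = np.where(data["sex"].to_numpy() == "male", 0.5, -0.5)
    val = data["valence_score"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(data)), sex, val, sex * val])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant valence or single sex?)")
    fit = sm.OLS(data["arousal_score"].to_numpy(dtype=float), X).fit()
    names = ["intercept", "sex", "valence", "sex:valence"]
    table = pd.DataFrame(
        {"beta": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}, index=names
    )
    return {"coefficients": table, "adj_r2": float(fit.rsquared_adj),
            "df_resid": int(fit.df_resid), "n": len(data), "fit": fit}


# ---------------------------------------------------------------------------
# Positive/negative category frequencies
# ---------------------------------------------------------------------------

def category_frequencies(
    matrix: RateMatrix,
    authors: pd.DataFrame,
    lexicon: CategoryLexicon,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-author percentage of tokens in the positive and negative sets,
    with group contrasts.

    pos_pct(a) = 100 * sum of positive-word counts / token total; likewise
    negative. Zero-token authors get missing percentages. The contrasts are
    Wilcoxon rank-sum tests of positive vs negative frequency across
    authors and of male vs female within each category.
    """
    windex = matrix.word_index()
    counts = matrix.rates * matrix.token_totals[:, None] / 1e6
    def pct(words: frozenset[str]) -> np.ndarray:
        cols = [windex[w] for w in words if w in windex]
        if not cols:
            return np.zeros(matrix.n_authors)
        total = counts[:, cols].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(matrix.token_totals > 0,
                            100.0 * total / matrix.token_totals, np.nan)

    table = pd.DataFrame(
        {
            "author_id": matrix.author_ids,
            "sex": authors["sex"].to_numpy(),
            "pos_pct": pct(lexicon.positive),
            "neg_pct": pct(lexicon.negative),
        }
    )
    ok = table.dropna(subset=["pos_pct", "neg_pct"])
    male = ok["sex"] == "male"
    contrasts = {
        "positive_vs_negative": compare_groups(ok["pos_pct"], ok["neg_pct"], seed=seed),
        "positive_male_vs_female": compare_groups(
            ok.loc[male, "pos_pct"], ok.loc[~male, "pos_pct"], seed=seed
        ),
        "negative_male_vs_female": compare_groups(
            ok.loc[male, "neg_pct"], ok.loc[~male, "neg_pct"], seed=seed
        ),
    }
    return table, contrasts
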