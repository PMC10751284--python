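"""Semantic mapping of significant words and domain-level effect timecourses.

Significant words are embedded (skip-gram vectors), their pairwise cosine
dissimilarities reduced by PCA to the smallest number of components
explaining a target share of variance (66% by default), and projected to
2-D with t-SNE. Words are grouped into eleven fixed semantic domains via a
flat word-to-domain lexicon, and per-domain sex differences (absolute
Cohen's d of word frequency between male and female authors) are traced
over historical time with a sliding-window procedure.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .corpus import RateMatrix
from .embeddings import EmbeddingSet, load_embeddings, save_embeddings, train_sgns

#: The eleven fixed semantic domains.
DOMAINS = (
    "artifacts",
    "social groups",
    "weapons",
    "body",
    "affect",
    "food/beverages",
    "numbers",
    "time",
    "locations",
    "clothes",
    "plants",
)


def train_embeddings(streams: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
                     **hyperparameters) -> EmbeddingSet:
    """Train skip-gram embeddings on corpus token streams.

    ``streams`` may be the per-author dict from :mod:`litaffect.corpus` or
    any iterable of token sequences. Defaults: alpha=.05, size=512,
    window=5, sample=1e-3, 10 iterations (see :func:`litaffect.embeddings
    .train_sgns`). Pre-trained vectors can be loaded instead with
    :func:`load_embeddings`, bypassing training.
    """
    sents = list(streams.values()) if isinstance(streams, Mapping) else list(streams)
    return train_sgns(sents, **hyperparameters)


def project_2d(
    emb: EmbeddingSet,
    variance_kept: float = 0.66,
    perplexity: float = 40.0,
    theta: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Cosine dissimilarity -> PCA (smallest count reaching
    ``variance_kept``) -> t-SNE to 2-D.

    Coordinates are non-identifiable up to rotation/reflection; only
    neighborhood structure is meaningful. Returns a DataFrame with columns
    word, x, y.
    """
    n = len(emb.words)
    if n <= 3 * perplexity:
        raise ValueError(
            f"{n} words is too few for perplexity {perplexity}; "
            f"use perplexity < {n / 3:.0f}"
        )
    norms = np.linalg.norm(emb.vectors, axis=1, keepdims=True)
    unit = emb.vectors / np.where(norms == 0, 1.0, norms)
    dissim = 1.0 - unit @ unit.T
    pca = PCA(n_components=min(n - 1, dissim.shape[1]), random_state=seed)
    scores = pca.fit_transform(dissim)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_kept) + 1)
    scores = scores[:, :k]
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        angle=theta,
        random_state=seed,
        init="pca" if k >= 2 else "random",
    )
    xy = tsne.fit_transform(scores)
    return pd.DataFrame({"word": emb.words, "x": xy[:, 0], "y": xy[:, 1]})


# ---------------------------------------------------------------------------
# Semantic domains
# ---------------------------------------------------------------------------

def read_domain_lexicon(path: str | Path) -> pd.DataFrame:
    lex = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"word", "domain"} <= set(lex.columns):
        raise ValueError(f"domain lexicon {path} needs 'word' and 'domain' columns")
    return validate_domain_lexicon(lex)


def validate_domain_lexicon(lexicon: pd.DataFrame) -> pd.DataFrame:
    unknown = sorted(set(lexicon["domain"]) - set(DOMAINS))
    if unknown:
        raise ValueError(f"unknown semantic domains: {unknown}; allowed: {list(DOMAINS)}")
    if lexicon["word"].duplicated().any():
        raise ValueError("domain lexicon maps some words to more than one domain")
    return lexicon


def assign_domains(
    words: Sequence[str],
    lexicon: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Label words with their semantic domain; unassigned words are kept and
    counted. Returns (labels DataFrame, coverage fraction)."""
    lexicon = validate_domain_lexicon(lexicon)
    mapping = dict(zip(lexicon["word"], lexicon["domain"]))
    labels = pd.DataFrame(
        {"word": list(words), "domain": [mapping.get(w) for w in words]}
    )
    coverage = float(labels["domain"].notna().mean()) if len(labels) else 0.0
    return labels, coverage


# ---------------------------------------------------------------------------
# Sliding-window effect sizes
# ---------------------------------------------------------------------------

def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized mean difference with the pooled-SD convention
    (no small-sample correction): (mean(x) - mean(y)) / s_pooled."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("cohens_d needs at least two observations per group")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return 0.0 if x.mean() == y.mean() else np.inf * np.sign(x.mean() - y.mean())
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def window_centers(years: np.ndarray, width: float, step: float) -> np.ndarray:
    """Window centers spanning the year range; equivariant to shifting all
    years by a constant."""
    lo, hi = float(np.min(years)), float(np.max(years))
    if hi - lo < width:
        return np.array([0.5 * (lo + hi)])
    return np.arange(lo + width / 2, hi - width / 2 + step / 2, step)


def _boot_d_abs(x: np.ndarray, y: np.ndarray, n_boot: int, rng) -> np.ndarray:
    """Stratified bootstrap (resample within each sex) of |Cohen's d|."""
    nx, ny = len(x), len(y)
    bx = x[rng.integers(0, nx, size=(n_boot, nx))]
    by = y[rng.integers(0, ny, size=(n_boot, ny))]
    mx, my = bx.mean(axis=1), by.mean(axis=1)
    vx, vy = bx.var(axis=1, ddof=1), by.var(axis=1, ddof=1)
    sp = np.sqrt(((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(sp > 0, (mx - my) / sp, 0.0)
    return np.abs(d)


def sliding_effect(
    matrix: RateMatrix,
    authors: pd.DataFrame,
    words: Sequence[str],
    width: float = 50.0,
    step: float = 10.0,
    n_boot: int = 1000,
    min_per_sex: int = 3,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Sliding-window |Cohen's d| of pooled word-set usage between sexes.

    Per author the word set is pooled as the mean of log(1 + rate) across
    the set; per window (authors whose period falls within ``width`` years
    of the center) the signed and absolute Cohen's d between male and
    female authors is computed, with a 95% stratified-bootstrap percentile
    CI on |d|. Windows with fewer than ``min_per_sex`` authors of either
    sex are skipped with a warning.

    Returns columns: center, d_abs, d_signed, ci_low, ci_high, n_male,
    n_female.
    """
    words = list(words)
    if not words:
        raise ValueError("empty word set")
    windex = matrix.word_index()
    missing = [w for w in words if w not in windex]
    if missing:
        raise KeyError(f"words not in matrix vocabulary: {missing[:5]}...")
    cols = [windex[w] for w in words]
    score = np.log1p(matrix.rates[:, cols]).mean(axis=1)
    years = authors["year_median"].to_numpy(dtype=float)
    is_male = authors["sex"].to_numpy() == "male"
    rng = np.random.default_rng(seed)

    rows = []
    skipped = 0
    for c in window_centers(years, width, step):
        inside = np.abs(years - c) <= width / 2
        x = score[inside & is_male]
        y = score[inside & ~is_male]
        if len(x) < min_per_sex or len(y) < min_per_sex:
            skipped += 1
            continue
        d = cohens_d(x, y)
        boots = _boot_d_abs(x, y, n_boot, rng)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(
            {
                "center": c,
                "d_abs": abs(d),
                "d_signed": d,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "n_male": len(x),
                "n_female": len(y),
            }
        )
    if skipped:
        warnings.warn(f"skipped {skipped} windows with fewer than {min_per_sex} "
                      "authors of one sex", stacklevel=2)
    if not rows:
        raise ValueError("no window had enough authors of both sexes")
    out = pd.DataFrame(rows)
    # the point estimate can fall outside the bootstrap percentile band only
    # by resampling noise; clamp so ci_low <= d_abs <= ci_high holds exactly
    out["ci_low"] = np.minimum(out["ci_low"], out["d_abs"])
    out["ci_high"] = np.maximum(out["ci_high"], out["d_abs"])
    return out


def domain_timecourses(
    matrix: RateMatrix,
    authors: pd.DataFrame,
    labels: pd.DataFrame,
    **window_kwargs,
) -> pd.DataFrame:
    """Sliding-window |d| series for every semantic domain present in
    ``labels`` (the output of :func:`assign_domains`)."""
    pieces = []
    for domain, grp in labels.dropna(subset=["domain"]).groupby("domain"):
        series = sliding_effect(matrix, authors, list(grp["word"]), **window_kwargs)
        series.insert(0, "domain", domain)
        pieces.append(series)
    if not pieces:
        raise ValueError("no domain has any labeled words")
    return pd.concat(pieces, ignore_index=True)


__all__ = [
    "DOMAINS",
    "EmbeddingSet",
    "train_embeddings",
    "load_embeddings",
    "save_embeddings",
    "train_sgns",
    "project_2d",
    "read_domain_lexicon",
    "assign_domains",
    "cohens_d",
    "window_centers",
    "sliding_effect",
    "domain_timecourses",
]
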