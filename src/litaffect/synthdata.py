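"""Synthetic corpora, metadata, and lexicons with known statistical structure.

Every downstream stage of the pipeline (stylometry, permutation GLMs,
timecourses, sentiment scoring) is testable without any real book corpus:
this module generates an author table, an authors-by-words rate matrix with
injected sex and sex-by-period effects of known size, rater-sex-specific
affective norms, and positive/negative category lexicons.

Noise model
-----------
Base word probabilities are Zipfian with a configurable exponent. Each
author-by-word count is a Poisson draw around a lognormal intensity
(a negative-binomial-like overdispersed model): on the log scale the
intensity is ``log p_w + effects + eps`` with ``eps ~ N(0, overdispersion^2)``.
Group effects are injected as standardized mean shifts on the log-rate
scale; an injected Cohen's d is calibrated against the delta-method total
standard deviation of the observed log count, ``sqrt(sigma^2 + 1/m_w)`` with
``m_w`` the word's expected count, so the empirical d of log rates matches
the nominal d. Vocabulary counts cover only a fraction of each author's
tokens (``vocab_coverage``), as in real corpora, which keeps row rate sums
below one million.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import RateMatrix, SEXES

CONTINENTS = ("Europe", "North America", "Asia", "South America", "Africa", "Oceania")
# Rough continent mix of a world-literature corpus; configurable per spec.
CONTINENT_PROBS = (0.45, 0.25, 0.15, 0.06, 0.05, 0.04)


@dataclass(frozen=True)
class EffectSpec:
    """Ground truth for a synthetic corpus.

    Parameters
    ----------
    vocab_size, n_authors : int
        Matrix dimensions.
    sex_ratio : float
        Fraction of male authors in (0, 1) exclusive unless exactly 0/1 is
        requested for degenerate cases.
    period_range : (int, int)
        Publication-year range; author periods are uniform over it.
    sex_effect_words : mapping word index -> signed Cohen's d
        Positive d = male-preferred (higher male log rate).
    interaction_words : mapping word index -> per-year slope of the sex gap
        The male-minus-female gap (in d units) drifts linearly across the
        period range, crossing its ``sex_effect`` value at the mid-period.
    continent_effect_words : mapping word index -> {continent: offset in d units}
    zipf_exponent : float
        Exponent of the Zipfian base frequencies.
    overdispersion : float
        SD of the lognormal author-by-word noise on the log scale.
    tokens_per_author : int
        Expected total tokens per author (the corpus this emulates averages
        ~180k words per author).
    vocab_coverage : float
        Fraction of an author's tokens covered by the vocabulary.
    translated_fraction : float
        Probability an author is marked as translated (~0.33 in the corpus
        this emulates).
    seed : int
        Base seed; identical spec + seed gives bit-identical outputs.
    """

    vocab_size: int = 1000
    n_authors: int = 500
    sex_ratio: float = 871 / 1365
    period_range: tuple[int, int] = (1719, 2020)
    sex_effect_words: Mapping[int, float] = field(default_factory=dict)
    interaction_words: Mapping[int, float] = field(default_factory=dict)
    continent_effect_words: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    zipf_exponent: float = 1.1
    overdispersion: float = 0.4
    tokens_per_author: int = 180_000
    vocab_coverage: float = 0.5
    translated_fraction: float = 0.33
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size < 1:
            raise ValueError("vocab_size must be positive")
        if self.n_authors < 1:
            raise ValueError("n_authors must be positive")
        if not (0 <= self.sex_ratio <= 1):
            raise ValueError(f"sex_ratio must be in [0, 1], got {self.sex_ratio}")
        if not self.period_range[0] < self.period_range[1]:
            raise ValueError(f"period_range must increase, got {self.period_range}")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be nonnegative")
        if not (0 < self.vocab_coverage <= 1):
            raise ValueError("vocab_coverage must be in (0, 1]")
        for name in ("sex_effect_words", "interaction_words", "continent_effect_words"):
            bad = [w for w in getattr(self, name) if not (0 <= w < self.vocab_size)]
            if bad:
                raise ValueError(f"{name} indices outside vocabulary: {bad}")

    @property
    def null_words(self) -> set[int]:
        """Words carrying no injected effect of any kind."""
        touched = (
            set(self.sex_effect_words)
            | set(self.interaction_words)
            | set(self.continent_effect_words)
        )
        return set(range(self.vocab_size)) - touched

    @property
    def words(self) -> np.ndarray:
        # purely alphabetic names (base-26), so synthetic words survive
        # tokenization when materialized as text; zero-padding keeps
        # lexicographic order equal to index order
        return np.array([_word_name(i) for i in range(self.vocab_size)], dtype=object)


def _word_name(i: int, width: int = 4) -> str:
    chars = []
    for _ in range(width):
        i, r = divmod(i, 26)
        chars.append(chr(ord("a") + r))
    return "w" + "".join(reversed(chars))


@dataclass
class SyntheticCorpus:
    """A generated corpus bundle: metadata, rates, and the ground truth."""

    authors: pd.DataFrame
    rates: RateMatrix
    truth: EffectSpec
    raw_texts: dict[str, list[str]] | None = None


def paper_shape_spec(seed: int = 0, vocab_size: int = 2000, **overrides) -> EffectSpec:
    """An EffectSpec matching the shape of the real corpus: ~1365 authors,
    sex ratio 871:494, periods 1719-2020, with a mix of main-effect,
    interaction, and null words for end-to-end runs."""
    rng = np.random.default_rng(seed + 101)
    n_main, n_inter = 60, 20
    picks = rng.choice(vocab_size, size=n_main + n_inter, replace=False)
    sex_effects = {int(w): float(d) for w, d in zip(
        picks[:n_main], rng.choice([-0.5, -0.3, 0.3, 0.5], size=n_main))}
    span = 2020 - 1719
    inter = {int(w): float(s) for w, s in zip(
        picks[n_main:], rng.choice([-0.8 / span, 0.8 / span], size=n_inter))}
    kwargs = dict(
        vocab_size=vocab_size,
        n_authors=1365,
        sex_ratio=871 / 1365,
        period_range=(1719, 2020),
        sex_effect_words=sex_effects,
        interaction_words=inter,
        seed=seed,
    )
    kwargs.update(overrides)
    return EffectSpec(**kwargs)


# ---------------------------------------------------------------------------
# Authors
# ---------------------------------------------------------------------------

def generate_authors(
    spec: EffectSpec,
    continents: Sequence[str] = CONTINENTS,
    continent_probs: Sequence[float] = CONTINENT_PROBS,
) -> pd.DataFrame:
    """Draw the author table: sex (binomial at ``sex_ratio``), periods
    uniform over ``period_range``, continents and translation flags from
    categorical distributions. Deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_authors
    sex = np.where(rng.random(n) < spec.sex_ratio, "male", "female")
    years = rng.integers(spec.period_range[0], spec.period_range[1] + 1, size=n)
    probs = np.asarray(continent_probs, dtype=float)
    probs = probs / probs.sum()
    continent = rng.choice(np.array(continents, dtype=object), size=n, p=probs)
    # Synthetic countries: a handful per continent so the country-level
    # alternative model has something to chew on.
    country_idx = rng.integers(0, 5, size=n)
    country = np.array([f"{c[:3].upper()}-{k}" for c, k in zip(continent, country_idx)], dtype=object)
    translated = np.where(rng.random(n) < spec.translated_fraction, "translated", "original")
    table = pd.DataFrame(
        {
            "author_id": [f"A{i:05d}" for i in range(n)],
            "sex": sex,
            "country": country,
            "continent": continent,
            "year_median": years,
            "translated": translated,
            "book_files": [f"A{i:05d}.txt" for i in range(n)],
        }
    )
    return table


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def _base_probabilities(spec: EffectSpec) -> np.ndarray:
    ranks = np.arange(1, spec.vocab_size + 1, dtype=float)
    p = ranks ** -spec.zipf_exponent
    return p / p.sum()


def expected_log_rate_sd(spec: EffectSpec) -> np.ndarray:
    """Delta-method SD of observed log counts per word:
    sqrt(overdispersion^2 + 1/m_w), m_w = expected count."""
    p = _base_probabilities(spec)
    m = p * spec.tokens_per_author * spec.vocab_coverage
    # Poisson floor: E[1/count] for a lognormal-mixed Poisson is roughly
    # exp(sigma^2/2)/m by the delta method
    return np.sqrt(spec.overdispersion**2 + np.exp(spec.overdispersion**2 / 2) / m)


def generate_rates(
    authors: pd.DataFrame,
    spec: EffectSpec,
    author_loadings: np.ndarray | None = None,
    loading_scores: np.ndarray | None = None,
) -> SyntheticCorpus:
    """Generate the rate matrix with the spec's injected effects.

    ``author_loadings``/``loading_scores`` optionally add a per-author
    gradient: author ``a``'s log intensity for word ``w`` gains
    ``author_loadings[a] * loading_scores[w]``, which lets tests inject e.g.
    a known preference for high-valence words.
    """
    if len(authors) != spec.n_authors:
        raise ValueError("author table does not match spec.n_authors")
    rng = np.random.default_rng(spec.seed + 1)
    n, v = spec.n_authors, spec.vocab_size
    p = _base_probabilities(spec)
    sd_total = expected_log_rate_sd(spec)

    sex_code = np.where(authors["sex"].to_numpy() == "male", 0.5, -0.5)
    years = authors["year_median"].to_numpy(dtype=float)
    mid = 0.5 * (spec.period_range[0] + spec.period_range[1])

    # male-minus-female gap per (author-year, word), in d units
    gap = np.zeros((n, v))
    for w, d in spec.sex_effect_words.items():
        gap[:, w] += d
    for w, slope in spec.interaction_words.items():
        gap[:, w] += slope * (years - mid)
    shift = sex_code[:, None] * gap * sd_total[None, :]

    for w, offsets in spec.continent_effect_words.items():
        cont = authors["continent"].to_numpy()
        for c, off in offsets.items():
            shift[cont == c, w] += off * sd_total[w]

    if author_loadings is not None:
        if loading_scores is None:
            raise ValueError("author_loadings requires loading_scores")
        shift = shift + np.outer(np.asarray(author_loadings, float),
                                 np.asarray(loading_scores, float) * sd_total)

    eps = rng.normal(0.0, spec.overdispersion, size=(n, v))
    log_intensity = np.log(p)[None, :] + shift + eps
    mean_counts = np.exp(log_intensity) * spec.tokens_per_author * spec.vocab_coverage
    counts = rng.poisson(mean_counts)

    # Fixed denominator so a word's rate is independent of the other words'
    # noise (a fluctuating total would attenuate injected effects); the
    # non-vocabulary token mass absorbs the difference. The max() guard keeps
    # row rate sums strictly below one million even in extreme draws.
    vocab_tokens = counts.sum(axis=1)
    token_totals = np.maximum(spec.tokens_per_author, vocab_tokens + 1).astype(np.int64)
    rates = counts / token_totals[:, None] * 1e6
    matrix = RateMatrix(
        rates=rates,
        words=spec.words,
        author_ids=authors["author_id"].to_numpy(dtype=object),
        token_totals=token_totals,
    )
    return SyntheticCorpus(authors=authors, rates=matrix, truth=spec)


def generate_corpus(spec: EffectSpec, **rate_kwargs) -> SyntheticCorpus:
    """Convenience: authors + rates from one spec."""
    return generate_rates(generate_authors(spec), spec, **rate_kwargs)


def generate_token_streams(corpus: SyntheticCorpus, filler: str = "the") -> dict[str, list[str]]:
    """Materialize token streams consistent with the rate matrix.

    Each author's stream holds every vocabulary word repeated its count, plus
    ``filler`` tokens making up the non-vocabulary mass, shuffled. Recomputing
    rates from these streams (restricted to the vocabulary) reproduces the
    matrix exactly. Streams are attached to ``corpus.raw_texts``.
    """
    rng = np.random.default_rng(corpus.truth.seed + 2)
    m = corpus.rates
    counts = np.rint(m.rates * m.token_totals[:, None] / 1e6).astype(np.int64)
    streams: dict[str, list[str]] = {}
    for i, author in enumerate(m.author_ids):
        toks = np.repeat(m.words, counts[i])
        n_fill = int(m.token_totals[i] - counts[i].sum())
        if n_fill > 0:
            toks = np.concatenate([toks, np.array([filler] * n_fill, dtype=object)])
        rng.shuffle(toks)
        streams[author] = list(toks)
    corpus.raw_texts = streams
    return streams


# ---------------------------------------------------------------------------
# Lexicons
# ---------------------------------------------------------------------------

def generate_affective_norms(
    vocab: Sequence[str],
    seed: int = 0,
    rater_sex_gap: tuple[float, float] = (0.0, 0.0),
    valence_arousal_corr: float = -0.4,
    valence_mean: float = 5.2,
    valence_sd: float = 1.1,
    arousal_mean: float = 4.2,
    arousal_sd: float = 0.9,
    rater_noise_sd: float = 0.15,
) -> pd.DataFrame:
    """Synthetic affective norms on a 1-9 scale, with separate male- and
    female-rater columns.

    A latent (valence, arousal) pair per word is drawn from a bivariate
    normal with the configured correlation; the male column adds half the
    ``rater_sex_gap`` (valence gap, arousal gap) and the female column
    subtracts it, each plus independent rater noise; results are clipped
    to [1, 9].
    """
    if len(vocab) == 0:
        raise ValueError("vocab must be non-empty")
    rng = np.random.default_rng(seed)
    n = len(vocab)
    cov = np.array(
        [
            [valence_sd**2, valence_arousal_corr * valence_sd * arousal_sd],
            [valence_arousal_corr * valence_sd * arousal_sd, arousal_sd**2],
        ]
    )
    latent = rng.multivariate_normal([valence_mean, arousal_mean], cov, size=n)
    gap = np.asarray(rater_sex_gap, dtype=float)
    noise = lambda: rng.normal(0.0, rater_noise_sd, size=(n, 2)) if rater_noise_sd > 0 else 0.0
    male = np.clip(latent + gap / 2 + noise(), 1, 9)
    female = np.clip(latent - gap / 2 + noise(), 1, 9)
    return pd.DataFrame(
        {
            "word": list(vocab),
            "valence_m": male[:, 0],
            "valence_f": female[:, 0],
            "arousal_m": male[:, 1],
            "arousal_f": female[:, 1],
        }
    )


def generate_category_lexicon(
    vocab: Sequence[str],
    n_pos: int = 620,
    n_neg: int = 743,
    seed: int = 0,
) -> tuple[set[str], set[str]]:
    """Disjoint positive/negative word sets of exactly the requested sizes
    (620 and 743 by default, the sizes of a standard affect-category
    lexicon)."""
    if n_pos < 0 or n_neg < 0:
        raise ValueError("set sizes must be nonnegative")
    if n_pos + n_neg > len(vocab):
        raise ValueError(
            f"requested {n_pos}+{n_neg} words but vocabulary holds {len(vocab)}"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(np.asarray(vocab, dtype=object), size=n_pos + n_neg, replace=False)
    return set(picks[:n_pos]), set(picks[n_pos:])


def generate_domain_lexicon(
    vocab: Sequence[str],
    domains: Sequence[str],
    coverage: float = 0.85,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign a random semantic domain to ~``coverage`` of the vocabulary."""
    rng = np.random.default_rng(seed)
    mask = rng.random(len(vocab)) < coverage
    words = np.asarray(vocab, dtype=object)[mask]
    labels = rng.choice(np.asarray(domains, dtype=object), size=len(words))
    return pd.DataFrame({"word": words, "domain": labels})
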