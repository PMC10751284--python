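"""Corpus ingestion: author metadata, tokenization, and the authors-by-words rate matrix.

The central container is :class:`RateMatrix`, an authors-by-words matrix of
occurrences per million tokens. Rows are authors (one pooled token stream per
author across all of their books), columns are vocabulary words that survive a
prevalence filter: a word is kept when it occurs in at least a given share
(default 10%) of male *or* female authors.

Metadata travels as a pandas DataFrame (the "author table") with columns
``author_id, sex, country, continent, year_median, translated, book_files``;
``year_median`` is the median publication year over the author's books and
serves as the author's historical period.
"""

from __future__ import annotations

import logging
import re
import warnings
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

log = logging.getLogger(__name__)

#: Default token pattern: maximal runs of Unicode letters, allowing internal
#: apostrophes and hyphens ("don't", "mother-in-law"); a maximal run of digits
#: is its own token. Case is folded with str.casefold (locale-independent).
TOKEN_RE = re.compile(r"[^\W\d_]+(?:['’-][^\W\d_]+)*|\d+", re.UNICODE)

METADATA_COLUMNS = [
    "author_id",
    "sex",
    "country",
    "continent",
    "year_median",
    "translated",
    "book_files",
]

SEXES = ("male", "female")


def tokenize(text: str, pattern: re.Pattern = TOKEN_RE) -> list[str]:
    """Lowercase and tokenize ``text``.

    Pure function of the text: the same input yields the same tokens on every
    platform and locale. The token rule is configurable via ``pattern``.
    """
    return pattern.findall(text.casefold())


@dataclass
class RateMatrix:
    """Authors-by-words occurrence rates per million tokens.

    Attributes
    ----------
    rates : ndarray, shape (n_authors, n_words)
        rate(a, w) = count(a, w) / token_total(a) * 1e6.
    words : ndarray of str
        Ordered vocabulary (columns).
    author_ids : ndarray of str
        Ordered author identifiers (rows).
    token_totals : ndarray of int
        Per-author total token counts (the rate denominator / 1e6).
    """

    rates: np.ndarray
    words: np.ndarray
    author_ids: np.ndarray
    token_totals: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.words = np.asarray(self.words, dtype=object)
        self.author_ids = np.asarray(self.author_ids, dtype=object)
        self.token_totals = np.asarray(self.token_totals)
        n_a, n_w = self.rates.shape
        if len(self.words) != n_w or len(self.author_ids) != n_a:
            raise ValueError("rates shape does not match index lengths")
        if len(self.token_totals) != n_a:
            raise ValueError("token_totals length does not match author count")
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")

    @property
    def n_authors(self) -> int:
        return self.rates.shape[0]

    @property
    def n_words(self) -> int:
        return self.rates.shape[1]

    def word_index(self) -> dict[str, int]:
        return {w: i for i, w in enumerate(self.words)}

    def select_words(self, keep: np.ndarray) -> "RateMatrix":
        """Return a copy restricted to the word columns selected by ``keep``."""
        return replace(self, rates=self.rates[:, keep], words=self.words[keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rates, index=list(self.author_ids), columns=list(self.words))


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the author-metadata TSV, dropping authors with missing sex/continent.

    Raises a ``ValueError`` carrying the offending line number for malformed
    rows. Authors lacking sex or continent are excluded (not imputed) with a
    logged warning, because every downstream contrast needs both.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # pandas reports the line number
        raise ValueError(f"malformed metadata TSV {path}: {exc}") from exc
    missing_cols = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"metadata {path} lacks columns: {missing_cols}")
    if table["author_id"].duplicated().any():
        dupes = table.loc[table["author_id"].duplicated(), "author_id"].tolist()
        raise ValueError(f"duplicate author_id values: {dupes}")
    bad_sex = ~table["sex"].isin(SEXES)
    bad_cont = table["continent"].str.strip() == ""
    drop = bad_sex | bad_cont
    if drop.any():
        warnings.warn(
            f"dropping {int(drop.sum())} authors with missing sex/continent: "
            f"{table.loc[drop, 'author_id'].tolist()}",
            stacklevel=2,
        )
        table = table.loc[~drop]
    table = table.reset_index(drop=True)
    table["year_median"] = table["year_median"].astype(float).astype(int)
    return table


def write_metadata(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in METADATA_COLUMNS if c in table.columns]
    table.to_csv(path, sep="\t", index=False, columns=cols)


def read_corpus(
    metadata_path: str | Path,
    text_dir: str | Path,
    pattern: re.Pattern = TOKEN_RE,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Read metadata and book files; return the author table and token streams.

    Each author contributes one pooled token stream across their books (the
    per-author GLM has one row per author). A listed file that does not exist
    is an error naming the path; an empty file contributes zero tokens with a
    warning.
    """
    authors = read_metadata(metadata_path)
    text_dir = Path(text_dir)
    streams: dict[str, list[str]] = {}
    for row in authors.itertuples(index=False):
        tokens: list[str] = []
        files = [f for f in str(row.book_files).split(";") if f]
        for name in files:
            fpath = text_dir / name
            if not fpath.exists():
                raise FileNotFoundError(f"book file not found for {row.author_id}: {fpath}")
            text = fpath.read_text(encoding="utf-8")
            toks = tokenize(text, pattern)
            if not toks:
                warnings.warn(f"empty book file {fpath} for {row.author_id}", stacklevel=2)
            tokens.extend(toks)
        if not tokens:
            warnings.warn(f"author {row.author_id} has zero tokens", stacklevel=2)
        streams[row.author_id] = tokens
    return authors, streams


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def compute_rates(
    streams: Mapping[str, Sequence[str]],
    vocabulary: Sequence[str] | None = None,
) -> RateMatrix:
    """Count tokens per author and convert to rates per million.

    ``token_total`` is the author's full stream length (all tokens, whether or
    not in ``vocabulary``), so restricting the vocabulary never inflates
    rates. Authors with zero tokens get an all-zero row.
    """
    if not streams:
        raise ValueError("no token streams given")
    author_ids = list(streams)
    counters = {a: Counter(streams[a]) for a in author_ids}
    if vocabulary is None:
        vocab = sorted(set().union(*(c.keys() for c in counters.values())))
    else:
        vocab = list(vocabulary)
    totals = np.array([len(streams[a]) for a in author_ids], dtype=np.int64)
    counts = np.zeros((len(author_ids), len(vocab)), dtype=np.int64)
    windex = {w: j for j, w in enumerate(vocab)}
    for i, a in enumerate(author_ids):
        for w, c in counters[a].items():
            j = windex.get(w)
            if j is not None:
                counts[i, j] = c
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(totals[:, None] > 0, counts / totals[:, None] * 1e6, 0.0)
    return RateMatrix(rates=rates, words=np.array(vocab, dtype=object),
                      author_ids=np.array(author_ids, dtype=object), token_totals=totals)


def filter_vocabulary(
    matrix: RateMatrix,
    authors: pd.DataFrame,
    threshold: float = 0.10,
) -> RateMatrix:
    """Keep words present in at least ``threshold`` of male OR female authors.

    Prevalence is computed on presence (rate > 0), not on any rate cutoff.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    _check_aligned(matrix, authors)
    present = matrix.rates > 0
    keep = np.zeros(matrix.n_words, dtype=bool)
    sexes = authors["sex"].to_numpy()
    for sex in SEXES:
        mask = sexes == sex
        if mask.any():
            keep |= present[mask].mean(axis=0) >= threshold
    return matrix.select_words(keep)


def apply_stoplist(matrix: RateMatrix, stoplist: Iterable[str]) -> RateMatrix:
    """Remove stoplist words (e.g. diachronic terms) from the vocabulary."""
    stop = set(stoplist)
    keep = np.array([w not in stop for w in matrix.words], dtype=bool)
    if not keep.any():
        warnings.warn("stoplist removed the entire vocabulary", stacklevel=2)
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("stoplist removed %d of %d words", n_removed, matrix.n_words)
    return matrix.select_words(keep)


def _check_aligned(matrix: RateMatrix, authors: pd.DataFrame) -> None:
    if list(matrix.author_ids) != list(authors["author_id"]):
        raise ValueError("matrix rows and author table are not aligned")


# ---------------------------------------------------------------------------
# Matrix file round-trip (MatrixMarket sparse triplets + index TSVs)
# ---------------------------------------------------------------------------

def write_rates(matrix: RateMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(directory / "rates.mtx"), sparse.coo_matrix(matrix.rates))
    pd.DataFrame({"author_id": matrix.author_ids, "token_total": matrix.token_totals}).to_csv(
        directory / "rates.rows.tsv", sep="\t", index=False
    )
    pd.DataFrame({"word": matrix.words}).to_csv(directory / "rates.cols.tsv", sep="\t", index=False)


def read_rates(directory: str | Path) -> RateMatrix:
    directory = Path(directory)
    rates = spio.mmread(str(directory / "rates.mtx")).toarray()
    rows = pd.read_csv(directory / "rates.rows.tsv", sep="\t", dtype={"author_id": str})
    cols = pd.read_csv(directory / "rates.cols.tsv", sep="\t", dtype=str, keep_default_na=False)
    return RateMatrix(
        rates=rates,
        words=cols["word"].to_numpy(dtype=object),
        author_ids=rows["author_id"].to_numpy(dtype=object),
        token_totals=rows["token_total"].to_numpy(),
    )
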