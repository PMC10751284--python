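# Methods

This note documents the models, conventions and numerical choices behind
`litaffect`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Corpus representation

Authors contribute one pooled token stream across their books; the row unit
of every analysis is the author, whose *historical period* is the median
publication year over their books. Tokenization (configurable) lowercases
with `str.casefold` and takes maximal letter runs with internal apostrophes
and hyphens; a maximal digit run is one token. The choice keeps number
*words* ("hundred") in the vocabulary while numerals are unlikely to pass
the prevalence filter. Rates are occurrences per million of the author's
full token count, so restricting the vocabulary never inflates rates. The
prevalence filter keeps a word when at least 10% of male **or** female
authors use it at all (presence, not a rate threshold — "occurring in"
reads as presence). Authors missing sex or continent are excluded, not
imputed, because every contrast needs both.

## Synthetic corpus generator

The generator emulates the frequency structure of a literature corpus, not
its language: base word probabilities are Zipfian (exponent 1.1 by
default), and each author×word count is Poisson around a lognormal
intensity — a negative-binomial-like overdispersed model with log-scale
noise SD `overdispersion` (default 0.4). The defaults mirror the corpus
shape the package targets: 1365 authors at the 871:494 male:female ratio,
periods uniform on 1719–2020, ~33% translated, 180,000 tokens per author,
and a vocabulary covering half of each author's tokens. The noise
distribution of real word rates is not characterized anywhere we know of;
the lognormal-Poisson form is an assumption, chosen so log rates are
approximately normal (making rank-based GLMs and Cohen's d well behaved)
while preserving count-level sampling noise for rare words.

Effects are injected on the log-rate scale so "Cohen's d of word
frequency" is well defined under Zipfian magnitudes. An injected d is
calibrated against the delta-method total SD of the observed log count,
`sqrt(sigma^2 + exp(sigma^2/2)/m_w)` with `m_w` the word's expected count,
so the *empirical* d matches the nominal one (verified to ±0.1 at n=1000
over 20 replicates). Sex-by-period interactions are a linear drift of the
sex gap across the period range, crossing the main-effect value at
mid-period. The token total used as the rate denominator is fixed per
author (with a guard for extreme draws): a fluctuating denominator would
couple every word to the noise of the Zipf head and attenuate injected
effects by ~10%. Raw token streams are materialized only on request as
shuffled count-exact word repetitions plus filler tokens; they reproduce
the rate matrix bit-for-bit but carry no syntax, so embedding-quality
claims on them are structural (shared contexts), never linguistic.

Synthetic affective norms draw a latent (valence, arousal) pair per word
from a bivariate normal (means 5.2/4.2, SDs 1.1/0.9, correlation −0.4,
clipped to [1,9] — values typical of published affective-norm datasets);
male/female rater columns differ by a configurable gap plus rater noise.

## Per-word inference

Each word's rate is rank-transformed across authors (average ranks) and
modeled by OLS on: intercept, sex (−0.5 female / +0.5 male), centered rank
of period, their product, translation (0/1), and drop-one geography
dummies (continent by default, country as the alternative model). Centering
before the product reduces main/interaction collinearity; the partial F is
invariant to recoding, but coefficient signs follow this convention. The
headline test drops both sex terms jointly (p=2); single-term tests (sex
alone, interaction alone) are a secondary pass used only to classify
significant words as main-effect / interaction / both, since the source
analysis does not state its classification rule.

The permutation scheme shuffles sex labels only, keeping period,
translation and geography fixed, and rebuilds the sex and sex×period
columns per shuffle — exact under exchangeability of labels given the
nuisance design, and simpler than Freedman–Lane residual permutation. All
words share the same shuffle schedule, which is what licenses the
max-statistic family-wise correction. The engine residualizes the two
permuted columns against the fixed design once per shuffle, so each
permutation costs one (2×n)·(n×W) product; 10,000 shuffles on 1365×25,040
is feasible, and the test-suite scales (500–1365 authors, 100–2000 words,
500–2000 shuffles) were chosen to exercise the same code paths at
desk-scale run times.

Empirical p-values use the (b+1)/(m+1) convention with the observed
labeling as permutation zero, so p ≥ 1/(n_perm+1) and no p is zero. When
the empirical p is ≤ 0.10, exceedances over the 90th null percentile are
fit by maximum likelihood to a generalized Pareto distribution and the
analytic tail probability replaces the empirical p (never exceeding it,
which preserves monotonicity in the observed statistic). The tail settings
(threshold 0.10, exceedance fraction 0.10, Kolmogorov–Smirnov
goodness-of-fit gate at 0.05 with empirical fallback) follow standard
practice for permutation-tail approximation; the single-threshold fit has
an irreducible replicate spread of roughly a factor 1.8 when extrapolating
three orders of magnitude, so its accuracy is assessed on central
tendency over replicates. Family-wise corrected p-values are tail
probabilities of the observed F under the max-over-words null, Pareto
refined the same way, and clamped to be ≥ the per-word refined p.

A zero sex coefficient ties direction to "female-preferred" with a
warning (an arbitrary but documented rule; exact zeros occur only in
degenerate constructions).

## Stylometry

PPMI treats the authors-by-words rate matrix as a co-occurrence mass table
(cell mass over total mass against the product of marginals, clipped at
zero). Cosine distances between PPMI rows are rank-converted (average
ranks for ties) into similarities, making the backbone invariant to any
monotone transform of the distances. The backbone is Kruskal's minimum
spanning tree on the distances plus the globally strongest non-tree edges
until the edge count reaches round(target_degree·n/2), enforced on the
final simple graph; ties break by lexicographic node-pair order for
determinism. All-zero PPMI rows (authors with no information) are dropped
with a warning before distances.

## Semantic map and timecourses

The embedding trainer is a minimal skip-gram with negative sampling:
dynamic windows, unigram^0.75 noise distribution, frequency subsampling at
the standard threshold rule, linear learning-rate decay, single worker and
seeded, hence bit-reproducible. Defaults are size 512, window 5, α=.05,
subsample 1e-3, 10 epochs, 5 negatives. The 2-D projection computes the
words' cosine dissimilarity matrix, keeps the smallest PCA component count
reaching 66% explained variance, and runs Barnes–Hut t-SNE (perplexity 40,
angle 0.1). Coordinates are non-identifiable up to rotation/reflection;
tests assert neighborhood structure only.

Domain membership is a flat word→domain lexicon over eleven fixed domains
(artifacts, social groups, weapons, body, affect, food/beverages, numbers,
time, locations, clothes, plants), validated against that label set; the
pipeline stays deterministic and dependency-light by not traversing a
lexical database at run time.

Sliding windows are 50 years wide at 10-year steps (configurable; the
defaults cover 1719–2020 with ~26 windows of adequate n). Window centers
derive from the observed year range, so shifting all years shifts centers
identically. Within a window, the word set is pooled per author as the
mean of log(1+rate) across the set (log1p handles zero rates; pooled-rate
default, with per-word averaging available by calling per word), and
Cohen's d uses the pooled-SD convention without small-sample correction;
the absolute value is taken after the signed d, which is retained in the
output. Note that pooling k words with independent noise and identical
shifts inflates the pooled d by ~sqrt(k) relative to the per-word d;
recovery tests therefore use single-word sets. CIs are 95% percentile
intervals from 1000 stratified (within-sex) bootstrap resamples; windows
with fewer than 3 authors of either sex are skipped with a warning.

## Affective scoring

The author score is Σ rating·log(rank)/Σ log(rank) over the lexicon words
the author uses, with ranks ascending over the author's own frequencies
and average ranks for ties. This is the only reading of "log-adjusted word
ranks" that makes the score frequency-sensitive: the most frequent word
carries the largest weight, the least frequent used word carries zero, and
tied frequencies reduce the score to the unweighted mean. The score is
invariant to rescaling an author's frequencies, a constant-rating input
returns that constant exactly, and fewer than two usable words yield a
missing score with a warning. Ratings are sex-matched: male authors (and
male-preferred words, in the word-level contrast) take male-rater columns.
A one-dimensional lexicon (e.g. happiness ratings) runs through the same
operations with the arousal columns absent.

Rank-sum contrasts weight words equally (one observation per word) and are
exact by full enumeration for combined n ≤ 20 — handling ties, with the
two-sided p as twice the smaller tail capped at 1, matching the
large-sample normal approximation with tie correction used above that
size. Difference-of-means CIs are percentile bootstrap (1000 resamples,
seeded). The valence–arousal model is OLS `arousal ~ sex * valence` with
sex coded ±0.5; coefficients, SEs, t values and adjusted R² are reported.
Category frequencies are raw percentage occurrences of disjoint
positive/negative word sets per author; zero-token authors get missing
values.

## Pipeline determinism

Every stage seeds its own generator from the config seed plus a fixed
offset; reruns with an identical config are bit-identical, verified by the
SHA-256 manifest (the graph writer's date stamp is stripped for this
reason). A stage failure aborts with the stage name and preserves
completed outputs. Embedding training is off by default in the orchestrated
run — it is the one stage whose cost grows with raw text volume rather than
matrix size — and is exercised through the library API and examples.

## What passing tests do and do not show

The generator emulates frequency structure, metadata imbalance and
injected effect sizes, so passing tests demonstrate calibration and power
of the *statistics* under a realistic noise model. They do not validate
linguistic assumptions about real prose: topical correlation between
words, non-stationary vocabulary, OCR noise, or semantic drift are all
outside the generator, and the affective-norm emulation reproduces scale
and correlation structure, not the content of any licensed lexicon.
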