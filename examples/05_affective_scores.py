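"""Sentiment scoring of authors with sex-matched affective norms.

Each author's valence and arousal is the log-rank-weighted mean of the
rater-sex-matched ratings of the lexicon words they use (Eq.-style score:
sum rating * log rank / sum log rank). The arousal ~ sex * valence OLS then
asks whether the valence-arousal trade-off differs between the sexes.
"""

import numpy as np

import litaffect as la

spec = la.EffectSpec(vocab_size=500, n_authors=700, seed=6)
authors = la.generate_authors(spec)
norms = la.generate_affective_norms(list(spec.words), seed=7)

# inject a real signal: female authors lean toward high-valence words
vm = norms["valence_m"].to_numpy()
z = (vm - vm.mean()) / vm.std()
loadings = np.where(authors["sex"] == "female", 1.0, -1.0)
corpus = la.generate_rates(authors, spec, author_loadings=loadings, loading_scores=z)

scores = la.score_authors(corpus.rates, authors, norms)
by_sex = scores.groupby("sex")[["valence_score", "arousal_score"]].mean().round(3)
print("mean author scores by sex (1-9 scale):")
print(by_sex.to_string())

model = la.valence_arousal_model(scores)
coefs = model["coefficients"]
print(f"\narousal ~ sex * valence: adj R2 = {model['adj_r2']:.3f}")
print(coefs.round(4).to_string())

pos, neg = la.generate_category_lexicon(list(spec.words), 60, 75, seed=8)
table, contrasts = la.category_frequencies(
    corpus.rates, authors, la.CategoryLexicon.from_sets(pos, neg), seed=9)
pvn = contrasts["positive_vs_negative"]
print(f"\npositive vs negative token share: {pvn['difference']:+.3f} pct points "
      f"(rank-sum p = {pvn['p']:.3g})")
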