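"""Skip-gram embeddings and the 2-D semantic map.

A toy corpus with two interchangeable word classes (fruit words sharing
contexts, tool words sharing different contexts) is embedded with the
skip-gram trainer; within-class cosine similarity should exceed
between-class, and the PCA + t-SNE projection keeps the classes apart.
"""

import numpy as np

import litaffect as la
from litaffect.semantic_map import project_2d

rng = np.random.default_rng(0)
fruit = ["apple", "pear", "plum", "grape", "peach", "mango"]
tools = ["hammer", "wrench", "pliers", "drill", "chisel", "rasp"]
sentences = []
for _ in range(400):
    if rng.random() < 0.5:
        sentences.append(["eat", fruit[rng.integers(6)], "sweet",
                          fruit[rng.integers(6)], "ripe"])
    else:
        sentences.append(["grip", tools[rng.integers(6)], "steel",
                          tools[rng.integers(6)], "bench"])

emb = la.train_embeddings(sentences, size=32, window=2, epochs=10, seed=1, sample=0)
within = np.mean([emb.similarity(a, b) for a in fruit for b in fruit if a != b])
between = np.mean([emb.similarity(a, b) for a in fruit for b in tools])
print(f"mean cosine similarity within class:  {within:+.3f}")
print(f"mean cosine similarity between class: {between:+.3f}")
print(f"margin (should be > 0): {within - between:+.3f}")

coords = project_2d(emb, perplexity=3, seed=0)
want = coords[coords["word"].isin(fruit + tools)]
print("\n2-D map coordinates (rotation/reflection arbitrary):")
print(want.round(1).to_string(index=False))
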