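"""Build the stylometric backbone graph of authors.

Rates are PPMI-normalized, cosine distances between author rows are
rank-converted to similarities, and the backbone keeps the minimum spanning
tree plus the strongest remaining edges up to average degree 20.
"""

import networkx as nx

import litaffect as la

corpus = la.generate_corpus(la.EffectSpec(vocab_size=400, n_authors=250, seed=1))
graph = la.stylometric_backbone(corpus.rates, corpus.authors, target_degree=20.0)

n, e = graph.number_of_nodes(), graph.number_of_edges()
print(f"backbone: {n} authors, {e} edges, average degree {2 * e / n:.1f}")
print(f"connected: {nx.is_connected(graph)}")
mst_edges = sum(1 for _, _, a in graph.edges(data=True) if a["mst"])
print(f"spanning-tree edges: {mst_edges} (= n - 1), extra strong edges: {e - mst_edges}")
# with no injected style differences between the sexes, mixing should be
# near zero (sex does not structure the graph)
print(f"sex assortativity: {nx.attribute_assortativity_coefficient(graph, 'sex'):+.3f}")
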