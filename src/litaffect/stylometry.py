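"""Stylometric similarity structure and its backbone graph.

The authors-by-words rate matrix is normalized with Positive Pointwise
Mutual Information (treating it as a co-occurrence mass table), cosine
distance between author rows summarizes stylometric differences, distances
are rank-converted to similarities, and the backbone graph is the minimum
spanning tree of the distances plus the globally strongest remaining edges
up to a target average degree (20 by default).

Because the backbone is built from distance *ranks*, it is invariant to any
monotone transform of the distance matrix.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .corpus import RateMatrix


def ppmi(matrix: RateMatrix | np.ndarray) -> np.ndarray:
    """Positive Pointwise Mutual Information of a nonnegative mass table.

    cell(a, w) = max(0, log[ p(a,w) / (p(a) p(w)) ]) where p(a,w) is the
    cell's share of the total mass and p(a), p(w) are the marginals. A
    rank-one table (rows proportional to each other) comes out all zero.
    """
    m = matrix.rates if isinstance(matrix, RateMatrix) else np.asarray(matrix, dtype=float)
    if np.any(m < 0):
        raise ValueError("ppmi needs a nonnegative matrix")
    total = m.sum()
    if total == 0:
        raise ValueError("ppmi undefined for an all-zero matrix")
    p = m / total
    pr = p.sum(axis=1, keepdims=True)
    pc = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p / (pr @ pc)
        out = np.log(ratio, out=np.zeros_like(p), where=ratio > 0)
    return np.maximum(out, 0.0)


def cosine_distance(weighted: np.ndarray) -> np.ndarray:
    """Pairwise cosine distance between rows: d(a,b) = 1 - cos(rows a,b).

    All-zero rows have no direction; they are excluded by the caller
    (a warning is raised here) and their distances set to NaN.
    """
    w = np.asarray(weighted, dtype=float)
    norms = np.linalg.norm(w, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero rows excluded from cosine distance",
                      stacklevel=2)
    safe = np.where(zero, 1.0, norms)
    unit = w / safe[:, None]
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist[zero, :] = np.nan
    dist[:, zero] = np.nan
    return dist


def rank_similarity(distance: np.ndarray) -> np.ndarray:
    """Rank-convert a distance matrix into a symmetric similarity matrix.

    Upper-triangle distances are ranked (average ranks for ties) and
    reversed, so the closest pair gets the largest similarity. The diagonal
    is set above the maximum similarity.
    """
    d = np.asarray(distance, dtype=float)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    sims = ranks.max() + 1 - ranks if len(ranks) else ranks
    out = np.zeros_like(d)
    out[iu] = sims
    out = out + out.T
    np.fill_diagonal(out, (sims.max() + 1) if len(sims) else 1.0)
    return out


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def backbone(
    distance: np.ndarray,
    target_degree: float = 20.0,
    node_ids: Sequence[str] | None = None,
    node_attributes: pd.DataFrame | None = None,
) -> nx.Graph:
    """Minimum-spanning-tree backbone with extra strong edges.

    Kruskal's MST on the distances guarantees connectivity; the globally
    strongest (smallest-distance) non-tree edges are then added until the
    edge count reaches ``round(target_degree * n / 2)``. Ties are broken by
    lexicographic node-pair order for determinism. Edge weights carry the
    rank-converted similarity.
    """
    d = np.asarray(distance, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("backbone needs at least two nodes")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN (drop zero rows first)")
    n_edges = int(round(target_degree * n / 2))
    max_edges = n * (n - 1) // 2
    if n_edges < n - 1 or n_edges > max_edges:
        raise ValueError(
            f"target_degree {target_degree} infeasible for n={n}: needs "
            f"{n - 1} <= edges <= {max_edges}, got {n_edges}"
        )
    sim = rank_similarity(d)
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, d[iu, ju]))  # by distance, then (i, j)
    uf = _UnionFind(n)
    mst_edges: list[tuple[int, int]] = []
    extra_edges: list[tuple[int, int]] = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if uf.union(i, j):
            mst_edges.append((i, j))
        else:
            extra_edges.append((i, j))
    chosen = mst_edges + extra_edges[: n_edges - len(mst_edges)]

    ids = list(node_ids) if node_ids is not None else [str(i) for i in range(n)]
    g = nx.Graph()
    for i, name in enumerate(ids):
        g.add_node(name)
    if node_attributes is not None:
        attrs = node_attributes.set_index("author_id") if "author_id" in node_attributes else node_attributes
        for name in ids:
            if name in attrs.index:
                g.nodes[name].update(attrs.loc[name].to_dict())
    for i, j in mst_edges:
        g.add_edge(ids[i], ids[j], weight=float(sim[i, j]), distance=float(d[i, j]), mst=True)
    for i, j in chosen[len(mst_edges):]:
        g.add_edge(ids[i], ids[j], weight=float(sim[i, j]), distance=float(d[i, j]), mst=False)
    return g


def export_graph(graph: nx.Graph, gexf_path=None, edgelist_path=None) -> None:
    """Write the backbone for external viewers: GEXF and/or edge-list TSV."""
    if gexf_path is not None:
        nx.write_gexf(graph, gexf_path)
    if edgelist_path is not None:
        rows = [
            {"source": u, "target": v, "similarity": d.get("weight"),
             "distance": d.get("distance"), "mst": d.get("mst")}
            for u, v, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(edgelist_path, sep="\t", index=False)


def stylometric_backbone(
    matrix: RateMatrix,
    authors: pd.DataFrame | None = None,
    target_degree: float = 20.0,
) -> nx.Graph:
    """Full stylometric path: PPMI -> cosine distance -> rank -> backbone."""
    weighted = ppmi(matrix)
    nonzero = np.linalg.norm(weighted, axis=1) > 0
    if not nonzero.all():
        weighted = weighted[nonzero]
    ids = list(np.asarray(matrix.author_ids)[nonzero])
    dist = cosine_distance(weighted)
    return backbone(dist, target_degree=target_degree, node_ids=ids, node_attributes=authors)
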