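"""Chemical-space embeddings of fingerprinted molecule sets.

Two methods are provided:

* a tree embedding: k-nearest-neighbour graph on Tanimoto distance
  (1 - similarity), reduced to a minimum spanning tree per component and
  laid out with a deterministic radial tree layout (defaults k=50, with
  LSH-accelerated neighbour search above an exactness threshold);
* t-SNE on the precomputed Tanimoto distance matrix (defaults
  perplexity=40, 300 iterations; perplexity is auto-reduced with a warning
  when the collection is too small).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

EXACT_KNN_LIMIT = 50_000
DEFAULT_K = 50
DEFAULT_KC = 10
DEFAULT_PERPLEXITY = 40.0
DEFAULT_TSNE_ITER = 300


@dataclass
class EmbeddingResult:
    method: str  # "tmap" | "tsne"
    coords: np.ndarray  # (n, 2)
    params: dict
    edges: list = field(default_factory=list)  # tree edges, tmap only
    library_label: list = field(default_factory=list)


def _tanimoto_distance_block(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xi = x.astype(np.int32)
    yi = y.astype(np.int32)
    inter = xi @ yi.T
    union = xi.sum(axis=1)[:, None] + yi.sum(axis=1)[None, :] - inter
    sim = np.ones(inter.shape, dtype=float)
    nz = union > 0
    sim[nz] = inter[nz] / union[nz]
    return 1.0 - sim


def tanimoto_distance_matrix(fps: np.ndarray) -> np.ndarray:
    return _tanimoto_distance_block(fps, fps)


def _minhash_signatures(fps: np.ndarray, n_hashes: int, seed: int) -> np.ndarray:
    """Min-hash signatures over on-bit sets (all-zero rows get a sentinel)."""
    rng = np.random.default_rng(seed)
    n, n_bits = fps.shape
    signatures = np.full((n, n_hashes), n_bits + 1, dtype=np.int64)
    for h in range(n_hashes):
        perm = rng.permutation(n_bits)
        ranked = np.where(fps > 0, perm[None, :], n_bits + 1)
        signatures[:, h] = ranked.min(axis=1)
    return signatures


def _lsh_candidates(
    fps: np.ndarray, k: int, kc: int, seed: int
) -> list[set[int]]:
    """Candidate neighbour sets from banded min-hash buckets.

    ``kc`` controls query expansion: the number of independent band tables
    (more tables, more probes per query).
    """
    n = len(fps)
    # single-hash bands: collision probability per table equals the Jaccard
    # similarity itself, which keeps recall high for moderately similar
    # neighbours at the cost of larger candidate pools
    rows_per_band = 1
    n_tables = max(1, 2 * kc)
    candidates: list[set[int]] = [set() for _ in range(n)]
    signatures = _minhash_signatures(fps, rows_per_band * n_tables, seed)
    for table in range(n_tables):
        band = signatures[:, table * rows_per_band : (table + 1) * rows_per_band]
        buckets: dict[tuple, list[int]] = {}
        for i in range(n):
            buckets.setdefault(tuple(band[i]), []).append(i)
        for members in buckets.values():
            if len(members) < 2:
                continue
            member_set = set(members)
            for i in members:
                candidates[i] |= member_set
    for i in range(n):
        candidates[i].discard(i)
    return candidates


def knn_graph(
    fps: np.ndarray,
    k: int = DEFAULT_K,
    kc: int = DEFAULT_KC,
    exact_limit: int = EXACT_KNN_LIMIT,
    seed: int = 0,
) -> nx.Graph:
    """Connect each molecule to its k nearest neighbours by Tanimoto
    distance.

    ``k`` is truncated to n-1 for small collections.  Search is exact below
    ``exact_limit`` molecules and LSH-approximate above (mode logged);
    nodes whose LSH candidate pool is smaller than k fall back to an exact
    scan.
    """
    fps = np.asarray(fps)
    if len(fps) < 2:
        raise ValueError("kNN graph needs at least 2 fingerprints")
    n = len(fps)
    k = min(k, n - 1)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    exact = n < exact_limit
    logger.info("kNN search mode: %s (n=%d, k=%d)", "exact" if exact else "lsh", n, k)
    if exact:
        dist = tanimoto_distance_matrix(fps)
        np.fill_diagonal(dist, np.inf)
        order = np.argsort(dist, axis=1, kind="stable")[:, :k]
        for i in range(n):
            for j in order[i]:
                graph.add_edge(i, int(j), weight=float(dist[i, j]))
        return graph
    candidates = _lsh_candidates(fps, k, kc, seed)
    for i in range(n):
        pool = sorted(candidates[i])
        if len(pool) < k:
            pool = [j for j in range(n) if j != i]
        dist = _tanimoto_distance_block(fps[i : i + 1], fps[pool])[0]
        order = np.argsort(dist, kind="stable")[:k]
        for idx in order:
            graph.add_edge(i, pool[idx], weight=float(dist[idx]))
    return graph


def minimum_spanning_forest(graph: nx.Graph) -> nx.Graph:
    """Deterministic MST per connected component (ties broken on node ids)."""
    tie_broken = nx.Graph()
    tie_broken.add_nodes_from(graph.nodes)
    for u, v, data in sorted(
        graph.edges(data=True),
        key=lambda e: (e[2]["weight"], min(e[0], e[1]), max(e[0], e[1])),
    ):
        tie_broken.add_edge(u, v, weight=data["weight"])
    return nx.minimum_spanning_tree(tie_broken, algorithm="kruskal")


def _layout_tree(tree: nx.Graph, root, offset: np.ndarray) -> dict:
    """Radial layout: wedges proportional to subtree size, radius = depth."""
    coords = {}
    order = list(nx.dfs_postorder_nodes(tree, root))
    parent = {root: None}
    for u, v in nx.bfs_edges(tree, root):
        parent[v] = u
    sizes = {node: 1 for node in tree.nodes}
    for node in order:
        if parent[node] is not None:
            sizes[parent[node]] += sizes[node]
    coords[root] = offset.copy()
    spans = {root: (0.0, 2.0 * math.pi)}
    depth = {root: 0}
    for u, v in nx.bfs_edges(tree, root):
        depth[v] = depth[u] + 1
    for node in nx.bfs_tree(tree, root).nodes:
        children = sorted(c for c in tree.neighbors(node) if parent.get(c) == node)
        if not children:
            continue
        lo, hi = spans[node]
        total = sum(sizes[c] for c in children)
        cursor = lo
        for child in children:
            width = (hi - lo) * sizes[child] / total
            spans[child] = (cursor, cursor + width)
            angle = cursor + width / 2.0
            radius = float(depth[child])
            coords[child] = offset + np.array(
                [radius * math.cos(angle), radius * math.sin(angle)]
            )
            cursor += width
    return coords


def tmap_layout(
    graph: nx.Graph, labels: list | None = None, seed: int = 0
) -> EmbeddingResult:
    """Minimum-spanning-tree embedding with a deterministic 2D tree layout.

    Components are laid out side by side; the result is reproducible for a
    fixed input graph.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if graph.number_of_nodes() == 1:
        return EmbeddingResult(
            method="tmap",
            coords=np.zeros((1, 2)),
            params={"seed": seed},
            edges=[],
            library_label=list(labels) if labels is not None else [],
        )
    forest = minimum_spanning_forest(graph)
    n = graph.number_of_nodes()
    coords = np.zeros((n, 2))
    x_offset = 0.0
    for component in sorted(nx.connected_components(forest), key=min):
        root = min(component)
        radius = max(1.0, float(len(component)) ** 0.5)
        positions = _layout_tree(
            forest.subgraph(component), root, np.array([x_offset + radius, 0.0])
        )
        for node, xy in positions.items():
            coords[node] = xy
        x_offset += 2.0 * radius + 2.0
    edges = [(u, v, d["weight"]) for u, v, d in forest.edges(data=True)]
    return EmbeddingResult(
        method="tmap",
        coords=coords,
        params={"seed": seed},
        edges=edges,
        library_label=list(labels) if labels is not None else [],
    )


def tsne_embed(
    fps: np.ndarray,
    perplexity: float = DEFAULT_PERPLEXITY,
    n_iter: int = DEFAULT_TSNE_ITER,
    seed: int = 0,
    labels: list | None = None,
) -> EmbeddingResult:
    """2D t-SNE of the Tanimoto distance matrix; same seed, same coords."""
    from sklearn.manifold import TSNE

    fps = np.asarray(fps)
    n = len(fps)
    if n < 5:
        raise ValueError("t-SNE needs at least 5 molecules")
    effective = perplexity
    if n <= 3 * perplexity:
        effective = max(2.0, (n - 1) / 3.0)
        warnings.warn(
            f"perplexity reduced from {perplexity} to {effective} for n={n}",
            stacklevel=2,
        )
        logger.warning("perplexity reduced to %.1f for n=%d", effective, n)
    dist = tanimoto_distance_matrix(fps)
    tsne = TSNE(
        n_components=2,
        perplexity=effective,
        max_iter=max(250, n_iter),
        random_state=seed,
        metric="precomputed",
        init="random",
    )
    coords = tsne.fit_transform(dist)
    return EmbeddingResult(
        method="tsne",
        coords=np.asarray(coords, dtype=float),
        params={
            "perplexity": effective,
            "requested_perplexity": perplexity,
            "n_iter": n_iter,
            "seed": seed,
        },
        library_label=list(labels) if labels is not None else [],
    )
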