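"""Dimensionality reduction, neighbor-graph clustering, and 2-D embedding.

Cells are clustered by greedy modularity optimization on a mutual-kNN graph
built in PC space. The 2-D stochastic-neighbor embedding is for reporting
only; nothing downstream consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .preprocess import SignatureMatrix


@dataclass
class ClusterAssignment:
    labels: pd.Series  # cell_id -> cluster label
    feature_space: str = "expression"
    parameters: dict = field(default_factory=dict)

    @property
    def cluster_ids(self) -> list[str]:
        return sorted(self.labels.unique())


def pca_reduce(signatures: SignatureMatrix, n_pcs: int = 20) -> np.ndarray:
    """Top principal components of the cells x genes z-score matrix.

    Sign convention: each component is flipped so its largest-|loading| gene
    has a positive loading, making the output deterministic.
    """
    X = signatures.values.T  # cells x genes
    n_pcs = int(min(n_pcs, min(X.shape)))
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(X)
    for k in range(n_pcs):
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            scores[:, k] *= -1
    return scores


def mutual_knn_graph(pcs: np.ndarray, k: int) -> nx.Graph:
    n = pcs.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    neighbor_sets = [set(row[1:]) for row in idx]  # drop self
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in neighbor_sets[i]:
            if i < j and i in neighbor_sets[j]:
                g.add_edge(i, j)
    return g


def knn_cluster(
    pcs: np.ndarray,
    k: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    cell_ids: list[str] | None = None,
    feature_space: str = "expression",
    min_cluster_size: int = 10,
) -> ClusterAssignment:
    """Mutual-kNN graph + greedy modularity communities.

    Mutual-kNN graphs shed small noise components, so communities below
    min_cluster_size (singletons included) are merged into the cluster with
    the nearest centroid. The procedure is deterministic for fixed inputs;
    the seed is recorded in the parameter block for provenance.
    """
    n = pcs.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    g = mutual_knn_graph(pcs, k)
    communities = nx.community.greedy_modularity_communities(g, resolution=resolution)
    member = np.full(n, -1, dtype=int)
    # stable ordering: big clusters first, ties by smallest member index
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    for ci, comm in enumerate(ordered):
        for node in comm:
            member[node] = ci
    # merge sub-threshold communities into the nearest retained centroid
    sizes = np.bincount(member)
    big = [ci for ci in range(len(ordered)) if sizes[ci] >= max(2, min_cluster_size)]
    if big:
        centroids = {ci: pcs[member == ci].mean(axis=0) for ci in big}
        small = [c for c in range(len(ordered)) if c not in big]
        for node in np.nonzero(np.isin(member, small))[0]:
            dists = {ci: np.linalg.norm(pcs[node] - c) for ci, c in centroids.items()}
            member[node] = min(sorted(dists), key=lambda ci: dists[ci])
    # relabel compactly by (size desc, first member)
    remaining = sorted(set(member), key=lambda ci: (-np.sum(member == ci), np.argmax(member == ci)))
    relabel = {old: f"C{i + 1}" for i, old in enumerate(remaining)}
    labels = [relabel[m] for m in member]
    index = cell_ids if cell_ids is not None else list(range(n))
    return ClusterAssignment(
        labels=pd.Series(labels, index=index, name="cluster"),
        feature_space=feature_space,
        parameters={"n_pcs": pcs.shape[1], "k": k, "resolution": resolution, "seed": seed},
    )


def embed_2d(pcs: np.ndarray, seed: int = 0) -> np.ndarray:
    """Exact (non-accelerated) t-SNE for reporting."""
    n = pcs.shape[0]
    perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    tsne = TSNE(
        n_components=2, method="exact", random_state=seed,
        perplexity=perplexity, init="pca", learning_rate="auto",
    )
    return tsne.fit_transform(pcs)
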