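"""Root-trunk-branch trajectory inference.

The backbone is a minimum spanning tree over cluster centroids in a 2-D
component space (top-2 PCs of the z-score matrix). The root is the leaf
cluster with the highest median naiveness score; pseudotime is the geodesic
distance along the backbone from the root centroid to each cell's
nearest-point projection onto its cluster's incident edges. Branches are the
maximal subtrees beyond the first junction (degree >= 3 node) on the walk
from the root; everything between root and junction is trunk.

This is a transparent, oracle-testable stand-in for tree-embedding
trajectory methods; the backbone builder is the extension point for
alternatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .cluster import pca_reduce
from .preprocess import SignatureMatrix


@dataclass
class TrajectoryModel:
    components: np.ndarray  # cells x 2
    backbone: nx.Graph  # nodes: cluster labels, attr "pos"; edges attr "length"
    root_cluster: str
    pseudotime: pd.Series  # cell_id -> geodesic distance from root centroid
    branch_label: pd.Series  # cell_id -> root | trunk | branch_i


def reduce_components(signatures: SignatureMatrix) -> np.ndarray:
    """Deterministic 2-D reduction (top-2 PCs, fixed sign convention)."""
    return pca_reduce(signatures, n_pcs=2)


def fit_backbone(components: np.ndarray, clusters: pd.Series) -> nx.Graph:
    """Minimum spanning tree over cluster centroids (Euclidean, 2-D).

    Kruskal with ties broken by lexicographic cluster-label pair, so the tree
    is deterministic even for equidistant centroids.
    """
    labels = sorted(clusters.unique())
    if len(labels) < 2:
        warnings.warn("single cluster: trivial single-node backbone")
        g = nx.Graph()
        if labels:
            g.add_node(labels[0], pos=components[np.asarray(clusters == labels[0])].mean(axis=0))
        return g
    member = clusters.to_numpy()
    pos = {lab: components[member == lab].mean(axis=0) for lab in labels}
    edges = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            edges.append((float(np.linalg.norm(pos[a] - pos[b])), a, b))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))
    parent = {lab: lab for lab in labels}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = nx.Graph()
    for lab in labels:
        tree.add_node(lab, pos=pos[lab])
    for length, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            tree.add_edge(a, b, length=length)
            if tree.number_of_edges() == len(labels) - 1:
                break
    return tree


def select_root(
    tree: nx.Graph, scores: pd.DataFrame, clusters: pd.Series
) -> str:
    """Leaf cluster with maximal median naiveness; ties by lower median
    exhaustion, then lexicographic label."""
    leaves = [n for n in tree.nodes if tree.degree(n) <= 1]
    if not leaves:
        leaves = list(tree.nodes)
    naive = scores["naiveness"] if "naiveness" in scores else scores.iloc[:, 0]
    exh = scores["exhaustion"] if "exhaustion" in scores else None

    def key(lab: str) -> tuple:
        cells = clusters.index[clusters == lab]
        med_n = float(naive.loc[cells].median())
        med_e = float(exh.loc[cells].median()) if exh is not None else 0.0
        return (-med_n, med_e, lab)

    return min(leaves, key=key)


def _node_distances(tree: nx.Graph, root: str) -> dict[str, float]:
    return nx.single_source_dijkstra_path_length(tree, root, weight="length")


def assign_pseudotime(
    tree: nx.Graph,
    root: str,
    components: np.ndarray,
    clusters: pd.Series,
) -> pd.Series:
    """Geodesic distance from the root centroid to each cell's projection.

    Each cell is projected (nearest point) onto the backbone edges incident
    to its own cluster's centroid; the best projection wins. Edges ending in
    a terminal (leaf) centroid are extended beyond the leaf, so cells past
    the last centroid keep their ordering instead of collapsing onto it;
    pseudotime is floored at 0 (cells "before" the root centroid sit at the
    root).
    """
    if tree.number_of_nodes() <= 1:
        return pd.Series(np.zeros(len(clusters)), index=clusters.index, name="pseudotime")
    dist = _node_distances(tree, root)
    pos = nx.get_node_attributes(tree, "pos")
    out = np.empty(len(clusters))
    member = clusters.to_numpy()
    for i, lab in enumerate(member):
        p = components[i]
        best_d2, best_pt = np.inf, 0.0
        for u, v, data in tree.edges(lab, data=True):
            a, b = pos[u], pos[v]
            ab = b - a
            denom = float(ab @ ab)
            t = 0.0 if denom == 0 else float((p - a) @ ab / denom)
            lo = -np.inf if (tree.degree(u) == 1 and u != root) else 0.0
            hi = np.inf if (tree.degree(v) == 1 and v != root) else 1.0
            t = float(np.clip(t, lo, hi))
            proj = a + t * ab
            d2 = float(np.sum((p - proj) ** 2))
            length = data["length"]
            if t > 1.0:  # beyond the leaf v
                pt = dist[v] + (t - 1.0) * length
            elif t < 0.0:  # beyond the leaf u
                pt = dist[u] - t * length
            else:
                pt = min(dist[u] + t * length, dist[v] + (1.0 - t) * length)
            if d2 < best_d2:
                best_d2, best_pt = d2, pt
        if not np.isfinite(best_d2):  # isolated cluster node
            best_pt = dist.get(lab, 0.0)
        out[i] = max(best_pt, 0.0)
    return pd.Series(out, index=clusters.index, name="pseudotime")


def _find_junction(tree: nx.Graph, root: str) -> tuple[list[str], str | None]:
    """Walk from the root until the first node of degree >= 3.

    Returns (path including root and junction, junction or None if the tree
    is a path with no junction)."""
    path = [root]
    prev = None
    node = root
    while True:
        if tree.degree(node) >= 3:
            return path, node
        nxt = [n for n in tree.neighbors(node) if n != prev]
        if not nxt:
            return path, None
        prev, node = node, nxt[0]
        path.append(node)


def assign_branches(
    tree: nx.Graph, root: str, clusters: pd.Series
) -> pd.Series:
    """Label cells root / trunk / branch_i by their cluster's backbone role.

    Clusters strictly between root and the first junction (inclusive of the
    junction) are trunk; each maximal subtree hanging off the junction is one
    branch, numbered by the lexicographically smallest cluster label it
    contains. A path graph yields root + trunk only; a star rooted at its
    center has an empty trunk and one branch per leaf.
    """
    cluster_role: dict[str, str] = {}
    if tree.number_of_nodes() <= 1:
        for lab in clusters.unique():
            cluster_role[lab] = "root"
    else:
        path, junction = _find_junction(tree, root)
        cluster_role[root] = "root"
        for node in path[1:]:
            cluster_role[node] = "trunk"
        if junction is not None:
            on_path = set(path)
            subtrees = []
            for nbr in tree.neighbors(junction):
                if nbr in on_path:
                    continue
                sub = set()
                stack = [nbr]
                prev = {nbr: junction}
                while stack:
                    cur = stack.pop()
                    sub.add(cur)
                    for nxt in tree.neighbors(cur):
                        if nxt != prev[cur]:
                            prev[nxt] = cur
                            stack.append(nxt)
                subtrees.append(sub)
            subtrees.sort(key=lambda s: min(s))
            for bi, sub in enumerate(subtrees, start=1):
                for node in sub:
                    cluster_role[node] = f"branch_{bi}"
    labels = clusters.map(lambda lab: cluster_role.get(lab, "trunk"))
    labels.name = "branch"
    return labels


def fit_trajectory(
    signatures: SignatureMatrix,
    clusters: pd.Series,
    scores: pd.DataFrame,
    n_backbone_pcs: int = 20,
) -> TrajectoryModel:
    """Components -> backbone -> root -> pseudotime -> branch labels.

    The reported components are the top-2 PCs, but the backbone tree and the
    cell projections are computed in a higher-dimensional PC space
    (n_backbone_pcs): two dimensions cannot faithfully separate several
    branch directions at once, and the MST topology over centroids becomes
    unreliable there.
    """
    components = reduce_components(signatures)
    feats = pca_reduce(signatures, n_pcs=n_backbone_pcs)
    tree = fit_backbone(feats, clusters)
    root = select_root(tree, scores, clusters)
    pt = assign_pseudotime(tree, root, feats, clusters)
    branches = assign_branches(tree, root, clusters)
    return TrajectoryModel(
        components=components,
        backbone=tree,
        root_cluster=root,
        pseudotime=pt,
        branch_label=branches,
    )


def name_branches(model: TrajectoryModel, scores: pd.DataFrame) -> dict[str, str]:
    """Map structural branch labels to phenotype names by score profile:
    highest mean cytotoxicity -> effector, highest mean exhaustion ->
    exhausted, remainder -> dysfunctional."""
    branch_ids = sorted(
        {b for b in model.branch_label.unique() if b.startswith("branch_")}
    )
    naming: dict[str, str] = {}
    if not branch_ids:
        return naming
    means = {
        b: scores.loc[model.branch_label.index[model.branch_label == b]].mean()
        for b in branch_ids
    }
    if "cytotoxicity" in scores.columns:
        eff = max(branch_ids, key=lambda b: means[b]["cytotoxicity"])
        naming[eff] = "effector"
    if "exhaustion" in scores.columns:
        rest = [b for b in branch_ids if b not in naming]
        if rest:
            exh = max(rest, key=lambda b: means[b]["exhaustion"])
            naming[exh] = "exhausted"
    for b in branch_ids:
        naming.setdefault(b, "dysfunctional")
    return naming
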