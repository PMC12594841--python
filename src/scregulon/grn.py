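"""Information-theoretic gene-regulatory-network inference.

The estimator is deliberately simple and oracle-testable: equal-frequency
rank binning, plug-in mutual information of the joint histogram, an empirical
permutation-null significance gate (Bonferroni-corrected over candidate
edges), data-processing-inequality pruning of network triangles, and a
bootstrap consensus over cell resamples. Regulons are assembled from the
pruned network with Spearman-correlation modes and MI-proportional
likelihood weights.

All MI values are in nats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata, spearmanr

from .preprocess import SignatureMatrix
from .regulons import Regulon, RegulonSet

Edge = tuple[str, str]


@dataclass
class MINetwork:
    """Undirected regulator-centric MI network: every edge touches a candidate
    TF; keys are lexicographically sorted gene-id pairs."""

    edges: dict[Edge, float]
    candidate_tfs: list[str]
    n_cells: int = 0
    meta: dict = field(default_factory=dict)

    def neighbors(self, node: str) -> list[str]:
        out = []
        for a, b in self.edges:
            if a == node:
                out.append(b)
            elif b == node:
                out.append(a)
        return out


def _edge_key(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


def default_n_bins(n: int) -> int:
    """floor(sqrt(n/5)), clipped to [2, 10]."""
    return int(np.clip(int(np.floor(np.sqrt(n / 5))), 2, 10))


def _bin_indices(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin index per observation from stable average ranks."""
    n = values.shape[-1]
    ranks = rankdata(values, method="average", axis=-1)
    return np.minimum(((ranks - 1.0) / n * n_bins).astype(np.int64), n_bins - 1)


def _mi_from_bins(bx: np.ndarray, by: np.ndarray, n_bins: int) -> float:
    n = len(bx)
    joint = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).reshape(n_bins, n_bins)
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int | None = None) -> float:
    """Plug-in MI (nats) of the equal-frequency rank-binned joint histogram."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    if n < 10:
        raise ValueError(f"need >= 10 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input vector; MI defined as 0")
        return 0.0
    if n_bins is None:
        n_bins = default_n_bins(n)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    return _mi_from_bins(_bin_indices(x, n_bins), _bin_indices(y, n_bins), n_bins)


def _mi_tf_rows(bins: np.ndarray, tf_rows: np.ndarray, n_bins: int) -> np.ndarray:
    """MI of each TF row against every gene row, vectorized.

    bins: (G, C) bin indices for all genes; tf_rows: indices into bins.
    Returns (len(tf_rows), G).
    """
    G, C = bins.shape
    eye = np.eye(n_bins)
    onehot = eye[bins]  # (G, C, nb)
    out = np.empty((len(tf_rows), G))
    for k, t in enumerate(tf_rows):
        joint = np.einsum("ci,gcj->gij", onehot[t], onehot) / C  # (G, nb, nb)
        px = joint.sum(axis=2, keepdims=True)
        py = joint.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = joint * np.log(joint / (px * py))
        out[k] = np.nansum(terms, axis=(1, 2))
    return out


def mi_null_threshold(
    values: np.ndarray,
    n_perm: int = 1000,
    alpha: float | None = None,
    n_bins: int | None = None,
    rng: np.random.Generator | None = None,
    n_candidate_edges: int | None = None,
) -> float:
    """Empirical (1 - alpha) quantile of MI between permuted gene pairs.

    alpha defaults to the Bonferroni gate 0.05 / n_candidate_edges. With the
    default permutation budget the extreme quantile saturates near the null
    maximum, which is the intended conservative behavior.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    if rng is None:
        rng = np.random.default_rng(0)
    if n_bins is None:
        n_bins = default_n_bins(n)
    if alpha is None:
        if n_candidate_edges is None:
            n_candidate_edges = max(1, g * (g - 1) // 2)
        alpha = 0.05 / n_candidate_edges
    bins = _bin_indices(values, n_bins)
    null = np.empty(n_perm)
    for i in range(n_perm):
        a, b = rng.choice(g, size=2, replace=False)
        null[i] = _mi_from_bins(bins[a], rng.permutation(bins[b]), n_bins)
    return float(np.quantile(null, 1.0 - alpha))


def apply_dpi(net: MINetwork, tolerance: float = 0.0) -> MINetwork:
    """Data-processing-inequality pruning.

    For every triangle in the (pre-pruning) network, the weakest edge is
    removed when strictly below (1 - tolerance) times the smaller of the other
    two. Removals are decided against the input network, so the result is
    independent of edge iteration order.
    """
    if not 0 <= tolerance < 1:
        raise ValueError("tolerance must be in [0, 1)")
    adj: dict[str, set[str]] = {}
    for a, b in net.edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    doomed: set[Edge] = set()
    for (a, c), mi_ac in net.edges.items():
        common = adj[a] & adj[c]
        for b in common:
            mi_ab = net.edges[_edge_key(a, b)]
            mi_bc = net.edges[_edge_key(b, c)]
            if mi_ac < min(mi_ab, mi_bc) * (1.0 - tolerance):
                doomed.add((a, c))
                break
    kept = {e: v for e, v in net.edges.items() if e not in doomed}
    return MINetwork(kept, list(net.candidate_tfs), net.n_cells, dict(net.meta))


def infer_single_network(
    signatures: SignatureMatrix,
    candidate_tfs: list[str],
    n_bins: int | None = None,
    alpha: float | None = None,
    tolerance: float = 0.0,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> MINetwork:
    """MI + permutation-null threshold + DPI on one (possibly resampled) matrix."""
    if rng is None:
        rng = np.random.default_rng(0)
    X = signatures.values
    g, n = X.shape
    if n_bins is None:
        n_bins = default_n_bins(n)
    gene_index = {gid: i for i, gid in enumerate(signatures.gene_ids)}
    tf_rows = [gene_index[t] for t in candidate_tfs if t in gene_index]
    tf_ids = [signatures.gene_ids[i] for i in tf_rows]
    n_candidate_edges = max(1, len(tf_rows) * (g - 1))
    threshold = mi_null_threshold(
        X, n_perm=n_perm, alpha=alpha, n_bins=n_bins, rng=rng,
        n_candidate_edges=n_candidate_edges,
    )
    bins = _bin_indices(X, n_bins)
    mi = _mi_tf_rows(bins, np.array(tf_rows), n_bins)
    edges: dict[Edge, float] = {}
    for k, tf in enumerate(tf_ids):
        for j in np.nonzero(mi[k] > threshold)[0]:
            gid = signatures.gene_ids[j]
            if gid == tf:
                continue
            key = _edge_key(tf, gid)
            edges[key] = max(edges.get(key, 0.0), float(mi[k, j]))
    net = MINetwork(edges, tf_ids, n_cells=n, meta={"threshold": threshold, "n_bins": n_bins})
    return apply_dpi(net, tolerance)


def bootstrap_consensus(
    signatures: SignatureMatrix,
    candidate_tfs: list[str],
    n_boot: int = 20,
    support_frac: float = 0.5,
    n_bins: int | None = None,
    alpha: float | None = None,
    tolerance: float = 0.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> MINetwork:
    """Consensus network over bootstrap resamples of cells.

    Each bootstrap resamples cells with replacement and runs the full
    MI -> threshold -> DPI chain; edges kept in >= support_frac of bootstraps
    survive, with consensus MI the mean over supporting bootstraps.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0 < support_frac <= 1:
        raise ValueError("support_frac must be in (0, 1]")
    rng = np.random.default_rng([seed, 97])
    n = signatures.n_cells
    support: dict[Edge, int] = {}
    mi_sum: dict[Edge, float] = {}
    tf_ids: list[str] = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = SignatureMatrix(
            signatures.values[:, idx], signatures.gene_ids,
            [signatures.cell_ids[i] for i in idx],
        )
        net = infer_single_network(
            boot, candidate_tfs, n_bins=n_bins, alpha=alpha,
            tolerance=tolerance, n_perm=n_perm, rng=rng,
        )
        tf_ids = net.candidate_tfs
        for e, v in net.edges.items():
            support[e] = support.get(e, 0) + 1
            mi_sum[e] = mi_sum.get(e, 0.0) + v
    min_support = support_frac * n_boot - 1e-9
    edges = {
        e: mi_sum[e] / support[e] for e, c in support.items() if c >= min_support
    }
    return MINetwork(edges, tf_ids, n_cells=n, meta={"n_boot": n_boot, "support_frac": support_frac})


def assemble_regulons(
    net: MINetwork, signatures: SignatureMatrix, min_regulon_size: int = 25
) -> RegulonSet:
    """Build regulons from a pruned network.

    mode(tf, target) = Spearman correlation of the two signature rows;
    likelihood = MI / max MI within the regulon. TFs with fewer than
    min_regulon_size surviving targets are dropped.
    """
    if not net.edges:
        warnings.warn("empty network; returning empty regulon set")
        return {}
    gene_index = {g: i for i, g in enumerate(signatures.gene_ids)}
    ranked = rankdata(signatures.values, axis=1)
    ranked = (ranked - ranked.mean(axis=1, keepdims=True)) / np.where(
        ranked.std(axis=1, keepdims=True) == 0, 1, ranked.std(axis=1, keepdims=True)
    )
    out: RegulonSet = {}
    for tf in net.candidate_tfs:
        targets = sorted(t for t in net.neighbors(tf) if t in gene_index)
        if len(targets) < min_regulon_size:
            continue
        ti = gene_index[tf]
        rows = np.array([gene_index[t] for t in targets])
        modes = np.clip(ranked[rows] @ ranked[ti] / signatures.n_cells, -1.0, 1.0)
        mis = np.array([net.edges[_edge_key(tf, t)] for t in targets])
        likelihood = mis / mis.max() if mis.max() > 0 else np.ones_like(mis)
        likelihood = np.clip(likelihood, 1e-12, 1.0)
        out[tf] = Regulon(tf=tf, targets=targets, modes=modes, likelihoods=likelihood)
    return out


def spearman_mode(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation used as a signed mode of regulation."""
    rho = spearmanr(x, y).statistic
    return float(0.0 if np.isnan(rho) else rho)
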