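"""End-to-end orchestration: simulate/load -> preprocess -> cluster ->
tissue preference -> phenotype scores -> trajectory -> branch GRNs ->
activity -> master-regulon ranking.

One global seed is fanned out to the stages by fixed offsets, so a run is
fully reproducible from (config, seed). Regulatory networks are inferred per
developmental branch (falling back to a pooled all-cell network when a
branch is too small), activities from the per-branch networks are combined
by the multi-network integration rule, and each branch's regulons are ranked
against that branch's differential signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import masters as ma
from . import preprocess as pp
from . import tissue as ti
from . import trajectory as tj
from .activity import ActivityMatrix, metaviper_integrate, viper_matrix
from .cluster import ClusterAssignment, knn_cluster, pca_reduce
from .grn import MINetwork, assemble_regulons, bootstrap_consensus
from .io_formats import ExpressionMatrix, GeneSignatureSet
from .regulons import RegulonSet
from .synthetic import SimulationConfig, SyntheticDataset, simulate, truth_signature_sets

log = logging.getLogger(__name__)


@dataclass
class GrnParams:
    n_bins: int | None = None
    n_boot: int = 20
    support_frac: float = 0.5
    min_regulon_size: int = 25
    tolerance: float = 0.0
    n_perm: int = 1000
    branch_min_cells: int = 250  # below this a branch uses the pooled network


@dataclass
class ClusterParams:
    n_pcs: int = 20
    k: int = 15
    resolution: float = 1.0


@dataclass
class RankParams:
    q_max: float = 0.05
    min_size: int = 25
    top_k: int = 3
    min_overlap: int = 10


@dataclass
class PipelineResult:
    em: ExpressionMatrix
    signatures: pp.SignatureMatrix
    clusters: ClusterAssignment
    scores: pd.DataFrame
    trajectory: tj.TrajectoryModel
    branch_names: dict[str, str]  # structural label -> phenotype name
    roe: pd.DataFrame
    networks: dict[str, MINetwork]
    regulon_sets: dict[str, RegulonSet]
    activity: ActivityMatrix
    rankings: dict[str, pd.DataFrame]  # branch label -> ranking table
    masters: dict[str, list[str]]
    reports: dict[str, pd.DataFrame] = field(default_factory=dict)


def preprocess_counts(
    em: ExpressionMatrix, min_cells_per_gene: int = 3, min_genes_per_cell: int = 50
) -> tuple[ExpressionMatrix, pp.SignatureMatrix]:
    em = pp.filter(em, min_cells_per_gene, min_genes_per_cell)
    em = pp.normalize_log(em)
    return em, pp.single_cell_signatures(em)


def infer_branch_networks(
    signatures: pp.SignatureMatrix,
    branch_labels: pd.Series,
    candidate_tfs: list[str],
    grn: GrnParams,
    seed: int,
) -> tuple[dict[str, MINetwork], dict[str, RegulonSet]]:
    """One consensus network + regulon set per branch (pooled fallback)."""
    branches = sorted(b for b in branch_labels.unique() if b.startswith("branch_"))
    pooled_net: MINetwork | None = None
    pooled_regs: RegulonSet | None = None
    nets: dict[str, MINetwork] = {}
    regsets: dict[str, RegulonSet] = {}
    for bi, branch in enumerate(branches):
        cells = branch_labels.index[branch_labels == branch]
        col_idx = [i for i, c in enumerate(signatures.cell_ids) if c in set(cells)]
        if len(col_idx) >= grn.branch_min_cells:
            sub = pp.SignatureMatrix(
                signatures.values[:, col_idx],
                signatures.gene_ids,
                [signatures.cell_ids[i] for i in col_idx],
            )
            net = bootstrap_consensus(
                sub, candidate_tfs, n_boot=grn.n_boot, support_frac=grn.support_frac,
                n_bins=grn.n_bins, tolerance=grn.tolerance, n_perm=grn.n_perm,
                seed=seed + 11 + bi,
            )
            regs = assemble_regulons(net, sub, grn.min_regulon_size)
        else:
            log.info("branch %s has < %d cells; using pooled network", branch, grn.branch_min_cells)
            if pooled_net is None:
                pooled_net = bootstrap_consensus(
                    signatures, candidate_tfs, n_boot=grn.n_boot,
                    support_frac=grn.support_frac, n_bins=grn.n_bins,
                    tolerance=grn.tolerance, n_perm=grn.n_perm, seed=seed + 10,
                )
                pooled_regs = assemble_regulons(pooled_net, signatures, grn.min_regulon_size)
            net, regs = pooled_net, pooled_regs
        nets[branch] = net
        regsets[branch] = regs
    return nets, regsets


def analyze(
    em: ExpressionMatrix,
    annotation: pd.DataFrame,
    gene_sets: GeneSignatureSet,
    candidate_tfs: list[str],
    seed: int = 0,
    grn: GrnParams | None = None,
    cluster: ClusterParams | None = None,
    rank: RankParams | None = None,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 50,
) -> PipelineResult:
    """Run the full analysis on a counts matrix + cell annotation."""
    grn = grn or GrnParams()
    cluster = cluster or ClusterParams()
    rank = rank or RankParams()

    em, signatures = preprocess_counts(em, min_cells_per_gene, min_genes_per_cell)
    ann = annotation.reindex(signatures.cell_ids)

    pcs = pca_reduce(signatures, cluster.n_pcs)
    clusters = knn_cluster(
        pcs, k=cluster.k, resolution=cluster.resolution, seed=seed + 2,
        cell_ids=signatures.cell_ids,
    )
    scores = pp_scores(signatures, gene_sets)
    traj = tj.fit_trajectory(signatures, clusters.labels, scores)
    branch_names = tj.name_branches(traj, scores)
    roe_table = ti.roe_report(
        clusters.labels, ann["tissue"], ann["patient"] if "patient" in ann else None
    )

    nets, regsets = infer_branch_networks(
        signatures, traj.branch_label, candidate_tfs, grn, seed
    )
    # one activity matrix per distinct regulon set (branches sharing the
    # pooled fallback share one network and must not be double-counted)
    seen: set[int] = set()
    act_list = []
    for b in sorted(nets):
        regs = regsets[b]
        if regs and id(regs) not in seen:
            seen.add(id(regs))
            act_list.append(
                viper_matrix(signatures, regs, min_overlap=rank.min_overlap, network_id=b)
            )
    if not act_list:
        raise RuntimeError("no branch produced any regulon; cannot score activity")
    integrated = metaviper_integrate(act_list)

    rankings: dict[str, pd.DataFrame] = {}
    masters_sel: dict[str, list[str]] = {}
    reports: dict[str, pd.DataFrame] = {}
    for branch in sorted(nets):
        regs = regsets[branch]
        if not regs:
            continue
        try:
            bs = ma.branch_signature(em, traj.branch_label, branch)
        except ma.BranchSizeError as exc:
            log.warning("skipping branch %s: %s", branch, exc)
            continue
        ranking = ma.rank_regulons(bs, regs, min_overlap=rank.min_overlap)
        rankings[branch] = ranking
        masters_sel[branch] = ma.select_masters(
            ranking, q_max=rank.q_max, min_size=rank.min_size, top_k=rank.top_k
        )
        if masters_sel[branch]:
            reports[f"grn_{branch}"] = ma.export_branch_grn(masters_sel[branch], regs, bs)
    all_masters = sorted({m for ms in masters_sel.values() for m in ms})
    if all_masters:
        reports["expression_vs_activity"] = ma.expression_vs_activity_report(
            all_masters, em, integrated, traj.branch_label, ann["tissue"]
        )
        if "cytotoxicity" in scores.columns:
            reports["saturation"] = ma.expression_score_saturation(
                all_masters, em, scores["cytotoxicity"]
            )

    return PipelineResult(
        em=em, signatures=signatures, clusters=clusters, scores=scores,
        trajectory=traj, branch_names=branch_names, roe=roe_table,
        networks=nets, regulon_sets=regsets, activity=integrated,
        rankings=rankings, masters=masters_sel, reports=reports,
    )


def pp_scores(signatures: pp.SignatureMatrix, gene_sets: GeneSignatureSet) -> pd.DataFrame:
    from .scores import score_panel

    return score_panel(signatures, gene_sets)


def run_synthetic(
    config: SimulationConfig,
    seed: int | None = None,
    grn: GrnParams | None = None,
    cluster: ClusterParams | None = None,
    rank: RankParams | None = None,
) -> tuple[SyntheticDataset, PipelineResult]:
    """Simulate a dataset and run the full pipeline on it, using the planted
    TF ids as the candidate-regulator universe and the planted programs as
    phenotype gene sets (segment and truth columns stay hidden from the
    pipeline; only tissue and patient annotation are passed on)."""
    if seed is not None:
        from dataclasses import replace

        config = replace(config, seed=seed)
    ds = simulate(config)
    gss = truth_signature_sets(ds.truth, config)
    ann = ds.annotation[["tissue", "patient"]]
    result = analyze(
        ds.counts, ann, gss, candidate_tfs=sorted(ds.truth.regulons),
        seed=config.seed, grn=grn, cluster=cluster, rank=rank,
    )
    return ds, result


def effector_branch_label(result: PipelineResult) -> str | None:
    """The structural branch label the score profile names 'effector'."""
    for label, name in result.branch_names.items():
        if name == "effector":
            return label
    return None
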