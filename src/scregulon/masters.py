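"""Branch-specific differential signatures and master-regulon ranking.

For one developmental branch, every gene gets a signed normal z statistic
from a two-sided Wilcoxon rank-sum test of branch cells vs all other cells
on log-normalized expression. Each regulon is then scored by analytic
rank-based enrichment of that branch signature; two-sided normal p-values
are Benjamini-Hochberg adjusted across the regulons of the branch, and
regulons are ranked by |NES|. "Master regulons" are the top-|NES| regulons
passing the FDR and size criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, ranksums, spearmanr
from statsmodels.stats.multitest import multipletests

from .activity import ActivityMatrix, MissingOverlapError, area_es, nes
from .io_formats import ExpressionMatrix
from .regulons import RegulonSet


class BranchSizeError(ValueError):
    pass


@dataclass
class BranchSignature:
    branch: str
    z: pd.Series  # gene -> signed z (positive = up in branch)
    n_branch: int
    n_rest: int


def branch_signature(
    em: ExpressionMatrix,
    branch_labels: pd.Series,
    branch: str,
    min_cells: int = 20,
    min_detect_frac: float = 0.0,
) -> BranchSignature:
    """Signed rank-sum z per gene for branch vs rest on the lognorm layer."""
    if "lognorm" not in em.layers:
        raise ValueError("lognorm layer missing; run normalize_log first")
    labels = branch_labels.reindex(em.cell_ids)
    in_branch = (labels == branch).to_numpy()
    n_branch, n_rest = int(in_branch.sum()), int((~in_branch).sum())
    if n_branch < min_cells or n_rest < min_cells:
        raise BranchSizeError(
            f"branch {branch!r}: {n_branch} vs {n_rest} cells; need >= {min_cells} each"
        )
    x = em.layers["lognorm"]
    keep = np.ones(em.n_genes, dtype=bool)
    if min_detect_frac > 0:
        detect = (em.dense_counts() > 0).mean(axis=1)
        keep = detect >= min_detect_frac
    xs = x[keep]
    res = ranksums(xs[:, in_branch], xs[:, ~in_branch], axis=1)
    stat = np.asarray(res.statistic, dtype=float)
    diff = xs[:, in_branch].mean(axis=1) - xs[:, ~in_branch].mean(axis=1)
    sign = np.sign(diff)
    z = np.where(sign != 0, np.abs(stat) * sign, stat)
    genes = [g for g, k in zip(em.gene_ids, keep) if k]
    return BranchSignature(
        branch=branch,
        z=pd.Series(z, index=genes, name="z"),
        n_branch=n_branch,
        n_rest=n_rest,
    )


def rank_regulons(
    branch_sig: BranchSignature,
    regulons: RegulonSet,
    min_overlap: int = 10,
) -> pd.DataFrame:
    """aREA NES of each regulon on the branch signature, BH-adjusted, ranked
    by |NES| descending. Columns: tf, nes, p, q, regulon_size, rank."""
    genes = list(branch_sig.z.index)
    sig = branch_sig.z.to_numpy()
    rows = []
    for tf in sorted(regulons):
        reg = regulons[tf]
        overlap = sum(t in branch_sig.z.index for t in reg.targets)
        if overlap < min_overlap:
            continue
        try:
            es, n_eff = area_es(sig, genes, reg)
        except MissingOverlapError:
            continue
        score = nes(es, n_eff)
        rows.append((tf, score, 2.0 * norm.sf(abs(score)), reg.size))
    if not rows:
        return pd.DataFrame(columns=["tf", "nes", "p", "q", "regulon_size", "rank"])
    df = pd.DataFrame(rows, columns=["tf", "nes", "p", "regulon_size"])
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values("nes", key=lambda s: s.abs(), ascending=False, kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df[["tf", "nes", "p", "q", "regulon_size", "rank"]].reset_index(drop=True)


def select_masters(
    ranking: pd.DataFrame,
    q_max: float = 0.05,
    min_size: int = 25,
    top_k: int = 3,
) -> list[str]:
    """TFs with q <= q_max and regulon_size >= min_size, top_k by |NES|."""
    if ranking.empty:
        return []
    ok = ranking[(ranking["q"] <= q_max) & (ranking["regulon_size"] >= min_size)]
    ok = ok.sort_values("nes", key=lambda s: s.abs(), ascending=False, kind="mergesort")
    return list(ok["tf"].head(top_k))


def export_branch_grn(
    masters: list[str],
    regulons: RegulonSet,
    branch_sig: BranchSignature,
) -> pd.DataFrame:
    """Induced TF -> target edge list for the selected masters.

    Mode signs are carried over bit-exactly; each target contributes one edge
    per master that regulates it. Columns are GraphML/edge-list friendly."""
    rows = []
    for tf in masters:
        reg = regulons[tf]
        for t, m, w in zip(reg.targets, reg.modes, reg.likelihoods):
            rows.append(
                {
                    "source": tf,
                    "target": t,
                    "mode": m,
                    "likelihood": w,
                    "target_z": branch_sig.z.get(t, np.nan),
                }
            )
    return pd.DataFrame(rows, columns=["source", "target", "mode", "likelihood", "target_z"])


def expression_vs_activity_report(
    masters: list[str],
    em: ExpressionMatrix,
    activities: ActivityMatrix,
    branch_labels: pd.Series,
    tissues: pd.Series,
) -> pd.DataFrame:
    """Mean lognorm expression and mean NES per master TF, by branch and by
    tissue (the expression-vs-activity contrast tables)."""
    if "lognorm" not in em.layers:
        raise ValueError("lognorm layer missing")
    gene_index = {g: i for i, g in enumerate(em.gene_ids)}
    rows = []
    for group_type, labels in (("branch", branch_labels), ("tissue", tissues)):
        labels = labels.reindex(em.cell_ids)
        for group in sorted(labels.dropna().unique()):
            mask = (labels == group).to_numpy()
            for tf in masters:
                expr = (
                    em.layers["lognorm"][gene_index[tf], mask].mean()
                    if tf in gene_index
                    else np.nan
                )
                act = (
                    activities.nes.loc[tf].reindex(em.cell_ids).to_numpy()[mask].mean()
                    if tf in activities.nes.index
                    else np.nan
                )
                rows.append(
                    {
                        "tf": tf,
                        "group_type": group_type,
                        "group": group,
                        "mean_expression": expr,
                        "mean_activity": act,
                        "n_cells": int(mask.sum()),
                    }
                )
    return pd.DataFrame(rows)


def expression_score_saturation(
    masters: list[str],
    em: ExpressionMatrix,
    score: pd.Series,
    n_bins: int = 4,
) -> pd.DataFrame:
    """Spearman of TF expression vs a phenotype score within expression-level
    bins (the saturating-correlation readout: strong at low expression,
    tapering at high expression)."""
    if "lognorm" not in em.layers:
        raise ValueError("lognorm layer missing")
    gene_index = {g: i for i, g in enumerate(em.gene_ids)}
    s = score.reindex(em.cell_ids).to_numpy()
    rows = []
    for tf in masters:
        if tf not in gene_index:
            continue
        expr = em.layers["lognorm"][gene_index[tf]]
        order = np.argsort(expr, kind="mergesort")
        splits = np.array_split(order, n_bins)
        for bi, idx in enumerate(splits, start=1):
            if len(idx) < 3 or np.ptp(expr[idx]) == 0:
                rho, p = np.nan, np.nan
            else:
                res = spearmanr(expr[idx], s[idx])
                rho, p = float(res.statistic), float(res.pvalue)
            rows.append(
                {
                    "tf": tf,
                    "bin": bi,
                    "expression_low": float(expr[idx].min()) if len(idx) else np.nan,
                    "expression_high": float(expr[idx].max()) if len(idx) else np.nan,
                    "spearman": rho,
                    "p": p,
                    "n_cells": len(idx),
                }
            )
    return pd.DataFrame(rows)
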