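"""Phenotype signature scoring and score-vs-component trend analysis.

A signature score is the unweighted mean of the member genes' population
z-scores; with all genes retained its population mean is ~0 by construction.
Scores are correlated against trajectory components (Pearson) and smoothed
with a tri-cube-weighted local linear (LOESS) fit.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .io_formats import GeneSignatureSet
from .preprocess import SignatureMatrix

log = logging.getLogger(__name__)


class MissingSignatureError(ValueError):
    pass


def signature_score(
    signatures: SignatureMatrix,
    gene_set: list[str],
    weights: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-cell mean of the member genes' z-score rows (deduplicated).

    Optional per-gene weights turn the mean into a weighted mean. Missing
    genes are logged with the fraction present.
    """
    genes = list(dict.fromkeys(gene_set))
    index = {g: i for i, g in enumerate(signatures.gene_ids)}
    present = [g for g in genes if g in index]
    if not present:
        raise MissingSignatureError(f"none of the {len(genes)} signature genes are present")
    if len(present) < len(genes):
        log.info(
            "signature: %d/%d genes present (%.0f%%)",
            len(present), len(genes), 100 * len(present) / len(genes),
        )
    rows = signatures.values[[index[g] for g in present]]
    if weights:
        w = np.array([weights.get(g, 1.0) for g in present], dtype=float)
        return (w[:, None] * rows).sum(axis=0) / w.sum()
    return rows.mean(axis=0)


def score_panel(signatures: SignatureMatrix, gss: GeneSignatureSet) -> pd.DataFrame:
    """Cells x signatures score table (the naiveness/cytotoxicity/exhaustion panel)."""
    cols = {}
    for name, genes in gss.sets.items():
        try:
            cols[name] = signature_score(signatures, genes)
        except MissingSignatureError:
            log.warning("signature %r has no genes in the data; skipped", name)
    if not cols:
        raise MissingSignatureError("no signature could be scored")
    return pd.DataFrame(cols, index=signatures.cell_ids)


def score_component_correlation(
    scores: pd.DataFrame, components: np.ndarray
) -> pd.DataFrame:
    """Pearson R and two-sided p for every (component, score) pair."""
    rows = []
    for ci in range(components.shape[1]):
        comp = components[:, ci]
        for name in scores.columns:
            r = pearsonr(comp, scores[name].to_numpy())
            rows.append(
                {
                    "component": f"component_{ci + 1}",
                    "score": name,
                    "r": float(r.statistic),
                    "p": float(r.pvalue),
                    "n": len(comp),
                }
            )
    return pd.DataFrame(rows)


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.5,
    grid: np.ndarray | int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Tri-cube-weighted local linear regression evaluated on a grid.

    At each grid point the span-fraction nearest observations get tri-cube
    weights (1 - (d/d_max)^3)^3 and a weighted line is fit. Returns
    (grid, fitted). span must be in (0, 1]; x must not be constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")
    if isinstance(grid, (int, np.integer)):
        grid = np.linspace(x.min(), x.max(), int(grid))
    m = max(2, int(np.ceil(span * n)))
    fitted = np.empty(len(grid))
    for gi, g in enumerate(grid):
        d = np.abs(x - g)
        local = np.argpartition(d, m - 1)[:m]
        dmax = d[local].max()
        if dmax == 0:
            w = np.ones(m)
        else:
            w = (1.0 - np.minimum(d[local] / dmax, 1.0) ** 3) ** 3
        # guard: all-zero weights (every local point at exactly dmax)
        if w.sum() == 0:
            w = np.ones(m)
        xw = x[local] - g
        W = w
        s0, s1, s2 = W.sum(), (W * xw).sum(), (W * xw**2).sum()
        t0, t1 = (W * y[local]).sum(), (W * xw * y[local]).sum()
        det = s0 * s2 - s1**2
        if det <= 1e-30 * max(s0 * s2, 1e-300):  # locally degenerate: weighted mean
            fitted[gi] = t0 / s0
        else:
            fitted[gi] = (s2 * t0 - s1 * t1) / det  # intercept at x = g
    return np.asarray(grid), fitted
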