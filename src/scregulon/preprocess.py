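"""Quality filtering, library-size normalization, and per-cell expression
signatures.

The per-cell signature is a population-referenced z-score: each gene's
log-normalized expression standardized over all cells. Regulon activity
scoring consumes this matrix; the z-score of a gene in one cell measures how
unusually high or low that gene is in that cell relative to the whole
population, which is what a regulator's footprint on its targets modulates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io_formats import ExpressionMatrix

log = logging.getLogger(__name__)

SCALE_FACTOR = 1e4  # log2(1 + 1e4 * count / total): CPM-like with single-cell scale


class EmptyResultError(ValueError):
    """Filtering removed every cell (or every gene)."""


@dataclass
class SignatureMatrix:
    """Genes x cells matrix of per-cell z-scores (gene-wise standardized
    log-normalized expression). Zero-variance genes are dropped."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene)]


def filter(
    em: ExpressionMatrix, min_cells_per_gene: int = 3, min_genes_per_cell: int = 50
) -> ExpressionMatrix:
    """Remove genes detected in too few cells, then cells with too few genes.

    Gene filter is applied first, then the cell filter on the gene-filtered
    matrix; original ordering is preserved.
    """
    if min_cells_per_gene < 0 or min_genes_per_cell < 0:
        raise ValueError("filter thresholds must be >= 0")
    counts = em.counts
    detected = (counts > 0).sum(axis=1)
    detected = np.asarray(detected).ravel()
    gene_keep = detected >= min_cells_per_gene
    counts = counts[gene_keep, :] if not sp.issparse(counts) else counts.tocsr()[gene_keep, :]
    genes_per_cell = np.asarray((counts > 0).sum(axis=0)).ravel()
    cell_keep = genes_per_cell >= min_genes_per_cell
    if not cell_keep.any():
        raise EmptyResultError(
            f"min_genes_per_cell={min_genes_per_cell} removed all {em.n_cells} cells"
        )
    counts = counts[:, cell_keep] if not sp.issparse(counts) else counts.tocsc()[:, cell_keep]
    if sp.issparse(counts):
        counts = counts.tocsr()
    return ExpressionMatrix(
        counts,
        [g for g, k in zip(em.gene_ids, gene_keep) if k],
        [c for c, k in zip(em.cell_ids, cell_keep) if k],
    )


def normalize_log(em: ExpressionMatrix) -> ExpressionMatrix:
    """Add a ``lognorm`` layer: log2(1 + 1e4 * count / cell_total)."""
    counts = em.dense_counts().astype(float)
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        raise EmptyResultError("cells with zero total counts must be filtered out first")
    lognorm = np.log2(1.0 + SCALE_FACTOR * counts / totals[None, :])
    layers = dict(em.layers)
    layers["lognorm"] = lognorm
    return ExpressionMatrix(em.counts, em.gene_ids, em.cell_ids, layers)


def single_cell_signatures(em: ExpressionMatrix) -> SignatureMatrix:
    """Gene-wise z-score of the lognorm layer across all cells.

    Every cell is referenced against the all-cell mean and standard deviation
    of each gene; zero-variance genes are dropped and reported.
    """
    if "lognorm" not in em.layers:
        raise ValueError("lognorm layer missing; run normalize_log first")
    if em.n_cells < 2:
        raise ValueError("need >= 2 cells to standardize (sd undefined)")
    x = em.layers["lognorm"]
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropping %d zero-variance genes from signature matrix", n_dropped)
    z = (x[keep] - mean[keep, None]) / sd[keep, None]
    return SignatureMatrix(z, [g for g, k in zip(em.gene_ids, keep) if k], list(em.cell_ids))
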