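"""Analytic rank-based enrichment: regulon activity as a normalized
enrichment score (NES), per cell, plus multi-network integration.

For one cell, every gene's signature z-score is converted to a quantile
q = rank/(n+1) over the gene universe. The two-tail score t2 = Phi^-1(q)
carries the direction of regulation; the one-tail score
t1 = Phi^-1(2|q - 1/2|) scores extremeness regardless of direction (genes at
either tail score high, mid-ranked genes low; over the population t1 is
standard normal). The enrichment score of a regulon blends the two by mode:

    es = sum_i w_i * (mode_i * t2_i + (1 - |mode_i|) * |t1_i|) / sum_i w_i

with likelihood weights w. The NES is es * sqrt(n_eff) where
n_eff = (sum w)^2 / sum w^2, calibrated so random regulons score ~N(0, 1).
Integration across networks is self-weighted:
sum_k NES_k |NES_k| / sqrt(sum_k NES_k^2), which preserves the variance-1
null under independence and is the identity for a single network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .preprocess import SignatureMatrix
from .regulons import Regulon, RegulonSet

log = logging.getLogger(__name__)


class MissingOverlapError(ValueError):
    pass


@dataclass
class ActivityMatrix:
    """Regulators x cells NES matrix (units: sd of the gene-shuffling null)."""

    nes: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    @property
    def regulators(self) -> list[str]:
        return list(self.nes.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.nes.columns)


def _tail_scores(signature: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-tail and folded one-tail normal scores of a signature vector
    (or genes x cells matrix; ranking is within each column)."""
    n = signature.shape[0]
    q = rankdata(signature, axis=0) / (n + 1.0)
    t2 = ndtri(q)
    folded = np.clip(2.0 * np.abs(q - 0.5), 1.0 / (n + 1.0), n / (n + 1.0))
    t1 = ndtri(folded)
    return t2, t1


def area_es(
    signature: np.ndarray, gene_ids: list[str], regulon: Regulon
) -> tuple[float, float]:
    """Enrichment score of one regulon against one signature vector.

    Returns (es, n_eff). Raises MissingOverlapError when no regulon target is
    in the signature's gene universe.
    """
    signature = np.asarray(signature, dtype=float)
    index = {g: i for i, g in enumerate(gene_ids)}
    present = [k for k, t in enumerate(regulon.targets) if t in index]
    if not present:
        raise MissingOverlapError(
            f"regulon {regulon.tf}: no targets overlap the signature gene universe"
        )
    t2, t1 = _tail_scores(signature)
    rows = np.array([index[regulon.targets[k]] for k in present])
    mode = regulon.modes[present]
    w = regulon.likelihoods[present]
    contrib = mode * t2[rows] + (1.0 - np.abs(mode)) * np.abs(t1[rows])
    es = float(np.sum(w * contrib) / np.sum(w))
    n_eff = float(np.sum(w) ** 2 / np.sum(w**2))
    return es, n_eff


def nes(es: float, n_eff: float) -> float:
    """Normalize an enrichment score against the variance-1 shuffling null."""
    return es * float(np.sqrt(n_eff))


def viper_matrix(
    signatures: SignatureMatrix,
    regulons: RegulonSet,
    min_overlap: int = 10,
    network_id: str = "network",
) -> ActivityMatrix:
    """NES for every (regulon, cell).

    Regulons with fewer than min_overlap targets present in the signature gene
    universe are skipped (below that the normal null calibration degrades).
    """
    index = {g: i for i, g in enumerate(signatures.gene_ids)}
    t2, t1 = _tail_scores(signatures.values)
    abs_t1 = np.abs(t1)
    rows: dict[str, np.ndarray] = {}
    for tf, reg in regulons.items():
        present = [k for k, t in enumerate(reg.targets) if t in index]
        if len(present) < min_overlap:
            log.info("skipping regulon %s: overlap %d < %d", tf, len(present), min_overlap)
            continue
        ridx = np.array([index[reg.targets[k]] for k in present])
        mode = reg.modes[present]
        w = reg.likelihoods[present]
        es_row = (w * mode) @ t2[ridx] + (w * (1.0 - np.abs(mode))) @ abs_t1[ridx]
        es_row /= w.sum()
        n_eff = w.sum() ** 2 / (w**2).sum()
        rows[tf] = es_row * np.sqrt(n_eff)
    if not rows:
        raise MissingOverlapError("no regulon met the minimum target overlap")
    nes_df = pd.DataFrame.from_dict(rows, orient="index", columns=signatures.cell_ids)
    return ActivityMatrix(nes_df.sort_index(), provenance=[network_id])


def metaviper_integrate(activities: list[ActivityMatrix]) -> ActivityMatrix:
    """Self-weighted integration of NES matrices from multiple networks.

    integrated = sum_k NES_k * |NES_k| / sqrt(sum_k NES_k^2); a regulator
    present in only some networks uses the available ones.
    """
    if not activities:
        raise ValueError("need at least one activity matrix")
    if len(activities) == 1:
        return ActivityMatrix(activities[0].nes.copy(), list(activities[0].provenance))
    shared = set(activities[0].cell_ids)
    for am in activities[1:]:
        shared &= set(am.cell_ids)
    if not shared:
        raise ValueError("activity matrices share no cell ids")
    cells = [c for c in activities[0].cell_ids if c in shared]
    regulators = sorted(set().union(*(am.regulators for am in activities)))
    num = np.zeros((len(regulators), len(cells)))
    denom = np.zeros_like(num)
    for am in activities:
        sub = am.nes.reindex(index=regulators, columns=cells)
        vals = sub.to_numpy()
        mask = ~np.isnan(vals)
        v = np.where(mask, vals, 0.0)
        num += v * np.abs(v)
        denom += v**2
    with np.errstate(divide="ignore", invalid="ignore"):
        integrated = num / np.sqrt(denom)
    integrated[denom == 0] = 0.0
    prov = [p for am in activities for p in am.provenance]
    return ActivityMatrix(pd.DataFrame(integrated, index=regulators, columns=cells), prov)
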