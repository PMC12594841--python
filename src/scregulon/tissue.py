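"""Observed/expected tissue-preference statistics (R_O/E).

For a cluster x tissue contingency table the expected count under
independence is row_total * col_total / grand_total; R_O/E is observed over
expected. R_O/E > 1 marks enrichment of a cluster in a tissue after
adjusting for cell-sampling biases; values above a "strong" threshold (2.5
by default) mark pronounced localization. Per-cluster significance comes
from a one-way ANOVA across tissues of per-patient R_O/E replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway

log = logging.getLogger(__name__)

STRONG_THRESHOLD = 2.5


@dataclass
class RoeTable:
    observed: pd.DataFrame  # clusters x tissues counts
    expected: pd.DataFrame
    roe: pd.DataFrame  # NaN where expected == 0 (undefined, not infinite)
    chi2_contrib: pd.DataFrame


def roe(observed: pd.DataFrame) -> RoeTable:
    obs = observed.astype(float)
    if (obs.to_numpy() < 0).any():
        raise ValueError("observed counts must be non-negative")
    total = obs.to_numpy().sum()
    if total == 0:
        raise ValueError("all-zero contingency table")
    row = obs.sum(axis=1).to_numpy()
    col = obs.sum(axis=0).to_numpy()
    expected = np.outer(row, col) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = obs.to_numpy() / expected
        chi2 = (obs.to_numpy() - expected) ** 2 / expected
    ratio[expected == 0] = np.nan
    chi2[expected == 0] = np.nan
    exp_df = pd.DataFrame(expected, index=obs.index, columns=obs.columns)
    return RoeTable(
        observed=obs,
        expected=exp_df,
        roe=pd.DataFrame(ratio, index=obs.index, columns=obs.columns),
        chi2_contrib=pd.DataFrame(chi2, index=obs.index, columns=obs.columns),
    )


def crosstab(clusters: pd.Series, tissues: pd.Series) -> pd.DataFrame:
    """Cluster x tissue cell-count table from aligned per-cell labels."""
    return pd.crosstab(clusters, tissues)


def enrichment_call(value: float, tol: float = 1e-12) -> str:
    """'enriched' (> 1), 'depleted' (< 1) or 'neutral' (= 1 within tol)."""
    if np.isnan(value):
        return "undefined"
    if value > 1.0 + tol:
        return "enriched"
    if value < 1.0 - tol:
        return "depleted"
    return "neutral"


def strong_enrichment(value: float, threshold: float = STRONG_THRESHOLD) -> bool:
    return bool(not np.isnan(value) and value >= threshold)


def per_patient_roe(
    clusters: pd.Series, tissues: pd.Series, patients: pd.Series
) -> dict[str, RoeTable]:
    """R_O/E computed within each patient's own contingency table."""
    out: dict[str, RoeTable] = {}
    for patient in sorted(patients.unique()):
        mask = patients == patient
        tab = pd.crosstab(clusters[mask], tissues[mask])
        if tab.to_numpy().sum() > 0:
            out[str(patient)] = roe(tab)
    return out


def per_patient_anova(
    clusters: pd.Series, tissues: pd.Series, patients: pd.Series
) -> pd.DataFrame:
    """One-way ANOVA of per-patient R_O/E across tissues, per cluster.

    Patients contributing no cells to a tissue are excluded from that tissue's
    replicate group (logged). Clusters without >= 2 tissues each backed by
    >= 2 patients get an undefined (NaN) p, never a fake 1.
    """
    tables = per_patient_roe(clusters, tissues, patients)
    all_clusters = sorted(clusters.unique())
    all_tissues = sorted(tissues.unique())
    rows = []
    for cl in all_clusters:
        groups = []
        for t in all_tissues:
            vals = []
            for patient, rt in tables.items():
                if cl in rt.roe.index and t in rt.roe.columns:
                    v = rt.roe.loc[cl, t]
                    if not np.isnan(v):
                        vals.append(v)
                else:
                    log.info("patient %s contributes no cells to (%s, %s)", patient, cl, t)
            if len(vals) >= 2:
                groups.append(np.asarray(vals))
        if len(groups) < 2:
            rows.append((cl, np.nan, np.nan))
            continue
        flat = np.concatenate(groups)
        if np.ptp(flat) == 0:  # identical replicates everywhere: no effect
            rows.append((cl, 0.0, 1.0))
            continue
        f, p = f_oneway(*groups)
        if np.isnan(f):  # zero within-group variance with equal means
            f, p = 0.0, 1.0
        rows.append((cl, float(f), float(p)))
    return pd.DataFrame(rows, columns=["cluster", "F", "p"]).set_index("cluster")


def roe_report(
    clusters: pd.Series, tissues: pd.Series, patients: pd.Series | None = None
) -> pd.DataFrame:
    """Long-format report: one row per (cluster, tissue) with pooled R_O/E,
    the enrichment call, and (when patients are given) per-patient mean R_O/E
    and the per-cluster ANOVA p."""
    table = roe(crosstab(clusters, tissues))
    rows = []
    anova = None
    patient_mean = None
    if patients is not None:
        anova = per_patient_anova(clusters, tissues, patients)
        per_pat = per_patient_roe(clusters, tissues, patients)
        stacked = pd.concat({p: rt.roe for p, rt in per_pat.items()})
        patient_mean = stacked.groupby(level=1).mean()
    for cl in table.roe.index:
        for t in table.roe.columns:
            v = table.roe.loc[cl, t]
            rows.append(
                {
                    "cluster": cl,
                    "tissue": t,
                    "observed": table.observed.loc[cl, t],
                    "expected": table.expected.loc[cl, t],
                    "roe": v,
                    "call": enrichment_call(v),
                    "strong": strong_enrichment(v),
                    "patient_mean_roe": (
                        patient_mean.loc[cl, t]
                        if patient_mean is not None and cl in patient_mean.index
                        and t in patient_mean.columns
                        else np.nan
                    ),
                    "anova_p": anova.loc[cl, "p"] if anova is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)
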