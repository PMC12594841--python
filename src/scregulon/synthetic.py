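"""Synthetic scRNA-seq generator with planted regulons and a branched
developmental topology.

The generator emulates the study design the pipeline is meant for: CD8+
T cells from several patients and three tissue compartments (blood, adjacent
normal, tumor), organized as a root -> trunk -> three-branch differentiation
tree. Each transcription factor drives one segment of the tree: its latent
activity ramps up smoothly with pseudotime inside that segment and is ~0
elsewhere, except that the trunk program persists into the branches
(progressive differentiation: branch cells retain the intermediate program
they passed through, while the naive root program switches off on exit).
Counts are negative binomial around log-linear means driven by the planted
regulons, so every downstream stage can be tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSignatureSet, write_counts

DEFAULT_SEGMENTS: tuple[tuple[str, float], ...] = (
    ("root", 0.20),
    ("trunk", 0.20),
    ("branch_effector", 0.25),
    ("branch_exhausted", 0.175),
    ("branch_dysfunctional", 0.175),
)

# pseudotime intervals: root pinned at 0, trunk [0.2, 0.5], branches [0.5, 1.0]
SEGMENT_INTERVALS = {"root": (0.0, 0.0), "trunk": (0.2, 0.5), "branch": (0.5, 1.0)}

DEFAULT_TISSUE_PROBS: dict[str, tuple[float, ...]] = {
    "root": (0.70, 0.20, 0.10),  # stem-like cells circulate
    "trunk": (0.30, 0.45, 0.25),
    "branch_effector": (0.45, 0.40, 0.15),  # effectors in blood / normal tissue
    "branch_exhausted": (0.10, 0.20, 0.70),  # exhausted cells in the tumor
    "branch_dysfunctional": (0.10, 0.20, 0.70),
}

DEFAULT_TISSUES = ("blood", "normal", "tumor")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 300
    n_tfs: int = 6
    regulon_size: int = 40
    frac_repressed: float = 0.25
    n_cells: int = 600
    n_patients: int = 14
    n_tissues: int = 3
    branch_spec: tuple[tuple[str, float], ...] = DEFAULT_SEGMENTS
    tissue_probs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_PROBS)
    )
    effect_strength: float = 1.5
    nb_dispersion: float = 10.0
    library_size_mean: float = 2000.0
    baseline_log_sd: float = 0.5
    size_factor_log_sd: float = 0.3
    activity_noise_frac: float = 0.1  # noise sd as a fraction of effect_strength
    activity_onset: float = 0.4  # switch-like commitment level at segment entry
    tf_self_expression: bool = True  # TF genes' own expression tracks their activity
    trunk_persists: bool = True  # trunk program stays on in branch cells
    target_overlap_frac: float = 0.0  # fraction of each regulon shared with the next
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_tfs", "regulon_size", "n_patients", "n_tissues"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be >= 0")
        if not 0 <= self.frac_repressed <= 1:
            raise ConfigurationError("frac_repressed must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.effect_strength < 0:
            raise ConfigurationError("effect_strength must be >= 0")
        fracs = [f for _, f in self.branch_spec]
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"branch_spec fractions must be >= 0 and sum to 1 (got sum {sum(fracs)})"
            )
        for seg, _ in self.branch_spec:
            probs = self.tissue_probs.get(seg)
            if probs is None:
                raise ConfigurationError(f"tissue_probs missing segment {seg!r}")
            if len(probs) != self.n_tissues:
                raise ConfigurationError(
                    f"tissue_probs[{seg!r}] has {len(probs)} entries, expected {self.n_tissues}"
                )
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(f"tissue_probs[{seg!r}] must be >= 0 and sum to 1")
        if self.regulon_size * self.n_tfs > self.n_genes - self.n_tfs and (
            self.target_overlap_frac == 0.0
        ):
            raise ConfigurationError(
                "regulon_size * n_tfs exceeds the non-TF gene pool "
                f"({self.regulon_size * self.n_tfs} > {self.n_genes - self.n_tfs})"
            )

    @property
    def segment_names(self) -> list[str]:
        return [s for s, _ in self.branch_spec]

    @property
    def tissue_names(self) -> list[str]:
        if self.n_tissues == len(DEFAULT_TISSUES):
            return list(DEFAULT_TISSUES)
        return [f"tissue_{i + 1}" for i in range(self.n_tissues)]

    def segment_interval(self, segment: str) -> tuple[float, float]:
        if segment == self.segment_names[0]:
            return SEGMENT_INTERVALS["root"]
        if segment == self.segment_names[1]:
            return SEGMENT_INTERVALS["trunk"]
        return SEGMENT_INTERVALS["branch"]


@dataclass
class GroundTruth:
    """Planted truth emitted by the generator for parameter-recovery tests."""

    segment_true: np.ndarray  # per-cell segment label
    pseudotime_true: np.ndarray  # per-cell, 0 at root
    tissue: np.ndarray
    patient: np.ndarray
    cell_ids: list[str]
    regulons: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    tf_activity: pd.DataFrame | None = None  # TF x cell latent activity
    driven_segment: dict[str, str] = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    counts: ExpressionMatrix
    annotation: pd.DataFrame  # index cell_id; tissue, patient, segment
    truth: GroundTruth


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def generate_topology(config: SimulationConfig) -> GroundTruth:
    """Assign each cell a segment, pseudotime, tissue, and patient.

    Segments follow the configured fractions; pseudotime is 0 for root cells
    and uniform within the segment's interval otherwise; tissues are sampled
    from the segment's tissue probabilities; patients uniformly.
    """
    config.validate()
    rng = _rng(config, 0)
    segs = config.segment_names
    fracs = np.array([f for _, f in config.branch_spec], dtype=float)
    n = config.n_cells
    seg_idx = rng.choice(len(segs), size=n, p=fracs)
    pseudotime = np.zeros(n)
    for i, seg in enumerate(segs):
        lo, hi = config.segment_interval(seg)
        mask = seg_idx == i
        if hi > lo:
            pseudotime[mask] = rng.uniform(lo, hi, size=int(mask.sum()))
        else:
            pseudotime[mask] = lo
    tissues = np.empty(n, dtype=object)
    for i, seg in enumerate(segs):
        mask = seg_idx == i
        probs = np.array(config.tissue_probs[seg], dtype=float)
        tissues[mask] = rng.choice(config.tissue_names, size=int(mask.sum()), p=probs)
    patients = rng.choice(
        [f"P{i + 1:02d}" for i in range(config.n_patients)], size=n
    )
    cell_ids = [f"cell_{i + 1:05d}" for i in range(n)]
    return GroundTruth(
        segment_true=np.array([segs[i] for i in seg_idx], dtype=object),
        pseudotime_true=pseudotime,
        tissue=tissues,
        patient=patients.astype(object),
        cell_ids=cell_ids,
    )


def _ramp(u: np.ndarray) -> np.ndarray:
    return np.clip(u, 0.0, 1.0)


def _gene_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    tfs = [f"TF{i + 1:02d}" for i in range(config.n_tfs)]
    others = [f"G{i + 1:04d}" for i in range(config.n_genes - config.n_tfs)]
    return tfs, others


def driving_order(config: SimulationConfig) -> list[str]:
    """Segments in TF-assignment order: branches first (effector branch is the
    first listed branch, so a single TF always drives it), then trunk, then root."""
    segs = config.segment_names
    return segs[2:] + [segs[1], segs[0]]


def simulate_tf_activity(truth: GroundTruth, config: SimulationConfig) -> GroundTruth:
    """Plant regulons and fill per-cell latent TF activity.

    Each TF drives one segment: on segment entry its activity switches on to
    activity_onset * effect_strength (switch-like lineage commitment) and
    then ramps linearly to effect_strength with the cell's position in the
    segment (gradual maturation), plus Gaussian noise with sd =
    activity_noise_frac * effect_strength. The root segment is a point in
    pseudotime, so its TF is constitutively active in root cells. When
    ``trunk_persists`` is set the trunk-driving TF stays fully active in branch
    cells (the trunk program is carried forward by its descendants).
    """
    config.validate()
    rng = _rng(config, 1)
    tfs, others = _gene_ids(config)
    segs = config.segment_names
    order = driving_order(config)
    driven = {tf: order[i % len(order)] for i, tf in enumerate(tfs)}

    # regulon targets: contiguous blocks of the non-TF gene pool, optionally
    # overlapping the next block by target_overlap_frac
    step = max(1, int(round(config.regulon_size * (1.0 - config.target_overlap_frac))))
    regulons: dict[str, list[tuple[str, int]]] = {}
    pool = list(others)
    for i, tf in enumerate(tfs):
        start = (i * step) % max(1, len(pool) - config.regulon_size + 1)
        targets = pool[start : start + config.regulon_size]
        n_rep = int(round(config.frac_repressed * len(targets)))
        modes = np.ones(len(targets), dtype=int)
        rep_idx = rng.choice(len(targets), size=n_rep, replace=False)
        modes[rep_idx] = -1
        regulons[tf] = list(zip(targets, (int(m) for m in modes)))

    n = len(truth.cell_ids)
    activity = np.zeros((len(tfs), n))
    branch_names = set(segs[2:])
    trunk = segs[1]
    for ti, tf in enumerate(tfs):
        seg = driven[tf]
        lo, hi = config.segment_interval(seg)
        in_seg = truth.segment_true == seg
        if hi > lo:
            u = (truth.pseudotime_true[in_seg] - lo) / (hi - lo)
            onset = config.activity_onset
            activity[ti, in_seg] = config.effect_strength * (
                onset + (1.0 - onset) * _ramp(u)
            )
        else:
            activity[ti, in_seg] = config.effect_strength
        if seg == trunk and config.trunk_persists:
            downstream = np.isin(truth.segment_true, list(branch_names))
            activity[ti, downstream] = config.effect_strength
    noise_sd = config.activity_noise_frac * config.effect_strength
    if noise_sd > 0:
        activity += rng.normal(0.0, noise_sd, size=activity.shape)

    return replace(
        truth,
        regulons=regulons,
        tf_activity=pd.DataFrame(activity, index=tfs, columns=truth.cell_ids),
        driven_segment=driven,
    )


def simulate_counts(truth: GroundTruth, config: SimulationConfig) -> SyntheticDataset:
    """Draw negative-binomial counts around regulon-driven log-linear means.

    log-mean mu_gc = baseline_g + sum_tf mode(tf, g) * activity(tf, c); counts
    ~ NB(mean = s_c * exp(mu_gc), dispersion = nb_dispersion) with per-cell
    size factors s_c ~ LogNormal (mean 1, so the expected library size is set
    by the baselines, which are scaled to library_size_mean). TF genes' own
    expression tracks their activity when ``tf_self_expression`` is on.
    """
    config.validate()
    if truth.tf_activity is None:
        raise ValueError("tf_activity not filled; run simulate_tf_activity first")
    rng = _rng(config, 2)
    tfs, others = _gene_ids(config)
    gene_ids = tfs + others
    n_genes, n = len(gene_ids), len(truth.cell_ids)
    gi = {g: i for i, g in enumerate(gene_ids)}

    weights = rng.lognormal(mean=0.0, sigma=config.baseline_log_sd, size=n_genes)
    weights /= weights.sum()
    baseline = np.log(config.library_size_mean * weights)

    mu = np.tile(baseline[:, None], (1, max(n, 1)))[:, :n] if n else np.zeros((n_genes, 0))
    act = truth.tf_activity.to_numpy()
    for ti, tf in enumerate(tfs):
        for target, mode in truth.regulons[tf]:
            mu[gi[target]] += mode * act[ti]
        if config.tf_self_expression:
            mu[gi[tf]] += act[ti]

    sf_sd = config.size_factor_log_sd
    size_factors = rng.lognormal(mean=-0.5 * sf_sd**2, sigma=sf_sd, size=n)
    mean = size_factors[None, :] * np.exp(mu)
    theta = config.nb_dispersion
    if np.isinf(theta):
        counts = rng.poisson(mean)
    else:
        counts = rng.poisson(rng.gamma(shape=theta, scale=mean / theta))
    em = ExpressionMatrix(counts.astype(np.int64), gene_ids, list(truth.cell_ids))
    annotation = pd.DataFrame(
        {"tissue": truth.tissue, "patient": truth.patient, "segment": truth.segment_true},
        index=pd.Index(truth.cell_ids, name="cell_id"),
    )
    return SyntheticDataset(counts=em, annotation=annotation, truth=truth)


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Run topology -> activity -> counts in one call."""
    truth = generate_topology(config)
    truth = simulate_tf_activity(truth, config)
    return simulate_counts(truth, config)


def truth_regulon_table(truth: GroundTruth) -> pd.DataFrame:
    rows = [
        (tf, target, float(mode), 1.0)
        for tf, targets in truth.regulons.items()
        for target, mode in targets
    ]
    return pd.DataFrame(rows, columns=["tf", "target", "mode", "likelihood"])


def truth_signature_sets(truth: GroundTruth, config: SimulationConfig) -> GeneSignatureSet:
    """Phenotype gene sets matched to the planted programs.

    naiveness = positive targets of the root-driving TF, cytotoxicity = of the
    first effector-branch TF, exhaustion = of the exhausted-branch TF. Only
    sets whose segment is actually driven are emitted.
    """
    segs = config.segment_names
    wanted = {"naiveness": segs[0], "cytotoxicity": segs[2]}
    if len(segs) > 3:
        wanted["exhaustion"] = segs[3]
    sets: dict[str, list[str]] = {}
    for name, seg in wanted.items():
        for tf, dseg in truth.driven_segment.items():
            if dseg == seg:
                sets[name] = [t for t, m in truth.regulons[tf] if m > 0]
                break
    return GeneSignatureSet(sets)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Serialize counts (.mtx + sidecars), annotation, and truth tables.

    Output is deterministic for a fixed config and seed, and round-trips
    losslessly through the io_formats readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(ds.counts, outdir)
    ds.annotation.rename_axis("cell_id").reset_index().to_csv(
        outdir / "annotation.tsv", sep="\t", index=False
    )
    truth_regulon_table(ds.truth).to_csv(outdir / "regulons.tsv", sep="\t", index=False)
    if ds.truth.tf_activity is not None:
        ds.truth.tf_activity.rename_axis("tf").to_csv(outdir / "activity.tsv", sep="\t")
    pd.DataFrame(
        {
            "cell_id": ds.truth.cell_ids,
            "pseudotime": ds.truth.pseudotime_true,
            "segment": ds.truth.segment_true,
        }
    ).to_csv(outdir / "pseudotime.tsv", sep="\t", index=False)
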