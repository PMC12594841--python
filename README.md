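# scregulon

Master-regulon discovery for single-cell RNA-seq, built around the biology of
CD8+ T-cell differentiation in tumors. Starting from a genes × cells count
matrix with tissue/patient annotation, the pipeline:

1. infers transcription-factor regulons from the data with an
   information-theoretic network algorithm (mutual information, permutation
   null, data-processing-inequality pruning, bootstrap consensus);
2. converts each cell's expression signature into **protein-activity** scores
   (normalized enrichment of each regulon's targets), integrating evidence
   from multiple networks;
3. clusters cells, quantifies per-cluster tissue preference with the
   observed/expected ratio R_O/E, and scores naïveness / cytotoxicity /
   exhaustion signatures;
4. fits a root–trunk–branch developmental trajectory with per-cell pseudotime
   and branch labels; and
5. ranks regulons against each branch's differential signature to nominate
   **master regulons** — the TFs most significantly driving that branch
   (in CD8+ TIL biology, canonical examples for the cytotoxic effector branch
   are ZEB2, TBX21/T-bet and PRDM1/Blimp-1).

A first-class synthetic-data generator plants known regulons, TF activities,
a branched topology, and tissue-sampling preferences, so every stage of the
pipeline is tested against ground truth.

## The statistics at the core

**Network inference.** For candidate regulator *t* and gene *g*, dependence is
measured by plug-in mutual information of the equal-frequency rank-binned
joint histogram, `I(t,g) = Σ_ij p_ij log(p_ij / (p_i q_j))` (nats). Edges must
exceed the empirical `(1 − 0.05/E)` quantile of a permutation null over the
`E` candidate edges. Triangles are pruned by the data-processing inequality
(the weakest edge of each triangle is an indirect interaction), and a
consensus is taken over bootstrap resamples of cells. Target **mode** (sign
of regulation) is the Spearman correlation of regulator and target
signatures; **likelihood** is MI scaled to the regulon maximum.

**Protein activity.** Each cell's gene-wise z-scores are rank-transformed to
quantiles `q`; the two-tail score is `t2 = Φ⁻¹(q)` and the folded one-tail
score `t1 = Φ⁻¹(2|q−½|)` rewards extremeness in either direction. A regulon's
enrichment score blends both by mode,

    es = Σ_i w_i (mode_i·t2_i + (1−|mode_i|)·|t1_i|) / Σ_i w_i ,

and the normalized enrichment score `NES = es·√n_eff` with
`n_eff = (Σw)²/Σw²` is standard normal under a random-regulon null.
Multi-network integration is self-weighted:
`NES* = Σ_k NES_k|NES_k| / √(Σ_k NES_k²)`.

**Tissue preference.** For a cluster × tissue contingency table,
`R_O/E = observed / expected` with the χ² independence expectation;
`R_O/E > 1` marks enrichment, and per-cluster significance is a one-way ANOVA
over per-patient R_O/E replicates across tissues.

**Master regulons.** Per branch, every gene gets a signed Wilcoxon rank-sum z
(branch vs rest); regulons are scored by the same enrichment statistic on
that signature, Benjamini–Hochberg corrected, ranked by |NES|, and filtered
by FDR and regulon size.

## Worked example

```python
from scregulon.synthetic import SimulationConfig
from scregulon.pipeline import run_synthetic, effector_branch_label

ds, res = run_synthetic(SimulationConfig(seed=1))   # 300 genes x 600 cells
eff = effector_branch_label(res)                    # 'branch_1'
print(res.rankings[eff].head(3).to_string(index=False))
```

```
  tf       nes            p            q  regulon_size  rank
TF01 11.394912 4.432796e-30 2.216398e-29            82     1
TF06 11.283686 1.579845e-29 3.949613e-29           103     2
TF02  1.572027 1.159443e-01 1.496477e-01            55     3
```

The generator planted TF01 and TF06 as drivers of the cytotoxic-effector
branch; the pipeline ranks exactly those two on top with q ≈ 1e-29, while the
exhausted-branch driver TF02 is correctly insignificant for this branch. The
trajectory recovered the five planted segments (cluster ARI 0.85 against the
planted labels at this seed), with a degree-4 trunk hub and the root placed
on the naïve population; the exhausted-dominated cluster shows tumor
R_O/E ≈ 1.7 and the root cluster blood R_O/E ≈ 1.9, reproducing the planted
tissue-sampling design.

The same analysis runs from the shell:

```bash
scregulon simulate --seed 1 --out data/
scregulon run --config run.yaml --outdir out/    # full pipeline + manifest
```

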