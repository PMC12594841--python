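import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri
from scipy.stats import rankdata, spearmanr

from scregulon.activity import (
    ActivityMatrix,
    MissingOverlapError,
    area_es,
    metaviper_integrate,
    nes,
    viper_matrix,
)
from scregulon.preprocess import SignatureMatrix
from scregulon.regulons import Regulon


def toy_regulon(targets, modes=None, likelihoods=None):
    k = len(targets)
    return Regulon(
        tf="TF",
        targets=list(targets),
        modes=np.ones(k) if modes is None else np.asarray(modes, float),
        likelihoods=np.ones(k) if likelihoods is None else np.asarray(likelihoods, float),
    )


def es_oracle(signature, gene_ids, regulon):
    """Spreadsheet-style recomputation of the enrichment score."""
    n = len(signature)
    q = rankdata(signature) / (n + 1)
    t2 = ndtri(q)
    folded = np.clip(2 * np.abs(q - 0.5), 1 / (n + 1), n / (n + 1))
    t1 = ndtri(folded)
    num = den = 0.0
    for t, m, w in zip(regulon.targets, regulon.modes, regulon.likelihoods):
        if t in gene_ids:
            i = gene_ids.index(t)
            num += w * (m * t2[i] + (1 - abs(m)) * abs(t1[i]))
            den += w
    return num / den


class TestAreaEs:
    def test_top_quantile_activators_positive(self, rng):
        sig = np.arange(20.0)
        genes = [f"g{i}" for i in range(20)]
        es, _ = area_es(sig, genes, toy_regulon(["g17", "g18", "g19"]))
        assert es > 0

    def test_mode_flip_negates_exactly(self, rng):
        sig = rng.normal(size=30)
        genes = [f"g{i}" for i in range(30)]
        reg = toy_regulon(["g1", "g5", "g7"], modes=[1, 1, 1])
        flipped = toy_regulon(["g1", "g5", "g7"], modes=[-1, -1, -1])
        assert area_es(sig, genes, reg)[0] == pytest.approx(
            -area_es(sig, genes, flipped)[0], abs=1e-12
        )

    def test_matches_hand_oracle_with_weights_and_partial_modes(self, rng):
        sig = rng.normal(size=10)
        genes = [f"g{i}" for i in range(10)]
        reg = toy_regulon(
            ["g0", "g3", "g4", "g8"],
            modes=[1.0, -0.5, 0.25, -1.0],
            likelihoods=[1.0, 0.8, 0.6, 0.4],
        )
        es, n_eff = area_es(sig, genes, reg)
        assert es == pytest.approx(es_oracle(sig, genes, reg), abs=1e-12)
        w = np.array([1.0, 0.8, 0.6, 0.4])
        assert n_eff == pytest.approx(w.sum() ** 2 / (w**2).sum())

    def test_no_overlap_raises_with_tf_name(self, rng):
        sig = rng.normal(size=10)
        with pytest.raises(MissingOverlapError, match="TF"):
            area_es(sig, [f"g{i}" for i in range(10)], toy_regulon(["absent"]))


class TestNes:
    def test_unit_n_eff_identity(self):
        assert nes(0.7, 1.0) == 0.7

    def test_duplicated_targets_collapse(self, rng):
        sig = rng.normal(size=50)
        genes = [f"g{i}" for i in range(50)]
        single = toy_regulon(["g3"])
        dup = toy_regulon(["g3", "g3"])
        assert nes(*area_es(sig, genes, single)) == pytest.approx(
            nes(*area_es(sig, genes, dup))
        )

    def test_analytic_nes_matches_permutation_z(self, rng):
        """|analytic NES - permutation z| small across random +/-1-mode
        regulons (gene-label shuffling null)."""
        n = 800
        sig = rng.normal(size=n)
        genes = [f"g{i}" for i in range(n)]
        q = rankdata(sig) / (n + 1)
        t2 = ndtri(q)
        devs = []
        for _ in range(10):
            size = int(rng.integers(25, 101))
            idx = rng.choice(n, size=size, replace=False)
            modes = rng.choice([-1.0, 1.0], size=size)
            reg = toy_regulon([genes[i] for i in idx], modes=modes)
            analytic = nes(*area_es(sig, genes, reg))
            perm_idx = np.argsort(rng.random((4000, n)), axis=1)[:, :size]
            null = (modes[None, :] * t2[perm_idx]).mean(axis=1)
            z = (analytic / np.sqrt(size) - null.mean()) / null.std()
            devs.append(abs(analytic - z))
        assert max(devs) <= 0.15


class TestViperMatrix:
    def test_composition_matches_per_cell_scores(self, rng):
        vals = rng.normal(size=(40, 3))
        genes = [f"g{i}" for i in range(40)]
        sig = SignatureMatrix(vals, genes, ["c1", "c2", "c3"])
        reg = toy_regulon([f"g{i}" for i in range(12)])
        am = viper_matrix(sig, {"TF": reg}, min_overlap=10)
        for j in range(3):
            expected = nes(*area_es(vals[:, j], genes, reg))
            assert am.nes.iloc[0, j] == pytest.approx(expected, abs=1e-10)

    def test_insufficient_overlap_skipped(self, rng):
        sig = SignatureMatrix(rng.normal(size=(30, 2)), [f"g{i}" for i in range(30)],
                              ["c1", "c2"])
        small = toy_regulon(["g1", "g2"])
        big = toy_regulon([f"g{i}" for i in range(15)])
        am = viper_matrix(sig, {"small": small, "big": big}, min_overlap=10)
        assert am.regulators == ["big"]
        with pytest.raises(MissingOverlapError):
            viper_matrix(sig, {"small": small}, min_overlap=10)

    def test_null_signature_gives_small_row_means(self, rng):
        sig = SignatureMatrix(rng.normal(size=(500, 200)),
                              [f"g{i}" for i in range(500)],
                              [f"c{i}" for i in range(200)])
        regs = {
            f"T{k}": toy_regulon(
                [f"g{i}" for i in rng.choice(500, 40, replace=False)],
                modes=rng.choice([-1.0, 1.0], 40),
            )
            for k in range(10)
        }
        am = viper_matrix(sig, regs)
        assert np.abs(am.nes.to_numpy().mean(axis=1)).max() < 0.2

    def test_recovers_planted_activity(self, dataset, signatures, truth_regulons):
        am = viper_matrix(signatures, truth_regulons)
        rhos = [
            abs(spearmanr(
                am.nes.loc[tf].to_numpy(),
                dataset.truth.tf_activity.loc[tf].reindex(am.cell_ids).to_numpy(),
            ).statistic)
            for tf in truth_regulons
        ]
        assert np.median(rhos) >= 0.6


class TestMetaViper:
    def test_single_network_identity(self, rng):
        nes_df = pd.DataFrame(rng.normal(size=(3, 5)), index=list("abc"),
                              columns=[f"c{i}" for i in range(5)])
        am = ActivityMatrix(nes_df, ["net1"])
        out = metaviper_integrate([am])
        pd.testing.assert_frame_equal(out.nes, nes_df)

    def test_two_identical_networks_scale_by_sqrt2(self, rng):
        """Two copies of the same evidence integrate to sqrt(2) x NES: the
        rule treats networks as independent and preserves the variance-1
        null under that assumption."""
        nes_df = pd.DataFrame(rng.normal(size=(3, 5)), index=list("abc"),
                              columns=[f"c{i}" for i in range(5)])
        am = ActivityMatrix(nes_df, ["n"])
        out = metaviper_integrate([am, am])
        np.testing.assert_allclose(out.nes.to_numpy(), np.sqrt(2) * nes_df.to_numpy())

    def test_partial_regulator_coverage_uses_available(self, rng):
        a = ActivityMatrix(pd.DataFrame([[1.0, -2.0]], index=["r1"], columns=["c1", "c2"]))
        b = ActivityMatrix(pd.DataFrame([[3.0, 0.5]], index=["r2"], columns=["c1", "c2"]))
        out = metaviper_integrate([a, b])
        np.testing.assert_allclose(out.nes.loc["r1"], [1.0, -2.0])
        np.testing.assert_allclose(out.nes.loc["r2"], [3.0, 0.5])

    def test_disjoint_cells_error(self):
        a = ActivityMatrix(pd.DataFrame([[1.0]], index=["r"], columns=["c1"]))
        b = ActivityMatrix(pd.DataFrame([[1.0]], index=["r"], columns=["c2"]))
        with pytest.raises(ValueError, match="share no cell"):
            metaviper_integrate([a, b])

    def test_permuted_network_degrades_gracefully(self, dataset, signatures, truth_regulons, rng):
        """Adding a label-permuted network keeps >= 80% of the informative
        network's truth correlation and beats the permuted network alone."""
        informative = viper_matrix(signatures, truth_regulons, network_id="good")
        genes = list(signatures.gene_ids)
        permuted_regs = {}
        for tf, reg in truth_regulons.items():
            idx = rng.choice(len(genes), size=reg.size, replace=False)
            permuted_regs[tf] = Regulon(tf, [genes[i] for i in idx], reg.modes,
                                        reg.likelihoods)
        permuted = viper_matrix(signatures, permuted_regs, network_id="perm")
        combined = metaviper_integrate([informative, permuted])

        def truth_corr(am):
            return np.median([
                abs(spearmanr(
                    am.nes.loc[tf].to_numpy(),
                    dataset.truth.tf_activity.loc[tf].reindex(am.cell_ids).to_numpy(),
                ).statistic)
                for tf in truth_regulons
            ])

        good, comb, perm = truth_corr(informative), truth_corr(combined), truth_corr(permuted)
        assert comb >= 0.8 * good
        assert comb > perm


def test_null_calibration_mean_and_sd(rng):
    """NES over 1000 random regulons on a standard-normal signature has mean
    in [-0.1, 0.1] and sd in [0.9, 1.1]."""
    n = 1000
    sig = SignatureMatrix(rng.normal(size=(n, 1)), [f"g{i}" for i in range(n)], ["c"])
    scores = []
    for _ in range(1000):
        size = int(rng.integers(25, 101))
        idx = rng.choice(n, size=size, replace=False)
        reg = toy_regulon([f"g{i}" for i in idx], modes=rng.choice([-1.0, 1.0], size))
        am = viper_matrix(sig, {"T": reg}, min_overlap=10)
        scores.append(am.nes.iloc[0, 0])
    assert -0.1 <= np.mean(scores) <= 0.1
    assert 0.9 <= np.std(scores) <= 1.1
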