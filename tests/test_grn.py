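import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scregulon.grn import (
    MINetwork,
    apply_dpi,
    assemble_regulons,
    bootstrap_consensus,
    default_n_bins,
    infer_single_network,
    mi_null_threshold,
    mutual_information,
)
from scregulon.preprocess import SignatureMatrix


def mi_oracle(x, y, n_bins):
    """Independent plug-in MI: sort-based equal-frequency bins + explicit sums."""
    n = len(x)
    bx = np.empty(n, dtype=int)
    by = np.empty(n, dtype=int)
    bx[np.argsort(x, kind="stable")] = np.repeat(np.arange(n_bins), n // n_bins)
    by[np.argsort(y, kind="stable")] = np.repeat(np.arange(n_bins), n // n_bins)
    mi = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            pij = np.sum((bx == i) & (by == j)) / n
            if pij > 0:
                pi = np.sum(bx == i) / n
                pj = np.sum(by == j) / n
                mi += pij * np.log(pij / (pi * pj))
    return mi


def dpi_oracle(net: MINetwork, tolerance: float) -> set:
    """Exhaustive triangle enumeration over all node triples."""
    und = {frozenset(e): v for e, v in net.edges.items()}
    nodes = sorted({n for e in net.edges for n in e})
    doomed = set()
    for a, b, c in itertools.combinations(nodes, 3):
        ab, bc, ac = frozenset((a, b)), frozenset((b, c)), frozenset((a, c))
        if ab in und and bc in und and ac in und:
            vals = [(und[ab], ab), (und[bc], bc), (und[ac], ac)]
            for v, e in vals:
                others = min(x for x, o in vals if o != e)
                if v < others * (1 - tolerance):
                    doomed.add(e)
    return {e for e in net.edges if frozenset(e) not in doomed}


def random_network(rng, n_nodes=20, p=0.3):
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    edges = {}
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if rng.random() < p:
                edges[(a, b)] = float(rng.random())
    return MINetwork(edges, candidate_tfs=nodes)


class TestMutualInformation:
    def test_matches_oracle_on_random_cases(self, rng):
        for _ in range(100):
            n_bins = int(rng.integers(2, 6))
            n = n_bins * int(rng.integers(5, 20))
            x, y = rng.normal(size=n), rng.normal(size=n)
            assert mutual_information(x, y, n_bins) == pytest.approx(
                mi_oracle(x, y, n_bins), abs=1e-12
            )

    def test_perfect_dependence_hits_log_bins(self, rng):
        x = rng.normal(size=400)
        assert mutual_information(x, x, n_bins=4) == pytest.approx(np.log(4), abs=1e-12)

    def test_independent_large_sample_near_zero(self, rng):
        x = rng.normal(size=10_000)
        y = rng.permutation(x)
        assert mutual_information(x, y) < 0.01

    def test_constant_vector_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert mutual_information(np.ones(20), np.arange(20.0)) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            mutual_information(np.arange(10.0), np.arange(12.0))

    def test_default_bin_rule(self):
        assert default_n_bins(10) == 2
        assert default_n_bins(180) == 6
        assert default_n_bins(10_000) == 10

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_monotone_invariant(self, seed):
        """MI(x, y) == MI(y, x) and is invariant to strictly monotone
        transforms of either argument (rank-based estimator)."""
        r = np.random.default_rng(seed)
        x = r.normal(size=60)
        y = x + r.normal(size=60)
        a = mutual_information(x, y, 4)
        assert mutual_information(y, x, 4) == pytest.approx(a, abs=1e-12)
        assert mutual_information(np.exp(x), y**3, 4) == pytest.approx(a, abs=1e-12)


class TestNullThreshold:
    def test_alpha_one_gives_null_minimum(self, rng):
        X = rng.normal(size=(20, 100))
        rng2 = np.random.default_rng(0)
        thr = mi_null_threshold(X, n_perm=200, alpha=1.0, rng=rng2)
        rng3 = np.random.default_rng(0)
        null = []
        from scregulon.grn import _bin_indices, _mi_from_bins

        bins = _bin_indices(X, default_n_bins(100))
        for _ in range(200):
            a, b = rng3.choice(20, size=2, replace=False)
            null.append(_mi_from_bins(bins[a], rng3.permutation(bins[b]), default_n_bins(100)))
        assert thr == pytest.approx(min(null))

    def test_reproducible_for_fixed_seed(self, rng):
        X = rng.normal(size=(15, 120))
        t1 = mi_null_threshold(X, n_perm=150, rng=np.random.default_rng(5))
        t2 = mi_null_threshold(X, n_perm=150, rng=np.random.default_rng(5))
        assert t1 == t2

    def test_threshold_shrinks_with_sample_size(self):
        """The MI estimator concentrates: null thresholds at n=1000 are
        stochastically below those at n=100 (20 replicates each)."""
        smaller = 0
        for rep in range(20):
            r = np.random.default_rng(100 + rep)
            t_small = mi_null_threshold(r.normal(size=(10, 100)), n_perm=100,
                                        alpha=0.05, rng=r)
            t_big = mi_null_threshold(r.normal(size=(10, 1000)), n_perm=100,
                                      alpha=0.05, rng=r)
            smaller += t_big < t_small
        assert smaller >= 15


class TestDpi:
    def test_weakest_triangle_edge_removed(self):
        net = MINetwork({("a", "b"): 0.5, ("b", "c"): 0.4, ("a", "c"): 0.1}, ["a", "b", "c"])
        out = apply_dpi(net)
        assert set(out.edges) == {("a", "b"), ("b", "c")}

    def test_triangle_free_identity(self, rng):
        net = MINetwork({("a", "b"): 0.5, ("c", "d"): 0.4, ("a", "d"): 0.1},
                        ["a", "b", "c", "d"])
        assert set(apply_dpi(net).edges) == set(net.edges)

    @pytest.mark.parametrize("tolerance", [0.0, 0.15])
    def test_matches_bruteforce_oracle(self, tolerance):
        rng = np.random.default_rng(42)
        for _ in range(50):
            net = random_network(rng, n_nodes=int(rng.integers(5, 26)))
            assert set(apply_dpi(net, tolerance).edges) == dpi_oracle(net, tolerance)


class TestConsensus:
    def test_single_bootstrap_support_one_equals_single_run(self, signatures, dataset):
        tfs = sorted(dataset.truth.regulons)
        net = bootstrap_consensus(signatures, tfs, n_boot=1, support_frac=1.0, seed=3)
        rng = np.random.default_rng([3, 97])
        idx = rng.integers(0, signatures.n_cells, size=signatures.n_cells)
        boot = SignatureMatrix(
            signatures.values[:, idx], signatures.gene_ids,
            [signatures.cell_ids[i] for i in idx],
        )
        single = infer_single_network(boot, tfs, rng=rng)
        assert net.edges == single.edges

    def test_full_support_subset_of_half_support(self, signatures, dataset):
        tfs = sorted(dataset.truth.regulons)
        full = bootstrap_consensus(signatures, tfs, n_boot=5, support_frac=1.0, seed=2)
        half = bootstrap_consensus(signatures, tfs, n_boot=5, support_frac=0.5, seed=2)
        assert set(full.edges) <= set(half.edges)


class TestRegulonAssembly:
    def test_modes_are_signed_correlations(self, rng):
        n = 200
        x = rng.normal(size=n)
        vals = np.vstack([x, x + 0.01 * rng.normal(size=n), -x + 0.01 * rng.normal(size=n)])
        sig = SignatureMatrix(vals, ["tf", "up", "down"], [f"c{i}" for i in range(n)])
        net = MINetwork({("tf", "up"): 1.0, ("down", "tf"): 0.5}, ["tf"], n)
        regs = assemble_regulons(net, sig, min_regulon_size=2)
        reg = regs["tf"]
        d = dict(zip(reg.targets, reg.modes))
        assert d["up"] > 0.99 and d["down"] < -0.99
        w = dict(zip(reg.targets, reg.likelihoods))
        assert w["up"] == 1.0 and w["down"] == pytest.approx(0.5)

    def test_small_regulons_dropped(self, rng):
        sig = SignatureMatrix(rng.normal(size=(3, 50)), ["tf", "a", "b"],
                              [f"c{i}" for i in range(50)])
        net = MINetwork({("a", "tf"): 1.0, ("b", "tf"): 1.0}, ["tf"], 50)
        assert assemble_regulons(net, sig, min_regulon_size=3) == {}

    def test_empty_network_warns(self, signatures):
        with pytest.warns(UserWarning, match="empty"):
            assert assemble_regulons(MINetwork({}, []), signatures) == {}

    def test_planted_repressors_recover_negative_modes(self, dataset, consensus_regulons):
        _, regs = consensus_regulons
        truth = dataset.truth
        flags = []
        for tf, targets in truth.regulons.items():
            if tf not in regs:
                continue
            modes = dict(zip(regs[tf].targets, regs[tf].modes))
            truemode = dict(targets)
            for t, m in modes.items():
                if truemode.get(t, 0) < 0:
                    flags.append(m < 0)
        assert np.mean(flags) >= 0.8


def test_parameter_recovery_f1(dataset, consensus_regulons):
    """Default synthetic conditions: median per-TF target F1 >= 0.6."""
    net, _ = consensus_regulons
    f1s = []
    for tf, targets in dataset.truth.regulons.items():
        true_set = {t for t, _ in targets}
        inferred = set(net.neighbors(tf)) - set(dataset.truth.regulons)
        tp = len(true_set & inferred)
        prec = tp / len(inferred) if inferred else 0.0
        rec = tp / len(true_set)
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    assert np.median(f1s) >= 0.6
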