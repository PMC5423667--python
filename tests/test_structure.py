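"""Chord distance, NJ + bootstrap, PCoA, Weir-Cockerham theta."""

import numpy as np
import pytest

import skagerrak as sk
from skagerrak.genotypes import MISSING

from conftest import tiny_table


def dm(labels, vals, metric="test"):
    return sk.DistanceMatrix(list(labels), np.asarray(vals, dtype=float), metric)


class TestChordDistance:
    def test_identical_profiles_zero(self):
        f = {"L1": {1: 0.3, 2: 0.7}, "L2": {5: 1.0}}
        assert sk.chord_distance(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_alleles_maximal(self):
        d = sk.chord_distance({"L1": {1: 1.0}}, {"L1": {2: 1.0}})
        assert d == pytest.approx(2 / np.pi * np.sqrt(2))

    def test_two_allele_closed_form(self):
        d = sk.chord_distance({"L1": {1: 1.0, 2: 0.0}}, {"L1": {1: 0.5, 2: 0.5}})
        assert d == pytest.approx(2 / np.pi * np.sqrt(2 * (1 - np.sqrt(0.5))))

    def test_mean_vs_rms_combination(self):
        fx = {"L1": {1: 1.0}, "L2": {1: 1.0}}
        fy = {"L1": {2: 1.0}, "L2": {1: 1.0}}
        dmax = 2 / np.pi * np.sqrt(2)
        assert sk.chord_distance(fx, fy, combine="mean") == pytest.approx(dmax / 2)
        assert sk.chord_distance(fx, fy, combine="rms") == pytest.approx(dmax / np.sqrt(2))

    def test_undefined_locus_dropped_with_warning(self):
        fx = {"L1": {1: 1.0}, "L2": {}}
        fy = {"L1": {2: 1.0}, "L2": {1: 1.0}}
        with pytest.warns(UserWarning, match="dropped"):
            d = sk.chord_distance(fx, fy)
        assert d == pytest.approx(2 / np.pi * np.sqrt(2))

    def test_invariant_to_allele_relabeling(self, six_pop_table):
        ft = sk.allele_frequencies(six_pop_table)
        d1 = sk.chord_matrix(ft)
        shifted = {
            p: {l: {a + 1000: f for a, f in ft.freq(p, l).items()} for l in ft.loci}
            for p in ft.populations
        }
        ft2 = sk.AlleleFrequencyTable(ft.populations, ft.loci, shifted, ft.n_copies)
        d2 = sk.chord_matrix(ft2)
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # d(A,B)=3, d(A,C)=4, d(B,C)=5 -> vA=1, vB=2, vC=3
        D = dm("ABC", [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        tree = sk.nj_tree(D)
        assert tree.distance("A", "B") == pytest.approx(3)
        assert tree.distance("A", "C") == pytest.approx(4)
        assert tree.distance("B", "C") == pytest.approx(5)

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) -> additive distances
        D = dm(
            "ABCD",
            [
                [0, 3, 8, 9],
                [3, 0, 9, 10],
                [8, 9, 0, 9],
                [9, 10, 9, 0],
            ],
        )
        tree = sk.nj_tree(D)
        assert frozenset({"C", "D"}) in tree.splits()  # == split {A,B}|{C,D}
        for a, b, d in (("A", "B", 3), ("A", "D", 9), ("C", "D", 9), ("B", "C", 9)):
            assert tree.distance(a, b) == pytest.approx(d)

    def test_ultrametric_topology_matches_independent_nj(self):
        pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(12)
        # random points in 3D -> Euclidean distances (metric, generic position)
        pts = rng.random((6, 3))
        labels = list("ABCDEF")
        M = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        mine = sk.nj_tree(dm(labels, M))
        other = skbio_nj(SkbioDM(M, ids=labels))

        def skbio_splits(t):
            out = set()
            all_leaves = frozenset(labels)
            for node in t.non_tips(include_self=False):
                side = frozenset(x.name for x in node.tips())
                if "A" in side:
                    side = all_leaves - side
                if 2 <= len(side) <= len(labels) - 2:
                    out.add(side)
            return out

        assert set(mine.splits()) == skbio_splits(other)

    def test_too_few_taxa_raises(self):
        with pytest.raises(ValueError):
            sk.nj_tree(dm("AB", [[0, 1], [1, 0]]))

    def test_newick_is_parseable(self):
        pytest.importorskip("dendropy")
        import dendropy

        D = dm("ABCDE", np.abs(np.subtract.outer(range(5), range(5))).astype(float))
        tree = sk.nj_tree(D)
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == set("ABCDE")


def two_cluster_table(seed=1):
    """Six populations in two strongly diverged clusters (independent
    ancestral pools)."""
    tA = sk.simulate_genotypes(
        sk.GenoSimConfig(pop_names=["A1", "A2", "A3"], sizes=[40] * 3, F=0.02,
                         missing_rate=0.0, n_alleles=6),
        seed=seed,
    )
    tB = sk.simulate_genotypes(
        sk.GenoSimConfig(pop_names=["B1", "B2", "B3"], sizes=[40] * 3, F=0.02,
                         missing_rate=0.0, n_alleles=6),
        seed=seed + 1000,
    )
    return sk.GenotypeTable(
        tA.individuals + tB.individuals,
        tA.populations + tB.populations,
        tA.loci,
        np.concatenate([tA.calls, tB.calls], axis=0),
    )


class TestBootstrapNJ:
    def test_strong_signal_split_is_supported(self):
        tree = sk.bootstrap_nj(two_cluster_table(), reps=200, seed=7)
        assert tree.supports[frozenset({"B1", "B2", "B3"})] > 0.95
        assert frozenset({"B1", "B2", "B3"}) in tree.significant_splits()

    def test_deterministic_given_seed(self):
        t = two_cluster_table(seed=4)
        s1 = sk.bootstrap_nj(t, reps=100, seed=5).supports
        s2 = sk.bootstrap_nj(t, reps=100, seed=5).supports
        assert s1 == s2

    def test_null_supports_stay_low_on_average(self, quiet_warnings):
        # no structure: supports should sit far below the strong-signal
        # regime (bootstrap proportions are not p-values, so individual
        # null runs can still flag a split; the average must not)
        max_sup = []
        for r in range(15):
            cfg = sk.GenoSimConfig(
                pop_names=[f"P{i}" for i in range(6)], sizes=[30] * 6, F=0.0,
                missing_rate=0.0, n_alleles=8,
                loci=[(f"L{i}", 100 + 60 * i) for i in range(12)],
            )
            t = sk.simulate_genotypes(cfg, seed=500 + r)
            tree = sk.bootstrap_nj(t, reps=100, seed=600 + r)
            max_sup.append(max(tree.supports.values()))
        assert np.mean(max_sup) < 0.70

    def test_single_locus_is_degenerate(self):
        t = two_cluster_table()
        one = sk.GenotypeTable(
            t.individuals, t.populations, t.loci[:1], t.calls[:, :1, :]
        )
        with pytest.raises(ValueError):
            sk.bootstrap_nj(one, reps=10, seed=0)


class TestPcoa:
    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(3)
        pts = rng.random((4, 2)) * 10
        M = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = sk.pcoa(dm("ABCD", M))
        C = res.coordinates[:, :2]
        rec = np.sqrt(((C[:, None] - C[None]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, M, atol=1e-9)

    def test_equidistant_simplex_has_equal_eigenvalues(self):
        k = 5
        M = np.ones((k, k)) - np.eye(k)
        res = sk.pcoa(dm([f"P{i}" for i in range(k)], M))
        assert res.eigenvalues.size == k - 1
        np.testing.assert_allclose(res.eigenvalues, res.eigenvalues[0], rtol=1e-9)
        np.testing.assert_allclose(res.percent_variance, 100 / (k - 1), rtol=1e-9)

    def test_percents_match_independent_decomposition(self):
        pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(9)
        pts = rng.random((6, 4))
        M = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = sk.pcoa(dm("ABCDEF", M))
        ref = skbio_pcoa(M)
        np.testing.assert_allclose(
            res.percent_variance[:4],
            100 * ref.proportion_explained.to_numpy()[:4],
            atol=1e-6,
        )

    def test_all_zero_distances(self):
        res = sk.pcoa(dm("ABC", np.zeros((3, 3))))
        assert res.coordinates.shape[1] == 0


def wc_theta_oracle(table, pop_a, pop_b):
    """Independent per-allele variance-components computation (plain loops,
    no shared code with the implementation)."""
    num = den = 0.0
    ma, mb = table.pop_mask(pop_a), table.pop_mask(pop_b)
    for j, _locus in enumerate(table.loci):
        ga = [tuple(c) for c in table.calls[ma, j, :] if c[0] != MISSING]
        gb = [tuple(c) for c in table.calls[mb, j, :] if c[0] != MISSING]
        n1, n2 = len(ga), len(gb)
        if n1 < 1 or n2 < 1 or n1 + n2 < 3:
            continue
        alleles = sorted({a for g in ga + gb for a in g})
        if len(alleles) < 2:
            continue
        nbar = (n1 + n2) / 2
        nc = 2 * nbar - (n1**2 + n2**2) / (2 * nbar)
        for al in alleles:
            p1 = sum(g.count(al) for g in ga) / (2 * n1)
            p2 = sum(g.count(al) for g in gb) / (2 * n2)
            h1 = sum(1 for g in ga if al in g and g[0] != g[1]) / n1
            h2 = sum(1 for g in gb if al in g and g[0] != g[1]) / n2
            pbar = (n1 * p1 + n2 * p2) / (2 * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
            hbar = (n1 * h1 + n2 * h2) / (2 * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


class TestWeirCockerhamTheta:
    def test_complete_fixation_is_one(self):
        t = tiny_table(
            [[(100, 100)], [(100, 100)], [(120, 120)], [(120, 120)]],
            pops=["A", "A", "B", "B"],
        )
        assert sk.pairwise_fst(t, "A", "B") == pytest.approx(1.0)

    def test_matches_component_oracle(self):
        rng = np.random.default_rng(21)
        calls = 100 + 2 * rng.integers(0, 5, size=(30, 4, 2))
        calls[rng.random((30, 4)) < 0.08] = 0
        t = tiny_table(calls, pops=["A"] * 14 + ["B"] * 16)
        assert sk.pairwise_fst(t, "A", "B") == pytest.approx(
            wc_theta_oracle(t, "A", "B"), abs=1e-10
        )

    def test_random_split_of_one_population_is_null(self):
        cfg = sk.GenoSimConfig(
            pop_names=["H1", "H2"], sizes=[100, 100], F=0.0,
            missing_rate=0.0, n_alleles=10,
            loci=[(f"L{i}", 100 + 60 * i) for i in range(10)],
        )
        t = sk.simulate_genotypes(cfg, seed=31)
        assert abs(sk.pairwise_fst(t, "H1", "H2")) < 0.02

    def test_invariant_to_population_order(self, six_pop_table):
        a = sk.pairwise_fst(six_pop_table, "N_G", "S_S")
        b = sk.pairwise_fst(six_pop_table, "S_S", "N_G")
        assert a == pytest.approx(b, abs=1e-14)


class TestFstPermutation:
    def test_fixed_difference_minimal_p(self):
        calls = [[(100, 100)]] * 8 + [[(120, 120)]] * 8
        t = tiny_table(calls, pops=["A"] * 8 + ["B"] * 8)
        theta, p = sk.fst_permutation_test(t, "A", "B", reps=99, seed=2)
        assert theta == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_deterministic_given_seed(self, two_pop_null_table):
        r1 = sk.fst_permutation_test(two_pop_null_table, "P1", "P2", reps=99, seed=3)
        r2 = sk.fst_permutation_test(two_pop_null_table, "P1", "P2", reps=99, seed=3)
        assert r1 == r2

    def test_invalid_reps(self, two_pop_null_table):
        with pytest.raises(ValueError):
            sk.fst_permutation_test(two_pop_null_table, "P1", "P2", reps=0)

    def test_matrix_layout(self, six_pop_table):
        res = sk.fst_matrix(six_pop_table, reps=49, seed=1)
        df = res.to_dataframe()
        pops = six_pop_table.population_order
        assert list(df.index) == pops
        # lower triangle theta, upper triangle p in (0, 1]
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                assert 0 < df.iloc[i, j] <= 1
                assert np.isfinite(df.iloc[j, i])
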