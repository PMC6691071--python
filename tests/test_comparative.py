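"""Distances, ordination, ANOSIM and tree building."""

import io

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode

from conftest import exhaustive_anosim_p, random_additive_tree
from ecosig.comparative import (
    Cladogram,
    anosim,
    bootstrap_consensus,
    correlation_scatter,
    euclidean_distances,
    majority_consensus,
    neighbor_joining,
    nmds,
    pearson_dissimilarities,
)


def _sig(rows: np.ndarray, ids=None) -> pd.DataFrame:
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=ids)


def _cladogram(newick: str) -> Cladogram:
    return Cladogram(TreeNode.read(io.StringIO(newick)))


class TestDistances:
    def test_euclidean_three_four_five(self):
        rows = np.zeros((2, 256))
        rows[1, 0], rows[1, 1] = 3.0, 4.0
        dm = euclidean_distances(_sig(rows))
        assert dm[0, 1] == pytest.approx(5.0)

    def test_euclidean_identical_rows_zero(self):
        rows = np.tile(np.arange(256.0), (2, 1))
        assert euclidean_distances(_sig(rows))[0, 1] == 0.0

    def test_euclidean_matches_bruteforce(self, rng):
        rows = rng.normal(size=(4, 256))
        dm = euclidean_distances(_sig(rows))
        for i in range(4):
            for j in range(4):
                expected = np.sqrt(((rows[i] - rows[j]) ** 2).sum())
                assert dm[i, j] == pytest.approx(expected)

    def test_pearson_self_zero_negation_two(self):
        base = np.arange(256.0)
        rows = np.vstack([base, base, -base])
        dm = pearson_dissimilarities(_sig(rows))
        assert dm[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert dm[0, 2] == pytest.approx(2.0)

    def test_pearson_matches_bruteforce(self, rng):
        rows = rng.normal(size=(3, 256))
        dm = pearson_dissimilarities(_sig(rows))
        for i in range(3):
            for j in range(3):
                r = np.corrcoef(rows[i], rows[j])[0, 1]
                assert dm[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_pearson_half_convention(self, rng):
        rows = rng.normal(size=(3, 256))
        full = pearson_dissimilarities(_sig(rows), "one_minus_r")
        half = pearson_dissimilarities(_sig(rows), "half")
        assert np.allclose(half.data, full.data / 2)

    def test_pearson_zero_variance_row_named(self):
        rows = np.vstack([np.arange(256.0), np.zeros(256)])
        with pytest.raises(ValueError, match="s1"):
            pearson_dissimilarities(_sig(rows))

    def test_correlation_scatter_identity_and_consistency(self, rng):
        rows = rng.normal(size=(5, 256))
        sig = _sig(rows)
        tbl = correlation_scatter(sig, ["s0", "s1"])
        assert tbl.loc["s0", "r_with_s0"] == pytest.approx(1.0)
        assert len(tbl) == 5
        assert len(correlation_scatter(sig, ["s0", "s1"], include_focal=False)) == 3
        dm = pearson_dissimilarities(sig)
        for sid in sig.index:
            assert tbl.loc[sid, "r_with_s0"] == pytest.approx(
                1 - dm["s0", sid], abs=1e-9
            )

    def test_correlation_scatter_missing_focal(self, rng):
        sig = _sig(rng.normal(size=(3, 256)))
        with pytest.raises(KeyError):
            correlation_scatter(sig, ["s0", "nope"])


class TestNmds:
    def test_equilateral_triangle_embeds_exactly(self):
        dm = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        res = nmds(dm, n_starts=3, seed=0)
        assert res.stress < 1e-6

    def test_planar_points_embed(self, rng):
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = nmds(DistanceMatrix(d, ids=[str(i) for i in range(6)]),
                   n_starts=5, seed=1)
        assert res.stress < 1e-4

    def test_deterministic_given_seed(self, rng):
        d = np.abs(rng.normal(size=(5, 5)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(5)])
        r1 = nmds(dm, n_starts=8, seed=4)
        r2 = nmds(dm, n_starts=8, seed=4)
        assert np.array_equal(
            r1.coordinates.to_numpy(), r2.coordinates.to_numpy()
        )
        assert r1.stress == r2.stress

    def test_more_starts_never_worse(self, rng):
        d = np.abs(rng.normal(size=(8, 8)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(8)])
        s_few = nmds(dm, n_starts=3, seed=9).stress
        s_many = nmds(dm, n_starts=20, seed=9).stress
        assert s_many <= s_few + 1e-12

    def test_coordinates_centered(self, rng):
        d = np.abs(rng.normal(size=(5, 5)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        res = nmds(DistanceMatrix(d, ids=list("abcde")), n_starts=2, seed=0)
        assert np.allclose(res.coordinates.to_numpy().mean(axis=0), 0, atol=1e-9)

    def test_stress_consistent_with_sklearn_smacof(self, rng):
        """Independent engine check: sklearn's non-metric SMACOF started from
        our best configuration finds no meaningfully better solution."""
        from sklearn.manifold import smacof

        d = np.abs(rng.normal(size=(7, 7)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(7)])
        mine = nmds(dm, n_starts=20, seed=3)
        _, sk_stress = smacof(
            d, metric=False, n_components=2,
            init=mine.coordinates.to_numpy(), n_init=1,
            max_iter=300, eps=1e-9, normalized_stress=True,
        )
        assert mine.stress <= sk_stress + 0.01

    def test_too_few_points_error(self):
        dm = DistanceMatrix(np.array([[0.0, 1], [1, 0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            nmds(dm, dims=2, n_starts=1, seed=0)


class TestAnosim:
    def _separated(self):
        d = np.full((6, 6), 5.0)
        within = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]
        for i, j in within:
            d[i, j] = d[j, i] = 1.0
        np.fill_diagonal(d, 0)
        ids = list("abcdef")
        groups = {"a": "g1", "b": "g1", "c": "g1", "d": "g2", "e": "g2", "f": "g2"}
        return DistanceMatrix(d, ids=ids), groups

    def test_perfect_separation_r_one(self):
        dm, groups = self._separated()
        res = anosim(dm, groups, n_permutations=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_equidistant_r_zero(self):
        d = np.ones((6, 6)) - np.eye(6)
        dm = DistanceMatrix(d, ids=list("abcdef"))
        groups = dict(zip("abcdef", ["g1"] * 3 + ["g2"] * 3))
        res = anosim(dm, groups, n_permutations=49, seed=0)
        assert res.R == pytest.approx(0.0)

    def test_montecarlo_matches_exhaustive(self, rng):
        d = np.abs(rng.normal(size=(6, 6))) + 0.1
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = list("abcdef")
        labels = ["g1"] * 3 + ["g2"] * 3
        r_exact, p_exact = exhaustive_anosim_p(d, labels)
        res = anosim(DistanceMatrix(d, ids=ids), dict(zip(ids, labels)),
                     n_permutations=999, seed=5)
        assert res.R == pytest.approx(r_exact)
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(res.p_value - p_exact) < 4 * se + 2 / 999

    def test_r_matches_skbio(self, rng):
        """Independent cross-check of the R statistic against scikit-bio."""
        from skbio.stats.distance import anosim as skbio_anosim

        d = np.abs(rng.normal(size=(8, 8))) + 0.1
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"s{i}" for i in range(8)]
        labels = ["g1"] * 4 + ["g2"] * 4
        dm = DistanceMatrix(d, ids=ids)
        mine = anosim(dm, dict(zip(ids, labels)), n_permutations=9, seed=0)
        ref = skbio_anosim(dm, grouping=labels, permutations=9)
        assert mine.R == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_invariant_to_monotone_transform(self, rng):
        d = np.abs(rng.normal(size=(8, 8))) + 0.1
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"s{i}" for i in range(8)]
        groups = dict(zip(ids, ["g1"] * 4 + ["g2"] * 4))
        r1 = anosim(DistanceMatrix(d, ids=ids), groups, 9, seed=0).R
        r2 = anosim(DistanceMatrix(d**2, ids=ids), groups, 9, seed=0).R
        r3 = anosim(DistanceMatrix(np.expm1(d), ids=ids), groups, 9, seed=0).R
        assert r1 == pytest.approx(r2) == pytest.approx(r3)

    def test_singleton_group_error(self):
        d = np.ones((3, 3)) - np.eye(3)
        dm = DistanceMatrix(d, ids=list("abc"))
        with pytest.raises(ValueError, match="fewer than 2"):
            anosim(dm, {"a": "g1", "b": "g1", "c": "g2"}, 9, seed=0)

    def test_p_value_never_zero(self):
        dm, groups = self._separated()
        res = anosim(dm, groups, n_permutations=999, seed=1)
        assert res.p_value >= 1 / 1000


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float), ids=list("abc")
        )
        clad = neighbor_joining(dm)
        lengths = clad.branch_lengths()
        assert lengths["a"] == pytest.approx(2.0)
        assert lengths["b"] == pytest.approx(3.0)
        assert lengths["c"] == pytest.approx(7.0)

    def test_additive_four_taxon_exact(self, rng):
        d, labels, internal, pendant = random_additive_tree(4, rng)
        clad = neighbor_joining(DistanceMatrix(d, ids=labels))
        got = clad.branch_lengths()
        assert set(clad.bipartitions()) == set(internal)
        for key, length in {**internal, **pendant}.items():
            assert got[key] == pytest.approx(length, abs=1e-9)

    def test_additive_recovery_many(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 9))
            d, labels, internal, _ = random_additive_tree(n, rng)
            clad = neighbor_joining(DistanceMatrix(d, ids=labels))
            assert set(clad.bipartitions()) == set(internal)

    def test_matches_skbio_on_additive_input(self, rng):
        from skbio.tree import nj as skbio_nj

        d, labels, internal, _ = random_additive_tree(6, rng)
        ref = skbio_nj(DistanceMatrix(d, ids=labels))
        ref_clad = Cladogram(ref)
        mine = neighbor_joining(DistanceMatrix(d, ids=labels))
        assert set(mine.bipartitions()) == set(ref_clad.bipartitions())

    def test_leaf_labels_preserved(self, rng):
        d = np.abs(rng.normal(size=(8, 8))) + 0.1
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"x{i}" for i in range(8)]
        clad = neighbor_joining(DistanceMatrix(d, ids=ids))
        assert clad.leaf_names == frozenset(ids)

    def test_too_few_taxa_error(self):
        dm = DistanceMatrix(np.array([[0.0, 1], [1, 0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_branch_lengths_nonnegative(self, rng):
        d = np.abs(rng.normal(size=(7, 7))) + 0.05
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        clad = neighbor_joining(DistanceMatrix(d, ids=[f"t{i}" for i in range(7)]))
        assert all(v >= 0 for v in clad.branch_lengths().values())


class TestConsensus:
    def test_identical_trees_full_support(self):
        t = _cladogram("((a:1,b:1):1,(c:1,d:1):1,e:1);")
        cons = majority_consensus([t, t, t])
        bips = cons.bipartitions()
        assert set(bips) == set(t.bipartitions())
        assert all(v == pytest.approx(100.0) for v in bips.values())

    def test_two_vs_one_conflict(self):
        t1 = _cladogram("((a,b),(c,d),e);")
        t2 = _cladogram("((a,c),(b,d),e);")
        cons = majority_consensus([t1, t1, t2])
        bips = cons.bipartitions()
        # splits are keyed by the side not containing the reference taxon 'a'
        assert frozenset({"c", "d", "e"}) in bips  # the {a,b} | {c,d,e} split
        assert frozenset({"c", "d"}) in bips
        assert frozenset({"b", "d"}) not in bips  # t2's conflicting split
        assert bips[frozenset({"c", "d", "e"})] == pytest.approx(200 / 3)

    def test_no_majority_gives_star(self):
        t1 = _cladogram("((a,b),(c,d),e);")
        t2 = _cladogram("((a,c),(b,d),e);")
        t3 = _cladogram("((a,d),(b,c),e);")
        cons = majority_consensus([t1, t2, t3])
        assert cons.bipartitions() == {}
        assert cons.leaf_names == frozenset("abcde")

    def test_idempotent_on_binary_tree(self, rng):
        d, labels, internal, pendant = random_additive_tree(6, rng)
        t = neighbor_joining(DistanceMatrix(d, ids=labels))
        cons = majority_consensus([t])
        assert set(cons.bipartitions()) == set(t.bipartitions())
        got, want = cons.branch_lengths(), t.branch_lengths()
        for key in want:
            assert got[key] == pytest.approx(want[key])

    def test_mismatched_leaf_sets_error(self):
        t1 = _cladogram("((a,b),(c,d),e);")
        t2 = _cladogram("((a,b),(c,f),e);")
        with pytest.raises(ValueError, match="leaf sets"):
            majority_consensus([t1, t2])


class TestBootstrapConsensus:
    def test_separating_bipartition_full_support(self, small_signatures, small_panel):
        truth = small_panel.truth
        sig = small_signatures
        clad = bootstrap_consensus(sig, n_boot=100, seed=3)
        bips = clad.bipartitions()
        host0_side = frozenset(
            sid for sid in sig.index
            if truth[sid] == "host0" and sid != small_panel.migrant_id
        ) | {small_panel.migrant_id}
        taxa = frozenset(sig.index)
        ref = min(taxa)
        key = host0_side if ref not in host0_side else taxa - host0_side
        assert key in bips
        assert bips[key] >= 95.0

    def test_single_replicate_equals_its_tree(self, small_signatures):
        sig = small_signatures
        clad = bootstrap_consensus(sig, n_boot=1, seed=7)
        rng = np.random.default_rng(7)
        cols = rng.integers(0, sig.shape[1], size=sig.shape[1])
        single = neighbor_joining(pearson_dissimilarities(sig.iloc[:, cols]))
        assert set(clad.bipartitions()) == set(single.bipartitions())

    def test_deterministic_given_seed(self, small_signatures):
        c1 = bootstrap_consensus(small_signatures, n_boot=25, seed=5)
        c2 = bootstrap_consensus(small_signatures, n_boot=25, seed=5)
        assert c1.bipartitions() == c2.bipartitions()
        assert c1.to_newick() == c2.to_newick()


class TestNewick:
    def test_roundtrip_preserves_topology_and_support(self, small_signatures):
        clad = bootstrap_consensus(small_signatures, n_boot=20, seed=1)
        newick = clad.to_newick()
        back = Cladogram(TreeNode.read(io.StringIO(newick)))
        assert back.leaf_names == clad.leaf_names
        assert set(back.bipartitions()) == set(clad.bipartitions())
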