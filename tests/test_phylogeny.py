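"""Spacer alignment, neighbor joining, Robinson-Foulds, clock calibration."""

import dendropy
import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from stcap.phylogeny import (
    CalibratedTree,
    NJResult,
    SpacerAlignment,
    align_spacers,
    calibrate,
    jc69_matrix,
    length_filter,
    neighbor_joining,
    nj_tree,
    p_distance_matrix,
    robinson_foulds,
    tree_splits,
)
from stcap.simulate import evolve_on_tree, random_clock_tree, random_dna

from _oracles import optimal_three_way_sp_cost, rf_by_enumeration, sp_cost


class TestAlignSpacers:
    def test_identical_sequences_no_gaps(self):
        seqs = {f"s{i}": "ACGTACGTAA" * 10 for i in range(4)}
        aln = align_spacers(seqs)
        assert aln.n_columns == 100
        assert all("-" not in s for s in aln.seqs)

    def test_substitution_only_input_stays_gapless(self, rng):
        tree = random_clock_tree(6, rng, depth=0.08)
        seqs = evolve_on_tree(tree, random_dna(800, rng), rng)
        aln = align_spacers(seqs)
        assert aln.n_columns == 800
        assert all("-" not in s for s in aln.seqs)

    def test_rows_roundtrip_with_indel(self, rng):
        tree = random_clock_tree(4, rng, depth=0.05)
        seqs = evolve_on_tree(tree, random_dna(300, rng), rng)
        name = sorted(seqs)[1]
        seqs[name] = seqs[name][:100] + seqs[name][108:]
        aln = align_spacers(seqs, min_fraction=0.5)
        for n, row in zip(aln.names, aln.seqs):
            assert row.replace("-", "") == seqs[n]

    def test_center_star_within_factor_two_of_optimal(self):
        a, b, c = "ACGTACGTACGT", "ACGTACCGTACGT", "ACCTACGTACG"
        aln = align_spacers({"a": a, "b": b, "c": c}, min_fraction=0.5)
        ours = sp_cost(aln.seqs)
        best = optimal_three_way_sp_cost(a, b, c)
        assert ours <= 2 * best

    def test_length_filter_uses_modal_length(self):
        seqs = {"a": "A" * 100, "b": "C" * 100, "c": "G" * 100, "d": "T" * 89}
        kept = length_filter(seqs, 0.90)
        assert set(kept) == {"a", "b", "c"}

    def test_too_few_after_filter(self):
        with pytest.raises(ValueError):
            align_spacers({"a": "A" * 100, "b": "A" * 10})


class TestDistances:
    def test_jc_self_zero_and_symmetric(self, rng):
        tree = random_clock_tree(5, rng, depth=0.04)
        seqs = evolve_on_tree(tree, random_dna(500, rng), rng)
        aln = SpacerAlignment(sorted(seqs), [seqs[k] for k in sorted(seqs)])
        d = jc69_matrix(aln)
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)
        assert (d >= 0).all()

    def test_saturation_raises_naming_pair(self):
        aln = SpacerAlignment(["x", "y"], ["A" * 100, "C" * 100])
        with pytest.raises(ValueError, match="x.*y"):
            jc69_matrix(aln)


def _additive_matrix():
    # tree ((a:2,b:3):1,(c:4,d:5):1) -> additive pairwise distances
    names = ["a", "b", "c", "d"]
    d = np.array([
        [0, 5, 7, 8],
        [5, 0, 8, 9],
        [7, 8, 0, 9],
        [8, 9, 9, 0],
    ], dtype=float)
    return d, names


class TestNeighborJoining:
    def test_four_point_condition_holds(self):
        d, _ = _additive_matrix()
        s1 = d[0, 1] + d[2, 3]
        s2 = d[0, 2] + d[1, 3]
        s3 = d[0, 3] + d[1, 2]
        assert s1 < s2 == s3  # ab|cd is the generating topology

    def test_additive_matrix_recovers_topology_and_lengths(self):
        d, names = _additive_matrix()
        tree = neighbor_joining(d, names)
        assert tree_splits(tree) == {frozenset({"c", "d"})} \
            or tree_splits(tree) == {frozenset({"a", "b"})}
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, x in enumerate(names):
            for j, y in enumerate(names):
                if i < j:
                    assert pdm.distance(taxa[x], taxa[y]) == pytest.approx(d[i, j])

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = neighbor_joining(d, ["a", "b", "c"])
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2
        leaf_a = next(l for l in tree.leaf_node_iter() if l.taxon.label == "a")
        assert leaf_a.edge.length == pytest.approx(la)
        assert pdm.distance(taxa["a"], taxa["b"]) == pytest.approx(4)

    def test_ultrametric_matches_upgma_topology(self, rng):
        for _ in range(10):
            tree = random_clock_tree(6, rng, depth=1.0)
            pdm = tree.phylogenetic_distance_matrix()
            taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
            names = [t.label for t in taxa]
            d = np.array([[pdm.distance(x, y) for y in taxa] for x in taxa])
            nj = neighbor_joining(d, names)
            link = hierarchy.average(squareform(d, checks=False))
            # UPGMA on an ultrametric matrix recovers the true tree
            upgma_splits = set()
            clusters = {i: frozenset([names[i]]) for i in range(6)}
            ref = sorted(names)[0]
            full = frozenset(names)
            for k, (x, y, _h, _c) in enumerate(link):
                merged = clusters[int(x)] | clusters[int(y)]
                clusters[6 + k] = merged
                canon = full - merged if ref in merged else merged
                if 1 < len(canon) < 5:
                    upgma_splits.add(canon)
            assert tree_splits(nj) == upgma_splits

    def test_negative_lengths_clamped(self):
        d = np.array([
            [0.0, 0.1, 0.4, 0.4],
            [0.1, 0.0, 0.4, 0.4],
            [0.4, 0.4, 0.0, 0.01],
            [0.4, 0.4, 0.01, 0.0],
        ])
        tree = neighbor_joining(d, list("abcd"))
        assert all((e.length or 0) >= 0 for e in tree.edges())


class TestRobinsonFoulds:
    def _tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_self_distance_zero(self):
        t = self._tree("((a,b),(c,d));")
        assert robinson_foulds(t, t) == 0

    def test_distinct_quartets_distance_two(self):
        t1 = self._tree("((a,b),(c,d));")
        t2 = self._tree("((a,c),(b,d));")
        assert robinson_foulds(t1, t2) == 2
        leaves = list("abcd")
        assert rf_by_enumeration(tree_splits(t1), tree_splits(t2), leaves) == 2

    def test_matches_enumeration_and_dendropy(self, rng):
        tns = dendropy.TaxonNamespace([f"t{i}" for i in range(7)])
        for seed in range(5):
            t1 = random_clock_tree(7, np.random.default_rng(seed), depth=1.0)
            t2 = random_clock_tree(7, np.random.default_rng(seed + 50), depth=1.0)
            ours = robinson_foulds(t1, t2)
            brute = rf_by_enumeration(tree_splits(t1), tree_splits(t2),
                                      sorted(l.taxon.label
                                             for l in t1.leaf_node_iter()))
            assert ours == brute
            # independent cross-check via dendropy's bipartition machinery
            s1 = t1.as_string(schema="newick")
            s2 = t2.as_string(schema="newick")
            d1 = dendropy.Tree.get(data=s1, schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=s2, schema="newick",
                                   taxon_namespace=tns)
            d1.is_rooted = False
            d2.is_rooted = False
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            from dendropy.calculate import treecompare
            assert ours == treecompare.symmetric_difference(d1, d2)

    def test_triangle_inequality_on_samples(self):
        trees = [random_clock_tree(6, np.random.default_rng(s), depth=1.0)
                 for s in range(3)]
        a, b, c = (robinson_foulds(trees[0], trees[1]),
                   robinson_foulds(trees[1], trees[2]),
                   robinson_foulds(trees[0], trees[2]))
        assert c <= a + b


def balanced_clock_tree() -> dendropy.Tree:
    """Fixed 8-leaf balanced ultrametric tree (depth 0.05) plus outgroup."""
    newick = ("((((t0:0.0125,t1:0.0125):0.0125,(t2:0.0125,t3:0.0125):0.0125)"
              ":0.025,((t4:0.0125,t5:0.0125):0.0125,"
              "(t6:0.0125,t7:0.0125):0.0125):0.025):0.05,out:0.1);")
    return dendropy.Tree.get(data=newick, schema="newick")


class TestNjTreeAndCalibration:
    def test_simulation_recovery_with_bootstrap(self):
        tree = balanced_clock_tree()
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            seqs = evolve_on_tree(tree, random_dna(2000, rng), rng)
            aln = SpacerAlignment(sorted(seqs), [seqs[k] for k in sorted(seqs)])
            res = nj_tree(aln, n_boot=50, seed=seed)
            hits += robinson_foulds(res.tree, tree) == 0
            assert all(0 <= s <= 100 for s in res.support.values())
        assert hits >= 4

    def test_single_point_calibration_closed_form(self):
        newick = "(((a:0.05,b:0.05):0.036,c:0.086):0.014,out:0.1);"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        res = NJResult(tree=tree, names=["a", "b", "c", "out"], support={},
                       bootstrap_trees=[], distances=np.zeros((4, 4)))
        cal = calibrate(res, [({"a", "b", "c"}, 8.6)], outgroup="out")
        assert cal.rate == pytest.approx(0.01)
        assert cal.ages[frozenset({"a", "b"})] == pytest.approx(5.0)

    def test_default_calibration_table_values(self):
        from stcap.phylogeny import APE_CALIBRATION_AGES
        assert sorted(APE_CALIBRATION_AGES.values()) == [6.4, 8.6, 15.2, 19.5]

    def test_simulated_clock_tree_ages_within_ten_percent(self):
        tree = balanced_clock_tree()
        rng = np.random.default_rng(4)
        seqs = evolve_on_tree(tree, random_dna(20_000, rng), rng)
        aln = SpacerAlignment(sorted(seqs), [seqs[k] for k in sorted(seqs)])
        res = nj_tree(aln, n_boot=100, seed=0)
        rate = 0.01  # subs/site/MY used to express true node ages
        cals = [({"t0", "t1", "t2", "t3"}, 0.025 / rate),
                ({"t4", "t5", "t6", "t7"}, 0.025 / rate)]
        cal = calibrate(res, cals, outgroup="out", n_boot_ci=50)
        true_ages = {
            frozenset({"t0", "t1"}): 1.25,
            frozenset({"t2", "t3"}): 1.25,
            frozenset({"t4", "t5"}): 1.25,
            frozenset({"t6", "t7"}): 1.25,
            frozenset({"t0", "t1", "t2", "t3"}): 2.5,
            frozenset({"t4", "t5", "t6", "t7"}): 2.5,
            frozenset({f"t{i}" for i in range(8)}): 5.0,
        }
        ok = sum(abs(cal.ages[c] - a) / a <= 0.10
                 for c, a in true_ages.items() if c in cal.ages)
        assert ok >= 0.9 * len(true_ages)

    def test_ages_monotone_root_to_tip(self):
        tree = balanced_clock_tree()
        rng = np.random.default_rng(9)
        seqs = evolve_on_tree(tree, random_dna(3000, rng), rng)
        aln = SpacerAlignment(sorted(seqs), [seqs[k] for k in sorted(seqs)])
        res = nj_tree(aln, n_boot=0, seed=0)
        cal = calibrate(res, [({"t0", "t1", "t2", "t3"}, 2.5)], outgroup="out")
        for node in cal.tree.preorder_internal_node_iter():
            clade = frozenset(l.taxon.label for l in node.leaf_iter())
            for ch in node.child_nodes():
                if ch.is_leaf():
                    continue
                child_clade = frozenset(l.taxon.label for l in ch.leaf_iter())
                if clade in cal.ages and child_clade in cal.ages:
                    assert cal.ages[clade] >= cal.ages[child_clade] - 1e-9

    def test_missing_calibration_taxa_raises(self):
        tree = balanced_clock_tree()
        res = NJResult(tree=tree, names=[f"t{i}" for i in range(8)] + ["out"],
                       support={}, bootstrap_trees=[],
                       distances=np.zeros((9, 9)))
        with pytest.raises(ValueError, match="absent"):
            calibrate(res, [({"nope"}, 5.0)], outgroup="out")
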