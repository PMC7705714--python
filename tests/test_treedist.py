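"""Tree-distance tests, anchored to a brute-force bipartition oracle that
enumerates splits as explicit leaf-set pairs."""

import itertools

import numpy as np
import pytest

from phyloaudit.distance import collapse_low_support, compare_trees, prune_to_shared_leaves
from phyloaudit.species import all_unrooted_topologies
from phyloaudit.tree import bipartition_table, parse_newick, write_newick

from conftest import random_binary_tree


# -- independent oracle ------------------------------------------------------


def _oracle_splits(tree):
    """All (leafset-below, length) edges by direct traversal; root-degree-2
    pair merged by summing lengths of equal splits."""
    all_leaves = frozenset(tree.leaf_names())

    def below(node):
        if node.is_leaf:
            return frozenset([node.label])
        return frozenset().union(*(below(c) for c in node.children))

    splits = {}
    for node in tree.postorder():
        if node is tree.root:
            continue
        side = below(node)
        canon = side if min(all_leaves) not in side else all_leaves - side
        splits[canon] = splits.get(canon, 0.0) + (node.length or 0.0)
    return splits, all_leaves


def oracle_compare(a, b):
    sa, leaves = _oracle_splits(a)
    sb, _ = _oracle_splits(b)
    n = len(leaves)
    nontrivial_a = {s for s in sa if 1 < len(s) < n - 1}
    nontrivial_b = {s for s in sb if 1 < len(s) < n - 1}
    rf = len(nontrivial_a ^ nontrivial_b)
    kf = sum(
        (sa.get(s, 0.0) - sb.get(s, 0.0)) ** 2 for s in set(sa) | set(sb)
    )
    return rf, rf / (2 * (n - 3)), kf


# -- example values ----------------------------------------------------------


class TestExamples:
    def test_identical_trees(self):
        s = "((A:1,B:1)90:0.5,C:1,(D:1,E:1)80:0.4);"
        r = compare_trees(parse_newick(s), parse_newick(s))
        assert (r.rf, r.nrfd, r.kf) == (0, 0.0, 0.0)
        assert r.support_diff_pct == 0.0
        assert not r.conflicting_bipartitions

    def test_five_leaf_one_nni_apart(self):
        a = parse_newick("((A:1,B:1):1,C:1,(D:1,E:1):1);")
        b = parse_newick("((A:1,C:1):1,B:1,(D:1,E:1):1);")
        r = compare_trees(a, b)
        assert r.rf == 2
        assert r.nrfd == pytest.approx(0.5)

    def test_kf_single_length_difference(self):
        a = parse_newick("((A:1,B:1):0.3,C:1,(D:1,E:1):1);")
        b = parse_newick("((A:1,B:1):0.1,C:1,(D:1,E:1):1);")
        r = compare_trees(a, b)
        assert r.nrfd == 0
        assert r.kf == pytest.approx(0.04)
        assert r.kf_root == pytest.approx(0.2)

    def test_leaf_set_mismatch_directs_to_pruning(self):
        a = parse_newick("((A:1,B:1):1,C:1,D:1);")
        b = parse_newick("((A:1,B:1):1,C:1,E:1);")
        with pytest.raises(ValueError, match="prune_to_shared_leaves"):
            compare_trees(a, b)

    def test_too_few_leaves(self):
        a = parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="4"):
            compare_trees(a, a)


# -- oracle equivalence ------------------------------------------------------


class TestOracleEquivalence:
    def test_all_five_taxon_pairs(self):
        rng = np.random.default_rng(11)
        topologies = all_unrooted_topologies(["A", "B", "C", "D", "E"])
        for t in topologies:
            for node in t.postorder():
                if node.parent is not None:
                    node.length = float(rng.uniform(0.05, 1.0))
        for a, b in itertools.product(topologies, repeat=2):
            r = compare_trees(a, b)
            rf, nrfd, kf = oracle_compare(a, b)
            assert r.rf == rf
            assert r.nrfd == pytest.approx(nrfd)
            assert r.kf == pytest.approx(kf)

    def test_random_six_taxon_pairs(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            a = random_binary_tree(rng, 6)
            b = random_binary_tree(rng, 6)
            r = compare_trees(a, b)
            rf, nrfd, kf = oracle_compare(a, b)
            assert (r.rf, r.nrfd) == (rf, pytest.approx(nrfd))
            assert r.kf == pytest.approx(kf)

    def test_rf_matches_dendropy(self):
        import dendropy
        from dendropy.calculate import treecompare

        rng = np.random.default_rng(13)
        ns = dendropy.TaxonNamespace()
        for _ in range(30):
            a = random_binary_tree(rng, 10)
            b = random_binary_tree(rng, 10)
            da = dendropy.Tree.get(data=write_newick(a), schema="newick", taxon_namespace=ns)
            db = dendropy.Tree.get(data=write_newick(b), schema="newick", taxon_namespace=ns)
            assert compare_trees(a, b).rf == treecompare.symmetric_difference(da, db)


class TestMetricProperties:
    def test_symmetry(self):
        rng = np.random.default_rng(14)
        for _ in range(30):
            a, b = random_binary_tree(rng, 8), random_binary_tree(rng, 8)
            r1, r2 = compare_trees(a, b), compare_trees(b, a)
            assert (r1.rf, r1.nrfd) == (r2.rf, r2.nrfd)
            assert r1.kf == pytest.approx(r2.kf)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(15)
        for _ in range(50):
            a, b, c = (random_binary_tree(rng, 7) for _ in range(3))
            assert compare_trees(a, c).rf <= compare_trees(a, b).rf + compare_trees(b, c).rf


# -- pruning -----------------------------------------------------------------


class TestPruning:
    def test_identical_leaf_sets_returned_unchanged(self):
        a = parse_newick("((A:1,B:1):1,C:1,D:1);")
        b = parse_newick("((A:1,C:1):1,B:1,D:1);")
        pa, pb = prune_to_shared_leaves(a, b)
        assert pa is a and pb is b

    def test_graft_then_prune_is_identity(self):
        a = parse_newick("((A:1,B:1):0.5,C:1,(D:1,E:1):0.5);")
        b = parse_newick("((A:1,(B:0.4,X:0.4):0.6):0.5,C:1,(D:1,E:1):0.5);")
        pa, pb = prune_to_shared_leaves(a, b)
        assert compare_trees(pa, pb).nrfd == 0

    def test_cherry_partner_lengths_summed(self):
        # removing B merges its cherry: path length A..C must be conserved
        b = parse_newick("(((A:0.2,B:0.3):0.4,C:0.5):0.1,(D:1,E:1):0.2,F:1);")
        a = parse_newick("((A:0.7,C:0.5):0.1,(D:1,E:1):0.2,F:1);")  # A edge 0.2+0.4=0.6? see below
        pa, pb = prune_to_shared_leaves(a, b)
        # path A-C in pruned b: 0.2 + 0.4 + 0.5 = 1.1 must equal original
        def path_len(tree, x, y):
            nodes = {n.label: n for n in tree.leaves()}
            def ancestors(n):
                out = []
                while n is not None:
                    out.append(n)
                    n = n.parent
                return out
            ax, ay = ancestors(nodes[x]), ancestors(nodes[y])
            common = next(n for n in ax if n in ay)
            total = 0.0
            for n in ax:
                if n is common:
                    break
                total += n.length or 0.0
            for n in ay:
                if n is common:
                    break
                total += n.length or 0.0
            return total

        assert path_len(pb, "A", "C") == pytest.approx(path_len(b, "A", "C"))

    def test_too_small_intersection(self):
        a = parse_newick("((A:1,B:1):1,C:1,D:1);")
        b = parse_newick("((A:1,B:1):1,C:1,E:1);")
        with pytest.raises(ValueError):
            prune_to_shared_leaves(a, b)


# -- support-threshold collapsing -------------------------------------------


class TestCollapse:
    def test_threshold_is_inclusive(self):
        t = parse_newick("((A:1,B:1)50:0.5,C:1,(D:1,E:1)51:0.5);")
        collapsed = collapse_low_support(t, 50)
        assert bipartition_table(collapsed).n_nontrivial == 1

    def test_all_above_threshold_unchanged(self):
        t = parse_newick("((A:1,B:1)80:0.5,C:1,(D:1,E:1)90:0.5);")
        assert compare_trees(collapse_low_support(t, 50), t).nrfd == 0

    def test_all_below_gives_star(self):
        t = parse_newick("((A:1,B:1)10:0.5,C:1,(D:1,E:1)30:0.5);")
        assert bipartition_table(collapse_low_support(t, 50)).n_nontrivial == 0

    def test_unsupported_edges_never_collapsed(self):
        t = parse_newick("((A:1,B:1):0.5,C:1,(D:1,E:1)10:0.5);")
        assert bipartition_table(collapse_low_support(t, 50)).n_nontrivial == 1

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(16)
        for _ in range(20):
            t = random_binary_tree(rng, 10, with_supports=True)
            once = collapse_low_support(t, 50)
            twice = collapse_low_support(once, 50)
            assert compare_trees(once, twice).nrfd == 0
            counts = [
                bipartition_table(collapse_low_support(t, thr)).n_nontrivial
                for thr in (0, 25, 50, 75, 100)
            ]
            assert counts == sorted(counts, reverse=True)

    def test_threshold_scale_checked(self):
        t = parse_newick("((A:1,B:1)0.9:0.5,C:1,(D:1,E:1)0.3:0.5);")
        with pytest.raises(ValueError, match="scale"):
            collapse_low_support(t, 50)

    def test_collapsed_vs_binary_keeps_denominator(self):
        t = parse_newick("((A:1,B:1)10:0.5,C:1,((D:1,E:1)90:0.3,F:1)90:0.4);")
        collapsed = collapse_low_support(t, 50)
        r = compare_trees(collapsed, t)
        assert r.rf == 1
        assert r.nrfd == pytest.approx(1 / 6)
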