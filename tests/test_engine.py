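"""Likelihood-engine tests: brute-force oracles for the likelihood, closed
forms for the two-taxon case, summation-mode behavior, and search contracts."""

from itertools import product

import numpy as np
import pytest

from phyloaudit.alignment import Alignment
from phyloaudit.engine import (
    SearchConfig,
    _climb,
    _fitch_score,
    _nni_moves,
    _apply_nni,
    au_test,
    bootstrap_support,
    combine_site_logls,
    generate_starting_tree,
    heuristic_search,
    log_likelihood,
    optimize_branch_lengths,
    per_site_log_likelihoods,
    site_patterns,
)
from phyloaudit.model import GTRModel
from phyloaudit.simulate import make_balanced_tree, make_star_tree, simulate_alignment
from phyloaudit.species import all_unrooted_topologies
from phyloaudit.tree import parse_newick, topology_key, write_newick


# -- brute-force likelihood oracle ------------------------------------------


def brute_force_logl(tree, aln, model):
    """Sum over every assignment of states to internal nodes, per site and
    rate category — the O(4^internals) definition of the likelihood."""
    rates, weights = model.category_rates()
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    mat = aln.matrix()
    row = {t: i for i, t in enumerate(aln.taxa)}
    code = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
    total = 0.0
    for site in range(aln.length):
        site_l = 0.0
        for r, w in zip(rates, weights):
            P = {
                id(n): model.transition_matrix(r * n.length)
                for n in nodes
                if n.parent is not None
            }
            acc = 0.0
            for assign in product(range(4), repeat=len(internals)):
                state = {id(n): a for n, a in zip(internals, assign)}
                for n in nodes:
                    if n.is_leaf:
                        state[id(n)] = code[mat[row[n.label], site].tobytes()]
                p = model.pi[state[id(tree.root)]]
                for n in nodes:
                    if n.parent is not None:
                        p *= P[id(n)][state[id(n.parent)], state[id(n)]]
                acc += p
            site_l += w * acc
        total += np.log(site_l)
    return total


class TestSitePatterns:
    def test_identical_columns_compress_to_one(self):
        aln = Alignment(taxa=["a", "b", "c"], seqs=["AAAA", "CCCC", "GGGG"])
        p = site_patterns(aln)
        assert p.n_patterns == 1 and p.weights[0] == 4

    def test_distinct_columns_kept(self):
        aln = Alignment(taxa=["a", "b"], seqs=["ACGT", "CAGT"])
        p = site_patterns(aln)
        assert p.n_patterns == 4

    def test_weights_conserve_length(self, gtr_gamma):
        tree = make_balanced_tree(8, 0.05)
        aln = simulate_alignment(tree, gtr_gamma, 333, seed=1)
        assert site_patterns(aln).weights.sum() == 333

    def test_non_nucleotide_rejected(self):
        aln = Alignment(taxa=["a", "b"], seqs=["ACGJ", "ACGT"])
        with pytest.raises(ValueError, match="non-nucleotide"):
            site_patterns(aln)


class TestLikelihoodOracles:
    def test_all_five_taxon_topologies_match_brute_force(self, gtr_uneven):
        rng = np.random.default_rng(31)
        truth = parse_newick("((A:0.2,B:0.15):0.1,(C:0.1,D:0.2):0.1,E:0.3);")
        aln = simulate_alignment(truth, gtr_uneven, 25, seed=32)
        for topo in all_unrooted_topologies(["A", "B", "C", "D", "E"]):
            for node in topo.postorder():
                if node.parent is not None:
                    node.length = float(rng.uniform(0.02, 0.6))
            bf = brute_force_logl(topo, aln, gtr_uneven)
            fast = log_likelihood(topo, aln, gtr_uneven)
            assert fast == pytest.approx(bf, abs=1e-8)

    def test_two_taxon_jc_closed_form(self, jc1):
        tree = parse_newick("(A:0.06,B:0.07);")
        aln = simulate_alignment(tree, jc1, 500, seed=33)
        mat = aln.matrix()
        n_diff = int((mat[0] != mat[1]).sum())
        t = 0.13
        p_same = 0.25 + 0.75 * np.exp(-4 * t / 3)
        p_diff = 0.25 - 0.25 * np.exp(-4 * t / 3)
        closed = (aln.length - n_diff) * np.log(0.25 * p_same) + n_diff * np.log(
            0.25 * p_diff
        )
        assert log_likelihood(tree, aln, jc1) == pytest.approx(closed, abs=1e-8)

    def test_gamma_mixture_matches_brute_force_two_taxa(self, gtr_gamma):
        tree = parse_newick("(A:0.1,B:0.2);")
        aln = simulate_alignment(tree, gtr_gamma, 40, seed=34)
        assert log_likelihood(tree, aln, gtr_gamma) == pytest.approx(
            brute_force_logl(tree, aln, gtr_gamma), abs=1e-8
        )

    def test_ambiguity_and_gaps_handled(self, gtr_gamma):
        tree = parse_newick("((A:0.1,B:0.1):0.05,C:0.1,D:0.1);")
        aln = Alignment(
            taxa=list("ABCD"), seqs=["ACGT-N", "ACRTTN", "AC-TTA", "ACGTTA"]
        )
        val = log_likelihood(tree, aln, gtr_gamma)
        assert np.isfinite(val) and val < 0


@pytest.fixture(scope="module")
def setup(gtr_gamma):
    tree = make_balanced_tree(8, 0.05)
    aln = simulate_alignment(tree, gtr_gamma, 800, seed=40)
    return tree, aln, gtr_gamma


class TestSummationModes:

    def test_exact_invariant_to_column_order(self, setup):
        tree, aln, model = setup
        rng = np.random.default_rng(41)
        perm = rng.permutation(aln.length)
        shuffled = Alignment(
            taxa=list(aln.taxa),
            seqs=["".join(s[i] for i in perm) for s in aln.seqs],
        )
        assert log_likelihood(tree, aln, model, "exact") == log_likelihood(
            tree, shuffled, model, "exact"
        )

    def test_duplicated_alignment_doubles_exactly(self, setup):
        tree, aln, model = setup
        doubled = Alignment(taxa=list(aln.taxa), seqs=[s + s for s in aln.seqs])
        assert log_likelihood(tree, doubled, model, "exact") == 2 * log_likelihood(
            tree, aln, model, "exact"
        )

    def test_modes_agree_to_rounding_but_not_bitwise(self, setup):
        tree, aln, model = setup
        exact = log_likelihood(tree, aln, model, "exact")
        others = [
            log_likelihood(tree, aln, model, m)
            for m in ("sequential", "reversed", "blocked:4", "shuffled:3")
        ]
        for v in others:
            assert abs(v - exact) < 1e-6 * aln.length
        assert len({exact, *others}) > 1  # the orders genuinely differ

    def test_modes_consistent_with_per_site_vector(self, setup):
        tree, aln, model = setup
        vec = per_site_log_likelihoods(tree, aln, model)
        assert vec.shape == (aln.length,)
        assert float(vec.sum()) == pytest.approx(
            log_likelihood(tree, aln, model, "sequential"), abs=1e-9
        )

    def test_unknown_mode_rejected(self, setup):
        tree, aln, model = setup
        with pytest.raises(ValueError):
            log_likelihood(tree, aln, model, "parallel")


class TestBranchLengthOptimization:
    def test_two_taxon_jc_distance_closed_form(self, jc1):
        tree = parse_newick("(A:0.05,B:0.05);")
        aln = simulate_alignment(tree, jc1, 4000, seed=50)
        mat = aln.matrix()
        p_hat = (mat[0] != mat[1]).mean()
        expected = -0.75 * np.log(1 - 4 * p_hat / 3)
        opt = optimize_branch_lengths(tree, aln, jc1, epsilon=1e-9)
        total = sum(n.length for n in opt.postorder() if n.parent is not None)
        assert total == pytest.approx(expected, abs=1e-4)

    def test_identical_sequences_drive_lengths_to_minimum(self, gtr_gamma):
        aln = Alignment(taxa=list("ABCD"), seqs=["ACGTACGTACGT"] * 4)
        tree = parse_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);")
        opt = optimize_branch_lengths(tree, aln, gtr_gamma)
        for node in opt.postorder():
            if node.parent is not None:
                assert node.length < 1e-5

    def test_reoptimization_is_a_fixed_point(self, gtr_gamma):
        truth = make_balanced_tree(8, 0.05)
        aln = simulate_alignment(truth, gtr_gamma, 500, seed=51)
        eps = 1e-4
        once = optimize_branch_lengths(truth, aln, gtr_gamma, epsilon=eps)
        twice = optimize_branch_lengths(once, aln, gtr_gamma, epsilon=eps)
        l1 = log_likelihood(once, aln, gtr_gamma)
        l2 = log_likelihood(twice, aln, gtr_gamma)
        assert abs(l2 - l1) < eps

    def test_consistency_as_length_grows(self, jc1):
        true_t = 0.15
        tree = parse_newick(f"(A:{true_t/2},B:{true_t/2});")
        errors = []
        for L in (1000, 10000, 100000):
            aln = simulate_alignment(tree, jc1, L, seed=[52, L])
            opt = optimize_branch_lengths(tree, aln, jc1, epsilon=1e-9)
            total = sum(n.length for n in opt.postorder() if n.parent is not None)
            errors.append(abs(total - true_t))
        assert errors[2] < errors[0]
        assert errors[2] < 0.01


class TestStartingTrees:
    def test_deterministic_given_seed(self, gtr_gamma):
        aln = simulate_alignment(make_balanced_tree(8, 0.05), gtr_gamma, 200, seed=60)
        for kind in ("random", "parsimony"):
            t1 = generate_starting_tree(aln, kind, 7)
            t2 = generate_starting_tree(aln, kind, 7)
            assert write_newick(t1) == write_newick(t2)

    def test_random_uniform_over_quartet_topologies(self):
        aln = Alignment(taxa=list("ABCD"), seqs=["ACGT"] * 4)
        counts = {}
        n = 3000
        for s in range(n):
            key = topology_key(generate_starting_tree(aln, "random", s))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 3
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        for c in counts.values():
            assert abs(c / n - 1 / 3) < 3 * se

    def test_parsimony_start_optimal_on_clean_data(self):
        # zero-homoplasy six-taxon data: one clean synapomorphy per internal edge
        taxa = list("ABCDEF")
        cols = [
            "CCAAAA",  # AB | rest
            "AACCAA",  # CD | rest
            "AAAACC",  # EF | rest
            "CCCCAA",  # ABCD | EF
            "ACGTCG",  # noise (all singletons, parsimony-neutral)
        ]
        aln = Alignment(taxa=taxa, seqs=["".join(c[i] for c in cols) for i in range(6)])
        patterns = site_patterns(aln)
        start = generate_starting_tree(aln, "parsimony", 0)
        best = min(
            _fitch_score(t, patterns) for t in all_unrooted_topologies(taxa)
        )
        assert _fitch_score(start, patterns) == best

    def test_too_few_taxa(self):
        aln = Alignment(taxa=list("ABC"), seqs=["ACGT"] * 3)
        with pytest.raises(ValueError):
            generate_starting_tree(aln, "random", 0)


class TestHeuristicSearch:
    def test_identical_config_identical_result(self, gtr_gamma):
        truth = make_balanced_tree(8, 0.1)
        aln = simulate_alignment(truth, gtr_gamma, 600, seed=70)
        cfg = SearchConfig(n_searches=2, seed=3, max_rounds=10)
        r1 = heuristic_search(aln, gtr_gamma, cfg)
        r2 = heuristic_search(aln, gtr_gamma, cfg)
        assert write_newick(r1.best_tree) == write_newick(r2.best_tree)
        assert r1.best_logl == r2.best_logl
        assert r1.log["seed"] == 3 and r1.log["summation_mode"] == "exact"

    def test_recovers_truth_on_informative_data(self, gtr_gamma):
        truth = make_balanced_tree(8, 0.1)
        cfg = SearchConfig(n_searches=2, seed=1, max_rounds=10)
        hits = 0
        for g in range(8):
            aln = simulate_alignment(truth, gtr_gamma, 1000, seed=[71, g])
            res = heuristic_search(aln, gtr_gamma, cfg)
            hits += topology_key(res.best_tree) == topology_key(truth)
        assert hits >= 6  # large majority

    def test_star_data_recovers_reference_less_often(self, gtr_gamma):
        cfg = SearchConfig(n_searches=2, seed=1, max_rounds=10)
        star_ref = make_star_tree(16, 0.1)
        balanced_ref = make_balanced_tree(16, 0.1)
        star_hits = balanced_hits = 0
        for g in range(3):
            a_star = simulate_alignment(star_ref, gtr_gamma, 800, seed=[72, g])
            a_bal = simulate_alignment(balanced_ref, gtr_gamma, 800, seed=[73, g])
            star_hits += topology_key(
                heuristic_search(a_star, gtr_gamma, cfg).best_tree
            ) == topology_key(star_ref)
            balanced_hits += topology_key(
                heuristic_search(a_bal, gtr_gamma, cfg).best_tree
            ) == topology_key(balanced_ref)
        assert star_hits < balanced_hits

    def test_nni_from_truth_accepts_no_move_on_clean_data(self, gtr_gamma):
        truth = make_balanced_tree(8, 0.1)
        aln = simulate_alignment(truth, gtr_gamma, 1000, seed=74)
        cfg = SearchConfig(n_searches=1, seed=0, max_rounds=10)
        final, _ = _climb(truth.copy(), site_patterns(aln), gtr_gamma, cfg)
        assert topology_key(final) == topology_key(truth)

    def test_spr_moves_reach_truth_small(self, gtr_gamma):
        truth = make_balanced_tree(8, 0.1)
        aln = simulate_alignment(truth, gtr_gamma, 800, seed=75)
        cfg = SearchConfig(n_searches=2, seed=2, moves="spr", max_rounds=8)
        res = heuristic_search(aln, gtr_gamma, cfg)
        assert topology_key(res.best_tree) == topology_key(truth)

    def test_nni_neighborhood_size(self):
        tree = make_balanced_tree(8, 0.1)
        from phyloaudit.tree import unrooted

        moves = _nni_moves(unrooted(tree))
        assert len(moves) == 2 * 5  # 2 moves per internal edge
        keys = set()
        for m in moves:
            cand, _ = _apply_nni(unrooted(tree), m)
            keys.add(topology_key(cand))
        assert len(keys) == 10  # all NNI neighbors distinct


class TestBootstrap:
    def test_supports_in_range_and_deterministic(self, gtr_gamma):
        truth = make_balanced_tree(8, 0.1)
        aln = simulate_alignment(truth, gtr_gamma, 400, seed=80)
        cfg = SearchConfig(n_searches=1, seed=4, max_rounds=6)
        t1 = bootstrap_support(aln, gtr_gamma, cfg, n_replicates=10, ml_tree=truth.copy())
        t2 = bootstrap_support(aln, gtr_gamma, cfg, n_replicates=10, ml_tree=truth.copy())
        sups1 = [n.support for n in t1.postorder() if n.support is not None]
        assert sups1 and all(0 <= s <= 100 for s in sups1)
        assert write_newick(t1) == write_newick(t2)
        assert t1.support_scale == "percent"

    def test_support_higher_on_informative_data(self, gtr_gamma):
        cfg = SearchConfig(n_searches=1, seed=5, max_rounds=6)
        means = {}
        for alpha in (0.001, 0.1):
            truth = make_balanced_tree(8, alpha)
            aln = simulate_alignment(truth, gtr_gamma, 500, seed=[81, int(alpha * 1000)])
            t = bootstrap_support(aln, gtr_gamma, cfg, n_replicates=12, ml_tree=truth.copy())
            sups = [n.support for n in t.postorder() if n.support is not None]
            means[alpha] = np.mean(sups)
        assert means[0.1] > means[0.001]


class TestAuTest:
    def test_same_topology_not_applicable(self, gtr_gamma):
        truth = make_balanced_tree(8, 0.1)
        aln = simulate_alignment(truth, gtr_gamma, 300, seed=90)
        res = au_test(aln, gtr_gamma, [truth, truth.copy()])
        assert not res.applicable and res.p_values is None

    def test_rejects_nni_neighbor_on_strong_data(self, gtr_gamma):
        truth = make_balanced_tree(8, 0.1)
        from phyloaudit.tree import unrooted

        base = unrooted(truth)
        neighbor, _ = _apply_nni(base, _nni_moves(base)[0])
        rejected = 0
        for g in range(5):
            aln = simulate_alignment(truth, gtr_gamma, 1000, seed=[91, g])
            res = au_test(aln, gtr_gamma, [base, neighbor], seed=g, n_resamples=500)
            assert res.applicable
            assert np.all((res.p_values >= 0) & (res.p_values <= 1))
            assert res.p_values[0] > res.p_values[1]
            rejected += res.p_values[1] <= 0.05
        assert rejected >= 4  # large majority

    def test_symmetric_candidates_get_symmetric_pvalues(self, gtr_gamma):
        # constant alignment: per-site log-likelihood vectors coincide, so the
        # RELL winners are perfect ties and both trees receive the same p
        aln = Alignment(taxa=list("ABCDE"), seqs=["ACGTACGTAC"] * 5)
        t1 = parse_newick("((A:0.01,B:0.01):0.01,C:0.01,(D:0.01,E:0.01):0.01);")
        t2 = parse_newick("((A:0.01,C:0.01):0.01,B:0.01,(D:0.01,E:0.01):0.01);")
        res = au_test(aln, gtr_gamma, [t1, t2], n_resamples=200)
        assert res.applicable
        assert res.p_values[0] == pytest.approx(res.p_values[1], abs=1e-9)
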