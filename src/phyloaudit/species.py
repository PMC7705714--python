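"""Species-level stage: concatenation supermatrices and a small-n
quartet-agreement species-tree estimator (the desk-scale stand-in for
summary-coalescent inference from gene trees).

The estimator maximizes the number of induced four-taxon topologies shared
between the candidate species tree and the gene trees. Up to 8 taxa the
maximum is found by exhaustive enumeration of all unrooted topologies; above
that a greedy mode (majority-rule consensus start, NNI hill-climbing on the
quartet score) is used with a warning. Edge support on the returned tree is
gene-tree concordance: the fraction of gene trees containing the bipartition
(a probability-scale value, deliberately simpler than a local posterior).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

from .alignment import Alignment
from .distance import compare_trees
from .engine import _apply_nni, _nni_moves
from .tree import Bipartition, Node, Tree, bipartition_table, topology_key

__all__ = [
    "GeneTreeSet",
    "SpeciesTreeComparison",
    "concatenate",
    "quartet_score",
    "infer_species_tree_small",
    "compare_species_phylogenies",
    "all_unrooted_topologies",
]


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------


def concatenate(alignments: Sequence[Alignment]) -> Alignment:
    """Column-wise supermatrix over the union of taxa (order of first
    appearance); taxa missing from a gene get gaps for that gene's block."""
    if not alignments:
        raise ValueError("nothing to concatenate")
    taxa: list[str] = []
    for aln in alignments:
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)
    parts = {t: [] for t in taxa}
    for aln in alignments:
        lookup = dict(zip(aln.taxa, aln.seqs))
        gap_block = "-" * aln.length
        for t in taxa:
            parts[t].append(lookup.get(t, gap_block))
    return Alignment(taxa=taxa, seqs=["".join(parts[t]) for t in taxa])


# ---------------------------------------------------------------------------
# quartet machinery
# ---------------------------------------------------------------------------


@dataclass
class GeneTreeSet:
    """A collection of (possibly multifurcating) gene trees over a shared
    taxon universe."""

    trees: list
    taxon_universe: frozenset = field(default=None)

    def __post_init__(self):
        union = frozenset().union(*(frozenset(t.leaf_names()) for t in self.trees))
        if self.taxon_universe is None:
            self.taxon_universe = union
        elif not union <= frozenset(self.taxon_universe):
            extra = sorted(union - frozenset(self.taxon_universe))
            raise ValueError(f"gene-tree leaves outside the taxon universe: {extra}")

    def __len__(self):
        return len(self.trees)


def _split_masks(tree: Tree, taxon_pos: dict) -> list[int]:
    """Nontrivial bipartitions as bitmasks over the taxon universe."""
    masks = []
    for bip in bipartition_table(tree).nontrivial:
        m = 0
        for t in bip.block:
            m |= 1 << taxon_pos[t]
        masks.append(m)
    return masks


def _quartet_pairing(masks: list[int], qa: int, qb: int, qc: int, qd: int) -> Optional[int]:
    """Which pairing a tree induces on quartet bits (a,b,c,d): 0 = ab|cd,
    1 = ac|bd, 2 = ad|bc, None = unresolved."""
    quartet = qa | qb | qc | qd
    pairs = ((qa | qb, qc | qd), (qa | qc, qb | qd), (qa | qd, qb | qc))
    for mask in masks:
        inside = mask & quartet
        for which, (p, q) in enumerate(pairs):
            if inside == p or inside == q:
                return which
    return None


def _quartet_table(tree: Tree, taxa: list, taxon_pos: dict) -> dict:
    """Map each resolvable quartet (as a frozenset of 4 bit positions) to its
    induced pairing."""
    present = [t for t in taxa if t in set(tree.leaf_names())]
    masks = _split_masks(tree, taxon_pos)
    table = {}
    for group in combinations(present, 4):
        bits = tuple(1 << taxon_pos[t] for t in group)
        pairing = _quartet_pairing(masks, *bits)
        if pairing is not None:
            table[frozenset(bits)] = pairing
    return table


def quartet_score(candidate: Tree, genes: GeneTreeSet | Sequence[Tree]) -> int:
    """Number of induced quartet topologies shared between the candidate and
    the gene trees, summed over gene trees and over quartets resolvable in
    both trees."""
    if not isinstance(genes, GeneTreeSet):
        genes = GeneTreeSet(trees=list(genes))
    taxa = sorted(genes.taxon_universe | frozenset(candidate.leaf_names()))
    taxon_pos = {t: i for i, t in enumerate(taxa)}
    cand_table = _quartet_table(candidate, taxa, taxon_pos)
    score = 0
    for gene in genes.trees:
        gene_table = _quartet_table(gene, taxa, taxon_pos)
        for quartet, pairing in gene_table.items():
            if cand_table.get(quartet) == pairing:
                score += 1
    return score


# ---------------------------------------------------------------------------
# species-tree search
# ---------------------------------------------------------------------------


def all_unrooted_topologies(taxa: Sequence[str]) -> list[Tree]:
    """All (2n-5)!! unrooted topologies on the given taxa, generated by
    sequential edge addition; deterministic order."""
    taxa = sorted(taxa)
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa")

    root = Node()
    for t in taxa[:3]:
        root.add_child(Node(label=t))
    trees = [Tree(root)]
    for label in taxa[3:]:
        nxt = []
        for tree in trees:
            edges = [n for n in tree.postorder() if n is not tree.root]
            for pos in range(len(edges)):
                t2 = tree.copy()
                target = [n for n in t2.postorder() if n is not t2.root][pos]
                parent = target.parent
                joint = Node()
                parent.children[parent.children.index(target)] = joint
                joint.parent = parent
                joint.add_child(target)
                joint.add_child(Node(label=label))
                nxt.append(t2)
        trees = nxt
    return trees


def _concordance_supports(tree: Tree, genes: GeneTreeSet) -> Tree:
    """Attach per-edge support = fraction of gene trees containing the
    bipartition (probability scale)."""
    out = tree.copy()
    leaf_set = frozenset(out.leaf_names())
    gene_tables = [set(bipartition_table(g).nontrivial) for g in genes.trees]

    def _below(node):
        if node.is_leaf:
            return frozenset([node.label])
        return frozenset().union(*(_below(c) for c in node.children))

    for node in out.postorder():
        if node.is_leaf or node is out.root:
            continue
        side = _below(node)
        if min(len(side), len(leaf_set - side)) < 2:
            continue
        bip = Bipartition.from_side(side, leaf_set)
        node.support = sum(bip in table for table in gene_tables) / len(gene_tables)
    out.support_scale = "probability"
    return out


def _majority_consensus(genes: GeneTreeSet) -> Tree:
    """Greedy consensus start: accept splits by descending frequency when
    compatible, then build the tree."""
    universe = frozenset(genes.taxon_universe)
    counts: dict[frozenset, int] = {}
    for g in genes.trees:
        if frozenset(g.leaf_names()) != universe:
            continue
        for bip in bipartition_table(g).nontrivial:
            counts[bip.block] = counts.get(bip.block, 0) + 1

    def _compatible(x: frozenset, y: frozenset) -> bool:
        return (
            not (x & y) or x <= y or y <= x or (x | y) == universe
        )

    accepted: list[frozenset] = []
    for block in sorted(counts, key=lambda b: (-counts[b], len(b), tuple(sorted(b)))):
        if all(_compatible(block, other) for other in accepted):
            accepted.append(block)

    # build from nested clusters: root holds everything
    root = Node()
    cluster_of: dict[int, frozenset] = {}
    nodes = {}
    for t in sorted(universe):
        leaf = Node(label=t)
        root.add_child(leaf)
        nodes[frozenset([t])] = leaf
    # choose the orientation of each split that does not contain the smallest
    # taxon, so clusters nest below the root
    anchor = min(universe)
    clusters = sorted(
        (b if anchor not in b else universe - b for b in accepted), key=len
    )
    tree = Tree(root)
    for cluster in clusters:
        if len(cluster) < 2 or len(universe - cluster) < 2:
            continue
        # collect current children of root-side whose leafsets nest in cluster
        def _below(node):
            if node.is_leaf:
                return frozenset([node.label])
            return frozenset().union(*(_below(c) for c in node.children))

        host = root
        moved = [c for c in host.children if _below(c) <= cluster]
        while True:
            deeper = None
            for c in host.children:
                if not c.is_leaf and cluster <= _below(c):
                    deeper = c
                    break
            if deeper is None:
                break
            host = deeper
            moved = [c for c in host.children if _below(c) <= cluster]
        if len(moved) < 2:
            continue
        joint = Node()
        for c in moved:
            host.children.remove(c)
            joint.add_child(c)
        host.add_child(joint)
    return tree


def _resolve_polytomies(tree: Tree) -> Tree:
    """Deterministically resolve multifurcations by pairing children in
    sorted order (arbitrary but reproducible starting point)."""
    out = tree.copy()

    def _min_leaf(node):
        if node.is_leaf:
            return node.label
        return min(_min_leaf(c) for c in node.children)

    for node in list(out.postorder()):
        limit = 3 if node is out.root else 2
        while len(node.children) > limit:
            kids = sorted(node.children, key=_min_leaf)
            a, b = kids[0], kids[1]
            joint = Node()
            node.children.remove(a)
            node.children.remove(b)
            joint.add_child(a)
            joint.add_child(b)
            node.add_child(joint)
            joint.parent = node
    return out


def infer_species_tree_small(genes: GeneTreeSet | Sequence[Tree]) -> Tree:
    """Species topology maximizing the quartet score.

    Exhaustive over all unrooted topologies for up to 8 taxa (ties broken by
    the lexicographically smallest canonical topology); larger taxon sets use
    a greedy consensus + NNI hill-climb with a warning. The returned tree
    carries gene-concordance supports and no branch lengths.
    """
    if not isinstance(genes, GeneTreeSet):
        genes = GeneTreeSet(trees=list(genes))
    taxa = sorted(genes.taxon_universe)
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa to infer a species tree")

    if len(taxa) <= 8:
        best_tree, best = None, (-1, None)
        for cand in all_unrooted_topologies(taxa):
            score = quartet_score(cand, genes)
            key = (-score, topology_key(cand))
            if best_tree is None or key < best:
                best_tree, best = cand, key
    else:
        warnings.warn(
            f"{len(taxa)} taxa: falling back to greedy quartet search "
            "(exhaustive mode caps at 8)"
        )
        tree = _resolve_polytomies(_majority_consensus(genes))
        cur = quartet_score(tree, genes)
        improved = True
        while improved:
            improved = False
            for move in _nni_moves(tree):
                cand, _ = _apply_nni(tree, move)
                s = quartet_score(cand, genes)
                if s > cur:
                    tree, cur = cand, s
                    improved = True
                    break
        best_tree = tree
    return _concordance_supports(best_tree, genes)


# ---------------------------------------------------------------------------
# Run1-vs-Run2 species comparison
# ---------------------------------------------------------------------------


@dataclass
class SpeciesTreeComparison:
    """Replicate comparison record: tree distance (%), branch distance (KF,
    None when either tree lacks branch lengths), and percentage of shared
    bipartitions with different support (None when the topologies differ)."""

    tree_distance_pct: float
    branch_distance: Optional[float]
    support_diff_pct: Optional[float]


def compare_species_phylogenies(run1: Tree, run2: Tree) -> SpeciesTreeComparison:
    result = compare_trees(run1, run2)
    return SpeciesTreeComparison(
        tree_distance_pct=100.0 * result.nrfd,
        branch_distance=result.kf,
        support_diff_pct=result.support_diff_pct if result.rf == 0 else None,
    )
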