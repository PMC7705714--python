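"""Simulation campaign: alpha-scaled balanced/star reference trees and
GTR+Gamma sequence alignments evolved along them.

The campaign's default design is 30 reference trees of 64 taxa (15 balanced,
15 star, one per alpha in 0.001..0.1), 500 alignments per tree with lengths
uniform on [300, 1000] bp, under GTR with equal exchangeabilities and equal
base frequencies, Gamma shape 1 with 4 categories, and no invariant sites.
Balanced trees have every external branch of length alpha and every internal
branch of length alpha/2; star trees additionally zero out the six internal
branches nearest the root, so that contracting them leaves a root polytomy of
eight subtrees.

Every alignment is generated from its own counter-derived seed
(``SeedSequence([master_seed, tree_index, alignment_index])``), so any single
file can be regenerated in isolation and two runs of the same campaign are
byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import Alignment, write_fasta
from .model import GTRModel
from .tree import Node, Tree, write_newick

__all__ = [
    "DEFAULT_ALPHAS",
    "SimulationDesign",
    "make_balanced_tree",
    "make_star_tree",
    "simulate_alignment",
    "run_campaign",
]

DEFAULT_ALPHAS = (
    0.001, 0.002, 0.003, 0.004, 0.005, 0.006, 0.007, 0.008, 0.009,
    0.01, 0.02, 0.04, 0.06, 0.08, 0.1,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


def make_balanced_tree(n_taxa: int, alpha: float) -> Tree:
    """Fully balanced rooted binary tree: external edges alpha, internal
    edges alpha/2, leaves labeled t1..tn left to right."""
    if not _is_power_of_two(n_taxa) or n_taxa < 4:
        raise ValueError(f"n_taxa must be a power of two >= 4, got {n_taxa}")
    counter = iter(range(1, n_taxa + 1))

    def _build(size: int) -> Node:
        if size == 1:
            return Node(label=f"t{next(counter)}", length=alpha)
        node = Node(length=alpha / 2.0)
        node.add_child(_build(size // 2))
        node.add_child(_build(size // 2))
        return node

    root = _build(n_taxa)
    root.length = None
    return Tree(root)


def make_star_tree(n_taxa: int, alpha: float) -> Tree:
    """Balanced tree whose six internal branches nearest the root (the two
    root-child edges and the four grandchild edges) have length zero."""
    if not _is_power_of_two(n_taxa) or n_taxa < 16:
        raise ValueError(f"n_taxa must be a power of two >= 16, got {n_taxa}")
    tree = make_balanced_tree(n_taxa, alpha)
    for child in tree.root.children:
        child.length = 0.0
        for grandchild in child.children:
            grandchild.length = 0.0
    return tree


def simulate_alignment(tree: Tree, model: GTRModel, length: int, seed) -> Alignment:
    """Evolve ``length`` sites down ``tree`` under ``model``.

    Root states are drawn from the equilibrium frequencies; each site draws a
    rate category once; each edge then samples child states from
    P(rate * branch length). Deterministic given the seed (an int or a
    ``numpy.random.SeedSequence``).
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    for node in tree.postorder():
        if node is not tree.root and node.length is None:
            raise ValueError(f"missing branch length above {node.label!r}")

    rng = np.random.default_rng(seed)
    rates, weights = model.category_rates()
    cats = rng.choice(len(rates), size=length, p=weights)
    cat_index = [np.flatnonzero(cats == k) for k in range(len(rates))]

    states: dict[int, np.ndarray] = {
        id(tree.root): rng.choice(4, size=length, p=model.pi)
    }
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_states = states[id(node.parent)]
        child = np.empty(length, dtype=np.int64)
        for k, idx in enumerate(cat_index):
            if idx.size == 0:
                continue
            P = model.transition_matrix(rates[k] * node.length)
            cum = np.cumsum(P, axis=1)
            cum[:, -1] = 1.0  # guard against roundoff at the last bin
            u = rng.random(idx.size)
            child[idx] = (u[:, None] > cum[parent_states[idx]]).sum(axis=1)
        states[id(node)] = child

    leaves = tree.leaves()
    seqs = [_BASES[states[id(leaf)]].tobytes().decode() for leaf in leaves]
    return Alignment(taxa=[leaf.label for leaf in leaves], seqs=seqs)


@dataclass
class SimulationDesign:
    """Parameters of the alpha-sweep campaign."""

    alphas: tuple = DEFAULT_ALPHAS
    shapes: tuple = ("balanced", "star")
    n_taxa: int = 64
    alignments_per_tree: int = 500
    length_range: tuple = (300, 1000)
    master_seed: int = 0

    def __post_init__(self):
        if any(a <= 0 for a in self.alphas):
            raise ValueError("all alpha values must be positive")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError(f"bad length range {self.length_range}")
        if not _is_power_of_two(self.n_taxa):
            raise ValueError("n_taxa must be a power of two")

    @property
    def n_trees(self) -> int:
        return len(self.alphas) * len(self.shapes)

    @property
    def total_alignments(self) -> int:
        return self.n_trees * self.alignments_per_tree

    def reference_tree(self, shape: str, alpha: float) -> Tree:
        if shape == "balanced":
            return make_balanced_tree(self.n_taxa, alpha)
        if shape == "star":
            return make_star_tree(self.n_taxa, alpha)
        raise ValueError(f"unknown tree shape {shape!r}")

    def alignment_seed(self, tree_index: int, aln_index: int) -> np.random.SeedSequence:
        """Counter-derived per-alignment seed (regenerable in isolation)."""
        return np.random.SeedSequence([self.master_seed, tree_index, aln_index])

    def iter_trees(self):
        index = 0
        for shape in self.shapes:
            for alpha in self.alphas:
                yield index, shape, alpha
                index += 1


def run_campaign(
    design: SimulationDesign,
    out_dir,
    model: GTRModel | None = None,
    limit: int | None = None,
) -> pd.DataFrame:
    """Generate the campaign to ``out_dir`` and return (and write) a manifest.

    ``limit`` caps the number of alignments per reference tree (a smoke run);
    the default generates the full design. The manifest TSV records shape,
    alpha, file paths, drawn length, and the seed key of every alignment.
    """
    model = model or GTRModel()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_tree = design.alignments_per_tree if limit is None else min(
        limit, design.alignments_per_tree
    )
    lo, hi = design.length_range

    rows = []
    for tree_index, shape, alpha in design.iter_trees():
        tree = design.reference_tree(shape, alpha)
        subdir = out_dir / f"{shape}_a{alpha:g}"
        subdir.mkdir(exist_ok=True)
        tree_file = subdir / "reference.nwk"
        tree_file.write_text(write_newick(tree) + "\n")
        for aln_index in range(per_tree):
            seed = design.alignment_seed(tree_index, aln_index)
            rng = np.random.default_rng(seed)
            length = int(rng.integers(lo, hi + 1))
            aln = simulate_alignment(tree, model, length, seed=rng)
            aln_file = subdir / f"gene{aln_index:04d}.fasta"
            write_fasta(aln, aln_file)
            rows.append(
                {
                    "gene_id": f"{shape}_a{alpha:g}_g{aln_index:04d}",
                    "shape": shape,
                    "alpha": alpha,
                    "tree_index": tree_index,
                    "aln_index": aln_index,
                    "aln_file": str(aln_file.relative_to(out_dir)),
                    "tree_file": str(tree_file.relative_to(out_dir)),
                    "length": length,
                    "seed_key": f"{design.master_seed}:{tree_index}:{aln_index}",
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


def config_fingerprint(*parts) -> str:
    """Short stable hash used to key cached per-gene audit results."""
    blob = "\x1f".join(repr(p) for p in parts).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
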