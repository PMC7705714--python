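"""Tree-to-tree comparison: Robinson-Foulds, Kuhner-Felsenstein, support
agreement, and support-threshold collapsing.

Conventions
-----------
* All comparisons act on the unrooted view of the trees.
* nRFD is normalized by 2(n-3), the maximum possible RF distance between two
  binary unrooted n-leaf trees, so multifurcating (collapsed) trees remain
  comparable to binary ones.
* KF is the plain sum of squared branch-length differences over matched
  bipartitions (external edges matched by leaf, internal edges by canonical
  split; an edge present in only one tree contributes its length squared).
  Some packages report the square root of this quantity; that variant is
  exposed as :attr:`ComparisonResult.kf_root`.
* The percentage of shared bipartitions with different support is only
  defined when the topologies are identical (RF = 0); otherwise it is None
  ("NA").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .tree import Bipartition, Tree, bipartition_table

__all__ = [
    "ComparisonResult",
    "compare_trees",
    "prune_to_shared_leaves",
    "collapse_low_support",
]


@dataclass
class ComparisonResult:
    n_shared_leaves: int
    rf: int
    nrfd: float
    kf: Optional[float]
    support_diff_pct: Optional[float]
    conflicting_bipartitions: list  # (origin "a"/"b", Bipartition, support)
    congruent_bipartitions: list  # (Bipartition, support_a, support_b)

    @property
    def kf_root(self) -> Optional[float]:
        """Square root of KF (the ape/phangorn reporting convention)."""
        return None if self.kf is None else math.sqrt(self.kf)


def _check_support_scales(a: Tree, b: Tree) -> None:
    if a.support_scale and b.support_scale and a.support_scale != b.support_scale:
        raise ValueError(
            f"support scales differ ({a.support_scale} vs {b.support_scale}); "
            "rescale before comparing"
        )


def compare_trees(a: Tree, b: Tree) -> ComparisonResult:
    """Compare two trees on the same leaf set.

    Raises if the leaf sets differ (use :func:`prune_to_shared_leaves` first)
    or if there are fewer than 4 shared leaves.
    """
    leaves_a = frozenset(a.leaf_names())
    leaves_b = frozenset(b.leaf_names())
    if leaves_a != leaves_b:
        raise ValueError(
            "leaf sets differ; call prune_to_shared_leaves(a, b) before comparing"
        )
    n = len(leaves_a)
    if n < 4:
        raise ValueError(f"need at least 4 leaves to compare trees, got {n}")
    _check_support_scales(a, b)

    table_a = bipartition_table(a)
    table_b = bipartition_table(b)
    nontrivial_a = table_a.nontrivial
    nontrivial_b = table_b.nontrivial

    only_a = set(nontrivial_a) - set(nontrivial_b)
    only_b = set(nontrivial_b) - set(nontrivial_a)
    shared = set(nontrivial_a) & set(nontrivial_b)
    rf = len(only_a) + len(only_b)
    nrfd = rf / (2.0 * (n - 3))

    # KF over the union of all (trivial and nontrivial) edges
    have_lengths = any(v[0] is not None for v in table_a.entries.values()) or any(
        v[0] is not None for v in table_b.entries.values()
    )
    kf = None
    if have_lengths:
        kf = 0.0
        for bip in set(table_a.entries) | set(table_b.entries):
            la = table_a.entries.get(bip, (0.0, None))[0] or 0.0
            lb = table_b.entries.get(bip, (0.0, None))[0] or 0.0
            kf += (la - lb) ** 2

    def _sort_key(bip: Bipartition):
        return tuple(sorted(bip.block))

    conflicting = [
        ("a", bip, nontrivial_a[bip][1]) for bip in sorted(only_a, key=_sort_key)
    ] + [("b", bip, nontrivial_b[bip][1]) for bip in sorted(only_b, key=_sort_key)]
    congruent = [
        (bip, nontrivial_a[bip][1], nontrivial_b[bip][1])
        for bip in sorted(shared, key=_sort_key)
    ]

    support_diff_pct = None
    if rf == 0:
        scored = [
            (sa, sb) for _, sa, sb in congruent if sa is not None and sb is not None
        ]
        if scored:
            n_diff = sum(1 for sa, sb in scored if sa != sb)
            support_diff_pct = 100.0 * n_diff / len(scored)
        elif not congruent:
            support_diff_pct = 0.0

    return ComparisonResult(
        n_shared_leaves=n,
        rf=rf,
        nrfd=nrfd,
        kf=kf,
        support_diff_pct=support_diff_pct,
        conflicting_bipartitions=conflicting,
        congruent_bipartitions=congruent,
    )


def _suppress_degree_two(tree: Tree) -> None:
    """Remove unifurcations in place, summing branch lengths."""
    changed = True
    while changed:
        changed = False
        for node in list(tree.postorder()):
            if node.is_leaf:
                continue
            if node is tree.root:
                if len(node.children) == 1:
                    child = node.children[0]
                    child.parent = None
                    child.length = None
                    tree.root = child
                    changed = True
                continue
            if len(node.children) == 1:
                child = node.children[0]
                child.length = (child.length or 0.0) + (node.length or 0.0)
                if child.support is None:
                    child.support = node.support
                parent = node.parent
                parent.children[parent.children.index(node)] = child
                child.parent = parent
                changed = True


def _prune_to(tree: Tree, keep: frozenset) -> Tree:
    pruned = tree.copy()

    def _strip(node):
        node.children = [c for c in node.children if _keep(c)]
        return node

    def _keep(node) -> bool:
        if node.is_leaf:
            return node.label in keep
        _strip(node)
        return bool(node.children)

    _strip(pruned.root)
    _suppress_degree_two(pruned)
    return pruned


def prune_to_shared_leaves(a: Tree, b: Tree) -> tuple[Tree, Tree]:
    """Restrict both trees to their common leaves, suppressing the resulting
    degree-2 vertices with branch lengths summed."""
    common = frozenset(a.leaf_names()) & frozenset(b.leaf_names())
    if len(common) < 4:
        raise ValueError(f"only {len(common)} shared leaves; need at least 4")
    pa = a if frozenset(a.leaf_names()) == common else _prune_to(a, common)
    pb = b if frozenset(b.leaf_names()) == common else _prune_to(b, common)
    return pa, pb


def collapse_low_support(tree: Tree, threshold: float) -> Tree:
    """Contract every internal edge whose support is <= ``threshold``
    (inclusive), creating polytomies; contracted edge lengths are discarded.

    Edges without a support value are never collapsed. The threshold must lie
    within the tree's declared support scale.
    """
    scale = tree.support_scale
    if scale == "percent" and not (0 <= threshold <= 100):
        raise ValueError(f"threshold {threshold} outside percent scale [0, 100]")
    if scale == "probability" and not (0 <= threshold <= 1):
        raise ValueError(f"threshold {threshold} outside probability scale [0, 1]")

    out = tree.copy()
    leaf_set = frozenset(out.leaf_names())

    def _leaves_below(node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        return frozenset().union(*(_leaves_below(c) for c in node.children))

    changed = True
    while changed:
        changed = False
        for node in list(out.postorder()):
            if node.is_leaf or node is out.root:
                continue
            if node.support is None or node.support > threshold:
                continue
            side = _leaves_below(node)
            if min(len(side), len(leaf_set - side)) < 2:
                continue  # trivial (root-artifact) edge: nothing to contract
            parent = node.parent
            idx = parent.children.index(node)
            for child in node.children:
                child.parent = parent
            parent.children[idx : idx + 1] = node.children
            changed = True
            break
    return out
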