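"""A compact, deterministic maximum-likelihood tree engine (GTR+Gamma).

The engine exists to make one mechanism auditable: the order in which
per-site log-likelihoods are added. Floating-point addition is not
associative, so multithreaded reductions and processor-specific kernels in
production ML programs can return slightly different log-likelihoods for the
same tree — enough to flip the outcome of a hill-climbing search when
candidate topologies are effectively tied. Here that nondeterminism is
*emulated*, not incurred: a ``summation mode`` chooses the addition order
explicitly, so every "run" is a pure function of (alignment, model, config).

Summation modes
---------------
``exact``          compensated (Kahan) summation over the canonical pattern
                   order; permutation-invariant reference.
``sequential``     naive left-to-right over sites in alignment column order.
``reversed``       naive right-to-left.
``blocked:K``      K contiguous blocks summed independently, then combined
                   (models a K-thread partial-sum reduction).
``shuffled:S``     naive summation over a pseudorandom site order with order
                   seed S (models a different processor kernel's operation
                   order).

Within branch-length optimization the engine always uses pattern-level
compensated summation; the configured mode applies where the mechanism acts
in the real programs — when log-likelihoods of *trees* are compared (move
acceptance during the search, and selection across starts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .alignment import Alignment
from .model import GTRModel
from .tree import Node, Tree, bipartition_table, topology_key, unrooted

__all__ = [
    "SearchConfig",
    "SearchResult",
    "AuTestResult",
    "SitePatterns",
    "site_patterns",
    "log_likelihood",
    "per_site_log_likelihoods",
    "optimize_branch_lengths",
    "generate_starting_tree",
    "heuristic_search",
    "bootstrap_support",
    "au_test",
    "combine_site_logls",
]

# ---------------------------------------------------------------------------
# site patterns
# ---------------------------------------------------------------------------

_IUPAC_MASK = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000, "U": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001, "K": 0b1100,
    "M": 0b0011, "B": 0b1110, "D": 0b1101, "H": 0b1011, "V": 0b0111,
    "N": 0b1111, "-": 0b1111, ".": 0b1111, "?": 0b1111,
}
_MASK_LUT = np.zeros(256, dtype=np.uint8)
for _ch, _m in _IUPAC_MASK.items():
    _MASK_LUT[ord(_ch)] = _m


@dataclass
class SitePatterns:
    """Compressed alignment columns in a canonical (lexicographic) order.

    ``matrix[k, j]`` is the 4-bit IUPAC state mask of taxon j in pattern k;
    ``weights`` are pattern multiplicities (summing to the alignment length);
    ``site_index`` maps original columns back onto patterns. Summation modes
    permute additions at evaluation time, never here.
    """

    taxa: list
    matrix: np.ndarray
    weights: np.ndarray
    site_index: np.ndarray
    _partials: dict = field(default_factory=dict, repr=False)

    @property
    def n_patterns(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return int(self.site_index.shape[0])

    def leaf_partial(self, taxon: str) -> np.ndarray:
        """(n_patterns, 4) 0/1 conditional likelihoods at a leaf."""
        if taxon not in self._partials:
            col = self.matrix[:, self.taxa.index(taxon)]
            bits = (col[:, None] >> np.arange(4)[None, :]) & 1
            self._partials[taxon] = bits.astype(float)
        return self._partials[taxon]


def site_patterns(aln: Alignment) -> SitePatterns:
    """Compress a nucleotide alignment into unique weighted columns."""
    raw = aln.matrix().view(np.uint8)
    masks = _MASK_LUT[raw]
    if np.any(masks == 0):
        bad_taxon, bad_site = np.argwhere(masks == 0)[0]
        residue = chr(raw[bad_taxon, bad_site])
        raise ValueError(
            f"non-nucleotide residue {residue!r} in {aln.taxa[bad_taxon]!r} "
            f"at site {bad_site + 1}"
        )
    cols = masks.T  # (L, n_taxa)
    pats, inverse, counts = np.unique(
        cols, axis=0, return_inverse=True, return_counts=True
    )
    return SitePatterns(
        taxa=list(aln.taxa),
        matrix=pats,
        weights=counts.astype(float),
        site_index=inverse.reshape(-1),
    )


# ---------------------------------------------------------------------------
# summation modes
# ---------------------------------------------------------------------------


def _parse_mode(mode: str) -> tuple[str, Optional[int]]:
    if ":" in mode:
        kind, param = mode.split(":", 1)
        return kind, int(param)
    return mode, None


def _kahan(values) -> float:
    total, comp = 0.0, 0.0
    for x in values:
        y = float(x) - comp
        t = total + y
        comp = (t - total) - y
        total = t
    return total


def _naive(values) -> float:
    total = 0.0
    for x in values:
        total += float(x)
    return total


def combine_site_logls(
    pattern_logls: np.ndarray, patterns: SitePatterns, mode: str = "exact"
) -> float:
    """Combine per-site log-likelihoods under the given summation mode."""
    kind, param = _parse_mode(mode)
    if kind == "exact":
        return _kahan(patterns.weights * pattern_logls)
    site_vals = pattern_logls[patterns.site_index]
    if kind == "sequential":
        return _naive(site_vals)
    if kind == "reversed":
        return _naive(site_vals[::-1])
    if kind == "blocked":
        if not param or param < 1:
            raise ValueError("blocked mode needs a positive block count, e.g. blocked:4")
        return _naive(_naive(block) for block in np.array_split(site_vals, param))
    if kind == "shuffled":
        if param is None:
            raise ValueError("shuffled mode needs an order seed, e.g. shuffled:7")
        perm = np.random.default_rng(param).permutation(site_vals.shape[0])
        return _naive(site_vals[perm])
    raise ValueError(f"unknown summation mode {mode!r}")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchConfig:
    """Settings of one fully specified inference run.

    Defaults follow the audited protocol: 20 tree searches split evenly
    between parsimony and random starting trees, log-likelihood epsilon
    0.0001, NNI moves, exact summation. Every field participates in the run
    log, implementing the recommendation that analyses disclose the
    parameters that actually determine their output.
    """

    n_searches: int = 20
    n_parsimony: Optional[int] = None  # default: half of n_searches
    moves: str = "nni"  # "nni" or "spr"
    epsilon: float = 1e-4
    seed: int = 0
    summation_mode: str = "exact"
    min_branch_length: float = 1e-8
    max_branch_length: float = 10.0
    max_rounds: int = 50
    max_sweeps: int = 100
    bl_xatol: float = 1e-6

    def __post_init__(self):
        if self.n_searches < 1:
            raise ValueError("n_searches must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.moves not in ("nni", "spr"):
            raise ValueError(f"unknown move set {self.moves!r}")
        _parse_mode(self.summation_mode)  # validate

    @property
    def parsimony_starts(self) -> int:
        return self.n_searches // 2 if self.n_parsimony is None else self.n_parsimony

    def run_log(self) -> dict:
        return {
            "n_searches": self.n_searches,
            "parsimony_starts": self.parsimony_starts,
            "moves": self.moves,
            "epsilon": self.epsilon,
            "seed": self.seed,
            "summation_mode": self.summation_mode,
            "min_branch_length": self.min_branch_length,
        }


@dataclass
class SearchResult:
    best_tree: Tree
    best_logl: float
    start_trees: list
    start_logls: list
    config: SearchConfig
    log: dict


@dataclass
class AuTestResult:
    """Approximately-unbiased test outcome for a set of candidate trees."""

    applicable: bool
    p_values: Optional[np.ndarray]
    significant: Optional[np.ndarray]
    n_resamples: int
    scales: tuple


# ---------------------------------------------------------------------------
# likelihood kernel
# ---------------------------------------------------------------------------

_TINY = 1e-320


class _Kernel:
    """Felsenstein pruning over site patterns with underflow rescaling.

    Conditional likelihood arrays use layout (n_categories, n_patterns, 4).
    Node ``i`` of the postorder list owns the edge between itself and its
    parent, of length ``t[i]``.
    """

    def __init__(
        self,
        tree: Tree,
        patterns: SitePatterns,
        model: GTRModel,
        *,
        min_bl: float = 1e-8,
        max_bl: float = 10.0,
        xatol: float = 1e-6,
        default_length: float = 0.1,
    ):
        leaf_names = set(tree.leaf_names())
        if leaf_names != set(patterns.taxa):
            missing = sorted(leaf_names ^ set(patterns.taxa))
            raise ValueError(f"tree and alignment taxa differ: {missing}")
        self.tree = tree
        self.patterns = patterns
        self.model = model
        self.min_bl = min_bl
        self.max_bl = max_bl
        self.xatol = xatol

        self.nodes = list(tree.postorder())
        self.N = len(self.nodes)
        self.root_i = self.N - 1
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent = np.array(
            [self.index[id(n.parent)] if n.parent is not None else -1 for n in self.nodes]
        )
        self.children = [
            [self.index[id(c)] for c in n.children] for n in self.nodes
        ]
        lengths = []
        for n in self.nodes:
            if n.parent is None:
                lengths.append(0.0)
            elif n.length is None:
                lengths.append(default_length)
            else:
                lengths.append(float(n.length))
        self.t = np.array(lengths)

        self.rates, self.weights = model.category_rates()
        self.ncat = len(self.rates)
        lam, right, left = model._eigen()
        self.lam, self.right, self.left = lam, right, left
        self.pi = model.pi
        self.npat = patterns.n_patterns
        self.w_pat = patterns.weights
        self._zeros = np.zeros(self.npat)
        self._pi_bcast = np.broadcast_to(
            self.pi[None, None, :], (self.ncat, self.npat, 4)
        )

    # -- transition matrices ------------------------------------------

    def _P(self, t: float) -> np.ndarray:
        ex = np.exp(self.lam[None, :] * (self.rates[:, None] * t))
        P = np.matmul(self.right[None, :, :] * ex[:, None, :], self.left)
        np.maximum(P, 0.0, out=P)
        return P

    def _P_derivs(self, t: float):
        """P(t), dP/dt, d2P/dt2 stacked per rate category (no clipping)."""
        lr = self.lam[None, :] * self.rates[:, None]  # (ncat, 4)
        ex = np.exp(lr * t)
        right = self.right[None, :, :]
        P = np.matmul(right * ex[:, None, :], self.left)
        P1 = np.matmul(right * (lr * ex)[:, None, :], self.left)
        P2 = np.matmul(right * (lr * lr * ex)[:, None, :], self.left)
        return P, P1, P2

    def _leaf_bcast(self, label: str) -> np.ndarray:
        lp = self.patterns.leaf_partial(label)
        return np.broadcast_to(lp[None, :, :], (self.ncat, self.npat, 4))

    # -- passes --------------------------------------------------------

    def _down(self):
        """Postorder conditional likelihoods.

        Returns (down, slog, C): subtree partials, their log-scalers, and
        per-edge child contributions C[i] = P(t_i) applied to down[i]."""
        down = [None] * self.N
        slog = [None] * self.N
        C = [None] * self.N
        for i, node in enumerate(self.nodes):
            if node.is_leaf:
                down[i] = self._leaf_bcast(node.label)
                slog[i] = self._zeros
            else:
                kids = self.children[i]
                prod = C[kids[0]].copy()
                lg = slog[kids[0]].copy()
                for c in kids[1:]:
                    prod *= C[c]
                    lg += slog[c]
                m = prod.max(axis=(0, 2))
                np.maximum(m, 1e-300, out=m)
                prod /= m[None, :, None]
                lg += np.log(m)
                down[i] = prod
                slog[i] = lg
            if node.parent is not None:
                P = self._P(self.t[i])
                C[i] = np.matmul(down[i], P.transpose(0, 2, 1))
        return down, slog, C

    def pattern_logls(self, cache=None) -> np.ndarray:
        down, slog, _ = cache if cache is not None else self._down()
        site_l = np.einsum("c,cns,s->n", self.weights, down[self.root_i], self.pi)
        return np.log(np.maximum(site_l, _TINY)) + slog[self.root_i]

    def total_logl(self) -> float:
        """Pattern-level compensated total (the internal reference value)."""
        return _kahan(self.w_pat * self.pattern_logls())

    def _edge_outer(self, i, down, slog, C):
        """Outside partial for a single edge, walking the root-to-edge path."""
        path = []
        j = i
        while j != self.root_i:
            path.append(j)
            j = self.parent[j]
        path.reverse()
        O = self._pi_bcast
        olog = self._zeros
        for j in path:
            p = self.parent[j]
            A = O
            lg = olog
            for s in self.children[p]:
                if s == j:
                    continue
                A = A * C[s]
                lg = lg + slog[s]
            if j == i:
                return A, lg
            tmp = np.matmul(A, self._P(self.t[j]))
            m = tmp.max(axis=(0, 2))
            np.maximum(m, 1e-300, out=m)
            tmp /= m[None, :, None]
            O = tmp
            olog = lg + np.log(m)
        raise AssertionError("unreachable")  # pragma: no cover

    # -- branch-length optimization -------------------------------------

    def _edge_pattern_logls(self, A_i, alog_i, down_i, slog_i, t: float):
        P = self._P(t)
        tmp = np.matmul(A_i, P)
        val = np.einsum("c,cnj,cnj->n", self.weights, tmp, down_i)
        return np.log(np.maximum(val, _TINY)) + alog_i + slog_i

    def optimize_edge(self, i, A_i, alog_i, down_i, slog_i):
        """Optimize one branch length by safeguarded Newton-Raphson on the
        per-edge likelihood (multiplicative steps when the curvature is not
        usable); returns (t*, pattern logls at t*).

        The chosen length is the best of all points visited, so the per-edge
        likelihood never decreases relative to the starting length."""
        lo, hi = self.min_bl, self.max_bl
        wc, w = self.weights, self.w_pat
        t = float(min(max(self.t[i], lo), hi))

        def site_vals(t):
            P, P1, P2 = self._P_derivs(t)
            v = np.einsum("c,cnj,cnj->n", wc, np.matmul(A_i, P), down_i)
            v1 = np.einsum("c,cnj,cnj->n", wc, np.matmul(A_i, P1), down_i)
            v2 = np.einsum("c,cnj,cnj->n", wc, np.matmul(A_i, P2), down_i)
            return np.maximum(v, _TINY), v1, v2

        best_t, best_ll = t, -np.inf
        for _ in range(30):
            v, v1, v2 = site_vals(t)
            ll = float(np.dot(w, np.log(v)))
            if ll > best_ll:
                best_t, best_ll = t, ll
            ratio = v1 / v
            grad = float(np.dot(w, ratio))
            hess = float(np.dot(w, v2 / v - ratio * ratio))
            if (t <= lo and grad < 0) or (t >= hi and grad > 0):
                break
            if hess < 0:
                step = -grad / hess
                t_new = t + step
                if not np.isfinite(t_new) or t_new <= 0:
                    t_new = t * 0.5 if grad < 0 else t * 2.0
            else:
                t_new = t * 2.0 if grad > 0 else t * 0.5
            t_new = float(min(max(t_new, lo), hi))
            if abs(t_new - t) < self.xatol:
                v, _, _ = site_vals(t_new)
                ll = float(np.dot(w, np.log(v)))
                if ll > best_ll:
                    best_t, best_ll = t_new, ll
                break
            t = t_new

        self.t[i] = best_t
        v, _, _ = site_vals(best_t)
        return best_t, np.log(v) + alog_i + slog_i

    def _refresh_to_root(self, i, down, slog, C) -> None:
        """After changing t[i], update C[i] and every ancestor's partials so
        the caches stay globally consistent (coordinate-ascent sweeps)."""
        C[i] = np.matmul(down[i], self._P(self.t[i]).transpose(0, 2, 1))
        j = self.parent[i]
        while j != -1:
            kids = self.children[j]
            prod = C[kids[0]].copy()
            lg = slog[kids[0]].copy()
            for c in kids[1:]:
                prod *= C[c]
                lg += slog[c]
            m = prod.max(axis=(0, 2))
            np.maximum(m, 1e-300, out=m)
            prod /= m[None, :, None]
            lg += np.log(m)
            down[j] = prod
            slog[j] = lg
            if j != self.root_i:
                C[j] = np.matmul(down[j], self._P(self.t[j]).transpose(0, 2, 1))
            j = self.parent[j]

    def optimize_all(self, epsilon: float, max_sweeps: int = 100, warn_cap: bool = True) -> float:
        """Coordinate-ascent sweeps of per-edge Newton optimization until a
        full sweep improves the log-likelihood by less than epsilon."""
        prev = self.total_logl()
        cur = prev
        for _ in range(max_sweeps):
            down, slog, C = self._down()
            for i in range(self.N - 1):
                A_i, alog_i = self._edge_outer(i, down, slog, C)
                self.optimize_edge(i, A_i, alog_i, down[i], slog[i])
                self._refresh_to_root(i, down, slog, C)
            site_l = np.einsum(
                "c,cns,s->n", self.weights, down[self.root_i], self.pi
            )
            cur = _kahan(
                self.w_pat * (np.log(np.maximum(site_l, _TINY)) + slog[self.root_i])
            )
            if cur - prev < epsilon:
                return cur
            prev = cur
        if warn_cap:
            warnings.warn(
                "branch-length optimization hit the sweep cap; returning best so far"
            )
        return cur

    def apply_lengths(self) -> None:
        """Write optimized lengths back onto the tree's nodes."""
        for i, node in enumerate(self.nodes):
            if node.parent is not None:
                node.length = max(float(self.t[i]), self.min_bl)


# ---------------------------------------------------------------------------
# public likelihood API
# ---------------------------------------------------------------------------


def _require_lengths(tree: Tree) -> None:
    for node in tree.postorder():
        if node.parent is not None and node.length is None:
            raise ValueError(f"missing branch length above {node.label!r}")


def log_likelihood(
    tree: Tree, aln: Alignment, model: GTRModel, mode: str = "exact"
) -> float:
    """Log-likelihood of an alignment on a tree, per-site values combined
    under the given summation mode."""
    _require_lengths(tree)
    patterns = site_patterns(aln)
    kern = _Kernel(tree, patterns, model)
    return combine_site_logls(kern.pattern_logls(), patterns, mode)


def per_site_log_likelihoods(tree: Tree, aln: Alignment, model: GTRModel) -> np.ndarray:
    """Per-site log-likelihood vector in original column order."""
    _require_lengths(tree)
    patterns = site_patterns(aln)
    kern = _Kernel(tree, patterns, model)
    return kern.pattern_logls()[patterns.site_index]


def optimize_branch_lengths(
    tree: Tree,
    aln: Alignment,
    model: GTRModel,
    epsilon: float = 1e-4,
    *,
    min_branch_length: float = 1e-8,
    max_sweeps: int = 100,
    xatol: float = 1e-6,
) -> Tree:
    """Return a copy of ``tree`` with branch lengths optimized by iterative
    per-edge Brent sweeps (terminating when a sweep gains < epsilon)."""
    out = tree.copy()
    patterns = site_patterns(aln)
    kern = _Kernel(out, patterns, model, min_bl=min_branch_length, xatol=xatol)
    kern.optimize_all(epsilon, max_sweeps)
    kern.apply_lengths()
    return out


# ---------------------------------------------------------------------------
# starting trees
# ---------------------------------------------------------------------------


def _insert_leaf(target: Node, leaf: Node) -> Node:
    """Insert ``leaf`` on the edge above ``target``; returns the new node."""
    parent = target.parent
    joint = Node()
    parent.children[parent.children.index(target)] = joint
    joint.parent = parent
    joint.add_child(target)
    joint.add_child(leaf)
    return joint


def _remove_insertion(joint: Node, target: Node) -> None:
    parent = joint.parent
    parent.children[parent.children.index(joint)] = target
    target.parent = parent


def _fitch_score(tree: Tree, patterns: SitePatterns) -> float:
    """Weighted Fitch parsimony score over site patterns (masks as state
    sets; multifurcations combined pairwise)."""
    col = {t: patterns.matrix[:, j] for j, t in enumerate(patterns.taxa)}
    score = 0.0
    masks: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            masks[id(node)] = col[node.label]
            continue
        cur = masks[id(node.children[0])]
        for child in node.children[1:]:
            other = masks[id(child)]
            inter = cur & other
            union_needed = inter == 0
            score += float(patterns.weights[union_needed].sum())
            cur = np.where(union_needed, cur | other, inter)
        masks[id(node)] = cur
    return score


def generate_starting_tree(aln: Alignment, kind: str, seed) -> Tree:
    """Build a starting topology by sequential taxon addition.

    ``kind="random"`` attaches each taxon to a uniformly random edge;
    ``kind="parsimony"`` attaches it to the edge minimizing the Fitch
    parsimony score (ties broken by edge enumeration order). The taxon
    addition order is a seed-determined shuffle in both cases; the result is
    deterministic given the seed. All branch lengths are initialized to 0.1.
    """
    if aln.n_taxa < 4:
        raise ValueError("need at least 4 taxa for a starting tree")
    if kind not in ("random", "parsimony"):
        raise ValueError(f"unknown starting-tree kind {kind!r}")
    rng = np.random.default_rng(seed)
    taxa = sorted(aln.taxa)
    order = [taxa[i] for i in rng.permutation(len(taxa))]

    root = Node()
    for label in order[:3]:
        root.add_child(Node(label=label))
    tree = Tree(root)
    patterns = site_patterns(aln) if kind == "parsimony" else None

    for label in order[3:]:
        edges = [n for n in tree.postorder() if n is not tree.root]
        leaf = Node(label=label)
        if kind == "random":
            target = edges[int(rng.integers(len(edges)))]
            _insert_leaf(target, leaf)
        else:
            best_target, best_score = None, np.inf
            for target in edges:
                joint = _insert_leaf(target, leaf)
                score = _fitch_score(tree, patterns)
                _remove_insertion(joint, target)
                if score < best_score:
                    best_target, best_score = target, score
            _insert_leaf(best_target, leaf)

    for node in tree.postorder():
        if node.parent is not None:
            node.length = 0.1
    return tree


# ---------------------------------------------------------------------------
# tree rearrangements
# ---------------------------------------------------------------------------


def _swap_nodes(x: Node, y: Node) -> None:
    px, py = x.parent, y.parent
    ix, iy = px.children.index(x), py.children.index(y)
    px.children[ix], py.children[iy] = y, x
    x.parent, y.parent = py, px


def _nni_moves(tree: Tree) -> list:
    """Enumerate NNI moves as (postorder position of the internal edge's
    child node, index of the swapped child of v, index of the swapped
    neighbor within the parent's children)."""
    nodes = list(tree.postorder())
    moves = []
    for pos, node in enumerate(nodes):
        if node.is_leaf or node is tree.root or len(node.children) != 2:
            continue
        parent = node.parent
        v_idx = parent.children.index(node)
        others = [j for j in range(len(parent.children)) if j != v_idx]
        if len(others) == 1:
            moves.append((pos, 0, others[0]))
            moves.append((pos, 1, others[0]))
        else:  # parent is the (degree >= 3) root
            moves.append((pos, 1, others[0]))
            moves.append((pos, 1, others[1]))
    return moves


def _apply_nni(tree: Tree, move) -> tuple[Tree, list]:
    pos, child_idx, other_idx = move
    cand = tree.copy()
    nodes = list(cand.postorder())
    v = nodes[pos]
    _swap_nodes(v.children[child_idx], v.parent.children[other_idx])
    return cand, [v]


def _subtree_positions(nodes: list) -> list[set]:
    pos = {id(n): i for i, n in enumerate(nodes)}
    below = [None] * len(nodes)
    for i, n in enumerate(nodes):
        s = {i}
        for c in n.children:
            s |= below[pos[id(c)]]
        below[i] = s
    return below


def _spr_moves(tree: Tree) -> list:
    """Enumerate SPR moves as (prune position, graft position) pairs over the
    postorder node list; regrafts inside the pruned subtree or adjacent to
    the original attachment are excluded."""
    nodes = list(tree.postorder())
    below = _subtree_positions(nodes)
    pos = {id(n): i for i, n in enumerate(nodes)}
    moves = []
    for i, v in enumerate(nodes):
        if v is tree.root:
            continue
        parent = v.parent
        if parent is tree.root and len(parent.children) <= 2:
            continue
        excluded = set(below[i])
        excluded.add(pos[id(parent)])
        for sib in parent.children:
            excluded.add(pos[id(sib)])
        for j, u in enumerate(nodes):
            if u is tree.root or j in excluded:
                continue
            moves.append((i, j))
    return moves


def _apply_spr(tree: Tree, move) -> Optional[tuple[Tree, list]]:
    prune_pos, graft_pos = move
    cand = tree.copy()
    nodes = list(cand.postorder())
    v, u = nodes[prune_pos], nodes[graft_pos]
    parent = v.parent

    parent.children.remove(v)
    v.parent = None
    if parent is cand.root:
        if len(parent.children) == 2:
            a, b = parent.children
            keep, move_child = (a, b) if not a.is_leaf else (b, a)
            if keep.is_leaf:
                return None
            move_child.length = (move_child.length or 0.0) + (keep.length or 0.0)
            keep.add_child(move_child)
            keep.parent = None
            keep.length = None
            cand.root = keep
            if u is keep:
                u = move_child
    elif len(parent.children) == 1:
        only = parent.children[0]
        only.length = (only.length or 0.0) + (parent.length or 0.0)
        grand = parent.parent
        grand.children[grand.children.index(parent)] = only
        only.parent = grand
        if u is parent:  # pragma: no cover - excluded by enumeration
            u = only

    half = (u.length or 0.0) / 2.0
    joint = Node(length=half)
    grand = u.parent
    grand.children[grand.children.index(u)] = joint
    joint.parent = grand
    u.length = half
    joint.add_child(u)
    joint.add_child(v)
    return cand, [joint, v]


# ---------------------------------------------------------------------------
# heuristic search
# ---------------------------------------------------------------------------


def _evaluate_candidate(
    cand: Tree,
    changed: list,
    patterns: SitePatterns,
    model: GTRModel,
    config: SearchConfig,
) -> float:
    """Log-likelihood (in the configured summation mode) of a candidate tree
    after re-optimizing the lengths of the edges touched by the move."""
    kern = _Kernel(
        cand,
        patterns,
        model,
        min_bl=config.min_branch_length,
        max_bl=config.max_branch_length,
        xatol=config.bl_xatol,
    )
    cache = kern._down()
    down, slog, C = cache
    pat = None
    for node in changed:
        i = kern.index[id(node)]
        A_i, alog_i = kern._edge_outer(i, down, slog, C)
        _, pat = kern.optimize_edge(i, A_i, alog_i, down[i], slog[i])
    if len(changed) > 1:
        pat = kern.pattern_logls()  # refresh after multi-edge updates
    kern.apply_lengths()
    return combine_site_logls(pat, patterns, config.summation_mode)


def _climb(
    tree: Tree,
    patterns: SitePatterns,
    model: GTRModel,
    config: SearchConfig,
) -> tuple[Tree, float]:
    """Hill-climb from a starting tree: first-improvement over the move set,
    accepting strictly improving moves; branch lengths are fully re-optimized
    after substantial gains and once more at the end."""

    def opt(t: Tree, max_sweeps: int) -> tuple[Tree, float]:
        kern = _Kernel(
            t,
            patterns,
            model,
            min_bl=config.min_branch_length,
            max_bl=config.max_branch_length,
            xatol=config.bl_xatol,
        )
        kern.optimize_all(config.epsilon, max_sweeps, warn_cap=False)
        kern.apply_lengths()
        return t, combine_site_logls(
            kern.pattern_logls(), patterns, config.summation_mode
        )

    tree, cur = opt(tree, config.max_sweeps)
    enumerate_moves = _nni_moves if config.moves == "nni" else _spr_moves
    apply_move = _apply_nni if config.moves == "nni" else _apply_spr

    for _ in range(config.max_rounds):
        accepted = False
        for move in enumerate_moves(tree):
            applied = apply_move(tree, move)
            if applied is None:
                continue
            cand, changed = applied
            cand_logl = _evaluate_candidate(cand, changed, patterns, model, config)
            if cand_logl > cur:
                if cand_logl - cur > config.epsilon:
                    # worthwhile move: cheap length re-fit before continuing
                    cand, cand_logl = opt(cand, 1)
                tree, cur = cand, cand_logl
                accepted = True
                break
        if not accepted:
            break
    tree, cur = opt(tree, config.max_sweeps)
    return tree, cur


def heuristic_search(aln: Alignment, model: GTRModel, config: SearchConfig) -> SearchResult:
    """Multi-start ML search: parsimony and random starting trees, strict
    hill-climbing over NNI or SPR, deterministic given the config.

    The best start is the one with the highest log-likelihood (in the
    configured summation mode); starts within epsilon of the maximum are
    tie-broken by the lexicographically smallest canonical topology.
    """
    patterns = site_patterns(aln)
    n_pars = config.parsimony_starts
    kinds = ["parsimony"] * n_pars + ["random"] * (config.n_searches - n_pars)

    start_trees, start_logls = [], []
    for s_idx, kind in enumerate(kinds):
        seed = np.random.SeedSequence([config.seed, 0, s_idx])
        start = generate_starting_tree(aln, kind, seed)
        tree, logl = _climb(start, patterns, model, config)
        start_trees.append(tree)
        start_logls.append(logl)

    best_logl = max(start_logls)
    contenders = [
        (topology_key(t), i)
        for i, (t, l) in enumerate(zip(start_trees, start_logls))
        if l >= best_logl - config.epsilon
    ]
    _, best_i = min(contenders)
    log = dict(config.run_log())
    log.update(
        n_patterns=patterns.n_patterns,
        n_sites=patterns.n_sites,
        start_kinds=kinds,
        start_logls=list(start_logls),
        best_start=best_i,
    )
    return SearchResult(
        best_tree=start_trees[best_i],
        best_logl=start_logls[best_i],
        start_trees=start_trees,
        start_logls=start_logls,
        config=config,
        log=log,
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(
    aln: Alignment,
    model: GTRModel,
    config: SearchConfig,
    n_replicates: int = 100,
    ml_tree: Optional[Tree] = None,
) -> Tree:
    """Standard nonparametric bootstrap: resample columns, re-search each
    replicate by NNI starting from the ML tree, and annotate each internal
    edge of the ML tree with the percentage of replicate trees containing its
    bipartition. Deterministic given the config seed."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if ml_tree is None:
        ml_tree = heuristic_search(aln, model, config).best_tree
    mat = aln.matrix()
    L = aln.length
    counts: dict = {}
    rep_config = replace(config, n_searches=1, moves="nni")
    for b in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, b]))
        idx = rng.integers(0, L, L)
        rep_aln = Alignment(
            taxa=list(aln.taxa),
            seqs=[row.tobytes().decode() for row in mat[:, idx]],
        )
        rep_patterns = site_patterns(rep_aln)
        rep_tree, _ = _climb(ml_tree.copy(), rep_patterns, model, rep_config)
        for bip in bipartition_table(rep_tree).nontrivial:
            counts[bip] = counts.get(bip, 0) + 1

    out = ml_tree.copy()
    leaf_set = frozenset(out.leaf_names())

    def _leaves_below(node):
        if node.is_leaf:
            return frozenset([node.label])
        return frozenset().union(*(_leaves_below(c) for c in node.children))

    from .tree import Bipartition

    for node in out.postorder():
        if node.is_leaf or node is out.root:
            continue
        side = _leaves_below(node)
        if min(len(side), len(leaf_set - side)) < 2:
            continue
        bip = Bipartition.from_side(side, leaf_set)
        node.support = 100.0 * counts.get(bip, 0) / n_replicates
    out.support_scale = "percent"
    return out


# ---------------------------------------------------------------------------
# AU test
# ---------------------------------------------------------------------------

_AU_SCALES = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4)


def au_test(
    aln: Alignment,
    model: GTRModel,
    trees: Sequence[Tree],
    *,
    scales: tuple = _AU_SCALES,
    n_resamples: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    optimize: bool = True,
    epsilon: float = 1e-4,
) -> AuTestResult:
    """Approximately-unbiased topology test via multiscale RELL bootstrap.

    Per-site log-likelihood vectors (after per-topology branch-length
    optimization) are resampled at each scale r; the acceptance probability
    of each topology is fit on the probit scale against sqrt(r) to estimate
    the signed-distance and curvature terms, giving an AU p-value per tree.
    If all supplied trees share one topology the test is not applicable.
    """
    keys = [topology_key(t) for t in trees]
    if len(set(keys)) < 2:
        return AuTestResult(
            applicable=False,
            p_values=None,
            significant=None,
            n_resamples=n_resamples,
            scales=tuple(scales),
        )

    unique_keys = sorted(set(keys))
    rep_index = {k: keys.index(k) for k in unique_keys}
    site_lls = []
    for k in unique_keys:
        t = trees[rep_index[k]]
        if optimize:
            t = optimize_branch_lengths(t, aln, model, epsilon)
        site_lls.append(per_site_log_likelihoods(t, aln, model))
    S = np.array(site_lls)  # (n_unique, L)
    n_unique, L = S.shape

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    bp = np.zeros((n_unique, len(scales)))
    for si, r in enumerate(scales):
        m = max(1, int(round(r * L)))
        counts = rng.multinomial(m, np.full(L, 1.0 / L), size=n_resamples)
        totals = counts @ S.T  # (B, n_unique)
        ties = totals == totals.max(axis=1, keepdims=True)
        bp[:, si] = (ties / ties.sum(axis=1, keepdims=True)).mean(axis=0)

    sq = np.sqrt(np.asarray(scales, dtype=float))
    X = np.column_stack([sq, 1.0 / sq])
    p_unique = np.empty(n_unique)
    eps_bp = 0.5 / n_resamples
    for t_i in range(n_unique):
        row = bp[t_i]
        if np.all(row >= 1 - eps_bp):
            p_unique[t_i] = 1.0
            continue
        if np.all(row <= eps_bp):
            p_unique[t_i] = 0.0
            continue
        clipped = np.clip(row, eps_bp, 1 - eps_bp)
        z = norm.ppf(1 - clipped)
        w = n_resamples * norm.pdf(z) ** 2 / (clipped * (1 - clipped))
        XtW = X.T * w
        d, c = np.linalg.solve(XtW @ X, XtW @ z)
        p_unique[t_i] = float(1 - norm.cdf(d - c))

    key_to_p = dict(zip(unique_keys, p_unique))
    p_values = np.array([key_to_p[k] for k in keys])
    return AuTestResult(
        applicable=True,
        p_values=p_values,
        significant=p_values <= alpha,
        n_resamples=n_resamples,
        scales=tuple(scales),
    )
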