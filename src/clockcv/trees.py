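"""Rooted time-trees, substitution trees and branch-rate maps.

Two tree flavours are used throughout the package:

* :class:`TimeTree` — a *chronogram*: a rooted binary tree whose node
  heights are ages in years before the most recent sampled tip.
* :class:`SubstTree` — a *phylogram*: the same shape with branch lengths
  in expected substitutions per site.

Both are stored as flat index arrays (tips ``0..n-1``, internal nodes
``n..2n-2``) so the likelihood engine and the MCMC can operate on them
without object traversal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np

__all__ = [
    "TimeTree",
    "SubstTree",
    "BranchRateMap",
    "TreeError",
    "NewickParseError",
    "parse_newick",
    "write_newick",
]


class TreeError(ValueError):
    """A structural or age-ordering invariant was violated."""


class NewickParseError(ValueError):
    """Malformed Newick input; carries the offending position when known."""


def _validate_topology(n_tips: int, parent: np.ndarray) -> tuple[np.ndarray, int]:
    """Check single-root binary structure; return (children[n_tips-1, 2], root)."""
    n_nodes = 2 * n_tips - 1
    if parent.shape != (n_nodes,):
        raise TreeError(
            f"parent array has shape {parent.shape}, expected ({n_nodes},)"
        )
    roots = np.flatnonzero(parent < 0)
    if len(roots) != 1:
        raise TreeError(f"tree must have exactly one root, found {len(roots)}")
    root = int(roots[0])
    if root < n_tips:
        raise TreeError("root must be an internal node")
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for node in range(n_nodes):
        p = parent[node]
        if p >= 0:
            children[p].append(node)
    child_arr = np.full((n_tips - 1, 2), -1, dtype=np.int64)
    for node in range(n_tips, n_nodes):
        kids = children[node]
        if len(kids) != 2:
            raise TreeError(
                f"internal node {node} has {len(kids)} children; trees must be binary"
            )
        child_arr[node - n_tips] = kids
    for tip in range(n_tips):
        if children[tip]:
            raise TreeError(f"tip {tip} has children")
    return child_arr, root


def _postorder(n_tips: int, children: np.ndarray, root: int) -> np.ndarray:
    """Internal nodes ordered children-before-parents (iterative DFS)."""
    order: list[int] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node >= n_tips:
            order.append(node)
            stack.extend(children[node - n_tips])
    order.reverse()
    return np.asarray(order, dtype=np.int64)


class _BaseTree:
    """Shared topology plumbing for TimeTree / SubstTree."""

    tip_names: list[str]
    parent: np.ndarray
    children: np.ndarray  # (n_tips-1, 2), row i -> internal node n_tips+i
    root: int

    def _init_topology(self, tip_names: Sequence[str], parent) -> None:
        self.tip_names = [str(t) for t in tip_names]
        if len(set(self.tip_names)) != len(self.tip_names):
            raise TreeError("tip names must be unique")
        if len(self.tip_names) < 2:
            raise TreeError("a tree needs at least 2 tips")
        self.parent = np.asarray(parent, dtype=np.int64).copy()
        self.children, self.root = _validate_topology(self.n_tips, self.parent)
        self.postorder = _postorder(self.n_tips, self.children, self.root)

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    def children_of(self, node: int) -> np.ndarray:
        return self.children[node - self.n_tips]

    def same_topology(self, other: "_BaseTree") -> bool:
        """Shape-and-labels isomorphism via canonical clade sets."""
        return self._clade_set() == other._clade_set()

    def _clade_set(self) -> frozenset[frozenset[str]]:
        clades: dict[int, frozenset[str]] = {
            i: frozenset([name]) for i, name in enumerate(self.tip_names)
        }
        for node in self.postorder:
            a, b = self.children_of(node)
            clades[node] = clades[a] | clades[b]
        return frozenset(clades.values())


class TimeTree(_BaseTree):
    """Rooted binary chronogram with node ages in years.

    Ages are measured backwards from the most recent tip (age 0).  Tip
    calendar dates, when known, are decimal years; internally only the
    age offsets matter.

    Parameters
    ----------
    tip_names : ordered tip labels.
    parent : int array of length ``2n-1``; ``parent[root] == -1``.
    age : float array of node ages (years before most recent tip).
    tip_dates : optional decimal-year sampling date per tip.
    allow_zero_branches : permit zero-duration branches (test scaffolding
        only; real chronograms require strictly positive durations).
    """

    def __init__(
        self,
        tip_names: Sequence[str],
        parent,
        age,
        tip_dates: Optional[Sequence[float]] = None,
        allow_zero_branches: bool = False,
    ):
        self._init_topology(tip_names, parent)
        self.age = np.asarray(age, dtype=float).copy()
        if self.age.shape != (self.n_nodes,):
            raise TreeError("age array has wrong shape")
        if not np.all(np.isfinite(self.age)):
            raise TreeError("node ages must be finite")
        self.tip_dates = None
        if tip_dates is not None:
            self.tip_dates = np.asarray(tip_dates, dtype=float).copy()
            if self.tip_dates.shape != (self.n_tips,):
                raise TreeError("tip_dates length must equal number of tips")
        self._check_ages(allow_zero_branches)

    def _check_ages(self, allow_zero: bool) -> None:
        for node in range(self.n_nodes):
            p = self.parent[node]
            if p < 0:
                continue
            dur = self.age[p] - self.age[node]
            if dur < 0 or (dur == 0 and not allow_zero):
                raise TreeError(
                    f"parent age {self.age[p]} not greater than child age "
                    f"{self.age[node]} at node {node}"
                )
        if abs(self.age[self.root] - self.age.max()) > 0:
            raise TreeError("root must be the oldest node")

    @property
    def root_age(self) -> float:
        return float(self.age[self.root])

    def branch_durations(self) -> np.ndarray:
        """Per-node duration of the branch above it (root entry is 0)."""
        dur = np.zeros(self.n_nodes)
        mask = self.parent >= 0
        dur[mask] = self.age[self.parent[mask]] - self.age[mask]
        return dur

    def to_subst_tree(self, rates: "BranchRateMap") -> "SubstTree":
        """Multiply branch durations by rates -> phylogram."""
        if rates.rate.shape != (self.n_nodes,):
            raise TreeError("rate map does not match tree size")
        blen = self.branch_durations() * rates.rate
        return SubstTree(self.tip_names, self.parent, blen)

    def copy(self) -> "TimeTree":
        return TimeTree(
            self.tip_names,
            self.parent,
            self.age,
            self.tip_dates,
            allow_zero_branches=True,
        )


class SubstTree(_BaseTree):
    """Rooted binary phylogram: branch lengths in substitutions/site.

    ``branch_length[node]`` is the length of the branch above ``node``;
    the root entry is ignored (kept 0).
    """

    def __init__(self, tip_names: Sequence[str], parent, branch_length):
        self._init_topology(tip_names, parent)
        self.branch_length = np.asarray(branch_length, dtype=float).copy()
        if self.branch_length.shape != (self.n_nodes,):
            raise TreeError("branch_length array has wrong shape")
        self.branch_length[self.root] = 0.0
        if not np.all(np.isfinite(self.branch_length)):
            raise TreeError("branch lengths must be finite")
        if np.any(self.branch_length < 0):
            raise TreeError("branch lengths must be non-negative")


@dataclass
class BranchRateMap:
    """Per-branch substitution rate (subs/site/year).

    ``rate[node]`` applies to the branch above ``node``; the root entry
    is unused but kept for alignment with the node arrays.
    """

    rate: np.ndarray
    clock_kind: str = "SC"

    def __post_init__(self):
        self.rate = np.asarray(self.rate, dtype=float)
        if self.clock_kind not in ("SC", "UCLN", "UCED"):
            raise ValueError(f"unknown clock kind {self.clock_kind!r}")
        # the root carries no branch; only off-root entries must be positive
        if self.rate.size and np.any(self.rate <= 0):
            raise ValueError("branch rates must be strictly positive")
        if self.clock_kind == "SC" and self.rate.size:
            if not np.allclose(self.rate, self.rate.flat[0]):
                raise ValueError("SC clock requires all branch rates equal")


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str, kind: str = "time", allow_zero_branches: bool = True):
    """Parse a Newick string into a :class:`TimeTree` or :class:`SubstTree`.

    Branch lengths are interpreted as durations in years (``kind="time"``,
    tip offsets become ages) or expected substitutions per site
    (``kind="subst"``).  ``[&rate=x]`` branch annotations, when present on
    every non-root branch, are attached to the returned tree as a
    :class:`BranchRateMap` under ``tree.branch_rates``.
    """
    if kind not in ("time", "subst"):
        raise ValueError("kind must be 'time' or 'subst'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            extract_comment_metadata=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        pos = ""
        col = getattr(exc, "col_num", None)
        if col is not None:
            pos = f" at column {col}"
        raise NewickParseError(f"malformed Newick{pos}: {exc}") from exc

    leaves = [lf for lf in dtree.leaf_node_iter()]
    n_tips = len(leaves)
    if n_tips < 2:
        raise NewickParseError("tree must have at least 2 tips")
    for nd in dtree.preorder_node_iter():
        kids = nd.child_nodes()
        if kids and len(kids) != 2:
            raise TreeError(
                f"non-binary node with {len(kids)} children is not supported"
            )

    tip_names = sorted(lf.taxon.label for lf in leaves)
    index = {}
    for lf in leaves:
        index[id(lf)] = tip_names.index(lf.taxon.label)
    next_internal = n_tips
    for nd in dtree.postorder_node_iter():
        if nd.child_nodes():
            index[id(nd)] = next_internal
            next_internal += 1

    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    length = np.zeros(n_nodes)
    rate = np.full(n_nodes, np.nan)
    for nd in dtree.preorder_node_iter():
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise NewickParseError("branch lengths are required")
            length[i] = float(nd.edge.length)
        ann = nd.annotations.get_value("rate")
        if ann is not None:
            rate[i] = float(ann)

    root = index[id(dtree.seed_node)]
    rates = None
    off_root = np.arange(n_nodes) != root
    if np.all(np.isfinite(rate[off_root])):
        rate[root] = np.nanmean(rate[off_root])  # placeholder, unused
        sc = bool(np.allclose(rate[off_root], rate[off_root][0]))
        rates = BranchRateMap(rate, clock_kind="SC" if sc else "UCLN")

    if kind == "subst":
        tree: TimeTree | SubstTree = SubstTree(tip_names, parent, length)
    else:
        # depth from root -> age = max depth - depth
        depth = np.zeros(n_nodes)
        order = _postorder(n_tips, _validate_topology(n_tips, parent)[0], root)
        for node in order[::-1]:
            for child in np.flatnonzero(parent == node):
                depth[child] = depth[node] + length[child]
        age = depth.max() - depth
        tree = TimeTree(
            tip_names, parent, age, allow_zero_branches=allow_zero_branches
        )
    tree.branch_rates = rates
    return tree


def _format_length(x: float) -> str:
    return np.format_float_positional(
        x, precision=10, unique=False, fractional=False, trim="0"
    )


def write_newick(tree, rates: Optional[BranchRateMap] = None) -> str:
    """Serialize a tree deterministically.

    Children are ordered lexicographically by their smallest descendant
    tip name, so topologically identical trees always produce
    byte-identical strings.  Rates, if given, are written as
    ``[&rate=x]`` branch annotations.
    """
    if isinstance(tree, TimeTree):
        length = tree.branch_durations()
    else:
        length = tree.branch_length

    min_tip: dict[int, str] = {
        i: name for i, name in enumerate(tree.tip_names)
    }
    for node in tree.postorder:
        a, b = tree.children_of(node)
        min_tip[node] = min(min_tip[a], min_tip[b])

    def annot(node: int) -> str:
        if rates is None or node == tree.root:
            return ""
        return f"[&rate={_format_length(rates.rate[node])}]"

    def render(node: int) -> str:
        if node < tree.n_tips:
            label = tree.tip_names[node]
        else:
            a, b = sorted(tree.children_of(node), key=lambda c: min_tip[c])
            label = f"({render(a)},{render(b)})"
        blen = length[node] if node != tree.root else 0.0
        return f"{label}{annot(node)}:{_format_length(blen)}"

    return render(tree.root) + ";"
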