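"""Time-calibrated (ultrametric) trees and the manipulations the rate tests need.

A :class:`Chronogram` wraps a rooted dendropy tree whose branch lengths are in
units of time (Ma by convention; the present is age 0 and node ages increase
toward the root).  On construction the tree is validated: branch lengths must
be present, tips must be contemporaneous within a relative tolerance, and every
internal node must be strictly older than its children.  All downstream
statistics consume either branching times (descending internal-node ages) or
internode intervals (the durations g_k spent with exactly k lineages).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "Chronogram",
    "InternodeIntervals",
    "TreeParseError",
    "TreeValidationError",
    "NotUltrametricError",
    "parse_tree",
    "read_trees",
    "branching_times",
    "internode_intervals",
    "truncate_recent",
    "prune_random",
    "extract_clade",
]


class TreeParseError(ValueError):
    """Malformed Newick/NEXUS input."""


class TreeValidationError(ValueError):
    """Structurally valid tree that violates chronogram requirements."""


class NotUltrametricError(TreeValidationError):
    """Tip ages differ beyond tolerance."""


_PLAIN_LABEL = re.compile(r"[A-Za-z0-9_.\-|]+\Z")


def _fmt_label(label: str) -> str:
    if _PLAIN_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


@dataclass(frozen=True)
class InternodeIntervals:
    """Durations g_k (k = 2..n) during which exactly k lineages exist.

    ``g[0]`` is the time spent with 2 lineages; ``g[-1]`` (g_n) runs from the
    last split to the present.  ``sum(g)`` equals the root age and
    ``T = sum(k * g_k)`` is the total lineage-time of the reconstructed tree.
    """

    g: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.g, dtype=float)
        if g.ndim != 1 or g.size < 1:
            raise ValueError("need at least one interval (n >= 2)")
        if np.any(g < 0):
            raise ValueError("negative internode interval")
        object.__setattr__(self, "g", g)

    @property
    def n(self) -> int:
        return self.g.size + 1

    @property
    def root_age(self) -> float:
        return float(self.g.sum())

    @property
    def k(self) -> np.ndarray:
        return np.arange(2, self.n + 1)

    @property
    def T(self) -> float:
        """Total lineage-time sum(k * g_k), k = 2..n."""
        return float(np.dot(self.k, self.g))

    def branching_times(self) -> np.ndarray:
        """Recover the descending vector of internal-node ages."""
        ages = self.root_age - np.cumsum(self.g)
        return np.concatenate([[self.root_age], ages[:-1]])

    @classmethod
    def from_branching_times(cls, t) -> "InternodeIntervals":
        t = np.asarray(t, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("need at least one branching time")
        if np.any(t <= 0):
            raise ValueError("branching times must be strictly positive")
        if np.any(np.diff(t) > 1e-12 * t[0]):
            raise ValueError("branching times must be non-increasing")
        g = np.empty(t.size)
        g[:-1] = t[:-1] - t[1:]
        g[-1] = t[-1]
        g[g < 0] = 0.0
        return cls(g)


class Chronogram:
    """Rooted ultrametric tree with node ages in time units (Ma).

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree with branch lengths on every non-root edge.
    rtol : float
        Relative ultrametricity tolerance: tip ages must equal 0 within
        ``rtol * root_age``.  Chronograms summarised from MCMC output carry
        rounding error, hence a tolerance rather than exact equality.
    """

    def __init__(self, tree: dendropy.Tree, rtol: float = 1e-6):
        self._tree = tree
        self.rtol = float(rtol)
        self._index_and_validate()

    # ------------------------------------------------------------------ io

    @classmethod
    def from_string(cls, text: str, schema: str = "newick", rtol: float = 1e-6) -> "Chronogram":
        if schema not in ("newick", "nexus"):
            raise ValueError(f"unsupported schema {schema!r}")
        try:
            tree = dendropy.Tree.get(
                data=text, schema=schema, suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises a zoo of DataError subclasses
            raise TreeParseError(f"could not parse {schema} input: {exc}") from exc
        return cls(tree, rtol=rtol)

    @classmethod
    def from_newick(cls, text: str, rtol: float = 1e-6) -> "Chronogram":
        return cls.from_string(text, "newick", rtol=rtol)

    @classmethod
    def from_file(cls, path, schema: str = "newick", rtol: float = 1e-6) -> "Chronogram":
        with open(path) as fh:
            return cls.from_string(fh.read(), schema, rtol=rtol)

    def to_newick(self, digits: int = 6) -> str:
        """Serialise as plain Newick with ``digits`` significant digits."""

        def rec(node) -> str:
            if node.is_leaf():
                return _fmt_label(node.taxon.label)
            parts = []
            for child in node.child_nodes():
                blen = node.age - child.age
                parts.append(f"{rec(child)}:{blen:.{digits}g}")
            return "(" + ",".join(parts) + ")"

        return rec(self._root) + ";"

    # ---------------------------------------------------------- validation

    def _index_and_validate(self):
        t = self._tree
        root = t.seed_node
        # collapse a unary chain at the root (a stem edge carries no information)
        while len(root.child_nodes()) == 1:
            root = root.child_nodes()[0]
        self._root = root

        leaves = []
        for leaf in root.leaf_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeValidationError("unlabeled tip")
            leaves.append(leaf)
        if len(leaves) < 2:
            raise TreeValidationError("a chronogram needs at least 2 tips")
        labels = [lf.taxon.label for lf in leaves]
        if len(set(labels)) != len(labels):
            raise TreeValidationError("duplicate tip labels")

        # depths from the (effective) root; root's own edge length is ignored
        root.depth = 0.0
        for node in root.preorder_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise TreeValidationError(
                    "missing branch length on edge above "
                    + (node.taxon.label if node.is_leaf() else "an internal node")
                )
            if node.edge.length < 0:
                raise TreeValidationError("negative branch length")
            node.depth = node.parent_node.depth + node.edge.length

        root_age = max(lf.depth for lf in leaves)
        if root_age <= 0:
            raise TreeValidationError("root age must be > 0 (all branch lengths zero?)")
        tol = self.rtol * root_age
        worst = max(abs(lf.depth - root_age) for lf in leaves)
        if worst > tol:
            raise NotUltrametricError(
                f"tip ages differ by up to {worst:.6g} (> tolerance {tol:.6g}); "
                "not an ultrametric chronogram"
            )

        internal = []
        for node in root.postorder_iter():
            if node.is_leaf():
                node.age = 0.0
                node.tipset = frozenset([node.taxon.label])
                node.first_tip = node.taxon.label
            else:
                node.age = root_age - node.depth if node is not root else root_age
                kids = node.child_nodes()
                node.tipset = frozenset().union(*(c.tipset for c in kids))
                node.first_tip = min(c.first_tip for c in kids)
                for c in kids:
                    if not c.is_leaf() and c.age >= node.age:
                        raise TreeValidationError(
                            "internal node not strictly older than its child "
                            "(zero or negative internal edge)"
                        )
                node.support = None
                if node.label is not None:
                    try:
                        node.support = float(node.label)
                    except ValueError:
                        pass
                internal.append(node)
        root.age = root_age

        internal.sort(key=lambda nd: (-nd.age, sorted(nd.tipset)))
        for i, nd in enumerate(internal):
            nd.cindex = i
        self._internal = internal
        self._leaves = sorted(leaves, key=lambda lf: lf.taxon.label)
        self._leaf_by_label = {lf.taxon.label: lf for lf in self._leaves}
        self.root_age = float(root_age)
        self.n = len(leaves)

    # ---------------------------------------------------------- properties

    @property
    def tip_labels(self) -> tuple:
        return tuple(lf.taxon.label for lf in self._leaves)

    @property
    def tips(self) -> frozenset:
        return self._root.tipset

    @property
    def internal_nodes(self) -> list:
        """Internal nodes ordered by decreasing age (ties by tip set)."""
        return list(self._internal)

    @property
    def root(self):
        return self._root

    @property
    def is_binary(self) -> bool:
        return all(len(nd.child_nodes()) == 2 for nd in self._internal)

    def require_binary(self, what: str = "this statistic"):
        if not self.is_binary:
            raise TreeValidationError(
                f"{what} requires a fully binary tree; resolve polytomies first"
            )

    def node_by_index(self, cindex: int):
        return self._internal[cindex]

    def clade_tips(self, node) -> tuple:
        return tuple(sorted(node.tipset))

    def edge_lengths(self) -> np.ndarray:
        """Lengths of all edges below the root (2n-2 for a binary tree)."""
        out = []
        for node in self._root.preorder_iter():
            if node is self._root:
                continue
            out.append(node.parent_node.age - node.age)
        return np.asarray(out)

    # ---------------------------------------------------------- statistics

    def branching_times(self) -> np.ndarray:
        """Descending internal-node ages, length n-1 (binary trees only)."""
        self.require_binary("branching times")
        ages = np.array([nd.age for nd in self._internal])
        return np.sort(ages)[::-1]

    def internode_intervals(self) -> InternodeIntervals:
        return InternodeIntervals.from_branching_times(self.branching_times())

    def mrca(self, tips):
        tips = list(tips)
        unknown = [t for t in tips if t not in self._leaf_by_label]
        if unknown:
            raise KeyError(f"unknown tips: {', '.join(sorted(unknown))}")
        if not tips:
            raise ValueError("empty tip set")
        target = set(tips)
        node = self._leaf_by_label[tips[0]]
        while not target.issubset(node.tipset):
            node = node.parent_node
        return node

    # ------------------------------------------------------- manipulations

    def _induced_newick(self, keep) -> str:
        """Full-precision Newick of the subtree induced on the kept tips."""

        def rec(node):
            if node.is_leaf():
                if node.taxon.label in keep:
                    return _fmt_label(node.taxon.label), 0.0
                return None
            alive = [r for r in (rec(c) for c in node.child_nodes()) if r is not None]
            if not alive:
                return None
            if len(alive) == 1:
                return alive[0]
            parts = [f"{s}:{node.age - a:.17g}" for s, a in alive]
            return "(" + ",".join(parts) + ")", node.age

        res = rec(self._root)
        if res is None:
            raise ValueError("no tips kept")
        return res[0] + ";"

    def prune_taxa(self, drop) -> "Chronogram":
        """Remove the named tips, suppressing unary nodes (ages preserved)."""
        drop = set(drop)
        unknown = drop - set(self.tip_labels)
        if unknown:
            raise KeyError(f"unknown tips: {', '.join(sorted(unknown))}")
        keep = set(self.tip_labels) - drop
        if len(keep) < 2:
            raise ValueError("pruning must leave at least 2 tips")
        return Chronogram.from_newick(self._induced_newick(keep), rtol=self.rtol)

    def prune_random(self, m: int, seed=None) -> "Chronogram":
        """Remove ``m`` uniformly chosen tips (reproducible under ``seed``)."""
        if m < 0 or m > self.n - 2:
            raise ValueError(f"m must be in [0, n-2] = [0, {self.n - 2}]")
        if m == 0:
            return self
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        drop = rng.choice(np.array(self.tip_labels, dtype=object), size=m, replace=False)
        return self.prune_taxa(drop)

    def extract_clade(self, tips=None, node=None) -> "Chronogram":
        """Subtree rooted at ``node`` (or at the MRCA of ``tips``), ages kept."""
        if node is None:
            if tips is None:
                raise ValueError("give either tips or node")
            node = self.mrca(tips)
        if node.is_leaf():
            raise ValueError("cannot extract a clade rooted at a tip")

        def rec(nd):
            if nd.is_leaf():
                return _fmt_label(nd.taxon.label), 0.0
            parts = [
                f"{s}:{nd.age - a:.17g}" for s, a in (rec(c) for c in nd.child_nodes())
            ]
            return "(" + ",".join(parts) + ")", nd.age

        return Chronogram.from_newick(rec(node)[0] + ";", rtol=self.rtol)

    def truncate_recent(self, depth: float) -> "Chronogram":
        """Cut off the most recent ``depth`` Ma.

        Every lineage crossing the time plane at ``depth`` before present is
        collapsed to a single terminal labeled by the lexicographically first
        descendant tip; nodes younger than ``depth`` disappear.  The result is
        ultrametric with root age ``root_age - depth`` and one tip per lineage
        alive at ``depth``.
        """
        if not (0 < depth < self.root_age):
            raise ValueError(
                f"truncation depth must lie in (0, root age) = (0, {self.root_age:.6g})"
            )

        def rec(node):
            # the caller guarantees node's parent is older than `depth`
            if node.is_leaf() or node.age <= depth:
                return _fmt_label(node.first_tip), depth
            parts = [
                f"{s}:{node.age - a:.17g}" for s, a in (rec(c) for c in node.child_nodes())
            ]
            return "(" + ",".join(parts) + ")", node.age

        return Chronogram.from_newick(rec(self._root)[0] + ";", rtol=self.rtol)

    # ----------------------------------------------------------- dunders

    def __repr__(self):
        return f"<Chronogram n={self.n} root_age={self.root_age:.4g}>"


# ----------------------------------------------------------- module-level ops


def parse_tree(text: str, schema: str = "newick", rtol: float = 1e-6) -> Chronogram:
    """Parse a serialized tree (Newick or a NEXUS TREES block)."""
    return Chronogram.from_string(text, schema, rtol=rtol)


def read_trees(path, schema: str = "newick", rtol: float = 1e-6) -> list:
    """Read every tree in a file (e.g. a posterior sample) as Chronograms."""
    try:
        tl = dendropy.TreeList.get(path=str(path), schema=schema,
                                   suppress_internal_node_taxa=True)
    except Exception as exc:
        raise TreeParseError(f"could not parse {schema} file {path}: {exc}") from exc
    return [Chronogram(t, rtol=rtol) for t in tl]


def branching_times(tree: Chronogram) -> np.ndarray:
    return tree.branching_times()


def internode_intervals(bt) -> InternodeIntervals:
    """Internode intervals from branching times (array or Chronogram)."""
    if isinstance(bt, Chronogram):
        return bt.internode_intervals()
    if isinstance(bt, InternodeIntervals):
        return bt
    return InternodeIntervals.from_branching_times(bt)


def truncate_recent(tree: Chronogram, depth: float) -> Chronogram:
    return tree.truncate_recent(depth)


def prune_random(tree: Chronogram, m: int, seed=None) -> Chronogram:
    return tree.prune_random(m, seed)


def extract_clade(tree: Chronogram, tips=None, node=None) -> Chronogram:
    return tree.extract_clade(tips=tips, node=node)
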