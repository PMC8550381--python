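"""Array-backed time trees.

A :class:`TimeTree` is a rooted phylogeny with branch lengths in time units
(millions of years throughout this package).  Newick/NEXUS parsing and
serialisation are delegated to :mod:`dendropy`; internally the tree is stored
as flat parent/child/branch-length arrays so that the likelihood kernels can
traverse it cheaply.

Conventions
-----------
* node indices ``0 .. n_tips-1`` are tips, in the order tip labels are listed;
  internal nodes follow, with the root last in postorder;
* ``depth`` is measured from the root toward the present, ``height`` is time
  before present (``max tip depth - depth``);
* a tree is *ultrametric* when the spread of root-to-tip depths is at most
  ``tol`` times the maximum depth (boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TimeTree",
    "TreeParseError",
    "read_tree",
    "check_ultrametric",
]


class TreeParseError(ValueError):
    """Raised when tree text cannot be interpreted as a valid time tree."""


@dataclass
class TimeTree:
    """Rooted phylogeny with branch lengths, stored as flat arrays.

    Parameters
    ----------
    parent
        ``parent[i]`` is the index of node ``i``'s parent, ``-1`` for the root.
    brlen
        Branch length subtending each node (ignored for the root).
    labels
        Tip labels for nodes ``0..n_tips-1``; internal labels optional.
    n_tips
        Number of tips (first ``n_tips`` indices).
    """

    parent: np.ndarray
    brlen: np.ndarray
    labels: list
    n_tips: int
    _children: list = field(default=None, repr=False, compare=False)
    _postorder: np.ndarray = field(default=None, repr=False, compare=False)
    _depth: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.brlen = np.asarray(self.brlen, dtype=float)
        n = self.parent.size
        if self.brlen.size != n:
            raise ValueError("parent and brlen length mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeParseError(f"expected exactly one root, found {roots.size}")
        if len(self.labels) < self.n_tips:
            raise ValueError("fewer labels than tips")
        tips = self.labels[: self.n_tips]
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeParseError(f"duplicate tip labels: {dup}")
        if np.any(self.brlen[np.arange(n) != roots[0]] < 0):
            raise TreeParseError("negative branch length")

    # ------------------------------------------------------------------
    # derived structure (cached)
    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def tip_labels(self) -> list:
        return list(self.labels[: self.n_tips])

    @property
    def children(self) -> list:
        if self._children is None:
            ch = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._children = ch
        return self._children

    @property
    def postorder(self) -> np.ndarray:
        """Node indices, children always before parents."""
        if self._postorder is None:
            order = []
            stack = [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(self.children[v])
            self._postorder = np.asarray(order[::-1], dtype=np.int64)
        return self._postorder

    @property
    def depth(self) -> np.ndarray:
        """Distance from the root to each node."""
        if self._depth is None:
            d = np.zeros(self.n_nodes)
            for v in self.postorder[::-1]:
                p = self.parent[v]
                if p >= 0:
                    d[v] = d[p] + self.brlen[v]
            self._depth = d
        return self._depth

    @property
    def height(self) -> np.ndarray:
        """Time before present of each node (0 at the deepest tip)."""
        return self.depth[: self.n_tips].max() - self.depth

    @property
    def total_branch_length(self) -> float:
        keep = np.arange(self.n_nodes) != self.root
        return float(self.brlen[keep].sum())

    def branching_times(self) -> np.ndarray:
        """Heights of internal nodes, sorted from the root downward."""
        internal = np.arange(self.n_tips, self.n_nodes)
        return np.sort(self.height[internal])[::-1]

    # ------------------------------------------------------------------
    # I/O
    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "TimeTree":
        nodes = list(dtree.preorder_node_iter())
        tips = [v for v in nodes if v.is_leaf()]
        internals = [v for v in nodes if not v.is_leaf()]
        labels = []
        for v in tips:
            lab = v.taxon.label if v.taxon is not None else v.label
            if lab is None:
                raise TreeParseError("unlabelled tip")
            labels.append(lab)
        index = {id(v): i for i, v in enumerate(tips)}
        # internal nodes after tips, root placed anywhere (parent -1 marks it)
        for j, v in enumerate(internals):
            index[id(v)] = len(tips) + j
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        brlen = np.zeros(n)
        for v in nodes:
            i = index[id(v)]
            if v.parent_node is not None:
                parent[i] = index[id(v.parent_node)]
                if v.edge.length is None:
                    who = labels[i] if i < len(tips) else f"internal node {i}"
                    raise TreeParseError(f"missing branch length on {who}")
                brlen[i] = float(v.edge.length)
            elif v.edge.length:
                brlen[i] = float(v.edge.length)
        int_labels = [v.label for v in internals]
        return cls(parent, brlen, labels + int_labels, n_tips=len(tips))

    @classmethod
    def from_string(cls, text: str, schema: str = "newick") -> "TimeTree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema=schema, preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeParseError(f"could not parse {schema} tree: {exc}") from exc
        return cls.from_dendropy(dtree)

    @classmethod
    def from_path(cls, path, schema: str = "newick") -> "TimeTree":
        with open(path) as fh:
            return cls.from_string(fh.read(), schema=schema)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i in range(self.n_tips):
            dnodes[i].taxon = taxa.new_taxon(self.labels[i])
        for i, p in enumerate(self.parent):
            if p >= 0:
                dnodes[p].add_child(dnodes[i])
                dnodes[i].edge.length = float(self.brlen[i])
        dtree.seed_node = dnodes[self.root]
        return dtree

    def to_newick(self) -> str:
        s = self.to_dendropy().as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".12g",
        )
        return s.strip() + "\n"

    def write(self, path, schema: str = "newick") -> None:
        if schema == "newick":
            text = self.to_newick()
        else:
            text = self.to_dendropy().as_string(schema=schema)
        with open(path, "w") as fh:
            fh.write(text)

    # ------------------------------------------------------------------
    # manipulation
    # ------------------------------------------------------------------
    def prune_to(self, keep_labels) -> "TimeTree":
        """Subtree induced by ``keep_labels``, unifurcations suppressed."""
        keep = set(keep_labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValueError(f"labels not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise ValueError("need at least two tips to prune to")
        n = self.n_nodes
        n_desc = np.zeros(n, dtype=np.int64)
        for v in self.postorder:
            if v < self.n_tips:
                n_desc[v] = 1 if self.labels[v] in keep else 0
            else:
                n_desc[v] = sum(n_desc[c] for c in self.children[v])
        # nodes retained: kept tips and internal nodes with >=2 kept children-sides
        new_parent = {}
        new_brlen = {}
        # walk from each retained node up to the nearest retained ancestor
        retained = []
        for v in self.postorder:
            if v < self.n_tips:
                if n_desc[v]:
                    retained.append(v)
            else:
                kids = [c for c in self.children[v] if n_desc[c]]
                if len(kids) >= 2 or (self.parent[v] < 0 and len(kids) >= 2):
                    retained.append(v)
        rset = set(retained)
        for v in retained:
            p = self.parent[v]
            length = self.brlen[v]
            while p >= 0 and p not in rset:
                length += self.brlen[p]
                p = self.parent[p]
            new_parent[v] = p if p >= 0 else -1
            new_brlen[v] = length
        tips = [v for v in retained if v < self.n_tips]
        internals = [v for v in retained if v >= self.n_tips]
        index = {v: i for i, v in enumerate(tips)}
        index.update({v: len(tips) + j for j, v in enumerate(internals)})
        parent = np.full(len(retained), -1, dtype=np.int64)
        brlen = np.zeros(len(retained))
        for v in retained:
            i = index[v]
            p = new_parent[v]
            parent[i] = index[p] if p >= 0 else -1
            brlen[i] = new_brlen[v] if p >= 0 else 0.0
        labels = [self.labels[v] for v in tips]
        return TimeTree(parent, brlen, labels, n_tips=len(tips))

    def __eq__(self, other) -> bool:  # structural equality for tests
        if not isinstance(other, TimeTree):
            return NotImplemented
        return (
            self.n_tips == other.n_tips
            and self.tip_labels == other.tip_labels
            and np.array_equal(self.parent, other.parent)
            and np.allclose(self.brlen, other.brlen)
        )


def read_tree(text: str, schema: str = "newick") -> TimeTree:
    """Parse Newick/NEXUS text into a :class:`TimeTree`."""
    return TimeTree.from_string(text, schema=schema)


def check_ultrametric(tree: TimeTree, tol: float = 1e-6):
    """Return ``(is_ultrametric, max_deviation)``.

    The deviation is the spread of root-to-tip depths; the tree passes when
    the spread is at most ``tol`` times the maximum depth (inclusive).
    """
    d = tree.depth[: tree.n_tips]
    spread = float(d.max() - d.min())
    return spread <= tol * d.max() if d.max() > 0 else True, spread
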