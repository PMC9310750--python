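"""Rooted time-calibrated trees.

The container is a flat, array-backed rooted tree: node ``0..n-1`` with a
parent array, branch lengths in Myr, and tip labels.  Newick reading and
writing are delegated to :mod:`dendropy`; everything numerical (likelihoods,
simulation, path sampling) works directly on the arrays.  Polytomies are
accepted and preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TreeError",
    "parse_newick",
    "write_newick",
    "prune_to_taxa",
    "is_ultrametric",
]


class TreeError(ValueError):
    """Malformed Newick or invalid tree structure."""


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths in Myr.

    ``parent[i]`` is the parent index of node ``i`` (-1 for the root) and
    ``blen[i]`` the length of the branch above node ``i`` (0.0 at the root).
    ``labels[i]`` is the tip label for leaves and an optional internal label
    (metadata only) otherwise.
    """

    parent: np.ndarray
    blen: np.ndarray
    labels: list
    _children: list = field(default=None, repr=False, compare=False)
    _postorder: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.blen = np.asarray(self.blen, dtype=float)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        roots = np.flatnonzero(self.parent < 0)
        return int(roots[0])

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
    def is_tip(self) -> np.ndarray:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.parent[self.parent >= 0]] = False
        return mask

    @property
    def tips(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tips]

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    def postorder(self) -> np.ndarray:
        """Node indices, children always before parents."""
        if self._postorder is None:
            order, stack, visited = [], [self.root], []
            while stack:
                v = stack.pop()
                visited.append(v)
                stack.extend(self.children[v])
            self._postorder = np.array(visited[::-1], dtype=np.int64)
        return self._postorder

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1]

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.blen[v]
        return d

    def heights(self) -> np.ndarray:
        """Node heights above the present (= max tip depth)."""
        d = self.depths()
        return d[self.tips].max() - d

    @property
    def height(self) -> float:
        return float(self.depths()[self.tips].max())

    def total_length(self) -> float:
        return float(self.blen[self.parent >= 0].sum())

    def tip_index(self) -> dict:
        return {self.labels[i]: int(i) for i in self.tips}

    def validate(self) -> None:
        n = self.n_nodes
        if n == 0:
            raise TreeError("empty tree")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        # reachability from the root via parent walks (also rejects cycles)
        for i in range(n):
            v, hops = i, 0
            while self.parent[v] >= 0:
                v = int(self.parent[v])
                hops += 1
                if hops > n:
                    raise TreeError("cycle detected in parent mapping")
            if v != roots[0]:
                raise TreeError(f"node {i} not connected to the root")
        nonroot = self.parent >= 0
        if not np.all(np.isfinite(self.blen[nonroot])):
            raise TreeError("missing or non-finite branch length on a non-root edge")
        if np.any(self.blen[nonroot] <= 0):
            bad = np.flatnonzero(nonroot & (self.blen <= 0))
            raise TreeError(f"non-positive branch lengths at nodes {bad.tolist()}")
        labs = self.tip_labels
        if any(l is None or l == "" for l in labs):
            raise TreeError("every tip must carry a label")
        if len(set(labs)) != len(labs):
            dup = sorted({l for l in labs if labs.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), self.blen.copy(), list(self.labels))


# -- Newick I/O (via dendropy) --------------------------------------------

def _from_dendropy(dt: dendropy.Tree) -> Phylogeny:
    nodes = list(dt.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    blen = np.zeros(len(nodes))
    labels = [None] * len(nodes)
    for nd in nodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                tok = nd.taxon.label if nd.taxon else (nd.label or f"node{i}")
                raise TreeError(f"missing branch length on edge above '{tok}'")
            blen[i] = nd.edge.length
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
    return Phylogeny(parent, blen, labels)


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Raises :class:`TreeError` on malformed input, duplicate tip labels,
    missing branch lengths on non-root edges, or non-positive branch lengths.
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dt)


def write_newick(tree: Phylogeny, precision: int = 12) -> str:
    """Serialize to Newick; ``parse_newick(write_newick(t))`` reproduces ``t``."""
    parts = [None] * tree.n_nodes
    fmt = f"%.{precision}g"
    for v in tree.postorder():
        kids = tree.children[v]
        if not kids:
            s = _quote(tree.labels[v])
        else:
            s = "(" + ",".join(parts[c] for c in kids) + ")"
            if tree.labels[v]:
                s += _quote(tree.labels[v])
        if tree.parent[v] >= 0:
            s += ":" + (fmt % tree.blen[v])
        parts[v] = s
    return parts[tree.root] + ";"


def _quote(label: str) -> str:
    if any(c in label for c in "()[]{}:;,'\" \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def save_newick(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


# -- manipulation ----------------------------------------------------------

def prune_to_taxa(tree: Phylogeny, keep) -> Phylogeny:
    """Restrict the tree to the tips in ``keep``.

    Degree-2 nodes created by pruning are suppressed with their branch
    lengths summed, so root-to-tip distances of retained tips are unchanged.
    """
    keep = set(keep)
    if not keep:
        raise TreeError("keep set is empty")
    have = set(tree.tip_labels)
    missing = sorted(keep - have)
    if missing:
        raise TreeError(f"labels not in tree: {missing}")

    n = tree.n_nodes
    retain = np.zeros(n, dtype=bool)
    is_tip = tree.is_tip
    for v in tree.postorder():
        if is_tip[v]:
            retain[v] = tree.labels[v] in keep
        else:
            retain[v] = any(retain[c] for c in tree.children[v])

    # new parent mapping with unifurcation suppression, lengths summed
    new_id = {}
    parent_new, blen_new, labels_new = [], [], []

    def add(parent_idx, length, label):
        parent_new.append(parent_idx)
        blen_new.append(length)
        labels_new.append(label)
        return len(parent_new) - 1

    def build(v, acc_len, parent_idx):
        kids = [c for c in tree.children[v] if retain[c]]
        if is_tip[v] or len(kids) == 0:
            add(parent_idx, acc_len, tree.labels[v])
        elif len(kids) == 1:
            # degree-2: pass through, summing lengths (a root unifurcation is
            # also collapsed so the new root is the MRCA of the kept tips)
            build(kids[0], acc_len + tree.blen[kids[0]], parent_idx)
        else:
            me = add(parent_idx, acc_len, tree.labels[v])
            for c in kids:
                build(c, tree.blen[c], me)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * n + 100))
    try:
        build(tree.root, 0.0, None)
    finally:
        sys.setrecursionlimit(old)

    parent_arr = np.array([-1 if p is None else p for p in parent_new], dtype=np.int64)
    return Phylogeny(parent_arr, np.array(blen_new), labels_new)


def is_ultrametric(tree: Phylogeny, rel_tol: float = 1e-6) -> bool:
    """True iff all root-to-tip path lengths agree to ``rel_tol`` x height."""
    d = tree.depths()[tree.tips]
    h = d.max()
    if h == 0:
        return True
    return bool(d.max() - d.min() <= rel_tol * h)


def patristic_matrix(tree: Phylogeny):
    """Pairwise tip-to-tip path lengths (ordered by ``tip_labels``)."""
    tips = tree.tips
    d = tree.depths()
    n = len(tips)
    # ancestor sets via parent walks (fine for test-sized trees)
    paths = []
    for t in tips:
        anc, v = {}, int(t)
        while v >= 0:
            anc[v] = d[v]
            v = int(tree.parent[v])
        paths.append(anc)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            common = max(paths[i].keys() & paths[j].keys(), key=lambda v: d[v])
            out[i, j] = out[j, i] = d[tips[i]] + d[tips[j]] - 2 * d[common]
    return out
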