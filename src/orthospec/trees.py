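"""Rooted phylogenetic trees.

The basic object is :class:`PhyloTree`, a rooted tree whose leaves carry
unique string labels and whose interior vertices have outdegree at least
two (vertices with in- and outdegree one are forbidden; species trees
relax this for their distinguished root, see :mod:`orthospec.labeled`).
Edges are oriented parent-to-child: for an edge ``e = [u, v]`` the child
``v`` is below the parent ``u`` (``v < u`` in the ancestor order).

The module provides the standard primitives this kind of analysis is
built from: Newick I/O, last common ancestors, restriction to a leaf
subset (with suppression of degree-two vertices), the *displays*
relation, enumeration of the displayed rooted triples, and the cluster
(leaf-set) system of a tree.

Tree equivalence (a leaf- and root-preserving graph isomorphism) is
decided via a canonical form in which children are ordered by their
smallest descendant leaf label; the canonical Newick serialization makes
equivalence a string comparison and all outputs deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import dendropy

__all__ = [
    "PhyloTree",
    "Triple",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "lca",
    "restrict",
    "displays",
    "all_triples",
    "clusters",
]


class NewickParseError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """Input violates the phylogenetic-tree axioms."""


@dataclass(frozen=True, order=True)
class Triple:
    """Rooted triple ``((a, b), out)``: a three-leaf tree with two interior
    vertices; ``a`` and ``b`` form the cherry, ``out`` is the outgroup.

    The cherry is unordered: the constructor normalizes ``a <= b`` so that
    ``Triple('y', 'x', 'z') == Triple('x', 'y', 'z')``.
    """

    a: str
    b: str
    outgroup: str

    def __post_init__(self) -> None:
        if len({self.a, self.b, self.outgroup}) != 3:
            raise ValueError(
                f"triple labels must be pairwise distinct: "
                f"(({self.a},{self.b}),{self.outgroup})"
            )
        x, y = sorted((self.a, self.b))
        object.__setattr__(self, "a", x)
        object.__setattr__(self, "b", y)

    @property
    def cherry(self) -> frozenset:
        return frozenset((self.a, self.b))

    @property
    def labels(self) -> frozenset:
        return frozenset((self.a, self.b, self.outgroup))

    def relabel(self, mapping: Mapping[str, str]) -> "Triple":
        """Image of the triple under a label map (labels must stay distinct)."""
        return Triple(mapping[self.a], mapping[self.b], mapping[self.outgroup])

    def as_tree(self) -> "PhyloTree":
        return PhyloTree.from_nested(((self.a, self.b), self.outgroup))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"(({self.a},{self.b}),{self.outgroup})"


class PhyloTree:
    """Immutable rooted phylogenetic tree.

    Vertices are opaque integer identifiers ``0..n-1``.  Construct via
    :meth:`from_nested`, :func:`parse_newick`, or the low-level
    constructor taking a parent->children map.

    Parameters
    ----------
    children
        Map vertex -> tuple of child vertices (leaves may be omitted).
    root
        The root vertex (indegree zero).
    labels
        Map leaf vertex -> unique label string.
    lengths
        Optional map vertex -> length of the edge above that vertex.
    allow_unary_root
        Permit the root to have a single child (used by the augmented
        species tree, which carries an extra vertex above the crown).
    """

    __slots__ = (
        "_children",
        "_parent",
        "_root",
        "_labels",
        "_lengths",
        "_node_of",
        "_allow_unary_root",
        "_leafsets",
        "_depth",
        "_canon",
    )

    def __init__(
        self,
        children: Mapping[int, Sequence[int]],
        root: int,
        labels: Mapping[int, str],
        lengths: Optional[Mapping[int, float]] = None,
        *,
        allow_unary_root: bool = False,
    ) -> None:
        self._children = {v: tuple(cs) for v, cs in children.items() if cs}
        self._root = root
        self._labels = dict(labels)
        self._lengths = dict(lengths) if lengths else None
        self._allow_unary_root = allow_unary_root
        parent: dict[int, int] = {}
        for v, cs in self._children.items():
            for c in cs:
                if c in parent:
                    raise TreeValidationError(f"vertex {c} has two parents")
                parent[c] = v
        self._parent = parent
        self._leafsets = None
        self._depth = None
        self._canon = None
        self._validate()
        self._node_of = {lab: v for v, lab in self._labels.items()}

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------

    @classmethod
    def from_nested(
        cls,
        nested,
        lengths: Optional[Mapping[str, float]] = None,
        *,
        allow_unary_root: bool = False,
    ) -> "PhyloTree":
        """Build a tree from nested tuples of leaf labels.

        ``(("a", "b"), "c")`` is the triple ``((a,b),c)``.
        """
        children: dict[int, list[int]] = {}
        labels: dict[int, str] = {}
        counter = itertools.count()

        def rec(node) -> int:
            v = next(counter)
            if isinstance(node, str):
                labels[v] = node
            else:
                children[v] = [rec(c) for c in node]
            return v

        root = rec(nested)
        return cls(children, root, labels, allow_unary_root=allow_unary_root)

    def _validate(self) -> None:
        nodes = set(self._children) | set(self._labels)
        for cs in self._children.values():
            nodes.update(cs)
        if self._root in self._parent:
            raise TreeValidationError("root has a parent")
        # connectivity / reachability
        seen = set()
        stack = [self._root]
        while stack:
            v = stack.pop()
            if v in seen:
                raise TreeValidationError(f"cycle through vertex {v}")
            seen.add(v)
            stack.extend(self._children.get(v, ()))
        if seen != nodes:
            raise TreeValidationError("tree is not connected")
        for v in nodes:
            if v != self._root and v not in self._parent:
                raise TreeValidationError(f"vertex {v} unreachable from root")
        # degree constraints and leaf labels
        for v in nodes:
            ncs = len(self._children.get(v, ()))
            if ncs == 0:
                if v not in self._labels:
                    raise TreeValidationError(f"leaf vertex {v} is unlabeled")
            else:
                if v in self._labels:
                    raise TreeValidationError(
                        f"interior vertex {v} carries a leaf label"
                    )
                if ncs == 1 and not (v == self._root and self._allow_unary_root):
                    raise TreeValidationError(
                        f"vertex {v} has in- and outdegree one"
                    )
        if len(set(self._labels.values())) != len(self._labels):
            dups = sorted(
                lab
                for lab in set(self._labels.values())
                if sum(1 for x in self._labels.values() if x == lab) > 1
            )
            raise TreeValidationError(f"duplicate leaf labels: {dups}")
        if self._lengths is not None:
            for v, ell in self._lengths.items():
                if ell is not None and ell < 0:
                    raise TreeValidationError(f"negative edge length above {v}")

    # ------------------------------------------------------------------
    # basic accessors
    # ------------------------------------------------------------------

    @property
    def root(self) -> int:
        return self._root

    def children(self, v: int) -> tuple:
        return self._children.get(v, ())

    def parent(self, v: int) -> Optional[int]:
        return self._parent.get(v)

    def is_leaf(self, v: int) -> bool:
        return v not in self._children

    def label(self, v: int) -> str:
        return self._labels[v]

    def node_of(self, label: str) -> int:
        try:
            return self._node_of[label]
        except KeyError:
            raise KeyError(f"no leaf labeled {label!r}") from None

    @property
    def leaf_labels(self) -> frozenset:
        return frozenset(self._node_of)

    def leaves(self) -> tuple:
        return tuple(v for v in self.postorder() if self.is_leaf(v))

    def interior(self) -> tuple:
        return tuple(v for v in self.postorder() if not self.is_leaf(v))

    def edges(self) -> tuple:
        """Directed edges ``(parent, child)``."""
        return tuple(
            (v, c) for v in self.preorder() for c in self.children(v)
        )

    def length(self, v: int) -> Optional[float]:
        """Length of the edge above ``v`` (None at the root / if absent)."""
        if self._lengths is None:
            return None
        return self._lengths.get(v)

    @property
    def has_lengths(self) -> bool:
        return self._lengths is not None

    def postorder(self) -> list:
        out: list[int] = []
        stack = [(self._root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                out.append(v)
            else:
                stack.append((v, True))
                for c in reversed(self.children(v)):
                    stack.append((c, False))
        return out

    def preorder(self) -> list:
        out: list[int] = []
        stack = [self._root]
        while stack:
            v = stack.pop()
            out.append(v)
            for c in reversed(self.children(v)):
                stack.append(c)
        return out

    def __len__(self) -> int:
        return len(self.postorder())

    # ------------------------------------------------------------------
    # ancestor order and lca
    # ------------------------------------------------------------------

    def depth(self, v: int) -> int:
        if self._depth is None:
            d = {self._root: 0}
            for u in self.preorder():
                for c in self.children(u):
                    d[c] = d[u] + 1
            self._depth = d
        return self._depth[v]

    def is_ancestor(self, anc: int, v: int) -> bool:
        """True iff ``v`` is at or below ``anc`` (v <= anc in the ancestor order)."""
        while v is not None and self.depth(v) > self.depth(anc):
            v = self.parent(v)
        return v == anc

    def lca_nodes(self, nodes: Iterable[int]) -> int:
        it = iter(nodes)
        try:
            cur = next(it)
        except StopIteration:
            raise ValueError("lca of an empty vertex set") from None
        for v in it:
            a, b = cur, v
            while self.depth(a) > self.depth(b):
                a = self.parent(a)
            while self.depth(b) > self.depth(a):
                b = self.parent(b)
            while a != b:
                a = self.parent(a)
                b = self.parent(b)
            cur = a
        return cur

    def lca(self, labels: Iterable[str]) -> int:
        """Most recent common ancestor of a nonempty leaf-label subset."""
        labels = list(labels)
        missing = [x for x in labels if x not in self._node_of]
        if missing:
            raise ValueError(f"labels not in the tree: {sorted(missing)}")
        return self.lca_nodes(self._node_of[x] for x in labels)

    def leafset(self, v: int) -> frozenset:
        """Labels of the leaves at or below ``v`` (the cluster L(v))."""
        if self._leafsets is None:
            ls: dict[int, frozenset] = {}
            for u in self.postorder():
                if self.is_leaf(u):
                    ls[u] = frozenset((self._labels[u],))
                else:
                    ls[u] = frozenset().union(*(ls[c] for c in self.children(u)))
            self._leafsets = ls
        return self._leafsets[v]

    # ------------------------------------------------------------------
    # restriction / display / triples / clusters
    # ------------------------------------------------------------------

    def restrict(self, labels: Iterable[str], *, with_map: bool = False):
        """Restriction to a leaf subset, suppressing degree-two vertices.

        Returns the restricted tree; with ``with_map=True`` also returns a
        map from new vertex ids to the original vertices they came from.
        Edge lengths (if present) are summed along suppressed paths.
        """
        want = frozenset(labels)
        if not want <= self.leaf_labels:
            raise ValueError(
                f"labels not in the tree: {sorted(want - self.leaf_labels)}"
            )
        if len(want) < 2:
            raise ValueError("restriction needs at least two leaves")
        root_r = self.lca(want)
        keep: dict[int, bool] = {}
        for v in self.postorder():
            if self.is_leaf(v):
                keep[v] = self.label(v) in want
            else:
                nkids = sum(
                    1 for c in self.children(v) if self.leafset(c) & want
                )
                keep[v] = nkids >= 2 or v == root_r
        # drop anything outside the subtree of root_r
        in_subtree = {root_r}
        for v in self.preorder():
            if v in in_subtree:
                in_subtree.update(self.children(v))
        children: dict[int, list[int]] = {}
        labels_out: dict[int, str] = {}
        lengths_out: dict[int, float] = {}
        new_id: dict[int, int] = {}
        counter = itertools.count()
        node_map: dict[int, int] = {}

        def add(v: int, length_acc: Optional[float]) -> int:
            nid = next(counter)
            new_id[v] = nid
            node_map[nid] = v
            if self.is_leaf(v):
                labels_out[nid] = self.label(v)
            if self._lengths is not None and length_acc is not None:
                lengths_out[nid] = length_acc
            return nid

        def walk(v: int, parent_new: Optional[int], length_acc) -> None:
            if not (self.leafset(v) & want) or v not in in_subtree:
                return
            ell = self.length(v) if self._lengths is not None else None
            acc = (
                None
                if length_acc is None and ell is None
                else (length_acc or 0.0) + (ell or 0.0)
            )
            if keep[v] and (self.is_leaf(v) and self.label(v) in want or not self.is_leaf(v)):
                nid = add(v, acc if parent_new is not None else None)
                if parent_new is not None:
                    children.setdefault(parent_new, []).append(nid)
                for c in self.children(v):
                    walk(c, nid, None)
            else:
                for c in self.children(v):
                    walk(c, parent_new, acc)

        walk(root_r, None, None)
        tree = PhyloTree(
            children,
            new_id[root_r],
            labels_out,
            lengths_out if self._lengths is not None else None,
        )
        if with_map:
            return tree, node_map
        return tree

    def canonical_key(self):
        """Canonical nested-tuple form: children sorted by smallest leaf label.

        Two trees on the same leaf set are equivalent (isomorphic fixing
        leaves and root) iff their canonical keys are equal.
        """
        if self._canon is None:
            memo: dict[int, tuple] = {}
            for v in self.postorder():
                if self.is_leaf(v):
                    memo[v] = self.label(v)
                else:
                    kids = sorted(
                        (memo[c] for c in self.children(v)),
                        key=_min_leaf,
                    )
                    memo[v] = tuple(kids)
            self._canon = memo[self._root]
        return self._canon

    def equivalent(self, other: "PhyloTree") -> bool:
        return self.canonical_key() == other.canonical_key()

    def displays(self, other: "PhyloTree") -> bool:
        """True iff restricting this tree to ``other``'s leaves yields ``other``."""
        if not other.leaf_labels <= self.leaf_labels:
            raise ValueError(
                "displayed tree has leaves outside the displaying tree: "
                f"{sorted(other.leaf_labels - self.leaf_labels)}"
            )
        return self.restrict(other.leaf_labels).equivalent(other)

    def displays_triple(self, r: Triple) -> bool:
        if not r.labels <= self.leaf_labels:
            raise ValueError(f"triple labels outside the tree: {r}")
        pair = self.lca((r.a, r.b))
        allthree = self.lca((r.a, r.b, r.outgroup))
        return pair != allthree

    def triples(self) -> frozenset:
        """All rooted triples displayed by the tree (the set R(T))."""
        out = set()
        labs = sorted(self.leaf_labels)
        for x, y, z in itertools.combinations(labs, 3):
            top = self.lca((x, y, z))
            for a, b, c in ((x, y, z), (x, z, y), (y, z, x)):
                if self.lca((a, b)) != top:
                    out.add(Triple(a, b, c))
                    break
        return frozenset(out)

    def clusters(self) -> frozenset:
        """Leaf sets of the interior vertices (the cluster system)."""
        return frozenset(
            self.leafset(v) for v in self.postorder() if not self.is_leaf(v)
        )

    # ------------------------------------------------------------------
    # Newick
    # ------------------------------------------------------------------

    def newick(
        self,
        *,
        include_lengths: bool = True,
        comments: Optional[Mapping[int, str]] = None,
    ) -> str:
        """Canonical Newick string (children sorted by smallest leaf label).

        ``comments`` attaches a bracketed comment (e.g. an NHX tag) after
        the given vertices.
        """

        def fmt(v: int) -> str:
            if self.is_leaf(v):
                s = _escape(self.label(v))
            else:
                kids = sorted(self.children(v), key=lambda c: min(self.leafset(c)))
                s = "(" + ",".join(fmt(c) for c in kids) + ")"
            if comments and v in comments:
                s += f"[{comments[v]}]"
            ell = self.length(v) if include_lengths else None
            if ell is not None:
                s += f":{ell:.10g}"
            return s

        return fmt(self._root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhyloTree({self.newick(include_lengths=False)})"


def _min_leaf(key) -> str:
    while not isinstance(key, str):
        key = key[0]
    return key


_NEEDS_QUOTE = set("()[]{}:;,'\" \t\n")


def _escape(label: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ----------------------------------------------------------------------
# Newick I/O (dendropy-backed reader)
# ----------------------------------------------------------------------


def _parse_newick_full(
    text: str, *, allow_unary_root: bool = False
):
    """Parse one Newick statement; returns (tree, comments-by-vertex).

    Degree-two interior vertices (other than a permitted unary root) are
    rejected, not suppressed.  Comments (e.g. NHX annotations) are
    returned keyed by vertex id for the annotated-tree readers.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise NewickParseError("Newick statement must end in ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
            extract_comment_metadata=False,
            preserve_underscores=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderError as exc:
        raise NewickParseError(str(exc)) from None
    children: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    lengths: dict[int, float] = {}
    comments: dict[int, str] = {}
    ids: dict = {}
    any_length = False
    for i, nd in enumerate(dtree.preorder_node_iter()):
        ids[nd] = i
        if nd.parent_node is not None:
            children.setdefault(ids[nd.parent_node], []).append(i)
        if nd.is_leaf():
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label is not None:
                labels[i] = nd.label
            else:
                raise NewickParseError(f"unlabeled leaf (vertex {i})")
        if nd.edge.length is not None:
            lengths[i] = float(nd.edge.length)
            any_length = True
        if nd.comments:
            comments[i] = ";".join(nd.comments)
    tree = PhyloTree(
        children,
        ids[dtree.seed_node],
        labels,
        lengths if any_length else None,
        allow_unary_root=allow_unary_root,
    )
    return tree, comments


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted Newick statement into a :class:`PhyloTree`.

    Polytomies are allowed; optional edge lengths and quoted labels are
    supported.  Vertices with in- and outdegree one are a validation
    error (they are not silently suppressed), as are duplicate leaf
    names.
    """
    tree, _ = _parse_newick_full(text)
    return tree


def write_newick(tree: PhyloTree, *, include_lengths: bool = True) -> str:
    """Deterministic canonical Newick serialization of ``tree``."""
    return tree.newick(include_lengths=include_lengths)


# ----------------------------------------------------------------------
# thin functional façade mirroring the operation names
# ----------------------------------------------------------------------


def lca(tree: PhyloTree, A: Iterable[str]) -> int:
    return tree.lca(A)


def restrict(tree: PhyloTree, Lp: Iterable[str]) -> PhyloTree:
    return tree.restrict(Lp)


def displays(tree: PhyloTree, other: PhyloTree) -> bool:
    return tree.displays(other)


def all_triples(tree: PhyloTree) -> frozenset:
    return tree.triples()


def clusters(tree: PhyloTree) -> frozenset:
    return tree.clusters()
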