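"""Reconciliation maps between event-labeled gene trees and species trees.

A reconciliation map ``mu`` sends every gene-tree vertex to a vertex or
edge of the species tree: extant genes to the species leaf they reside
in, speciations to the interior vertex ``lca_S(sigma(L(x)))`` (there is
no freedom here), and duplications to an edge — canonically the edge
immediately above ``lca_S(sigma(L(x)))``, although any edge between that
one and the constraints imposed by neighbouring vertices is feasible,
which is what :func:`enumerate_duplication_placements` explores.

Such a map exists precisely when the species tree displays every
informative species triple of the gene tree; :func:`construct_reconciliation`
checks this precondition and then builds the canonical map in one
bottom-up pass over the gene tree (O(|L||B|)).

:func:`validate_reconciliation` checks an arbitrary candidate map
against the full axiom set — leaf anchoring, image types, ancestor-order
preservation (strict except between two duplications), the lca anchoring
of speciations — plus the derived properties that must hold for any
valid map (the duplication image lying strictly above the lca of its
species set, and the lca-domination inequality
``lca_S(mu(x), mu(y)) <= mu(lca_T(x, y))``).  Violations of the derived
properties indicate a bug rather than a mere invalid input, and are
reported with their own clause tags.

The ancestor order is extended from vertices to edges the standard way:
for an edge ``e = [u, v]``, ``x < e`` iff ``x <= v``, ``e < x`` iff
``u <= x``, and ``[u, v] <= [a, b]`` iff ``v <= b``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Union

from .labeled import Event, GeneTree, SpeciesTree
from .triples import species_triples

__all__ = [
    "VertexImage",
    "EdgeImage",
    "Violation",
    "ReconciliationMap",
    "ReconciliationError",
    "construct_reconciliation",
    "validate_reconciliation",
    "enumerate_duplication_placements",
    "write_reconciliation_tsv",
    "read_reconciliation_tsv",
]


class VertexImage(NamedTuple):
    """Image of a gene-tree vertex at a species-tree vertex."""

    node: int


class EdgeImage(NamedTuple):
    """Image of a gene-tree vertex on a species-tree edge [parent, child]."""

    parent: int
    child: int


Image = Union[VertexImage, EdgeImage]


@dataclass(frozen=True)
class Violation:
    """One violated reconciliation axiom.

    ``clause`` is the axiom tag: ``i``..``v`` for the defining
    conditions, ``D1``..``D3`` and ``Eq1`` for the derived properties,
    ``total``/``rho`` for bookkeeping checks.
    """

    clause: str
    vertices: tuple
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"({self.clause}) at {self.vertices}: {self.message}"


@dataclass(frozen=True)
class ReconciliationMap:
    """Total map from gene-tree vertices to species-tree vertices/edges."""

    images: Mapping[int, Image]

    def __getitem__(self, v: int) -> Image:
        return self.images[v]

    def __len__(self) -> int:
        return len(self.images)

    def with_image(self, v: int, img: Image) -> "ReconciliationMap":
        d = dict(self.images)
        d[v] = img
        return ReconciliationMap(d)


class ReconciliationError(ValueError):
    """No reconciliation map exists (precondition failure)."""


# ----------------------------------------------------------------------
# species-tree order helpers
# ----------------------------------------------------------------------


class _Order:
    """Ancestor order on a species tree, extended to edges."""

    def __init__(self, s: SpeciesTree):
        self.s = s
        self.anc: dict[int, frozenset] = {}
        tree = s.tree
        for v in tree.preorder():
            p = tree.parent(v)
            base = self.anc[p] if p is not None else frozenset()
            self.anc[v] = base | {v}

    def vleq(self, a: int, b: int) -> bool:
        """a <= b among vertices (b is an ancestor of or equal to a)."""
        return b in self.anc[a]

    def leq(self, x: Image, y: Image, *, strict: bool) -> bool:
        if isinstance(x, VertexImage) and isinstance(y, VertexImage):
            return self.vleq(x.node, y.node) and not (strict and x == y)
        if isinstance(x, VertexImage) and isinstance(y, EdgeImage):
            # vertex below edge: x <= child(y); equality cannot occur
            return self.vleq(x.node, y.child)
        if isinstance(x, EdgeImage) and isinstance(y, VertexImage):
            return self.vleq(x.parent, y.node)
        return self.vleq(x.child, y.child) and not (strict and x == y)

    def lower(self, x: Image) -> int:
        """Representative vertex of an image (an edge's lower endpoint)."""
        return x.node if isinstance(x, VertexImage) else x.child


def _species_lca_map(g: GeneTree, s: SpeciesTree) -> dict:
    """lca_S(sigma(L(x))) for every gene-tree vertex, one bottom-up pass."""
    below = g.species_below()
    return {v: s.lca(below[v]) for v in g.tree.postorder()}


# ----------------------------------------------------------------------
# construction (M1)-(M3)
# ----------------------------------------------------------------------


def construct_reconciliation(g: GeneTree, s: SpeciesTree) -> ReconciliationMap:
    """The canonical reconciliation map.

    Rules: leaves to their species leaf; speciations to the lca of their
    species set; duplications to the edge whose lower endpoint is that
    lca.  Requires (checked) that ``s`` displays every species triple of
    ``g``; otherwise no reconciliation map exists at all and a
    :class:`ReconciliationError` lists the undisplayed triples.
    """
    missing_species = g.species_set - s.species
    if missing_species:
        raise ReconciliationError(
            f"species tree lacks species {sorted(missing_species)}"
        )
    undisplayed = [r for r in species_triples(g) if not s.displays_triple(r)]
    if undisplayed:
        raise ReconciliationError(
            "species tree does not display the informative triples: "
            + ", ".join(map(str, undisplayed))
        )
    lca_map = _species_lca_map(g, s)
    tree = g.tree
    images: dict[int, Image] = {}
    for v in tree.postorder():
        ev = g.events[v]
        if ev is Event.EXTANT:
            images[v] = VertexImage(s.tree.node_of(g.sigma[tree.label(v)]))
        elif ev is Event.SPECIATION:
            images[v] = VertexImage(lca_map[v])
        else:  # duplication: the edge immediately above the lca
            lo = lca_map[v]
            images[v] = EdgeImage(s.tree.parent(lo), lo)
    return ReconciliationMap(images)


# ----------------------------------------------------------------------
# validation
# ----------------------------------------------------------------------


def validate_reconciliation(
    g: GeneTree, s: SpeciesTree, mu: ReconciliationMap
) -> list:
    """All axiom violations of a candidate map (empty iff valid).

    Reports every failed clause rather than stopping at the first, with
    the offending vertices and a clause tag.
    """
    tree = g.tree
    nodes = tree.postorder()
    missing = [v for v in nodes if v not in mu.images]
    if missing:
        raise ValueError(f"map is not total: vertices {missing} unmapped")
    order = _Order(s)
    lca_map = _species_lca_map(g, s)
    stree = s.tree
    edge_set = set(s.edges())
    out: list[Violation] = []

    def add(clause: str, vertices, message: str) -> None:
        out.append(Violation(clause, tuple(vertices), message))

    for v in nodes:
        ev = g.events[v]
        img = mu[v]
        if ev is Event.EXTANT:
            want = VertexImage(stree.node_of(g.sigma[tree.label(v)]))
            if img != want:
                add("i", (v,), f"leaf maps to {img}, expected {want}")
        elif ev is Event.SPECIATION:
            if not isinstance(img, VertexImage):
                add("ii", (v,), "speciation must map to a species-tree vertex")
            else:
                node = img.node
                if stree.is_leaf(node) or node == s.rho:
                    add("ii", (v,), "speciation image must lie in W \\ B, below rho")
                if node != lca_map[v]:
                    add("v", (v,), "speciation image is not lca_S(sigma(L(x)))")
        else:  # duplication
            if not isinstance(img, EdgeImage):
                add("iii", (v,), "duplication must map to a species-tree edge")
            elif (img.parent, img.child) not in edge_set:
                add("iii", (v,), f"{img} is not an edge of the species tree")
        if isinstance(img, VertexImage) and img.node == s.rho:
            add("rho", (v,), "nothing may map to the extra root vertex")

    # derived per-vertex properties (hold for every valid map)
    for v in nodes:
        img = mu[v]
        if isinstance(img, VertexImage):
            if tree.is_leaf(v):
                want = stree.node_of(g.sigma[tree.label(v)])
                if img.node != want:
                    add("D1", (v,), "leaf not anchored at its species")
            elif img.node != lca_map[v]:
                add("D2a", (v,), "vertex image differs from lca_S(sigma(L(x)))")
        elif isinstance(img, EdgeImage) and (img.parent, img.child) in edge_set:
            if not order.leq(VertexImage(lca_map[v]), img, strict=True):
                add("D2b", (v,), "edge image not strictly above lca_S(sigma(L(x)))")

    # ancestor-order preservation, all comparable pairs
    for x in nodes:
        y = tree.parent(x)
        path_up = []
        while y is not None:
            path_up.append(y)
            y = tree.parent(y)
        for y in path_up:
            both_dup = (
                g.events[x] is Event.DUPLICATION
                and g.events[y] is Event.DUPLICATION
            )
            ok = order.leq(mu[x], mu[y], strict=not both_dup)
            if not ok:
                clause = "iv.1" if both_dup else "iv.2"
                add(
                    clause,
                    (x, y),
                    f"mu({x})={mu[x]} not {'<=' if both_dup else '<'} mu({y})={mu[y]}",
                )
            both_edge = isinstance(mu[x], EdgeImage) and isinstance(mu[y], EdgeImage)
            if not order.leq(mu[x], mu[y], strict=not both_edge):
                add("D3", (x, y), "ancestor order not preserved (edge/vertex rule)")

    # lca domination: lca_S(mu(x), mu(y)) <= mu(lca_T(x, y))
    for x, y in itertools.combinations(nodes, 2):
        w = stree.lca_nodes((order.lower(mu[x]), order.lower(mu[y])))
        top = mu[tree.lca_nodes((x, y))]
        if not order.leq(VertexImage(w), top, strict=False):
            add("Eq1", (x, y), "lca_S(mu(x), mu(y)) not below mu(lca_T(x, y))")
    return out


# ----------------------------------------------------------------------
# alternative duplication placements
# ----------------------------------------------------------------------


def enumerate_duplication_placements(
    g: GeneTree, s: SpeciesTree, limit: int = 100
) -> list:
    """Up to ``limit`` distinct valid maps differing only on duplications.

    For each duplication vertex the candidate images are the edges on the
    path from the canonical edge (above ``lca_S(sigma(L(x)))``) up to the
    extra root edge; candidate combinations are screened through
    :func:`validate_reconciliation`, in deterministic order starting from
    the canonical map.  A gene tree without duplications yields exactly
    one map.
    """
    base = construct_reconciliation(g, s)
    dups = [
        v for v in g.tree.postorder() if g.events[v] is Event.DUPLICATION
    ]
    if not dups:
        return [base]
    stree = s.tree
    candidates = []
    for v in dups:
        img = base[v]
        chain = [img]
        w = img.parent
        while stree.parent(w) is not None:
            chain.append(EdgeImage(stree.parent(w), w))
            w = stree.parent(w)
        candidates.append(chain)
    found = []
    for combo in itertools.product(*candidates):
        mu = ReconciliationMap(
            {**base.images, **dict(zip(dups, combo))}
        )
        if not validate_reconciliation(g, s, mu):
            found.append(mu)
            if len(found) >= limit:
                break
    return found


# ----------------------------------------------------------------------
# TSV I/O: gene_vertex_id, target_kind (vertex|edge), target_id(s)
# ----------------------------------------------------------------------


def _canonical_ids(tree) -> tuple:
    """Stable string ids: leaves by label, interior by canonical preorder."""
    order = []
    def walk(v):
        order.append(v)
        kids = sorted(tree.children(v), key=lambda c: min(tree.leafset(c)))
        for c in kids:
            walk(c)
    walk(tree.root)
    ids = {}
    k = 0
    for v in order:
        if tree.is_leaf(v):
            ids[v] = tree.label(v)
        else:
            ids[v] = f"n{k}"
            k += 1
    return ids, {name: v for v, name in ids.items()}


def write_reconciliation_tsv(
    mu: ReconciliationMap, g: GeneTree, s: SpeciesTree
) -> str:
    gids, _ = _canonical_ids(g.tree)
    sids, _ = _canonical_ids(s.tree)
    lines = ["# gene_vertex\ttarget_kind\ttarget\n"]
    for v in sorted(g.tree.postorder(), key=lambda v: gids[v]):
        img = mu[v]
        if isinstance(img, VertexImage):
            lines.append(f"{gids[v]}\tvertex\t{sids[img.node]}\n")
        else:
            lines.append(
                f"{gids[v]}\tedge\t{sids[img.parent]},{sids[img.child]}\n"
            )
    return "".join(lines)


def read_reconciliation_tsv(
    text: str, g: GeneTree, s: SpeciesTree
) -> ReconciliationMap:
    _, gback = _canonical_ids(g.tree)
    _, sback = _canonical_ids(s.tree)
    images: dict[int, Image] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"reconciliation TSV line {lineno}: expected 3 columns")
        gname, kind, target = parts
        if gname not in gback:
            raise ValueError(f"line {lineno}: unknown gene vertex {gname!r}")
        v = gback[gname]
        if kind == "vertex":
            images[v] = VertexImage(sback[target])
        elif kind == "edge":
            pname, cname = target.split(",")
            images[v] = EdgeImage(sback[pname], sback[cname])
        else:
            raise ValueError(f"line {lineno}: unknown target kind {kind!r}")
    return ReconciliationMap(images)
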