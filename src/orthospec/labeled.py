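"""Event-labeled gene trees and species trees.

A gene tree here is the triple ``(T, t, sigma)``: a phylogenetic tree
``T`` on a set ``L`` of genes, an event map ``t`` marking every interior
vertex as a speciation or a duplication (leaves are the extant genes),
and a species assignment ``sigma`` sending each gene to the species it
resides in.  The one compatibility requirement between ``t`` and
``sigma`` is condition (C): the species sets found below distinct
children of a *speciation* vertex must be disjoint — two genes from the
same species can only coalesce in a duplication.  The converse is not
required: disjointness does not force a speciation label.

A species tree on the species set ``B`` carries one extra vertex and
edge above the last common ancestor of ``B``, so that duplications
predating the first speciation have an edge to map to.  That root is the
single permitted in/outdegree-one exception to the tree axioms.

File conventions: event labels travel as NHX-style tags on interior
nodes (``[&&NHX:Ev=S]`` / ``[&&NHX:Ev=D]``; leaves are implicitly extant
genes), and the species assignment is encoded in leaf names as
``<gene>@<species>``, optionally overridden by a two-column TSV
(gene, species).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .trees import PhyloTree, TreeValidationError, _parse_newick_full

__all__ = [
    "Event",
    "GeneTree",
    "SpeciesTree",
    "ConditionCViolation",
    "GeneTreeError",
    "make_gene_tree",
    "check_condition_C",
    "make_species_tree",
    "read_gene_tree",
    "write_gene_tree",
    "read_species_tree",
    "write_species_tree",
    "read_species_map",
    "write_species_map",
]


class Event(enum.Enum):
    """Vertex event types.

    Observable gene trees use only SPECIATION, DUPLICATION and EXTANT;
    LOSS occurs only in the simulator's true (unpruned) scenarios.
    """

    SPECIATION = "S"   # filled circle in the usual drawings
    DUPLICATION = "D"  # square
    EXTANT = "E"       # circled dot: an observed, extant gene (leaf)
    LOSS = "X"         # crossed circle: a lost lineage (true scenario only)


class GeneTreeError(ValueError):
    """Invalid (T, t, sigma) combination."""


@dataclass(frozen=True)
class ConditionCViolation:
    """A speciation vertex with overlapping species sets below two children."""

    vertex: int
    child_pair: tuple
    shared_species: frozenset

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"speciation vertex {self.vertex}: children {self.child_pair} "
            f"share species {sorted(self.shared_species)}"
        )


def _species_below(tree: PhyloTree, sigma: Mapping[str, str]) -> dict:
    out: dict[int, frozenset] = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            out[v] = frozenset((sigma[tree.label(v)],))
        else:
            out[v] = frozenset().union(*(out[c] for c in tree.children(v)))
    return out


def _check_condition_C(
    tree: PhyloTree, events: Mapping[int, Event], sigma: Mapping[str, str]
) -> list:
    below = _species_below(tree, sigma)
    violations = []
    for v in tree.postorder():
        if events.get(v) is not Event.SPECIATION:
            continue
        for c1, c2 in itertools.combinations(tree.children(v), 2):
            shared = below[c1] & below[c2]
            if shared:
                violations.append(ConditionCViolation(v, (c1, c2), shared))
    return violations


@dataclass(frozen=True)
class GeneTree:
    """An event-labeled gene tree ``(T, t, sigma)``.

    Construct via :func:`make_gene_tree` (validating) or
    :func:`read_gene_tree`; instances are assumed valid.
    """

    tree: PhyloTree
    events: Mapping[int, Event]
    sigma: Mapping[str, str]  # gene leaf label -> species label

    @property
    def species_set(self) -> frozenset:
        """The species universe B = sigma(L)."""
        return frozenset(self.sigma.values())

    def event(self, v: int) -> Event:
        return self.events[v]

    def species_below(self) -> dict:
        """Per-vertex species set sigma(L(v))."""
        return _species_below(self.tree, self.sigma)

    def sigma_of(self, leaf_label: str) -> str:
        return self.sigma[leaf_label]


def make_gene_tree(
    topology: PhyloTree,
    t: Mapping[int, Event],
    sigma: Mapping[str, str],
) -> GeneTree:
    """Validate and assemble an event-labeled gene tree.

    Fails loudly when the label placement is wrong (a leaf marked as
    speciation/duplication, an interior vertex marked extant, a loss
    label in an observable tree), when ``t`` or ``sigma`` is not total,
    when fewer than three genes are present, or when condition (C) is
    violated at some speciation vertex.
    """
    if len(topology.leaf_labels) < 3:
        raise GeneTreeError("a gene tree needs at least three genes")
    for v in topology.postorder():
        ev = t.get(v)
        if ev is None:
            raise GeneTreeError(f"event map is not total: vertex {v} unlabeled")
        if ev is Event.LOSS:
            raise GeneTreeError(
                f"vertex {v}: loss labels do not occur in observable gene trees"
            )
        if topology.is_leaf(v) and ev is not Event.EXTANT:
            raise GeneTreeError(f"leaf {topology.label(v)!r} labeled {ev.name}")
        if not topology.is_leaf(v) and ev is Event.EXTANT:
            raise GeneTreeError(f"interior vertex {v} labeled EXTANT")
    missing = topology.leaf_labels - set(sigma)
    if missing:
        raise GeneTreeError(f"sigma is not total: missing {sorted(missing)}")
    events = {v: t[v] for v in topology.postorder()}
    sig = {lab: sigma[lab] for lab in topology.leaf_labels}
    violations = _check_condition_C(topology, events, sig)
    if violations:
        raise GeneTreeError(
            "condition (C) violated: " + "; ".join(map(str, violations))
        )
    return GeneTree(topology, events, sig)


def check_condition_C(g: GeneTree) -> list:
    """All condition-(C) violations in ``g`` (empty iff (C) holds).

    Each violation names the speciation vertex, the offending child pair
    and the shared species.  Duplication vertices are unconstrained, and
    disjointness is never used to *infer* a speciation.
    """
    return _check_condition_C(g.tree, g.events, g.sigma)


# ----------------------------------------------------------------------
# species trees
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesTree:
    """Species tree on ``B`` with the extra root vertex and edge.

    ``tree`` is the augmented :class:`PhyloTree`: its root ``rho`` has a
    single child, the crown vertex ``lca_S(B)``.  Triples, displaying and
    clusters are inherited from the unaugmented topology on ``B``.
    """

    tree: PhyloTree

    @property
    def rho(self) -> int:
        return self.tree.root

    @property
    def crown(self) -> int:
        """lca_S(B), the unique child of the extra root."""
        (c,) = self.tree.children(self.tree.root)
        return c

    @property
    def species(self) -> frozenset:
        return self.tree.leaf_labels

    @property
    def root_edge(self) -> tuple:
        return (self.rho, self.crown)

    def edges(self) -> tuple:
        return self.tree.edges()

    def lca(self, species: Iterable[str]) -> int:
        return self.tree.lca(species)

    def displays_triple(self, r) -> bool:
        return self.tree.displays_triple(r)

    def displays(self, other: PhyloTree) -> bool:
        return self.tree.displays(other)

    def clusters(self) -> frozenset:
        """Cluster system over B (extra root excluded; root cluster B included)."""
        return frozenset(
            self.tree.leafset(v)
            for v in self.tree.postorder()
            if not self.tree.is_leaf(v) and v != self.rho
        )

    @property
    def n_interior(self) -> int:
        """Interior vertices of the unaugmented topology."""
        return sum(
            1
            for v in self.tree.postorder()
            if not self.tree.is_leaf(v) and v != self.rho
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SpeciesTree({self.tree.newick(include_lengths=False)})"


def make_species_tree(topology: PhyloTree) -> SpeciesTree:
    """Augment a phylogenetic tree on ``B`` with the extra root vertex.

    A single labeled vertex (|B| = 1) is permitted and yields the
    two-vertex, one-edge species tree.  Feeding an already augmented tree
    (unary root) is an error.
    """
    if isinstance(topology, SpeciesTree):
        raise TreeValidationError("tree is already an augmented species tree")
    if len(topology.children(topology.root)) == 1:
        raise TreeValidationError(
            "root already has outdegree one: tree appears to be augmented"
        )
    nodes = topology.postorder()
    rho = max(nodes) + 1
    children = {v: topology.children(v) for v in nodes if not topology.is_leaf(v)}
    children[rho] = (topology.root,)
    labels = {v: topology.label(v) for v in nodes if topology.is_leaf(v)}
    lengths = (
        {v: topology.length(v) for v in nodes if topology.length(v) is not None}
        if topology.has_lengths
        else None
    )
    aug = PhyloTree(children, rho, labels, lengths, allow_unary_root=True)
    return SpeciesTree(aug)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

DEFAULT_SEP = "@"
DEFAULT_EV_KEY = "Ev"

_EV_CODE = {Event.SPECIATION: "S", Event.DUPLICATION: "D"}
_CODE_EV = {"S": Event.SPECIATION, "D": Event.DUPLICATION}


def _parse_nhx_comment(comment: str, key: str) -> Optional[str]:
    body = comment
    if body.startswith("&&NHX"):
        body = body[len("&&NHX"):]
    for part in body.split(":"):
        if "=" in part:
            k, val = part.split("=", 1)
            if k == key:
                return val
    return None


def read_gene_tree(
    text: str,
    species_map: Optional[Mapping[str, str]] = None,
    *,
    sep: str = DEFAULT_SEP,
    ev_key: str = DEFAULT_EV_KEY,
) -> GeneTree:
    """Read an event-annotated Newick/NHX gene tree.

    Every interior node must carry an ``Ev=S`` or ``Ev=D`` NHX tag;
    leaves are extant genes.  The species of each gene is taken from
    ``species_map`` if given, otherwise from the ``<gene><sep><species>``
    leaf-name convention.
    """
    tree, comments = _parse_newick_full(text)
    events: dict[int, Event] = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            events[v] = Event.EXTANT
            continue
        tag = _parse_nhx_comment(comments.get(v, ""), ev_key)
        if tag is None:
            raise GeneTreeError(
                f"interior vertex {v} has no {ev_key}= event annotation"
            )
        if tag not in _CODE_EV:
            raise GeneTreeError(f"unknown event code {tag!r} at vertex {v}")
        events[v] = _CODE_EV[tag]
    sigma: dict[str, str] = {}
    for lab in tree.leaf_labels:
        if species_map is not None and lab in species_map:
            sigma[lab] = species_map[lab]
        elif sep in lab:
            sigma[lab] = lab.rsplit(sep, 1)[1]
        else:
            raise GeneTreeError(
                f"cannot determine the species of gene {lab!r}: no {sep!r} "
                "in the name and no species map entry"
            )
    return make_gene_tree(tree, events, sigma)


def write_gene_tree(g: GeneTree, *, ev_key: str = DEFAULT_EV_KEY) -> str:
    """Serialize a gene tree as canonical Newick with NHX event tags."""
    comments = {
        v: f"&&NHX:{ev_key}={_EV_CODE[g.events[v]]}"
        for v in g.tree.postorder()
        if not g.tree.is_leaf(v)
    }
    return g.tree.newick(comments=comments)


def read_species_tree(text: str) -> SpeciesTree:
    """Read a species tree from Newick.

    Accepts either the plain topology on ``B`` (which is then augmented
    with the extra root) or the already augmented form with a unary root.
    """
    tree, _ = _parse_newick_full(text, allow_unary_root=True)
    if len(tree.children(tree.root)) == 1:
        return SpeciesTree(tree)
    return make_species_tree(tree)


def write_species_tree(s: SpeciesTree, *, include_lengths: bool = True) -> str:
    """Serialize the augmented species tree (unary root written explicitly)."""
    return s.tree.newick(include_lengths=include_lengths)


def read_species_map(text: str) -> dict:
    """Two-column TSV (gene <TAB> species), no header, '#' comments."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"species map line {lineno}: expected 2 columns")
        gene, sp = parts
        if gene in out and out[gene] != sp:
            raise ValueError(f"species map line {lineno}: conflicting entry for {gene!r}")
        out[gene] = sp
    return out


def write_species_map(sigma: Mapping[str, str]) -> str:
    return "".join(f"{g}\t{s}\n" for g, s in sorted(sigma.items()))
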