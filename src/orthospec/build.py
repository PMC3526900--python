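"""Triple consistency and species-tree construction (the BUILD algorithm).

A set of rooted triples is *consistent* when some phylogenetic tree
displays them all.  BUILD (Aho, Sagiv, Szymanski & Ullman) decides this
in polynomial time: at each recursion level it forms the graph on the
current label subset with an edge ``{x, y}`` for every triple
``((x, y), z)`` whose three labels all lie in the subset, and recurses
into the connected components.  A connected graph on two or more labels
certifies inconsistency; otherwise the components become the subtrees of
the current root.

The output tree is minor-minimal (contracting any edge destroys the
display of some triple) but not necessarily the unique, nor the
vertex-minimal, tree displaying the input.  Component and recursion
order are canonicalized (sorted by smallest label) so the result is
deterministic.
"""

from __future__ import annotations

from typing import Iterable, Optional

import networkx as nx

from .labeled import GeneTree, SpeciesTree, make_species_tree
from .trees import PhyloTree, Triple
from .triples import TripleSet, species_triples

__all__ = [
    "InconsistentTriplesError",
    "build_tree",
    "is_consistent",
    "infer_species_tree",
]


class InconsistentTriplesError(Exception):
    """The triple set is displayed by no phylogenetic tree.

    ``certificate`` is the label subset at which the recursion failed:
    its Aho graph is connected with at least two vertices.
    """

    def __init__(self, certificate: frozenset):
        self.certificate = frozenset(certificate)
        super().__init__(
            "inconsistent triple set; connected Aho graph on "
            f"{sorted(self.certificate)}"
        )


def _as_triples(R) -> frozenset:
    if isinstance(R, TripleSet):
        return R.triples
    return frozenset(R)


def build_tree(
    R: TripleSet | Iterable[Triple], X: Optional[Iterable[str]] = None
) -> PhyloTree:
    """Construct a tree on ``X`` displaying every triple in ``R``.

    ``X`` defaults to the labels named by ``R`` (or the TripleSet's
    universe).  Labels of ``X`` not occurring in any triple attach as
    leaves at the top level.  Raises :class:`InconsistentTriplesError`
    with a certificate subset when no such tree exists.
    """
    triples = _as_triples(R)
    if X is None:
        X = R.labels if isinstance(R, TripleSet) else frozenset().union(
            *(r.labels for r in triples)
        ) if triples else frozenset()
    universe = frozenset(X)
    if not universe:
        raise ValueError("label universe is empty")
    stray = frozenset().union(*(r.labels for r in triples)) - universe if triples else frozenset()
    if stray:
        raise ValueError(f"triples name labels outside X: {sorted(stray)}")

    def rec(labels: frozenset, active: list) -> object:
        if len(labels) == 1:
            (x,) = labels
            return x
        if len(labels) == 2:
            return tuple(sorted(labels))
        graph = nx.Graph()
        graph.add_nodes_from(labels)
        graph.add_edges_from((r.a, r.b) for r in active)
        comps = sorted(
            (frozenset(c) for c in nx.connected_components(graph)), key=min
        )
        if len(comps) == 1:
            raise InconsistentTriplesError(labels)
        kids = []
        for comp in comps:
            sub = [r for r in active if r.labels <= comp]
            kids.append(rec(comp, sub))
        return tuple(kids)

    nested = rec(universe, [r for r in triples])
    if isinstance(nested, str):
        # single label: a tree that is just one leaf
        return PhyloTree({}, 0, {0: nested})
    return PhyloTree.from_nested(nested)


def is_consistent(R: TripleSet | Iterable[Triple]) -> bool:
    """True iff some phylogenetic tree displays all of ``R``.

    The empty set is consistent by convention.
    """
    triples = _as_triples(R)
    if not triples:
        return True
    try:
        build_tree(triples)
    except InconsistentTriplesError:
        return False
    return True


def infer_species_tree(g: GeneTree) -> SpeciesTree:
    """Species tree for an event-labeled gene tree, if one exists.

    Pipeline: project the speciation-rooted, distinct-species triples of
    ``g`` to species labels, run BUILD over ``B = sigma(L)``, and augment
    the result with the extra root vertex.  The returned tree displays
    every species triple of ``g``; if the triple set is inconsistent no
    species tree exists and :class:`InconsistentTriplesError` propagates.
    """
    R = species_triples(g)
    topo = build_tree(R, g.species_set)
    return make_species_tree(topo)
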