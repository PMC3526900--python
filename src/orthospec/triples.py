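"""Informative triples of an event-labeled gene tree.

Not every rooted triple of a gene tree says something about the species
tree: triples rooted in a duplication can contradict the true species
phylogeny, because paralogs may diverge long before the species carrying
them do.  The informative set keeps exactly the triples of ``T`` whose
root (the lca of their three leaves) is a *speciation* and whose leaves
lie in three pairwise distinct species.  Projecting those through
``sigma`` yields the species-level constraint set, which any species
tree for ``(T, t, sigma)`` must display — and whose consistency is also
sufficient for one to exist.

The reverse construction (:func:`gene_tree_from_triples`) shows the
constraint set is otherwise arbitrary: for *any* set of species triples,
consistent or not, there is an event-labeled gene tree producing exactly
that set (one speciation-rooted triple subtree per input triple, with
fresh genes, joined under a duplication root).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import FrozenSet, Iterable, Mapping, Optional

from .labeled import Event, GeneTree, make_gene_tree
from .trees import PhyloTree, Triple

__all__ = [
    "TripleSet",
    "informative_gene_triples",
    "species_triples",
    "gene_tree_from_triples",
    "read_triples",
    "write_triples",
]


@dataclass(frozen=True)
class TripleSet:
    """A set of rooted triples over a label universe.

    Set semantics: duplicates collapse, and the cherry of each triple is
    unordered.  ``labels`` is the universe the triples live over (gene
    labels for the gene-level set, species labels for its projection);
    it may be larger than the labels actually named by the triples.
    """

    triples: FrozenSet[Triple]
    labels: FrozenSet[str]

    @classmethod
    def of(
        cls, triples: Iterable[Triple], labels: Optional[Iterable[str]] = None
    ) -> "TripleSet":
        ts = frozenset(triples)
        named = frozenset().union(*(r.labels for r in ts)) if ts else frozenset()
        universe = frozenset(labels) if labels is not None else named
        if not named <= universe:
            raise ValueError(
                f"triples name labels outside the universe: {sorted(named - universe)}"
            )
        return cls(ts, universe)

    def __iter__(self):
        return iter(sorted(self.triples))

    def __len__(self) -> int:
        return len(self.triples)

    def __contains__(self, r: Triple) -> bool:
        return r in self.triples

    def union(self, other: "TripleSet") -> "TripleSet":
        return TripleSet(self.triples | other.triples, self.labels | other.labels)

    def relabel(self, mapping: Mapping[str, str]) -> "TripleSet":
        """Image under a label map; triples whose labels collide are dropped
        (a triple needs three distinct labels)."""
        out = set()
        for r in self.triples:
            imgs = {mapping[r.a], mapping[r.b], mapping[r.outgroup]}
            if len(imgs) == 3:
                out.add(r.relabel(mapping))
        return TripleSet.of(out, {mapping[x] for x in self.labels})


def informative_gene_triples(g: GeneTree) -> TripleSet:
    """The gene-level informative triple set.

    Exactly the triples ``((x, y), z)`` displayed by ``T`` whose root
    ``lca_T(x, y, z)`` is a speciation vertex and whose three leaves map
    to pairwise distinct species.  Structurally these are: ``x, y`` below
    one child of a speciation vertex (in different species) and ``z``
    below another child.
    """
    tree = g.tree
    out: set[Triple] = set()
    for v in tree.postorder():
        if g.events.get(v) is not Event.SPECIATION:
            continue
        kids = tree.children(v)
        all_leaves = tree.leafset(v)
        for c in kids:
            inside = tree.leafset(c)
            outside = all_leaves - inside
            for x, y in itertools.combinations(sorted(inside), 2):
                if g.sigma[x] == g.sigma[y]:
                    continue
                for z in outside:
                    if g.sigma[z] not in (g.sigma[x], g.sigma[y]):
                        out.add(Triple(x, y, z))
    return TripleSet.of(out, tree.leaf_labels)


def species_triples(g: GeneTree) -> TripleSet:
    """The species-level constraint set: the sigma-image of the
    informative gene triples, with set semantics.

    Computed directly on per-vertex species sets, without materializing
    the (possibly much larger) gene-level set.
    """
    tree = g.tree
    below = g.species_below()
    out: set[Triple] = set()
    for v in tree.postorder():
        if g.events.get(v) is not Event.SPECIATION:
            continue
        kids = tree.children(v)
        for c in kids:
            inside = below[c]
            outside = frozenset().union(
                *(below[c2] for c2 in kids if c2 != c)
            )
            for a, b in itertools.combinations(sorted(inside), 2):
                for z in outside - {a, b}:
                    out.add(Triple(a, b, z))
    return TripleSet.of(out, g.species_set)


def gene_tree_from_triples(
    R: TripleSet | Iterable[Triple], *, binary: bool = False
) -> GeneTree:
    """Event-labeled gene tree whose species triple set is exactly ``R``.

    Works for any nonempty ``R`` over species labels, consistent or not:
    each triple becomes a speciation-rooted three-gene subtree with fresh
    genes (named ``g<k>_<i>@<species>``), and the subtrees are joined
    under a duplication root.  With a single triple the duplication root
    is omitted (it would have outdegree one).  With ``binary=True`` the
    join is a caterpillar of duplication vertices instead of a single
    multifurcation.
    """
    triples = sorted(R if isinstance(R, TripleSet) else frozenset(R))
    if not triples:
        raise ValueError("cannot build a gene tree from an empty triple set")

    children: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    events: dict[int, Event] = {}
    sigma: dict[str, str] = {}
    counter = itertools.count()

    def leaf(k: int, i: int, species: str) -> int:
        v = next(counter)
        name = f"g{k}_{i}@{species}"
        labels[v] = name
        events[v] = Event.EXTANT
        sigma[name] = species
        return v

    roots = []
    for k, r in enumerate(triples, start=1):
        cherry = next(counter)
        events[cherry] = Event.SPECIATION
        children[cherry] = [leaf(k, 1, r.a), leaf(k, 2, r.b)]
        top = next(counter)
        events[top] = Event.SPECIATION
        children[top] = [cherry, leaf(k, 3, r.outgroup)]
        roots.append(top)

    if len(roots) == 1:
        root = roots[0]
    elif binary:
        cur = roots[0]
        for nxt in roots[1:]:
            join = next(counter)
            events[join] = Event.DUPLICATION
            children[join] = [cur, nxt]
            cur = join
        root = cur
    else:
        root = next(counter)
        events[root] = Event.DUPLICATION
        children[root] = roots

    tree = PhyloTree(children, root, labels)
    # node ids survive construction unchanged, so events carry over directly
    return make_gene_tree(tree, events, sigma)


# ----------------------------------------------------------------------
# TSV I/O: three columns x, y, z meaning ((x,y),z); '#' comments
# ----------------------------------------------------------------------


def read_triples(text: str, labels: Optional[Iterable[str]] = None) -> TripleSet:
    out = set()
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"triple TSV line {lineno}: expected 3 columns")
        out.add(Triple(*parts))
    return TripleSet.of(out, labels)


def write_triples(R: TripleSet) -> str:
    lines = ["# x\ty\tz  meaning ((x,y),z)\n"]
    for r in sorted(R.triples):
        lines.append(f"{r.a}\t{r.b}\t{r.outgroup}\n")
    return "".join(lines)
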