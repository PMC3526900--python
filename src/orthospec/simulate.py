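"""Duplication-loss simulation of gene families along species trees.

Ground truth is generated in two stages.

**Species trees** follow an age model: a ranked topology grown by
successive uniformly random merges of lineages (balanced in
expectation), with internal vertices assigned uniformly ordered ages in
(0, 1), the root at age 1 and leaves at age 0.  The resulting trees are
ultrametric with unit root-to-leaf depth.  The extra root edge above the
crown is given the mean edge length of the topology, so duplications
predating the first speciation have somewhere to happen.

**Gene trees** evolve down the species tree.  A single gene lineage
enters the extra root edge.  On a species edge of length ``l`` each gene
lineage draws Poisson(rate * l) duplication and loss counts with
i.i.d. uniform positions, applied in temporal order: a loss terminates
the lineage, a duplication spawns a copy that evolves independently on
the remaining stretch of the edge.  At a speciation vertex every
surviving lineage is transmitted to both daughter edges; at a species
leaf the survivors become extant genes.  The constraint that every
species retains at least one gene copy (sigma(L) = B) is enforced
locally: the event draws of the lineages entering an edge are resampled
until at least one of them reaches the bottom, which by induction keeps
every species populated at any loss rate.

The *true* gene tree contains the loss leaves and every event; the
*observable* gene tree is its restriction to the extant genes, with
degree-two vertices suppressed and event labels carried over.  The true
reconciliation map (speciations to species vertices, duplications and
losses to species edges with their positions) is recorded for every
vertex.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .labeled import Event, GeneTree, SpeciesTree, make_gene_tree, make_species_tree
from .trees import PhyloTree

__all__ = [
    "SimulationParams",
    "TrueScenario",
    "sim_species_tree",
    "sim_gene_tree",
    "observable",
    "draw_event_positions",
]

_MAX_EDGE_RESAMPLES = 10_000


@dataclass(frozen=True)
class SimulationParams:
    """Duplication-loss simulation parameters.

    Rates are per unit branch length; with unit-depth species trees a
    rate of 1.0 means one expected event per root-to-leaf path per
    lineage.
    """

    n_species: int
    dup_rate: float
    loss_rate: float
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("need at least three species")
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be nonnegative")


@dataclass
class TrueScenario:
    """A complete simulated history and its observable part."""

    species_tree: SpeciesTree
    true_tree: PhyloTree
    true_events: Mapping[int, Event]
    mu_hat: Mapping[int, tuple]  # ("vertex", w) | ("edge", (u, v), position)
    observable_tree: GeneTree
    obs_to_true: Mapping[int, int]  # observable vertex -> true-tree vertex
    params: SimulationParams

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.true_events.values() if e is Event.DUPLICATION)

    @property
    def n_losses(self) -> int:
        return sum(1 for e in self.true_events.values() if e is Event.LOSS)


# ----------------------------------------------------------------------
# species trees (age model)
# ----------------------------------------------------------------------


def sim_species_tree(n: int, rng: np.random.Generator) -> SpeciesTree:
    """Ultrametric binary species tree on ``n >= 3`` species, unit depth.

    Ranked topology by successive uniform random merges; internal ages
    uniformly ordered in (0, 1) with the root at age 1, leaves at age 0.
    """
    if n < 3:
        raise ValueError("need at least three species")
    labels = [f"s{i}" for i in range(1, n + 1)]
    children: dict[int, tuple] = {}
    label_map = {i: lab for i, lab in enumerate(labels)}
    age = {i: 0.0 for i in range(n)}
    active = list(range(n))
    next_id = n
    internal_ages = np.sort(rng.uniform(0.0, 1.0, size=n - 2)) if n > 2 else []
    merge_ages = list(internal_ages) + [1.0]
    for a in merge_ages:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        u, v = active[i], active[j]
        children[next_id] = (u, v)
        age[next_id] = float(a)
        active = [x for x in active if x not in (u, v)] + [next_id]
        next_id += 1
    root = active[0]
    lengths = {}
    for p, kids in children.items():
        for c in kids:
            lengths[c] = age[p] - age[c]
    topo = PhyloTree(children, root, label_map, lengths)
    s = make_species_tree(topo)
    # extra root edge: mean edge length of the topology
    mean_len = float(np.mean([lengths[c] for c in lengths]))
    # rebuild with lengths carried over plus the root edge
    children_aug = {
        v: s.tree.children(v) for v in s.tree.postorder() if not s.tree.is_leaf(v)
    }
    labels_aug = {
        v: s.tree.label(v) for v in s.tree.postorder() if s.tree.is_leaf(v)
    }
    full_lengths = {}
    # map: the augmented tree reused the topology's vertex ids
    for v in s.tree.postorder():
        if v == s.rho:
            continue
        if v == s.crown:
            full_lengths[v] = mean_len
        else:
            full_lengths[v] = topo.length(v)
    aug = PhyloTree(
        children_aug, s.rho, labels_aug, full_lengths, allow_unary_root=True
    )
    return SpeciesTree(aug)


# ----------------------------------------------------------------------
# gene trees
# ----------------------------------------------------------------------


def draw_event_positions(
    rate: float, length: float, rng: np.random.Generator, start: float = 0.0
) -> list:
    """Positions of a Poisson(rate * (length - start)) number of events,
    i.i.d. uniform on (start, length), sorted by time."""
    if rate <= 0 or length <= start:
        return []
    k = rng.poisson(rate * (length - start))
    return sorted(rng.uniform(start, length, size=k).tolist())


@dataclass
class _Lineage:
    """Sampled fate of one gene lineage on one species edge.

    ``steps`` is the time-ordered list of duplications applied to the
    continuing lineage, each carrying the independently evolved offspring
    copy; ``lost_at`` is the loss position terminating the lineage, or
    None if it survives to the bottom of the edge.
    """

    steps: list = field(default_factory=list)  # [(position, _Lineage offspring)]
    lost_at: Optional[float] = None

    def survivors(self) -> int:
        n = 0 if self.lost_at is not None else 1
        return n + sum(off.survivors() for _, off in self.steps)


def _evolve_lineage(
    start: float, length: float, params: SimulationParams, rng: np.random.Generator
) -> _Lineage:
    dup_pos = draw_event_positions(params.dup_rate, length, rng, start)
    loss_pos = draw_event_positions(params.loss_rate, length, rng, start)
    events = sorted(
        [(p, "D") for p in dup_pos] + [(p, "X") for p in loss_pos]
    )
    lin = _Lineage()
    for pos, kind in events:
        if kind == "X":
            lin.lost_at = pos
            break  # later events of a dead lineage never happen
        lin.steps.append((pos, _evolve_lineage(pos, length, params, rng)))
    return lin


def _edge_lineages(
    k: int, length: float, params: SimulationParams, rng: np.random.Generator
) -> list:
    """Fates of the ``k`` lineages entering a species edge, conditioned on
    at least one gene copy reaching the bottom (sigma(L) = B)."""
    for _ in range(_MAX_EDGE_RESAMPLES):
        lins = [_evolve_lineage(0.0, length, params, rng) for _ in range(k)]
        if sum(l.survivors() for l in lins) >= 1:
            return lins
    raise RuntimeError(
        "edge conditioning failed: no surviving lineage in "
        f"{_MAX_EDGE_RESAMPLES} resamples"
    )


class _GeneTreeBuilder:
    def __init__(self) -> None:
        self.children: dict[int, list] = {}
        self.labels: dict[int, str] = {}
        self.events: dict[int, Event] = {}
        self.mu: dict[int, tuple] = {}
        self._counter = itertools.count()
        self.root: Optional[int] = None
        self._species_gene_count: dict[str, int] = {}

    def new_node(
        self, parent: Optional[int], event: Event, image: tuple
    ) -> int:
        v = next(self._counter)
        self.events[v] = event
        self.mu[v] = image
        if parent is None:
            self.root = v
        else:
            self.children.setdefault(parent, []).append(v)
        return v

    def new_loss(self, parent: Optional[int], edge: tuple, pos: float) -> int:
        v = self.new_node(parent, Event.LOSS, ("edge", edge, pos))
        self.labels[v] = f"loss{v}"
        return v

    def new_extant(self, parent: Optional[int], species: str, node: int) -> int:
        v = self.new_node(parent, Event.EXTANT, ("vertex", node))
        i = self._species_gene_count.get(species, 0) + 1
        self._species_gene_count[species] = i
        self.labels[v] = f"{species}_{i}@{species}"
        return v


def sim_gene_tree(
    s: SpeciesTree,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
) -> TrueScenario:
    """Simulate one gene family along ``s``; returns the full scenario.

    Requires edge lengths on the species tree (as produced by
    :func:`sim_species_tree`).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    stree = s.tree
    if not stree.has_lengths:
        raise ValueError("species tree must carry edge lengths")
    b = _GeneTreeBuilder()

    def process_edge(sp_child: int, entering: list) -> None:
        """entering: gene-tree parent handles (None = tree root pending)."""
        sp_parent = stree.parent(sp_child)
        edge = (sp_parent, sp_child)
        length = stree.length(sp_child)
        lins = _edge_lineages(len(entering), length, params, rng)
        survivors: list = []  # parent handles arriving at sp_child

        def materialize(parent, lin: _Lineage) -> None:
            cur = parent
            for pos, offspring in lin.steps:
                cur = b.new_node(cur, Event.DUPLICATION, ("edge", edge, pos))
                materialize(cur, offspring)
            if lin.lost_at is not None:
                b.new_loss(cur, edge, lin.lost_at)
            else:
                survivors.append(cur)

        for parent, lin in zip(entering, lins):
            materialize(parent, lin)
        if stree.is_leaf(sp_child):
            for parent in survivors:
                b.new_extant(parent, stree.label(sp_child), sp_child)
        else:
            arrived = [
                b.new_node(parent, Event.SPECIATION, ("vertex", sp_child))
                for parent in survivors
            ]
            for daughter in stree.children(sp_child):
                process_edge(daughter, list(arrived))

    process_edge(s.crown, [None])
    true_tree = PhyloTree(b.children, b.root, b.labels)
    obs, obs_map, sigma = _observable(true_tree, b.events, b.labels)
    return TrueScenario(
        species_tree=s,
        true_tree=true_tree,
        true_events=b.events,
        mu_hat=b.mu,
        observable_tree=obs,
        obs_to_true=obs_map,
        params=params,
    )


def _observable(true_tree: PhyloTree, events, labels) -> tuple:
    extant = [
        true_tree.label(v)
        for v in true_tree.postorder()
        if true_tree.is_leaf(v) and events[v] is Event.EXTANT
    ]
    if len(extant) < 3:
        raise ValueError(
            f"only {len(extant)} extant genes: no observable gene tree"
        )
    restricted, node_map = true_tree.restrict(extant, with_map=True)
    obs_events = {v: events[node_map[v]] for v in restricted.postorder()}
    sigma = {lab: lab.rsplit("@", 1)[1] for lab in restricted.leaf_labels}
    g = make_gene_tree(restricted, obs_events, sigma)
    return g, node_map, sigma


def observable(ts: TrueScenario) -> GeneTree:
    """The observable event-labeled gene tree of a scenario: the true tree
    restricted to extant genes, degree-two vertices suppressed, event
    labels carried over."""
    return ts.observable_tree
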