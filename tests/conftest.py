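"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own algorithms: tree
enumeration is by recursive set partition, lca by root-path
intersection, and triple extraction by direct definition over all
three-leaf subsets.  They are used to freeze and cross-check expected
values at small sizes.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import orthospec as osp
from orthospec import Event, PhyloTree, Triple


# ----------------------------------------------------------------------
# independent oracles
# ----------------------------------------------------------------------


def set_partitions(items):
    """All partitions of a list into unordered nonempty blocks."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def all_rooted_trees(labels):
    """Every rooted phylogenetic tree on the given labels, as nested tuples.

    Interior vertices have outdegree >= 2; polytomies included.
    """
    labels = sorted(labels)
    if len(labels) == 1:
        return [labels[0]]
    out = []
    for part in set_partitions(labels):
        if len(part) < 2:
            continue
        blocks = sorted(part, key=min)
        for combo in itertools.product(*(all_rooted_trees(b) for b in blocks)):
            out.append(tuple(combo))
    return out


def naive_lca(tree: PhyloTree, labels) -> int:
    """lca by intersecting root paths (independent of the fast path)."""
    paths = []
    for lab in labels:
        v = tree.node_of(lab)
        path = []
        while v is not None:
            path.append(v)
            v = tree.parent(v)
        paths.append(path)
    common = set(paths[0]).intersection(*map(set, paths[1:]))
    # deepest common vertex = first on any root path
    for v in paths[0]:
        if v in common:
            return v
    raise AssertionError("no common ancestor")  # pragma: no cover


def brute_informative_triples(g) -> frozenset:
    """Gene-level informative triples straight from the definition:
    all three-leaf subsets, speciation lca, pairwise distinct species."""
    tree = g.tree
    out = set()
    for xs in itertools.combinations(sorted(tree.leaf_labels), 3):
        if len({g.sigma[x] for x in xs}) != 3:
            continue
        if g.events[tree.lca(xs)] is not Event.SPECIATION:
            continue
        top = tree.lca(xs)
        for a, b, c in (
            (xs[0], xs[1], xs[2]),
            (xs[0], xs[2], xs[1]),
            (xs[1], xs[2], xs[0]),
        ):
            if tree.lca((a, b)) != top:
                out.add(Triple(a, b, c))
                break
    return frozenset(out)


def brute_is_consistent(triples, labels) -> bool:
    """Consistency by exhaustive enumeration of all rooted trees."""
    triples = frozenset(triples)
    if not triples:
        return True
    for nested in all_rooted_trees(sorted(labels)):
        if isinstance(nested, str):
            continue
        t = PhyloTree.from_nested(nested)
        if all(t.displays_triple(r) for r in triples):
            return True
    return False


def random_nested(labels, rng, max_block=3):
    """Random rooted topology (with polytomies) on the given labels."""
    labels = list(labels)
    if len(labels) == 1:
        return labels[0]
    k = int(rng.integers(2, min(len(labels), max_block) + 1))
    rng.shuffle(labels)
    # split into k nonempty blocks
    cuts = sorted(rng.choice(np.arange(1, len(labels)), size=k - 1, replace=False))
    blocks, prev = [], 0
    for c in list(cuts) + [len(labels)]:
        blocks.append(labels[prev:c])
        prev = c
    return tuple(random_nested(b, rng, max_block) for b in blocks)


def contract_edge(tree: PhyloTree, parent: int, child: int) -> PhyloTree:
    """Contract an interior edge: the child's children move to the parent."""
    assert not tree.is_leaf(child)
    children = {}
    for v in tree.postorder():
        if tree.is_leaf(v) or v == child:
            continue
        kids = []
        for c in tree.children(v):
            if v == parent and c == child:
                kids.extend(tree.children(child))
            else:
                kids.append(c)
        children[v] = kids
    labels = {v: tree.label(v) for v in tree.postorder() if tree.is_leaf(v)}
    return PhyloTree(children, tree.root, labels)


# ----------------------------------------------------------------------
# fixtures
# ----------------------------------------------------------------------


@pytest.fixture(scope="session")
def sim_batch():
    """200 simulated scenarios across the full rate range (seeded).

    Species counts 5-12 keep per-replicate validation cheap while still
    exercising multi-copy gene families.
    """
    rng = np.random.default_rng(20120919)
    batch = []
    for _ in range(200):
        n = int(rng.integers(5, 13))
        dup = float(rng.uniform(0.0, 1.0))
        loss = float(rng.uniform(0.0, 1.0))
        s = osp.sim_species_tree(n, rng)
        ts = osp.sim_gene_tree(s, osp.SimulationParams(n, dup, loss), rng)
        batch.append(ts)
    return batch


@pytest.fixture()
def example_gene_tree():
    """Five genes in three species, one duplication at the root; its only
    informative triple is ((b1,c1),a1)."""
    return osp.read_gene_tree(
        "((a1@A,(b1@B,c1@C)[&&NHX:Ev=S])[&&NHX:Ev=S],"
        "(a2@A,b2@B)[&&NHX:Ev=S])[&&NHX:Ev=D];"
    )
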