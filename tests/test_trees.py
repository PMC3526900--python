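"""Core tree model: Newick I/O, lca, restriction, display, triples."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orthospec import (
    NewickParseError,
    PhyloTree,
    TreeValidationError,
    Triple,
    all_triples,
    clusters,
    displays,
    parse_newick,
    restrict,
    write_newick,
)
from conftest import all_rooted_trees, naive_lca, random_nested


class TestParseNewick:
    def test_smallest_tree(self):
        t = parse_newick("((a,b),c);")
        assert t.leaf_labels == {"a", "b", "c"}
        assert len(t) == 5
        assert t.lca(("a", "b", "c")) == t.root

    def test_polytomy_allowed(self):
        t = parse_newick("(a,b,c);")
        assert len(t.interior()) == 1

    def test_unary_vertex_rejected(self):
        with pytest.raises(TreeValidationError, match="in- and outdegree one"):
            parse_newick("((a),b);")

    def test_duplicate_leaf_names_rejected(self):
        with pytest.raises(TreeValidationError, match="duplicate"):
            parse_newick("((a,b),a);")

    @pytest.mark.parametrize("bad", ["((a,b),c)", "((a,b),c;", "(a,,b);"])
    def test_malformed_syntax(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)

    def test_quoted_labels(self):
        t = parse_newick("(('sp one','sp two'),x);")
        assert "sp one" in t.leaf_labels


class TestWriteNewick:
    def test_canonical_order(self):
        assert write_newick(parse_newick("((b,a),c);")) == "((a,b),c);"
        assert write_newick(parse_newick("(c,(b,a));")) == "((a,b),c);"

    def test_roundtrip_equivalence(self):
        rng = np.random.default_rng(5)
        labels = [f"t{i}" for i in range(9)]
        for _ in range(30):
            t = PhyloTree.from_nested(random_nested(labels, rng))
            assert parse_newick(write_newick(t)).equivalent(t)

    def test_lengths_preserved(self):
        text = "((a:1.5,b:2):0.5,c:1);"
        t = parse_newick(text)
        t2 = parse_newick(write_newick(t))
        for lab in "abc":
            assert t2.length(t2.node_of(lab)) == pytest.approx(
                t.length(t.node_of(lab))
            )
        assert write_newick(t) == "((a:1.5,b:2):0.5,c:1);"


class TestLca:
    def test_singleton(self):
        t = parse_newick("((a,b),c);")
        assert t.lca(("a",)) == t.node_of("a")

    def test_forced_by_topology(self):
        t = parse_newick("((a,b),c);")
        assert t.lca(("a", "b")) != t.root
        assert t.lca(("a", "c")) == t.root
        assert t.lca(t.leaf_labels) == t.root

    def test_outside_leafset_rejected(self):
        with pytest.raises(ValueError, match="not in the tree"):
            parse_newick("((a,b),c);").lca(("a", "zz"))

    def test_agrees_with_root_path_oracle(self):
        rng = np.random.default_rng(11)
        labels = [f"t{i}" for i in range(20)]
        for _ in range(20):
            t = PhyloTree.from_nested(random_nested(labels, rng))
            for _ in range(10):
                k = int(rng.integers(1, 6))
                sub = list(rng.choice(labels, size=k, replace=False))
                assert t.lca(sub) == naive_lca(t, sub)


class TestRestrict:
    def test_two_leaves(self):
        r = restrict(parse_newick("((a,b),c);"), {"a", "c"})
        assert write_newick(r) == "(a,c);"

    def test_identity(self):
        t = parse_newick("((a,(b,(c,d))),e);")
        assert restrict(t, t.leaf_labels).equivalent(t)

    def test_interior_path_suppressed(self):
        t = parse_newick("(a,(b,(c,d)));")
        r = restrict(t, {"a", "d"})
        assert write_newick(r) == "(a,d);"
        assert all(
            len(r.children(v)) != 1 for v in r.postorder()
        ), "no degree-2 vertices may remain"

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        labels = [f"t{i}" for i in range(10)]
        for _ in range(20):
            t = PhyloTree.from_nested(random_nested(labels, rng))
            sub = set(rng.choice(labels, size=5, replace=False))
            once = t.restrict(sub)
            assert once.restrict(sub).equivalent(once)

    def test_lengths_summed_over_suppressed_path(self):
        t = parse_newick("((a:1,(b:1,c:1):2):3,d:6);")
        r = t.restrict({"a", "b", "d"})
        # path b -> (b,c) vertex -> (a,(b,c)) vertex collapses: 1 + 2
        assert r.length(r.node_of("b")) == pytest.approx(3.0)
        assert r.length(r.node_of("d")) == pytest.approx(6.0)

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            restrict(parse_newick("((a,b),c);"), {"a"})


class TestDisplays:
    def test_examples(self):
        t = parse_newick("((a,b),(c,d));")
        assert displays(t, parse_newick("((a,b),c);"))
        assert not displays(t, parse_newick("((a,c),b);"))

    def test_star_does_not_display_resolved_triple(self):
        star = parse_newick("(a,b,c);")
        assert not displays(star, parse_newick("((a,b),c);"))

    def test_leafset_violation(self):
        with pytest.raises(ValueError):
            displays(parse_newick("((a,b),c);"), parse_newick("((a,b),z);"))


class TestAllTriples:
    def test_examples(self):
        assert all_triples(parse_newick("((a,b),c);")) == {Triple("a", "b", "c")}
        assert all_triples(parse_newick("((a,b),(c,d));")) == {
            Triple("a", "b", "c"),
            Triple("a", "b", "d"),
            Triple("c", "d", "a"),
            Triple("c", "d", "b"),
        }
        assert all_triples(parse_newick("(a,b,c,d);")) == frozenset()

    def test_binary_tree_has_all_three_subsets_resolved(self):
        t = parse_newick("(((a,b),(c,d)),(e,f));")
        n = len(t.leaf_labels)
        assert len(all_triples(t)) == n * (n - 1) * (n - 2) // 6

    def test_every_triple_is_displayed(self):
        rng = np.random.default_rng(7)
        labels = [f"t{i}" for i in range(7)]
        for _ in range(10):
            t = PhyloTree.from_nested(random_nested(labels, rng))
            for r in all_triples(t):
                assert t.displays_triple(r)
                assert displays(t, r.as_tree())

    def test_each_three_subset_star_or_unique_triple(self):
        """On every tree with <= 5 leaves, each 3-subset restricts to a star
        or to exactly one of the three possible triples."""
        labels = ["a", "b", "c", "d", "e"]
        for nested in all_rooted_trees(labels):
            t = PhyloTree.from_nested(nested)
            shown = all_triples(t)
            for xs in itertools.combinations(labels, 3):
                candidates = [
                    r
                    for r in (
                        Triple(xs[0], xs[1], xs[2]),
                        Triple(xs[0], xs[2], xs[1]),
                        Triple(xs[1], xs[2], xs[0]),
                    )
                    if r in shown
                ]
                sub = t.restrict(xs)
                if len(sub.interior()) == 2:
                    assert len(candidates) == 1
                else:
                    assert candidates == []


class TestClusters:
    def test_examples(self):
        assert clusters(parse_newick("((a,b),c);")) == {
            frozenset("ab"),
            frozenset("abc"),
        }
        assert clusters(parse_newick("(a,b,c);")) == {frozenset("abc")}

    def test_caterpillar_count(self):
        n = 8
        nested = "t0"
        for i in range(1, n):
            nested = (nested, f"t{i}") if i == 1 else (nested, f"t{i}")
        t = PhyloTree.from_nested(nested)
        assert len(clusters(t)) == n - 1


class TestTriple:
    @given(st.permutations(["x", "y", "z"]))
    @settings(max_examples=6, deadline=None)
    def test_cherry_symmetry(self, perm):
        a, b, z = perm
        assert Triple(a, b, z) == Triple(b, a, z)
        assert Triple(a, b, z) != Triple(a, z, b) or b == z

    def test_distinct_labels_required(self):
        with pytest.raises(ValueError):
            Triple("x", "x", "y")


def test_enumeration_oracle_counts():
    # rooted phylogenetic trees on n labeled leaves: 1, 4, 26, 236
    assert len(all_rooted_trees(["a", "b"])) == 1
    assert len(all_rooted_trees(["a", "b", "c"])) == 4
    assert len(all_rooted_trees(["a", "b", "c", "d"])) == 26
    assert len(all_rooted_trees(["a", "b", "c", "d", "e"])) == 236
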