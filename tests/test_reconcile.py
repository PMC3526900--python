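"""Reconciliation map construction, validation, and placement freedom."""

import pytest

import orthospec as osp
from orthospec import (
    EdgeImage,
    Event,
    ReconciliationError,
    VertexImage,
    construct_reconciliation,
    enumerate_duplication_placements,
    infer_species_tree,
    read_gene_tree,
    read_species_tree,
    species_triples,
    validate_reconciliation,
)
from orthospec.reconcile import (
    read_reconciliation_tsv,
    write_reconciliation_tsv,
)


@pytest.fixture()
def mirror_case():
    """Gene tree mirroring the species tree: one gene per species, all
    speciations; the map is forced everywhere."""
    g = read_gene_tree(
        "((a1@A,b1@B)[&&NHX:Ev=S],(c1@C,d1@D)[&&NHX:Ev=S])[&&NHX:Ev=S];"
    )
    s = read_species_tree("((A,B),(C,D));")
    return g, s


class TestConstruct:
    def test_topology_isomorphism_when_no_duplications(self, mirror_case):
        g, s = mirror_case
        mu = construct_reconciliation(g, s)
        for v in g.tree.postorder():
            img = mu[v]
            assert isinstance(img, VertexImage)
            if g.tree.is_leaf(v):
                assert s.tree.label(img.node) == g.sigma[g.tree.label(v)]
            else:
                assert s.tree.leafset(img.node) == {
                    g.sigma[x] for x in g.tree.leafset(v)
                }

    def test_root_duplication_maps_to_extra_edge(self):
        g = read_gene_tree(
            "((a1@A,b1@B)[&&NHX:Ev=S],(a2@A,b2@B)[&&NHX:Ev=S])[&&NHX:Ev=D];"
        )
        s = read_species_tree("(A,B);")
        mu = construct_reconciliation(g, s)
        assert mu[g.tree.root] == EdgeImage(*s.root_edge)

    def test_precondition_enforced(self):
        g = read_gene_tree("((a1@A,b1@B)[&&NHX:Ev=S],c1@C)[&&NHX:Ev=S];")
        wrong = read_species_tree("((A,C),B);")
        with pytest.raises(ReconciliationError, match="does not display"):
            construct_reconciliation(g, wrong)

    def test_matches_true_map_on_speciations(self, sim_batch):
        """The constructed map to the *true* species tree agrees with the
        simulator's ground-truth map on every observable speciation
        vertex (speciation images are forced)."""
        for ts in sim_batch[:40]:
            g = ts.observable_tree
            mu = construct_reconciliation(g, ts.species_tree)
            for v in g.tree.postorder():
                if g.events[v] is Event.SPECIATION:
                    kind, node = ts.mu_hat[ts.obs_to_true[v]][:2]
                    assert kind == "vertex"
                    assert mu[v] == VertexImage(node)


class TestValidate:
    def test_constructed_map_is_valid(self, sim_batch):
        for ts in sim_batch[:40]:
            g = ts.observable_tree
            mu = construct_reconciliation(g, ts.species_tree)
            assert validate_reconciliation(g, ts.species_tree, mu) == []

    def test_tampered_duplication_rootward_of_speciation(self):
        """Moving a duplication image above an ancestral speciation image
        breaks the strict order requirement."""
        g = read_gene_tree("((a1@A,a2@A)[&&NHX:Ev=D],d1@D)[&&NHX:Ev=S];")
        s = read_species_tree("(((A,B),C),D);")
        mu = construct_reconciliation(g, s)
        dup = next(
            v for v in g.tree.postorder() if g.events[v] is Event.DUPLICATION
        )
        bad = mu.with_image(dup, EdgeImage(*s.root_edge))
        clauses = {v.clause for v in validate_reconciliation(g, s, bad)}
        assert "iv.2" in clauses

    def test_tampered_speciation_image(self, mirror_case):
        g, s = mirror_case
        mu = construct_reconciliation(g, s)
        bad = mu.with_image(g.tree.root, VertexImage(s.tree.node_of("A")))
        clauses = {v.clause for v in validate_reconciliation(g, s, bad)}
        assert "v" in clauses and "ii" in clauses

    def test_wrong_image_kind_reported(self, mirror_case):
        g, s = mirror_case
        mu = construct_reconciliation(g, s)
        bad = mu.with_image(g.tree.root, EdgeImage(*s.root_edge))
        clauses = {v.clause for v in validate_reconciliation(g, s, bad)}
        assert "ii" in clauses

    def test_non_total_map_rejected(self, mirror_case):
        g, s = mirror_case
        mu = construct_reconciliation(g, s)
        partial = osp.ReconciliationMap(
            {v: img for v, img in mu.images.items() if v != g.tree.root}
        )
        with pytest.raises(ValueError, match="not total"):
            validate_reconciliation(g, s, partial)

    def test_lca_domination_inequality_holds(self, sim_batch):
        """lca_S(mu(x), mu(y)) stays below mu(lca_T(x, y)) for all pairs;
        the validator reports it as Eq1, so an empty report suffices."""
        for ts in sim_batch[:40]:
            g = ts.observable_tree
            s = infer_species_tree(g)
            mu = construct_reconciliation(g, s)
            assert validate_reconciliation(g, s, mu) == []


class TestPlacementFreedom:
    def test_no_duplications_unique_map(self, mirror_case):
        g, s = mirror_case
        assert len(enumerate_duplication_placements(g, s)) == 1

    def test_three_placements_along_root_path(self):
        g = read_gene_tree("((a1@A,a2@A)[&&NHX:Ev=D],d1@D)[&&NHX:Ev=S];")
        s = read_species_tree("(((A,B),C),D);")
        maps = enumerate_duplication_placements(g, s, limit=10)
        assert len(maps) == 3
        non_dups = [
            v for v in g.tree.postorder() if g.events[v] is not Event.DUPLICATION
        ]
        for mu in maps:
            assert validate_reconciliation(g, s, mu) == []
            assert all(mu[v] == maps[0][v] for v in non_dups)

    def test_freedom_grows_with_path_depth(self):
        shallow = read_species_tree("((A,B),D);")
        deep = read_species_tree("((((A,E),B),C),D);")
        g = read_gene_tree("((a1@A,a2@A)[&&NHX:Ev=D],d1@D)[&&NHX:Ev=S];")
        assert len(
            enumerate_duplication_placements(g, deep, limit=20)
        ) > len(enumerate_duplication_placements(g, shallow, limit=20))


class TestRegression:
    def test_duplication_rooted_triple_contradicts_species_tree(self):
        """A triple rooted in a duplication may contradict the true species
        tree; the informative set excludes it, and reconciliation to the
        truth still succeeds."""
        g = read_gene_tree("((x1@X,z1@Z)[&&NHX:Ev=S],y1@Y)[&&NHX:Ev=D];")
        s = read_species_tree("((X,Y),Z);")
        assert not s.displays_triple(osp.Triple("X", "Z", "Y"))
        assert len(species_triples(g)) == 0
        mu = construct_reconciliation(g, s)
        assert validate_reconciliation(g, s, mu) == []

    def test_existence_round_trip(self, sim_batch):
        """A species tree is inferable iff the constructed reconciliation to
        it succeeds; on simulated data both always hold."""
        for ts in sim_batch[:30]:
            g = ts.observable_tree
            s = infer_species_tree(g)  # must not raise
            mu = construct_reconciliation(g, s)
            assert validate_reconciliation(g, s, mu) == []


class TestTSV:
    def test_roundtrip(self, mirror_case):
        g, s = mirror_case
        mu = construct_reconciliation(g, s)
        text = write_reconciliation_tsv(mu, g, s)
        mu2 = read_reconciliation_tsv(text, g, s)
        assert mu2.images == dict(mu.images)
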