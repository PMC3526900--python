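# Methods

## Trees, order conventions, and equivalence

A phylogenetic tree is rooted, with uniquely labeled leaves and no
vertex of in- and outdegree one.  Edges are directed parent→child; for
an edge e = [u, v] the child v lies *below* u (v ≺ u in the ancestor
order ≼).  The order is extended to edges the standard way: for a vertex
x and edge e = [u, v], x ≺ e iff x ≼ v and e ≺ x iff u ≼ x; for edges
e = [u, v] and f = [a, b], e ≼ f iff v ≼ b.

Two trees are equivalent when a bijection fixing the leaves and the
roots extends to a graph isomorphism.  We decide this with a canonical
form — children ordered by their smallest descendant leaf label — which
also makes every serialization deterministic.  Restriction to a leaf
subset keeps the vertices with at least two children carrying selected
leaves (plus the subset's lca as root) and sums edge lengths along
suppressed paths.

Species trees carry one deliberate exception to the degree rule: an
extra root vertex ρ_S with a single child, the crown lca_S(B).  The edge
[ρ_S, lca_S(B)] is where duplications older than the first speciation
map.  Triples, displaying and clusters of a species tree are those of
its unaugmented topology on B; ρ_S is excluded from interior-vertex
counts and never receives a reconciliation image.

## Event-labeled gene trees

A gene tree is the 3-tuple (T, t, σ): topology on the gene set L
(|L| ≥ 3), event map t (speciation / duplication on interior vertices,
extant on leaves), species assignment σ: L → B with B = σ(L) unless a
larger universe is given explicitly.  The single compatibility axiom is
condition (C): below any two distinct children of a *speciation* vertex
the species sets are disjoint.  A consequence used as a test invariant:
two distinct genes residing in the same species always coalesce in a
duplication.  The converse is never applied — disjointness does not
force a speciation label — and t need not be discriminating (adjacent
equal labels are allowed).

Constructors validate loudly: misplaced labels, partial maps, loss
labels in observable trees, and each condition-(C) violation (named
speciation vertex, child pair, shared species) are errors.

File conventions (chosen here; the underlying theory prescribes none):
NHX tags `[&&NHX:Ev=S|D]` on interior Newick nodes, species encoded in
leaf names as `gene@species` with an optional two-column TSV override.

## Informative triples and species-tree inference

The informative gene triples 𝔾 are the triples of T whose root (the lca
of their three leaves) is a speciation and whose leaves lie in three
pairwise distinct species; 𝔊 is their σ-image with set semantics.
Structurally, a member of 𝔾 is a pair of genes from different species
below one child of a speciation vertex plus an outgroup gene below
another child, so 𝔊 is computed directly from per-vertex species sets
without materializing 𝔾; a randomized test pins the fast path to the
σ-image of the definitional enumeration.

Consistency of 𝔊 is decided by BUILD with canonicalized recursion
(components sorted by smallest label): deterministic output, and on
failure a certificate — the label subset whose Aho graph is connected.
Connected components come from networkx.  Labels of B named by no triple
attach as singleton components at the top level.  BUILD's output is
minor-minimal but not unique and not vertex-minimal; enumerating all
minor-minimal trees, finding vertex-minimal ones, and repairing an
inconsistent 𝔊 via maximum consistent subsets are out of scope.

The reverse construction (any triple set over species, consistent or
not, is 𝔊 of some gene tree) joins one speciation-rooted triple subtree
per input triple, with fresh genes `g<k>_<i>@<species>`, under a
duplication root.  Degenerate case: with a single input triple the
literal construction would give the root outdegree one, so the
duplication root is omitted; a `binary=True` flag replaces the
multifurcating root by a caterpillar of duplications (losses implied by
that refinement are not materialized — observable trees carry none).

## Reconciliation maps

μ maps extant genes to their species leaf, speciations to
lca_S(σ(L(x))) — both forced — and duplications to edges.  The canonical
map places each duplication on the edge immediately above
lca_S(σ(L(x))); it exists exactly when S displays all of 𝔊 (checked as
a precondition, with the undisplayed triples listed).  All σ(L(x)) come
from one bottom-up pass and each lca_S from a climb of the species tree,
within the O(|L||B|) contract; no sparse-table lca preprocessing is
attempted at this scale.

The validator re-checks everything rather than trusting the
constructor: leaf anchoring, image types (speciations to interior
non-root vertices, duplications to edges), strict ancestor-order
preservation except between two duplications (where equality of edge
images is allowed — two nested duplications may share an edge), the lca
anchoring of speciation images, the derived facts that any vertex image
equals lca_S(σ(L(x))) and any edge image lies strictly above it, and the
inequality lca_S(μ(x), μ(y)) ≼ μ(lca_T(x, y)) over all vertex pairs.
The derived clauses are theorems for any valid map, so their violation
tags (D1–D3, Eq1) flag implementation bugs.  All violations are
reported, not just the first.

Alternative maps differ only on duplications: candidates for each
duplication are the edges from the canonical one up the root path,
screened through the validator in deterministic order.  Enumeration is
exhaustive-with-limit; it is meant for inspecting placement freedom on
small instances, not for counting the (possibly exponential) full set.

## Simulator

**Species trees (age model).**  Ranked topology by successive uniformly
random merges of lineages; internal vertices receive uniformly ordered
ages in (0, 1), root age 1, leaves age 0.  The trees are ultrametric
with unit root-to-leaf depth and balanced in expectation.  This is a
stand-in realization reproducing the two properties the original age
model is used for (balance, unit depth); the branching-order
distribution of the original model is not restated anywhere accessible,
so the exact law may differ.  The extra root edge gets the mean edge
length of the topology — a convention needed only so that pre-speciation
duplications have a Poisson exposure.

**Gene trees.**  One lineage enters the root edge.  Per species edge of
length ℓ, each gene lineage draws Poisson(r_dup·ℓ) duplications and
Poisson(r_loss·ℓ) losses with i.i.d. uniform positions, applied in
temporal order: a loss ends the lineage (later drawn events are
discarded), a duplication spawns a copy that evolves independently on
the remainder of the edge with fresh draws.  Speciation transmits every
surviving lineage to both daughter edges; survivors at species leaves
become extant genes.  Rates live in [0, 1] in the experiments but any
nonnegative value is accepted.

**Retention constraint (σ(L) = B).**  The requirement that every
species keeps at least one gene copy is enforced locally: the joint
event draws of the lineages entering an edge are resampled until at
least one lineage reaches the edge's bottom (capped at 10,000 attempts).
By induction along the tree every species leaf then receives a gene.
The alternative — rejecting entire gene trees — preserves the
unconditional per-edge law but its acceptance probability decays
geometrically in the species count and is out of reach in the high-loss
regime; the per-edge conditioning is the same constraint applied at the
finest scale where it is decidable.  Consequence worth knowing: on edges
entered by a single lineage, losses are effectively suppressed, so the
*realized* loss count is smaller than r_loss·(total tree length) at high
rates.

**Observable part.**  The true tree (with loss leaves and every event)
is restricted to extant genes; vertices left with fewer than two
surviving children are suppressed and event labels carry over.  The
observable tree always passes gene-tree validation — condition (C) holds
by construction — and the true reconciliation map (speciations at
species vertices, duplications and losses on edges with positions) is
recorded for every true-tree vertex, with an explicit
observable-to-true vertex correspondence for ground-truth comparisons.

**What the simulator does not emulate:** horizontal transfer, incomplete
lineage sorting, sequence evolution, and any error in the event labels
or in σ.  Passing tests therefore show that the *inference* machinery is
exact under the duplication-loss model with perfect annotations; they do
not certify robustness to mislabeled events, which real orthology
pipelines produce.

## Split recovery and the experiment

Recovery = 100 · |clusters(inferred) ∩ clusters(true)| / |clusters(true)|,
clusters taken over B with the root cluster included and ρ_S excluded.
When the inferred tree is a homomorphic contraction of the truth — the
typical outcome — this equals the interior-vertex ratio, and the
interior-vertex difference (reported as a diagnostic) is the rooted
split metric.  The contraction property is *monitored* per replicate
(`is_contraction` column), not assumed: BUILD may resolve a
multifurcation in a way no triple implies, and the simulations here do
hit occasional counterexamples (about 2 in 20 high-loss replicates),
which the tests surface as warnings with the full rows.

Drivers: a rate-grid experiment (defaults: 5×5 grid on [0,1]², species
counts uniform on 10–30, one replicate per cell) for the heat-map view,
and a uniform-sampling protocol for summary statistics.  The high-loss
headline run uses 20 trees with 10–30 species, r_loss ~ U[0.8, 1.0],
r_dup ~ U[0, 1]; these sizes keep the full pipeline comfortably
desk-scale (seconds) while exercising multi-copy, multi-loss families.
Every run is reproducible from a single integer seed: one generator is
threaded through all sampling, with per-replicate sub-seeds drawn below
2³¹.

## Numerical and degenerate-input choices

- Edge lengths are exact floats; ultrametricity of simulated trees is
  tested to 1e-9.  Lengths are serialized with `%.10g`.
- |B| = 1 is permitted for species trees (two vertices, one edge); 𝔊 is
  then empty and any inference is the trivial tree.  Gene trees require
  |L| ≥ 3; smaller inputs are rejected at construction.
- The empty triple set is consistent by convention; BUILD returns the
  star tree on the given universe.
- Ties everywhere (child order, component order, triple order) break by
  lexicographic label comparison, so equal inputs give byte-equal
  outputs.

## Known limitations

- BUILD returns one canonical minor-minimal tree; the constraint set
  rarely determines the species tree uniquely, and no attempt is made to
  enumerate or rank the alternatives.
- The duplication-placement enumerator is exponential in the number of
  duplication vertices and intended for small instances.
- The validator's pairwise order checks are quadratic in the gene-tree
  size; fine for trees with hundreds of vertices, not for genome-scale
  forests.
- The age-model realization is an approximation (see above); quantities
  that depend on fine topology statistics of the species-tree prior
  should be interpreted with that in mind.
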