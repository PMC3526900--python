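# orthospec

**Species trees from event-labeled gene trees.**

Orthology analysis marks each interior vertex of a gene tree *T* as a
speciation (the descendant genes are orthologs) or a duplication (they
are paralogs).  Together with the assignment σ of each extant gene to
the species it resides in, such an event-labeled gene tree (*T*, *t*, σ)
already constrains the species phylogeny — without reconciling against
any candidate species tree.  `orthospec` implements that inference and
quantifies, by simulation, how much species-tree signal event-labeled
gene trees carry under gene duplication and loss.

## The method

Not every rooted triple of *T* is trustworthy: a triple rooted in a
duplication can contradict the species phylogeny, because paralogs may
diverge long before the species carrying them do.  The *informative*
triples are

𝔾(*T*, *t*, σ) = { ((x,y),z) displayed by *T* : *t*(lca(x,y,z)) = speciation
and σ(x), σ(y), σ(z) pairwise distinct },

and their projection to species labels,
𝔊 = { ((σx, σy), σz) : ((x,y),z) ∈ 𝔾 }, is the constraint set:

- every species tree for (*T*, *t*, σ) displays all of 𝔊, and
- a species tree exists **iff** 𝔊 is consistent, decidable with the
  BUILD (Aho) algorithm, which also constructs a minor-minimal tree
  displaying 𝔊;
- given such a tree *S*, a reconciliation map μ: V(T) → W(S) ∪ H(S)
  always exists and is computable in O(|L||B|): extant genes anchor at
  their species, each speciation x maps to lca_S(σ(L(x))) (no freedom),
  and each duplication maps to an edge — canonically the one just above
  lca_S(σ(L(x))).

The package validates candidate maps against the full axiom set
(including the derived order-preservation inequality
lca_S(μ(x), μ(y)) ≼ μ(lca_T(x,y))), enumerates the alternative
duplication placements, and ships a duplication–loss simulator
(age-model ultrametric species trees, per-edge Poisson(r·ℓ) events) with
a split-recovery experiment driver.

## Worked example

A gene family over four species in which one lineage was duplicated
before the first speciation below it:

```python
import orthospec as osp

g = osp.read_gene_tree(
    "(((s1_1@s1,s2_1@s2)[&&NHX:Ev=S],(s1_2@s1,(s2_2@s2,s3_1@s3)[&&NHX:Ev=S])"
    "[&&NHX:Ev=S])[&&NHX:Ev=D],s4_1@s4)[&&NHX:Ev=S];"
)
for r in sorted(osp.species_triples(g)):
    print(r)
s = osp.infer_species_tree(g)
print(osp.write_species_tree(s))
mu = osp.construct_reconciliation(g, s)
print("violations:", osp.validate_reconciliation(g, s, mu))
```

prints

```
((s1,s2),s4)
((s1,s3),s4)
((s2,s3),s1)
((s2,s3),s4)
(((s1,(s2,s3)),s4));
violations: []
```

The four species triples rooted in speciations pin down the fully
resolved species tree `((s1,(s2,s3)),s4)` — the triples spanning the
duplication root (e.g. relating `s1_1` to `s1_2`'s subtree) were
discarded as uninformative.  The extra pair of parentheses in the output
is the distinguished root edge above lca(s1..s4), which exists so that
duplications predating all speciations have an edge to map to.  The
constructed reconciliation map passes every validity condition.

The same pipeline is available from the shell:

```bash
orthospec simulate --n-species 10 --dup-rate 0.5 --loss-rate 0.5 --seed 7 \
    --reps 1 --out-dir scenario/
orthospec infer -g scenario/rep0000.genetree.nhx --out inferred.nwk
orthospec reconcile -g scenario/rep0000.genetree.nhx -s inferred.nwk --out mu.tsv
orthospec validate -g scenario/rep0000.genetree.nhx -s inferred.nwk --reconciliation mu.tsv
```

`infer` exits with code 2 when no species tree exists (the triple set is
inconsistent), printing the certificate subset; `validate` exits 1 and
reports each violated condition.

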