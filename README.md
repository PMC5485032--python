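# diatomevo

Comparative-genomics and molecular-evolution toolkit built around the kind
of analyses used to characterize diatom genomes (the focal organism being a
*Pseudo-nitzschia*-like pennate diatom): protein-family clustering of
homology networks, Dollo-parsimony reconstruction of gene-family gains and
losses across Stramenopiles, phylogeny-based detection of horizontal gene
transfer from bacteria, discovery of conserved noncoding elements (CNEs)
from whole-genome alignments, gene-family expansion scoring, reciprocal-
best-hit orthology, NG86 Ka:Ks estimation and LTR insertion-age dating.

It is aimed at researchers who want these classic pipeline stages as
tested, reusable library functions — every stage is exercisable on
synthetic data with planted ground truth, so the statistical behaviour of
each method (recall, false-positive rate, calibration, estimator bias) can
be measured without genome-scale downloads.

## The methods

- **Family clustering** — an undirected homology graph weighted by best
  bitscore is clustered with the Markov Cluster algorithm: the
  column-stochastic flow matrix is alternately squared (expansion) and
  entry-wise powered with inflation *I* then renormalized, until the flow
  stabilizes; connected components of the limiting flow are the families.
- **Orphans and expansions** — orphan genes are focal-species proteins in
  singleton or focal-only clusters. Family expansion in the focal species
  is scored per family as `Z = (n_focal − mean(n)) / SD(n)` over all
  species' member counts.
- **Dollo parsimony** — each family arises exactly once; for a binary
  presence row the minimal history places the gain on the edge above the
  MRCA of the present leaves, with one loss per maximal absent subtree
  inside the gain clade. Per-edge gain/loss totals and per-species orphan
  counts are aggregated over all families.
- **HGT classification** — a gene is a transfer candidate when its
  (unrooted) gene tree contains a bipartition side with ≥ 90% of leaves
  from {bacteria, archaea, scope group}, no metazoa/plantae/fungi, at
  least 5 bacterial members (10 when the focal species is the only
  eukaryote in the clade), and support ≥ 0.5 at the clade or on average
  over the tree; weakly supported clades in well-supported trees are kept
  at medium confidence. The taxonomic scope widens from diatoms to
  stramenopiles to the SAR supergroup, and the same machinery with red
  algae as donor flags genes of red-algal origin.
- **CNE discovery** — a 20 bp window slides at 10 bp steps along the
  reference row of each alignment block; a window passes for a species
  when its column identity reaches the threshold (default 0.70) and it
  overlaps no gene in either genome. Passing windows merge into elements;
  a TSS-proximity test compares element–TSS distances with length-matched
  intergenic controls (Welch's t-test).
- **Molecular evolution** — Ka and Ks by Nei–Gojobori (1986) counting with
  equal-weight pathway averaging and Jukes–Cantor correction; nucleotide
  distances by the Kimura two-parameter formula
  `K = −½·ln((1−2P−Q)·√(1−2Q))`; LTR insertion ages as `T = K/(2r)` from
  sister-LTR divergence.

## Worked example

```python
from diatomevo import simulate, dollo, hgt, molevo

# gene-family gains and losses on a simulated 8-species tree
tree, taxa = simulate.simulate_species_tree(
    8, {"diatom": 0.5, "other-stramenopile": 0.5}, seed=42)
matrix, truth = simulate.simulate_dollo_families(tree, 500, seed=43, loss_prob=0.1)
recs = dollo.reconstruct_matrix(tree, matrix)
table = dollo.aggregate_events(recs, tree)
print("gains:", table.per_edge["gains"].sum(), "losses:", table.per_edge["losses"].sum())
# gains: 500 losses: 84

# a planted bacteria→diatom transfer is called at high confidence
gt, gtaxa, _ = simulate.simulate_gene_tree_with_hgt(seed=7, planted=True)
call = hgt.classify_tree(gt, gtaxa, "Pmultistriata")
print(call.verdict, call.confidence, call.best.donor_count)
# candidate high 10

# Ka:Ks on a codon pair simulated under positive selection (dN/dS = 2)
s1, s2, _ = simulate.simulate_codon_pair(500, 0.3, 2.0, seed=11)
r = molevo.ng86_kaks(s1, s2)
print(f"Ka={r.ka:.4f} Ks={r.ks:.4f} Ka:Ks={r.ratio:.3f}")
# Ka=0.5728 Ks=0.3181 Ka:Ks=1.801

# dating an LTR insertion from sister-LTR divergence (true age 1 Myr)
l1, l2, _ = simulate.simulate_ltr_pair(5000, 1.0e6, 1e-8, seed=5)
age = molevo.ltr_age(molevo.k2p_distance(l1, l2), 1e-8)
print(f"{age.age:,.0f} years")
# 1,034,485 years
```

Every number above is what the code prints: 500 families yield exactly 500
gain events (one per family, the Dollo constraint); the Ka:Ks estimate
1.80 sits below the simulated dN/dS of 2.0, the known mild conservativeness
of counting estimators at moderate divergence; the recovered insertion age
is within ~3% of the simulated 1 Myr.

A command-line interface mirrors the library (`diatomevo cluster`, `rbh`,
`dollo`, `hgt-scan`, `cne-scan`, `expansion`, `kaks`, `ltr-age`, and
`diatomevo sim …` for the generators); run `diatomevo --help`.

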