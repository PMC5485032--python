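# Methods

This note documents the models and procedures implemented in `diatomevo`,
the assumptions behind them, the parameters that matter, what the
synthetic-data generators do and do not emulate, and the numerical and
design choices made where the design was genuinely open.

## Coordinate and tree conventions

All coordinates inside the package are 0-based half-open on the forward
strand. GFF3 (1-based inclusive) and MAF (0-based but strand-relative)
coordinates are converted at read time and back at write time; nothing
downstream ever re-converts. Newick internal-node labels that parse as
numbers are interpreted as support values for the edge above the node;
values in (1, 100] are treated as bootstrap percentages and divided by
100. An unlabeled internal node has *missing* support (`None`), which is
deliberately distinct from zero support: missing values are excluded from
tree-average support and route the HGT support rule to its tree-average
branch. Trees whose root is a basal polytomy are rejected by the Dollo
stage rather than auto-rooted, because gain placement depends on the root.

## Family clustering (MCL)

The homology graph symmetrizes directed similarity hits: an undirected
edge survives when at least one direction passes both the e-value
threshold (default 1e-5) and the coverage threshold, weighted by the best
bitscore over directions. Bitscore weighting (rather than −log e-value)
is a configurable choice; nothing downstream depends on it.

Markov clustering uses the canonical scheme: self loops equal to each
node's maximum incident weight are added, columns are normalized, and the
iteration alternates expansion (matrix squaring) with inflation
(entry-wise power, default 2.0, pruning of entries < 1e-5, column
renormalization) until the largest entry change falls below 1e-6.
Clusters are connected components of the limiting flow matrix, which
always refine the graph's components, so disconnected subgraphs can never
merge. Nodes are sorted internally, making the result independent of
input order. A debug flag records the deviation of every column sum from
1 after each inflation; the invariant holds to ~1e-15 in practice.
Non-convergence within the iteration cap returns the current clustering
with a flag rather than raising.

## Orphans, single-copy clusters, expansion Z-scores

Orphans are focal-species proteins with no detectable homolog outside the
focal species; the report separates singletons (unclustered proteins and
size-1 clusters) from members of multi-protein clusters whose species set
is exactly the focal species, because the two classes are usually quoted
separately. Orphans plus non-orphans always sum to the proteome size.

The expansion score per family is
`Z = (n_focal − mean) / SD` over the per-species member counts, with the
population (divide-by-N) standard deviation taken over *all* species
including the focal one. The divisor convention is ambiguous in common
usage; population SD was chosen and is switchable by recomputing from the
returned mean/SD columns. A useful consequence used as a test invariant:
for any family, the Z-scores obtained by letting each species play the
focal role average to exactly zero. Zero-SD families get an explicit
`defined = False` flag, never a numeric Z and never a division error.
Domain-family assignment (e.g. HMM searches against a domain-superfamily
database) is an upstream step: the module consumes a ready protein→family
table.

## Dollo parsimony

Under Dollo parsimony a family arises exactly once and can only be lost.
For a presence row the implementation places the gain on the edge
subtending the MRCA of the present leaves and one loss on each maximal
subtree of the gain clade containing no present leaf.

*Why this is the unique minimum.* Any valid single-gain history must gain
at or above the MRCA. Moving the gain one edge higher adds the sibling
subtree of the previous gain node to the gain clade; that subtree
contains no present leaf (otherwise the MRCA would be higher), so it
costs at least one extra loss and saves none. By induction the MRCA
placement strictly minimizes events, and given the gain, the loss set —
the maximal absent subtrees — is unique. This matches the semantics of
classic Dollo implementations (e.g. Phylip's `dollop`). The brute-force
check in the benchmark suite enumerates every gain placement
exhaustively and has agreed on 100% of ~1000 random rows per run.

In simulation-recovery experiments a planted history can differ from the
reconstruction when losses prune one flank of the gain clade entirely —
the planted gain then sits above the MRCA of the surviving leaves and the
minimal history is cheaper than the planted one. These rows are flagged
as simulation homoplasy, not errors; at the default loss probability of
0.1 on an 8-taxon tree roughly 90% of families are unambiguous, and on
those the per-edge aggregates match the planted truth exactly.

Single-leaf families are reported both as a gain on the terminal edge and
in the per-species orphan tally; users reconcile the two as their
downstream summary requires.

## HGT classification

Gene trees are treated as unrooted: every bipartition (one side per edge)
is evaluated on the side containing the focal gene, plus the full leaf
set (the only clade of a star tree). This avoids committing to any
rooting procedure and makes the scan deterministic. The rule, with all
thresholds exposed as parameters:

- target fraction ≥ 0.90 — leaves from {bacteria, archaea} ∪ scope group,
  counted over *leaves*, not distinct species;
- zero leaves from metazoa, plantae or fungi;
- ≥ 5 bacterial leaves, or ≥ 10 when the focal species provides the only
  eukaryote leaves in the clade (guarding against single-protein
  misplacement, e.g. long-branch attraction);
- clade support ≥ 0.5, or tree-average support ≥ 0.5 (mean over internal
  edges with non-missing support). A candidate whose qualifying clade is
  itself weakly supported (≤ 0.5 or missing) but whose tree average
  passes is labelled *medium* confidence, otherwise *high*.

When several clades qualify, the reported one maximizes target fraction,
then preference for clade-level support, then size; all qualifiers are
listed. Scopes widen from `diatom` through `stramenopile` to `SAR`; the
package's closed taxon vocabulary has no dedicated labels for alveolates
and rhizarians, so at SAR scope the `other-eukaryote` group stands in for
them — a documented approximation, configurable via `SCOPE_GROUPS`. The
narrowest qualifying scope is the reported origin label.

The red-algal-origin classifier reuses the same machinery with
{red-alga} as the donor group and a membership minimum of 2. No explicit
published criteria exist for that classification; the reuse is an
assumption, flagged as such in the API.

The supporting feature statistics use Welch's two-sample t-test for
continuous gene features (lengths, GC fraction) and the Mann–Whitney U
test for counts (exons per gene), with identical samples short-circuited
to p = 1.

## CNE discovery

The scan slides a 20 bp window at 10 bp steps along the reference row of
each alignment block. Identity between the reference and another species
is computed over aligned columns with gap columns counted in the
denominator — conservative and deterministic. The per-window identity
threshold defaults to 0.70. The threshold is a prominent parameter: the
pass criterion per window is a design decision, because only the emergent
statistics of merged elements (mean length, mean identity) are typically
reported, not the windowing rule itself. A window passes for a species
only if, additionally, neither its reference interval nor its projection
onto that species overlaps an annotated gene; full gene spans are used
(exon-only exclusion would be a stricter variant).

Overlapping and adjacent passing windows merge while the running
intersection of their passing-species sets stays non-empty; the merged
element's conserved-species set is that intersection and its identity is
recomputed over the merged columns. Intersection semantics were chosen
over union as the conservative default. Merging is idempotent and
order-independent.

Recovered coordinates are resolvable only to the step grid: a boundary
window straddling the edge of a true element can pass by background
chance, so recovery is asserted to within one step of the grid-snapped
true coordinates. In benchmark runs every planted intergenic element of
length ≥ 20 at identity ≥ threshold is recovered at that tolerance and no
emitted element overlaps a gene in any conserved species.

The TSS-proximity test defines the TSS as the annotated, strand-aware
gene start, measures the minimum absolute distance from each element
midpoint to any TSS, and compares elements against length-matched
intervals sampled uniformly from intergenic space (default 1000 controls,
seeded) with Welch's t-test. Calibration: with elements drawn from the
control distribution the empirical type-I error at α = 0.05 stays within
[0.03, 0.07] over 500 replicates; with elements planted within 200 bp of
TSSs on a 100 kb / 50-gene genome, power exceeds 0.9 at p < 0.01.

## Reciprocal best hits and divergence profiles

RBH first discards hits whose query coverage falls below 0.30 (the
coverage filter applies to the query sequence of each direction), then
pairs (a, b) where each is the other's unique top-bitscore hit. Ties for
best hit disqualify the protein — a conservative, deterministic rule.
The output is a partial matching. The divergence profile takes, per
query, the percent identity of its maximum-score hit (ties resolved to
the higher identity) and reports the empirical cumulative distribution.

## NG86 Ka:Ks

Potential synonymous sites are counted per codon position as the fraction
of synonymous changes among the *non-stop* single-base alternatives at
that position, so S + N equals exactly three sites per codon; site counts
are averaged over the two sequences. Observed differences average over
all minimal mutational pathways between differing codons with equal
weight, excluding pathways through stop codons (falling back to all
pathways when every one is blocked). The Jukes–Cantor correction
`d = −¾·ln(1 − 4p/3)` maps proportions to distances; p ≥ 0.75 is reported
as saturated (`None`) rather than a number, as is the ratio when Ks = 0.
The estimator is symmetric in its arguments to ~1e-12. Codons containing
a gap in either sequence are excluded pairwise; the universal genetic
code is fixed.

This is a single fully-specified counting estimator rather than a
model-selection ensemble over maximum-likelihood substitution models;
the known consequences are a mild downward bias of the ratio at dN/dS > 1
and upward at dN/dS ≪ 1 (visible in the benchmark: median ratio ≈ 1.78 at
simulated 2.0, ≈ 0.22 at 0.2, both within 15%). Positive selection is
flagged at ratio strictly greater than 1; undefined ratios are reported
separately, never flagged.

## K2P distance and LTR ages

The Kimura two-parameter distance is
`K = −½·ln((1 − 2P − Q)·√(1 − 2Q))` with P and Q the transition and
transversion proportions over sites free of gaps and ambiguity codes.
Non-positive logarithm arguments flag saturation; no numeric K is
invented. Insertion age is `T = K/(2r)`: the two LTRs of an element are
identical at insertion and each accumulates substitutions at rate *r*
(substitutions/site/year), so their divergence is twice the per-copy
distance. The substitution rate has *no default* — it varies by lineage
by an order of magnitude, so the API forces an explicit choice, and K is
always reported alongside T so relative comparisons survive any rate.
The age histogram bins datable elements (saturated ones excluded) and
reports the proportion per bin.

## What the synthetic data emulate — and what they do not

The generators are deterministic under a fixed seed and always emit a
truth object. Default parameters define the study conditions of the
benchmark suite:

- **Species trees**: random binary topologies by sequential joining,
  exponential branch lengths (mean 0.1). No molecular clock, no
  birth–death realism — topology is all the downstream analyses use.
- **Dollo families**: one gain edge uniform over edges, independent loss
  probability 0.1 per edge strictly below the gain, subtree-pruning
  losses, empty families resampled. Gains are not modelled as a process
  in time, only as placements.
- **Gene trees with transfers**: planted clade of 10 bacterial leaves
  plus the recipient diatom(s), clade support drawn from U(0.7, 1.0),
  other supports U(0.3, 1.0); the null background holds 22 eukaryote
  leaves (metazoa, fungi, plantae, other eukaryotes, diatoms, other
  stramenopiles) and 6 bacteria scattered at random, enough bacteria
  that the donor-count rule is genuinely exercised by the null.
- **Alignment blocks**: gap-free 800 bp blocks, background per-site
  identity 0.25 (unrelated sequence), planted elements with evenly
  spaced mismatches so every window of the element meets its stated
  identity, genes annotated at identical offsets in all species. No
  indel model and no alignment error — the scan, not the aligner, is
  under test.
- **Codon pairs**: per-site proposals accepted with probability 1 for
  synonymous and ω-weighted for nonsynonymous changes, stops rejected,
  until the target synonymous divergence (Ks ≈ 0.3 over 500 codons) is
  reached. This is an accept/reject scheme, not a continuous-time codon
  model: it controls realized dN/dS exactly but has no
  transition/transversion or codon-frequency structure.
- **LTR pairs**: per-site Poisson substitution counts at total distance
  2rT with transition:transversion ratio 2, refused beyond expected
  distance 0.75 (saturation).
- **Similarity tables**: planted ortholog pairs score in a band strictly
  above all decoys; decoys are one-directional so they cannot form
  reciprocal pairs of their own; a configurable fraction of planted
  pairs carries focal coverage below 0.30 as filter traps.

Passing benchmarks on these data demonstrates algorithmic correctness and
statistical calibration under clean conditions. They do not demonstrate
robustness to alignment error, annotation error, compositional biases,
rate heterogeneity or incomplete taxon sampling, all of which affect real
genome analyses.

## Problem sizes

The benchmark suite (also run by `scripts/acceptance.py`) uses: 200
random trees × 5 rows for the Dollo oracle; 500 families on 8 taxa for
Dollo recovery; 200 planted + 200 null gene trees for HGT recall/FPR and
500 trees ≤ 12 leaves for the HGT oracle; 100 alignment blocks (plus 20
background-only) for the CNE scan; 500 null and 100 planted replicates
with 200 controls for the TSS test; 20 seeds of a 5 × 20-node planted
partition for MCL; 20 seeds × 300 planted pairs for RBH; 100 replicates
per ω ∈ {0.2, 1, 2} at 500 codons for NG86; 50 five-kb pairs for LTR
dating; 20 random 50 × 13 matrices for the Z-score. The full suite
completes in well under a minute on a single CPU.

## Known limitations

- The MCL implementation targets desk-scale graphs (10⁴–10⁵ edges); it
  uses sparse matrices but makes no claim to reproduce genome-scale runs
  of the reference implementation bit-for-bit.
- The HGT rule counts leaves, not distinct species, toward the 90%
  fraction; whether published analyses counted species is not decidable
  from their descriptions.
- NG86 saturates (returns `None`) at proportions ≥ 0.75; deeply diverged
  pairs need a model-based estimator outside this package's scope.
- The CNE merge rule and window-pass criterion are this package's
  definitions (documented above), not reconstructions of any specific
  pipeline's unpublished internals.
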