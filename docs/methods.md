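# Methods

## Genome neighbourhoods

A genome neighbourhood (GN) is defined on gene *rank* — the 0-based
position of a gene along its scaffold ordered by start coordinate — not on
nucleotide distance. The window around a target at rank *r* is
[*r* − *f*, *r* + *f*] clipped to the scaffold, with flank *f* = 5 by
default, so interior targets give 11-gene GNs. Windows on one scaffold
that overlap are merged transitively into a single multi-target GN;
windows that merely touch (adjacent, zero-gene gap) also merge by default,
a behaviour exposed as `merge_adjacent` since the boundary case is a
genuine design choice — merging avoids counting a boundary gene in two
GNs, which would break the disjointness invariant the enrichment counts
rely on. Truncated (scaffold-edge) GNs are flagged and excluded from the
similarity and reconstruction stages by the ≥ 11-gene size filter.
Strand is ignored for membership: clusters routinely mix orientations.

A GN qualifies as a biosynthetic gene cluster when its genes carry
domains from ≥ 3 distinct enzyme classes under a user-supplied
domain → class map (e.g. scaffold-generating, oxidising, acylating); the
map ships with a default covering the stock palette.

Clade labels spread from reference leaves outward: an unlabeled leaf takes
the label of its smallest enclosing clade that contains reference leaves,
provided they agree; otherwise it is reported ambiguous rather than
guessed. A merged GN whose targets fall in different clades is attributed
to each clade and flagged, since the analyses are per-clade.

## Enrichment

For each clade and each domain observed in its GNs, the test is the
hypergeometric upper tail P(X ≥ k) with N = all genes pooled across the
included genomes, K = genes carrying the domain anywhere, n = genes in
the clade's GNs, k = GN genes carrying it. Counting is per gene (a gene
with several hits of one domain counts once), which keeps k ≤ n
well-defined. The survival function is evaluated with scipy's
`hypergeom.sf`; a grid test against exact rational summation (N ≤ 200)
holds it to < 1e-10 relative error. Bonferroni uses m = the number of
distinct domains observed in that clade's GNs at the chosen level
(family, or subfamily with family fallback); m is recorded in every
result row. The significance threshold defaults to adjusted *P* < 0.01.

The **conservative** variant reduces k only: within the tree restricted
to the clade's leaves, every maximal monophyletic group in which *all*
leaves carry the trait contributes only its highest per-leaf count. This
treats a trait shared by a whole subtree as one vertically inherited
observation. Two consequences are worth knowing. First,
k_conservative ≤ k_naive always, so the conservative p-value is never
smaller — under the null its false-positive rate is bounded by the naive
rate (both are measured by `gnevo.studies.enrichment_study`). Second,
when a planted trait saturates *every* leaf of a small clade, the whole
clade collapses to a single leaf's count and detection then depends on
the domain's rarity in the background universe; in the replicated power
study (20 GNs of 11 genes in a 5,000-gene universe, background placement
0.02, foreground 0.9) the naive test detects the planted domain in
≥ 90% of replicates while the conservative test is, by design, far more
reticent in this saturated regime. In larger universes where the domain
is relatively rarer, the conservative test regains power (the end-to-end
synthetic pipeline detects its planted association conservatively).

The universe includes the target genes themselves (switchable in
principle but not a default worth hiding); per-genome reruns restrict
N, K, n, k to one genome at a time.

## Pairwise similarity

Identity is computed on full protein sequences by global alignment
(BLOSUM62, gap open 10, extend 0.5 — Biopython's `PairwiseAligner`), with
identity = identical pairs / all alignment columns, gap columns included.
The first optimal alignment under the library's deterministic enumeration
is used; the alignment *score* is verified against an independent
three-state Gotoh dynamic programme in the tests. Genes lacking a
translation count for GN membership but are excluded from all
sequence-based indices (including the DSS denominator, which preserves
DSS(a, a) = 1 exactly).

For a shared domain with unequal copy numbers, surplus copies on the
larger side are dropped lowest-best-identity first (ties by gene id) and
the Hungarian algorithm (scipy `linear_sum_assignment`) then maximises
total identity; the assignment equals the brute-force permutation maximum
on every random instance tested. DSS sums matched-pair identities over
shared domains and divides by Σ over the union of domains of
max(copies_a, copies_b): unmatched copies and one-sided domains
contribute zero to the numerator but inflate the denominator, penalising
copy-number mismatch. Jaccard uses domain-name sets only. Comparison
granularity defaults to subfamily names (CYP705A, ACT_IIIa) with family
fallback, and an optional whitelist restricts the comparison to
specialized-metabolism domains.

## Ancestral reconstruction

Leaves whose GN fails the size filter are pruned (suppressed unary nodes
sum their branch lengths). A GN represented by several leaves keeps the
leaf maximising mean DSS to the other retained leaves' GNs; because all
such leaves share one GN this mean ties under the default "all leaves"
comparison and resolves lexicographically, so a k-nearest (patristic)
variant is exposed for users who want tree-local representativeness.

Fitch's bottom-up pass gives the parsimony score (number of union
events). The per-node most-parsimonious state sets are computed by the
unit-cost min-change dynamic programme (down costs by postorder, up costs
by preorder; a state is kept iff down + up equals the global minimum),
which is exact under ties; the score and root sets are verified against
exhaustive enumeration of all internal labelings on trees ≤ 8 leaves. A
branch is called a gain or loss only when both endpoint sets are disjoint
singletons; branches touching a node that admits both states are reported
ambiguous — no acceleration/delay heuristic forces them. The score is
invariant to rerooting; event polarity is reported for the chosen rooting
(named outgroup, else midpoint). Multifurcations are resolved arbitrarily
to binary with zero-length branches and logged.

## Synthetic data

The generator emulates exactly the structure the pipeline assumes and no
more: per-gene Bernoulli domain placement (background probability 0.02
genome-wide; foreground 0.9 inside the planted clade's windows),
independent across genes — no linkage beyond the planted windows; Yule
trees (unit birth rate) as neutral scaffolds; two-state Markov traits
(gain 0.03, loss 0.01 per unit branch length — a handful of expected
events on a ~40-leaf tree); and protein families under an equal-frequency
20-state substitution chain. For the protein chain, a site on a branch of
length *t* keeps its residue with probability e^(−rt) and otherwise
redraws uniformly over all 20, so expected identity over patristic
distance *d* is exactly 1/20 + (19/20)·e^(−rd); a per-branch
"switch to a different residue" rule would not compose across branches
and was rejected for that reason. Default sizes: 13 genomes × 2 scaffolds
× 40 genes, one target per genome at an interior rank, protein length
120, substitution rate 0.3.

What passing tests on these data do *not* show: robustness to gene
duplication and rearrangement, correlated domain placement (operon-like
linkage), annotation noise, or non-Yule tree shapes. The generator is a
test harness for the statistics, not a genome-evolution model.

## Study and test sizes

The replicated studies use 500 null and 100 planted enrichment replicates
(5,000 genes, 20 GNs, 30 domains), 200 event-recovery replicates on
39-leaf trees, 500–1,000 random instances for the assignment and
collapsing property checks, and exhaustive oracles on trees ≤ 8 leaves
and hypergeometric grids N ≤ 200 — sizes at which the exhaustive oracles
are exact yet the whole suite runs in well under a minute per study.

## Known limitations

- Phylogenetic regression cross-checks (PLR/PGLMM) are out of scope; the
  enrichment output schema keeps clade/domain keys so external results
  can be joined.
- The Bonferroni family (m per clade and level) is one defensible choice
  among several; m is emitted so users can re-adjust.
- Identity is computed on whole proteins, not excised domain envelopes;
  with envelope coordinates in hand the same machinery applies but
  numbers will differ.
- The conservative test's power loss in trait-saturated small clades is
  intrinsic (see Enrichment above).
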