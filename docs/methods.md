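# Methods

## Anchors and gene ranks

All collinearity analysis runs in *rank space*: each gene's 0-based order
index along its chromosome, assigned by ascending start coordinate (ties by
end, then gene id). Coordinates are GFF3 1-based inclusive; ranks are
internal. Anchors come from a 12-column tabular similarity search
(query, subject, pident, length, mismatch, gapopen, qstart, qend, sstart,
send, evalue, bitscore). Rows with E-value above the cutoff (default 1e−5)
and self-hits are dropped; the stated "p-value" threshold of such searches
is read as an E-value, which is what the tabular format carries. Top-hit
filtering keeps one subject per query: highest bitscore, then lowest
E-value, then lexicographically smallest subject id. The last tie-break is
arbitrary but fixed — reproducibility requires *some* total order, and
subject id is the only stable key left.

When a gene has several transcripts, the longest isoform is selected by
summed CDS length when CDS features exist, else by mRNA span; the package
works from coordinates, so "longest protein" is operationalised as longest
coding extent.

## Synteny blocks

A block between two chromosomes is a maximal chain of anchors whose ranks
increase strictly on the first chromosome and change strictly monotonically
on the second (ascending or descending — inverted segments count, and gene
strand is ignored throughout), with consecutive rank steps bounded by
`max_rank_gap` on both sides.

* `min_anchors = 4` — a block must contain more than 3 consecutive
  homologous genes.
* `max_rank_gap = 25` — "consecutive" is relaxed to a bounded rank gap, as
  in standard collinearity tools; `max_rank_gap = 1` recovers strict
  adjacency.
* `allow_descending = True` — inversions are expected biology.

Chains are found by longest-chain dynamic programming (O(n²) per chromosome
pair) and extracted greedily: the best remaining chain is reported, its
anchors removed, and the search repeated until no chain reaches
`min_anchors`. "Best" is a total order — longer first, ascending before
descending, then the lexicographically smallest (rank_a, rank_b) sequence —
so the output is deterministic and each anchor belongs to at most one
block. Anchors where one gene hits a run of rank-consecutive partners
(tandem arrays) are collapsed to the lowest-rank hit before chaining, which
stops tandem duplications from inflating chains.

A note on symmetry: no deterministic numeric tie-break can make greedy
extraction invariant under swapping the two genomes (a chain and its
transpose cannot be ordered consistently from both sides), so each
chromosome pair is canonicalised to a fixed orientation — lexicographic on
(species, chromosome) — chained there, and swapped back. Swapping input
genomes therefore yields exactly mirrored blocks, by construction.

Greedy exclusivity has one measurable consequence: enlarging
`max_rank_gap` can merge two chains into one longer chain whose extraction
strands a few anchors below `min_anchors`, so the *total* anchors in blocks
is not monotone in the gap parameter; the largest block's size is, and that
is the invariant the tests pin down.

Block *coverage* is the union of block spans (half-open bp intervals over
the anchor genes, merged before summing) divided by total assembly length;
assembly lengths come from `##sequence-region` pragmas when present, else
from the last gene end per chromosome.

## Karyotype events

Given blocks among one outgroup and two ingroup descendants:

1. **Proto-chromosomes.** Descendant chromosomes are paired by
   maximum-weight one-to-one matching (scipy's linear sum assignment),
   weight = total anchors in the blocks linking a pair. Equal-weight optima
   are broken toward lexicographically earlier chromosome pairs via an
   integer penalty smaller than any weight difference. Chromosomes without
   a positive-weight partner stay unpaired and are reported as
   lineage-specific, not ancestral.
2. **Retention.** An outgroup chromosome maps to a proto-chromosome only if
   blocks meeting the support thresholds (`min_blocks = 1` qualifying
   blocks of `min_anchors = 4` anchors, exposed because tiny spurious
   blocks otherwise inflate fission counts) link it to **both** descendant
   members.
3. **Counting.** On the bipartite map: an outgroup chromosome of degree
   *n* ≥ 2 contributes *n*−1 fissions; a proto-chromosome of degree
   *m* ≥ 2 contributes *m*−1 fusions; degree-0 outgroup chromosomes are
   losses; degree-0 paired proto-chromosomes are gains. Many-to-many maps
   are decomposed edge-wise, so the same chromosome may appear in both
   tallies — the two rules are defined independently and both are applied.
4. **Gain origin.** A gain is flagged duplicative iff either member shares
   a within-genome block with a different chromosome of its own genome;
   otherwise a duplicative origin is excluded.

The event totals are pure graph identities, so they are re-verified in the
tests against independent recomputation on random maps.

## Expansion dating

For an aligned paralog pair, p is the fraction of differing sites over
columns where both sequences carry A/C/G/T (pairwise deletion of gaps and
ambiguity codes, as distance tools conventionally do). The Jukes–Cantor
correction JC = −(3/4)·ln(1 − 4p/3) diverges at p ≥ 0.75, which raises a
saturation error rather than returning a number. The age is JC/(2r); the
factor 2 is the two lineages separating the paralogs. **r is always
user-supplied** (substitutions/site/Myr): no published constant is assumed,
and the simulator's default r = 10⁻³ is a package choice of a plausible
invertebrate nuclear rate, stated here once and used consistently on both
the generating and the inference side.

Peak decomposition uses a Gaussian KDE (Silverman bandwidth by default; a
numeric bandwidth is interpreted in age units and converted to scipy's
scale factor), evaluated on a 1024-point grid padded by 3 bandwidths. Local
maxima below `min_peak_fraction = 0.05` of the global maximum are ignored;
members are assigned by watershed at the density minimum between adjacent
peaks, with boundary ties going to the lower-age peak. A constant age
vector yields a single degenerate peak; fewer than two ages is an error.
Subfamily fractions are reported per pair (fractions of each subfamily's
pairs per peak, summing to 1) and per gene (each gene attributed to the
peak of its youngest pair — its most recent duplication), since a
gene-level tally is the other defensible reading of "ratio of genes in
each peak".

Tandem clusters are single-linkage runs of family genes along a
chromosome: consecutive members join when the rank gap ≤ `max_gap_genes`
(default 10) **and** the bp gap ≤ `max_gap_bp` (default 1 Mb). The defaults
are deliberately permissive — published cluster figures are drawn without
stated thresholds — and both are exposed.

## The simulator

The generator emulates the three-genome comparative design: an outgroup
standing in for the ancestral karyotype (default 26 chromosomes × 100
genes), a planted event plan producing the ingroup proto-ancestor, and two
descendants (default divergence 44 Myr) with independent inversions
(default 5 per genome, 4–12 genes each) and Jukes–Cantor sequence
divergence. Anchor tables are emitted from the true ortholog map with
configurable dropout and spurious near-cutoff hits; tandem bursts (default
plan mirrors a two-wave family history at 65 and 11 Ma) grow arrays around
founder genes spread along the gene-richest chromosome, emitting indel-free
aligned pairs with exact ages.

Deliberate simplifications, and what they mean for the tests:

* Sequence evolution is pure Jukes–Cantor — no indels, no rate variation,
  no codon structure — so analytic expectations exist and clock recovery is
  a clean test of the dating arithmetic, not of alignment quality.
* Event chromosomes are disjoint across event types ("non-overlapping"
  plans), and fission pieces keep at least 8 genes, so planted totals are
  exactly recoverable; real many-to-many histories (a chromosome that both
  fissioned and re-fused) are measurable by the event calculus but not
  planted by the generator.
* Anchors derive from the true ortholog map: homology search artefacts
  beyond uniform dropout and uniform spurious pairs are not modelled.
* Gene spacing is uniform-random; no repeat landscape, no Hi-C, no
  demography.

Passing tests therefore certify the inference algorithms under the stated
noise model, not robustness to real annotation and homology-search error,
which the exposed thresholds (`min_blocks`, `min_anchors`, E-value cutoff)
exist to absorb on real data.

Determinism: one `numpy` PCG64 stream per simulation, seeded from the
config; identical configs give byte-identical output files.

## Problem sizes used in the checked runs

The test suite and the acceptance script run at desk scale, chosen to keep
the full suite around a minute while leaving every ratio (genes per
chromosome vs. block minimum, events vs. chromosome count) comfortably in
the regime the method assumes: oracle comparisons at ≤ 12 genes per
chromosome (exhaustive enumeration is exact there), null and recovery
scans at 8×40 and 20×100 genes over 100 seeds, clock recovery with 200
pairs per burst of 10 kb over 20 seeds, and the acceptance script at
26×100 genes.

## Known limitations

* Exactly one outgroup and two descendants; no squid-branch events, no
  breakpoint localisation, no temporal ordering of events.
* Event counts are parsimony identities on block support; they inherit any
  block-detection threshold sensitivity, which on real data calls for a
  sensitivity scan over `min_blocks`/`min_anchors`.
* The Jukes–Cantor clock assumes a single constant rate; ages scale as 1/r,
  so they are only as good as the supplied rate.
* KDE peak counts depend on bandwidth near the merging point of close
  bursts; the bandwidth is exposed and the default is Silverman's rule.
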