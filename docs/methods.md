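# Methods

## Cluster model

A tRNA gene cluster is defined on the genome's annotated tRNA genes alone;
sequence content and strand are ignored (dense tRNA arrays in phage genomes
are routinely mixed-strand, and the density criterion is a purely positional
one). Internally all coordinates are 0-based half-open; the density of a
window of consecutive genes is measured over the span from the first
member's start to the last member's end, so a cluster's density is an
intrinsic property of its members rather than of any surrounding window
convention. Both thresholds are inclusive:

- `min_density` — default 2.0 tRNA/kb, the conventional floor for calling a
  run of tRNA genes an array;
- `min_genes` — default 15, the survey floor separating large clusters from
  the small multi-gene groups common in many genomes.

### Detection algorithm

1. Enumerate every window of consecutive genes meeting both thresholds
   (O(n²); genomes carry at most a few dozen tRNA genes, so this is
   negligible).
2. Keep the maximal windows: those not strictly contained in another
   qualifying window. Note that merging two overlapping qualifying windows
   whose union still qualifies is subsumed by this step — the union of two
   overlapping consecutive-gene windows is itself a window, so if it
   qualifies it is in the enumeration and the parts are discarded as
   non-maximal.
3. If maximal windows still overlap (their union fails the density test),
   resolve deterministically: commit the window with the most genes (ties:
   leftmost), then re-scan the gene ranges on either side. Reported
   clusters are therefore disjoint, and the output is independent of input
   ordering.

Circular genomes are handled opt-in by virtually doubling the gene list
with coordinates shifted by the genome length, restricting windows to at
most n genes, and de-duplicating detected clusters by their member sets
modulo n; a cluster crossing the origin is reported once with its second
arc's coordinates extending past the genome length and a `wraparound` flag.
Linear mode is the default because public virus FASTA records do not encode
topology uniformly.

The test suite checks this definition against an independently written
brute-force enumerator on hundreds of random instances, plus direct
assertions of the threshold, maximality and disjointness invariants.

## Synteny grouping

A cluster's signature is the string of single-letter isotypes of its
members in genomic order, over a 23-symbol alphabet (20 standard amino
acids, O = pyrrolysine, U = selenocysteine, X = undetermined). Because no
reading strand is privileged, signatures are canonicalized to the
lexicographically smaller of the string and its reversal before grouping
(this can be disabled). Grouping is exact string equality on canonical
signatures; groups are labelled G1, G2, … by decreasing size with
lexicographic tie-breaking, and one-member groups are singletons.

Variant arrangements (e.g. a cluster missing a terminal block of genes
relative to a group's arrangement) are deliberately *not* merged into
groups. Instead, near-matches are reported with their Levenshtein distance
(minimized over the orientation pairings of the canonical forms; edlib
provides the computation, a textbook dynamic program in the tests checks
it). Exposing the tolerance as a report rather than a merge keeps the
grouping a well-defined partition. X participates literally in signatures
and never matches a determined isotype.

## Codon usage

RSCU follows the standard definition: count × family size / family total,
per synonymous family of the standard genetic code; stop codons are
excluded, single-codon families (Met, Trp) are pinned at 1 when observed,
and families with zero total are reported as missing — never as 0, which
would be indistinguishable from "observed family, unused codon".

Anticodon → codon decoding is the exact Watson–Crick reverse complement;
wobble-expanded decoding is out of scope. Pyl and SeC tRNAs contribute to
isotype tallies but supply no standard-code sense codon. "Preferred" means
RSCU strictly > 1; codons at exactly 1 are unbiased, not preferred. The
cluster-vs-target matching fraction uses set semantics — which codons are
supplied, not in what dosage — while copy numbers remain available in the
cluster × 64-codon matrix export. The genome-wide RSCU scope includes all
CDS (the MCP among them). The MCP is located by a case-insensitive product
match on "major capsid" (configurable); among multiple matches the longest
CDS wins.

## Cohort statistics

- Quantiles (medians, IQRs) use linear interpolation, the common default.
- Two-group comparisons use the two-sided Mann–Whitney U with tie
  correction and continuity correction (normal approximation); the
  statistic reported is U for the first group, so U_a + U_b = n_a·n_b. The
  p-value is withheld below 3 observations per group.
- Spearman correlations use average ranks for ties and the t-distribution
  p-value approximation; constant inputs yield a missing correlation.
- Lifestyle is keyword-based, mirroring how the question is asked of
  annotation: any CDS product containing "integrase" flags the genome
  temperate (subtype serine/tyrosine when named), no CDS annotations at all
  yields unknown, otherwise virulent. Excisionase/recombinase keywords are
  deliberately not used.
- The per-family table computes its ranges and average GC over the family
  members that carry at least one tRNA gene, matching the semantics of a
  "families harboring tRNA genes" overview.

## Synthetic data generator

The generator emulates the statistical shape of a viral survey cohort:
genome lengths 5 kb–1.2 Mb (log-uniform in the cohort generator), a default
GC target of 0.44 (the cohort-median GC of tRNA-carrying virus genomes),
planted clusters of ≥ 15 genes at 2–10 tRNA/kb, loose tRNA genes, and CDSs
with controllable synonymous bias. Specifics:

- tRNA genes are fixed at 72 bp (typical tRNA gene size; configurable
  constant). A planted cluster's span is solved from the density
  definition, span = 1000·n/density bp, and genes are uniformly spaced so
  the first starts and the last ends exactly at the span boundaries; the
  achieved density equals the target up to integer rounding (within 5%).
- Features are laid out left to right with gaps of
  `1000·N/min_density + 500` bp, where N is the genome's total tRNA gene
  count. This guarantees exact planted-cluster recovery: any detection
  window bridging a gap g holds at most N genes over at least g bp, hence
  falls below the density floor. (A gap based only on
  `min_genes/min_density` is *not* sufficient when a planted cluster is
  denser than the floor — a bridging window can then still clear it.)
  Infeasible packings raise before any output is produced.
- Background sequence is i.i.d. with P(G or C) = the GC target, so the
  realized GC is within binomial sampling error of the target.
- Biased CDSs start with ATG, end with TAA, and draw body codons by
  sampling amino acids uniformly over the 20 standard ones, then a codon
  within the family with weight w for designated codons and 1 otherwise.
  For a 2-codon family with one designated codon, the expected RSCU is
  2·w/(w+1) (1.5 at w = 3); w = 1 gives uniform synonymous usage and an
  expected RSCU of 1 everywhere.
- All randomness flows from one `numpy` Generator seeded per spec; equal
  specs give byte-identical outputs. The planted truth table records every
  feature with its cluster membership.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: realistic tRNA sequences or secondary
structure, predictor error modes (missed genes, wrong anticodons),
non-tRNA genes interleaved inside arrays, phylogenetic correlation between
genomes, and genome-scale gene-content realism. Tests against synthetic
genomes validate the decision rules and the recovery machinery, not
biological prevalence claims.

## Problem sizes

The default test and acceptance runs use genomes of 20–240 kb with up to
~75 planted tRNA genes, 100-seed recovery sweeps, 500 random instances for
the brute-force cross-check, and 10,000-codon CDSs for bias recovery —
sizes at which every decision rule and statistical property of the method
is exercised while the full suite runs in well under a minute.

## Known limitations

- The detector's overlap-resolution rule (most genes first, leftmost tie)
  is one deterministic choice among defensible ones; on real data the
  ambiguous case — two overlapping maximal dense runs whose union is too
  sparse — is rare.
- `fraction_clustered` matches genes to cluster members by coordinates, so
  in circular mode the members of a wraparound cluster taken from the
  shifted copy should be compared modulo genome length by the caller.
- GFF3 parsing expects tRNA features annotated with `product` (or
  `isotype`/`anticodon`) attributes; GenBank flat files are out of scope.
- Multiple-testing correction is intentionally absent from the comparison
  report; callers running many comparisons should adjust downstream.
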