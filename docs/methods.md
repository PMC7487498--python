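# Methods

## Coordinates, sequences, codes

All coordinates are 0-based half-open internally.  GenBank's 1-based
inclusive convention is converted exactly once, at parse time; a `join`
spanning the circular origin becomes a single feature flagged `wrap=True`
whose sequence is materialized by concatenating the tail and head of the
circle.  N bases are retained in sequences but excluded from every
composition denominator.  Translation supports NCBI genetic codes 1
(standard) and 4 (protozoan mitochondrial) only — the two codes relevant to
cyanidiophycean mitogenome annotation; a trailing stop is removed silently,
internal stops are kept as `*` and reported, and `compare_genetic_codes`
flags CDSs whose two readings diverge (code 4 reads TGA as Trp, which can
extend reading frames and mislead annotation).  Multiallelic VCF sites
expand to one record per alternate allele; SNP counting counts records.

## Skew statistics and profiles

GC-skew = (G−C)/(G+C), AT-skew = (A−T)/(A+T), computed on the analyzed
strand.  Windowed profiles default to 1 kbp windows advanced in 20 bp steps
(48 bp disjoint windows for GC-content); circular genomes wrap windows
across the origin so every start 0, step, 2·step, … is covered, linear
genomes truncate.  A window with a zero denominator records value 0 with an
`undefined` flag rather than NaN, so cumulative sums stay defined — AT-rich
windows do occur in C-type genomes.  The cumulative GC-skew is a true
running sum over *disjoint* step-sized chunks, not overlapping windows;
GC-content windows are likewise disjoint.  Whether deposited-strand
orientation matches the analyzed strand is taken as given.

## Replication-signature classification

A profile is classified `single_strand_biased` when at least 95% of windows
share one skew sign and the cumulative curve is monotone in that direction;
`origin_flanked` when the cumulative curve, rotated to start at its global
minimum, rises to its maximum and falls back with both arms covering at
least 30% of the circle; otherwise `none`.  Two numerical choices matter:

- **Monotonicity resolution.**  Decreasing runs are counted on the
  cumulative curve aggregated into disjoint *window-sized* (1 kb) chunks,
  with a tolerance of `run_tol = 2` chunks.  At the raw 20 bp step
  resolution a chunk holds only ~9 G/C bases, so its skew has a standard
  deviation near 1/3 and short decreasing runs occur with high probability
  even under a strong uniform bias; window-sized chunks (~430 G/C bases)
  make the monotonicity test meaningful.  The fine-resolution cumulative
  series is still computed and exported for plotting.
- **Arm sign-consistency.**  A null random walk rotated to its minimum
  always yields two superficially monotone arms, so the V/Λ test
  additionally requires ≥90% of the rising arm's chunks positive and ≥90%
  of the falling arm's negative.  A genuine replication bias at asymmetry
  ≥0.3 passes this with margin; neutral genomes essentially never do.

The origin estimate is the cumulative minimum (chunk boundary), the
terminus the maximum; resolution is therefore one window.  Classification
requires at least 10 windows.  All thresholds (0.95 sign fraction, run
tolerance, 30% arm coverage, 0.90 arm consistency) are keyword arguments.

## G4Hunter scan

Within a maximal run of k guanines every base scores min(k, 4); cytosine
runs score the negative; other bases 0.  Window means (default window 25)
are computed at every start, and consecutive same-sign qualifying windows
(|mean| ≥ 1.2, the method's customary default) merge into maximal regions
re-scored over the merged span.  Strand `+` marks G-driven hits, `−`
C-driven.

## Protein properties

"Conserved sites" are alignment columns free of gaps and `X` in every taxon
— sites present in all species, not invariant sites.  Group comparisons run
on those columns by default (full-length sequences available for length
contrasts).  Charge classes default to positive {R, K, H} and negative
{D, E}; the hydrophilic/hydrophobic split is by sign of the Kyte–Doolittle
value (hydrophobic > 0).  Both partitions are a configurable `ClassScheme`,
since published composition figures rarely state their members.  GRAVY is
the mean Kyte–Doolittle hydropathy; the aliphatic index uses mole-percent
weights 1, 2.9, 3.9, 3.9 for A, V, I, L; the instability index is
(10/L)·Σ DIWV over adjacent residue pairs with the Guruprasad et al. (1990)
dipeptide weights as used by ExPASy ProtParam.  The constant tables live in
`cyanomito.tables` with provenance noted; the test suite cross-checks GRAVY
and instability against Biopython's independent ProtParam implementation.
Composition contrasts use per-taxon concatenation over conserved columns
(`concatenated_group_composition`); per-gene records are available where
per-gene resolution matters.

## Group testing

Kruskal–Wallis with tie correction; p from the χ² approximation with
df = k−1, or optionally from label permutations (recommended when the
pooled sample is ~10–15, as with 13 taxa in groups of 5/4/4).  Post-hoc:
Dunn's z-tests on the pooled ranks with Bonferroni adjustment over the
k(k−1)/2 pairs — the procedure is recorded in output metadata because
SPSS-style reports often leave their pairwise adjustment unstated, making
exact significance-marker reproduction impossible; pairwise tests run only
when the omnibus rejects at the configured α (default 0.05).

## TIGER and Ka/Ks

Each site induces a partition of the taxa by character state, with all
unknowns (`-`, `X`, `?`, `N`) pooled into one set.  The agreement of site i
with site j is the fraction of j's sets that are subsets of some set of i;
the TIGER rate of site i is its mean agreement with all other sites (1 =
fully compatible, low variability).  Rate binning is equal-width over
[min, max] into ranks 1..n (default 100), ties sharing a bin and constant
vectors degenerating to bin 1; the occupied-bin count is reported so
partition counts under either reading ("bins requested" vs "bins occupied")
are checkable.

Ka/Ks uses NG86 counting: per-codon synonymous site fractions averaged over
the pair, multi-substitution codons averaged over equally weighted
substitution paths excluding those through stops (with an unfiltered
fallback if every path hits a stop), Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3) applied to both proportions.  p ≥ 3/4 yields an
undefined (`None`) distance rather than an error; Ks = 0 leaves the ratio
undefined.  NG86 was chosen as the estimator because it is the transparent
counting baseline; the method name travels with every result.  Codon
alignments are inputs — a back-translation helper builds them from protein
alignments plus CDSs, but alignment construction itself is out of scope.

## SNP density

Density = n_SNPs / (genome length in kbp), the convention that reproduces
published per-genome figures (a non-coding-length denominator is a
configuration away, via the feature-kind set).  "Coding" defaults to the
union of CDS, tRNA and rRNA footprints, consistent with how the non-coding
fraction of a genome summary is computed (intergenic = non-coding).
Changing the feature-kind set changes the coding/non-coding split, never
the SNP count.

## Synthetic generators

The mitogenome simulator draws bases i.i.d. from a composition tilted
toward G over C: the G+C mass m is split m(1+α)/2 : m(1−α)/2, so the
expected GC-skew is exactly α; the A/T pair is tilted by α·`at_fraction`
(default 0.4), reproducing the empirical joint pattern of extreme GC-skew
(~0.7) with moderate AT-skew (~0.28).  The default composition has GC
content 0.43, the G-type regime.  Unidirectional genomes are tilted
everywhere; bidirectional genomes tilt the origin→terminus arc +α and the
complementary arc −α with the terminus antipodal; neutral genomes are
untilted.  Defaults for validation runs: 30 kb genomes (the size class of
these mitogenomes), asymmetry 0.3 as the weakest signal the classifier is
expected to resolve, 100 replicates per mode.

The protein-group simulator draws residues i.i.d. per taxon from a uniform
baseline, with one group's R+K+H mass raised by `class_shift` percentage
points (compensated proportionally elsewhere); the 4-point default contrast
matches the observed positive-charge gap between clades (≈10.8% vs ≈7.1%).
Group sizes default to 5/4/4 over 13 taxa and alignment length to 3845,
the conserved-site geometry of the 16-gene concatenation.  The codon-pair
simulator mutates each position synonymously with probability
`target_ps`·(synonymous fraction) and nonsynonymously with
`target_pn`·(nonsynonymous fraction), so expected difference counts equal
target·sites.  The variant simulator places SNPs uniformly within requested
coding/intergenic compartments and emits minimal VCF 4.2 text.

What the generators deliberately omit: phylogenetic correlation, among-site
rate heterogeneity, codon usage bias, replication-fork mechanics, indels.
Passing recovery tests therefore shows the statistics detect the encoded
signal at realistic effect sizes and lengths — not that real data are this
clean; on real alignments, shared ancestry inflates between-taxon
similarity and rate heterogeneity broadens the TIGER distribution.

One integer seed expands to independent substreams per generator, so
operations are individually reproducible and mutually independent.

## Validation problem sizes

The recovery suite uses 30 kb genomes × 100 replicates per replication
mode at α = 0.3 (classifier), 10,000 null replicates at the 5/4/4 split
(test calibration), and 50 pairs × 500 codons at equal divergence targets
0.05 (Ka/Ks).  These sizes give binomial/sampling noise comfortably inside
the asserted bounds while keeping the whole validation run under a minute.

## Known limitations

- The classifier assumes a single origin (or none); multi-origin or
  recombination-driven replication produces `none` or unstable calls.
- TIGER is O(columns²·taxa) as implemented; fine for mitogenome-scale
  alignments (thousands of columns), not for genome-scale matrices.
- NG86 ignores transition/transversion bias and codon frequencies; ratios
  on highly diverged pairs (p near saturation) are undefined by design.
- Published gene-count conventions (tRNA counting, ORF inclusion) vary;
  gene counts are reported by feature kind and summed, without attempting
  to match any particular table's convention.
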