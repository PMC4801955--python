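# Methods

`dietbarcoder` re-implements, as a tested library, the computation behind an
18S rRNA V9 metabarcoding diet analysis: a custom reference database is
interrogated for its taxonomic resolution, paired 2×150 bp reads are
trimmed, merged and assigned to reference amplicons at an identity
threshold, near-identical species are discriminated by diagnostic
nucleotides, and the quantitative value of read counts is evaluated against
communities of known composition. Every stage can be exercised end-to-end
on synthetic data, so the whole pipeline is testable without any external
download.

## Sequence identity

All identity computations use one definition: a global alignment with free
end gaps (semi-global), scored match +1, mismatch −1, gap −1, with identity
= matches / aligned columns over the aligned core. Internal gaps count as
mismatch columns; free terminal overhangs are excluded, so a truncated but
otherwise perfect read still has identity 1.0 against its source amplicon.
A single substitution on an L-mer gives (L−1)/L.

Because several alignments can share the optimal score while disagreeing on
matches and columns, the dynamic program optimizes lexicographically:
maximize score, then matches, then minimize aligned columns. This makes
the returned identity unique, symmetric in its arguments, and independent
of traceback tie-breaking. The kernels are numba-compiled; a pure-Python
Needleman–Wunsch oracle in the test suite checks them on random pairs with
substitutions and indels.

The identity definition itself is a stated design choice: the original
clustering software's gap treatment is not documented in the source study,
and free-end-gap identity is the natural choice for short amplicons read by
potentially truncated sequences.

## Reference database and resolution analysis

Amplicons are extracted between a forward primer site and the reverse
complement of the reverse primer (IUPAC degeneracy honoured, up to
`max_mismatch` substitutions, no indels; coordinates 0-based half-open;
the amplicon excludes the primers). Defaults are the EMP V9 primer pair;
primers are configuration, not results.

Synonymy — species whose amplicons are 100% identical over at least 64
aligned nucleotides — is found by exact-duplicate bucketing plus pairwise
alignment of bucket representatives and union-find, which also catches
containment (a shorter amplicon inside a longer one). Synonymy groups are
the locus's hard resolution limit: reads from group members are
indistinguishable and collapse to one OTU.

Diagnostic positions for a set of aligned, equal-length near-identical
amplicons are all columns with ≥2 observed states. The resulting key maps
each species to its nucleotide tuple at those columns and fails loudly if
two species share a tuple.

## Read processing

Quality trimming is a sliding-window 3′ cut (window = 10% of read length,
at least 1): the read is cut at the start of the first window whose mean
Phred drops below the threshold (default Q20); reads shorter than 20 nt are
discarded.

Merging searches every ungapped overlap offset of the forward read against
the reverse-complemented reverse read and keeps the offset maximizing
matches (ties: longer overlap). The merge is accepted when the overlap is
≥10 nt, contains ≤1 mismatch, and its match count is inconsistent with a
random overlap — binomial tail probability P[X ≥ matches | n = overlap,
p = 0.25] ≤ 0.01. The binomial test is an explicit, testable stand-in for
the named merger's "observed expected alignment score" cut-off, of which
only the 0.01 threshold is documented. At disagreeing overlap columns the
base with the higher Phred wins and keeps its quality (ties go to the
forward read); agreeing columns keep the higher quality. Ungapped overlap
only: 2×150 reads over a ≤174 nt template are fully nested and indels in
the overlap have no support in this setting.

Forward-only mode returns the forward read untouched and exists for the
bidirectional-versus-single-direction comparison: merged reads recover the
template's 3′ end from the mate and carry the better base at every overlap
column, while single-direction reads keep their error-prone tail and lose
whatever quality trimming removes.

## Taxonomic assignment

Closed-reference assignment is an exhaustive best-identity search over the
database; a read is assigned to the best record iff identity ≥ threshold
(ties by lexicographic record id), else "Unassigned". Equivalence is
defined against this exhaustive search, not against any clustering
heuristic's internals. Open-reference assignment adds greedy
abundance-ordered centroid clustering of the unassigned reads: dereplicate,
order by decreasing duplicate count (ties by smallest read id), join the
first centroid at ≥ threshold identity or seed `denovo-<n>`.

OTU tables carry integer counts (samples × OTUs) with an explicit
"Unassigned" column. Singletons are OTUs with total count 1 across all
samples. Predator removal drops listed OTUs and reports the per-sample
removed fraction of assigned reads.

## Character-based classification and discrepancy

Each read is aligned semi-globally to an anchor amplicon; the bases mapped
to the key's diagnostic columns form the observed tuple. A diagnostic
column outside the read's aligned span ⇒ "too-short"; a tuple absent from
the key (including any N, or a deletion at a diagnostic column, rendered as
"-") ⇒ "other-combination"; otherwise the mapped species. Treating N and
indel columns as other-combination rather than too-short is a stated
choice: the read covered the column but the base call is unusable.

The discrepancy report compares clustering-based and character-based counts
per species: (clustering − character) / clustering × 100, rounded to one
decimal; the totals row uses summed species counts; other-combination and
too-short rows are percentages of total clustering-assigned reads. This
denominator convention reproduces every percentage printed in the source
study's comparison table from its printed count pairs.

## Quantification

Mock designs hold species × sample individual counts, individual lengths,
and the synonymy collapse map; expected profiles are collapsed count
fractions. Biomass conversion is dry weight = a·L^b (mg, L in mm) times a
carbon fraction (default 0.40); the shipped coefficient file contains
clearly-marked synthetic placeholders because the study cites external
regressions without printing them — users supply their own.

Two correlation views, both Pearson with two-sided t-distribution p-values
on n−2 df: "within taxon" (one taxon's fraction across ≥3 sample
compositions) and "among taxa" (all OTU fractions within one sample,
≥3 shared OTUs). Technical-replicate consistency is a per-OTU
Kruskal–Wallis test on relative abundances with the fraction of OTUs at
p < 0.05 as summary (whether the source study tested per-OTU or whole
profiles is unstated; per-OTU with a summary fraction is our choice).
Rarefaction is the analytic hypergeometric expectation
E[S_d] = Σ_o (1 − C(N−n_o, d)/C(N, d)) — deterministic, no resampling, and
equal to the mean over all without-replacement subsamples (checked against
exhaustive enumeration).

## Ordination and group tests

Correspondence analysis is computed by reciprocal averaging (power
iteration of the weighted double-averaging operator), site scores
initialized to an index ramp, convergence tolerance 1e-10, at most 1000
iterations, axes extracted sequentially. For plain CA, higher axes are
kept weighted-orthogonal to previous axes each iteration; the eigenvalues
match a direct SVD of the chi-square-standardized matrix to machine
precision. For DCA, axes ≥2 are instead detrended against every previous
axis by Hill's method — 26 equal-width segments, weighted segment means
removed. Axis orientation is fixed by making the first sample's score
non-negative. Nonlinear rescaling is off by default; the `rescale` flag
applies a simplified standardisation (unit weighted variance of site
scores), not Hill's full segment-wise rescaling.

Before ordination, OTUs are kept only if their relative abundance strictly
exceeds 0.5% in at least one sample, and relative abundances are
square-root transformed. Per-OTU two-group comparisons use the two-sided
Mann–Whitney U test (exact null for groups of ≤8 without ties, otherwise
normal approximation with tie correction), α = 0.05 with no multiplicity
correction by default — matching how the source analysis counted
significant OTUs — with an optional Benjamini–Hochberg flag.

## Synthetic data

The generator plants the structures the analysis must resolve: synonymy
groups sharing one amplicon, near-identical groups differing at exactly k
columns (the clupeid analogue uses the four-species key with tuples
CGC/CAT/TGC/CGT at three columns), and independent random amplicons of
120–134 nt. The packaged mock design reproduces the printed 13-species ×
4-sample composition (884 individuals; the most uneven sample has 89% of
counts in one euphausiid).

Sequencing simulation: template = forward primer + amplicon +
reverse-complemented reverse primer (adapter-padded if shorter than the
read length); forward read = first 150 nt, reverse read = last 150 nt
reverse-complemented. Template weights are individual count × rDNA copy
number and reads are drawn multinomially — the mechanism that makes
multicopy metabarcoding semi-quantitative. Copy numbers are log-uniform on
[1, 10^4] by default (a constant-copy-number null mode isolates multinomial
noise). Qualities follow a linear per-cycle profile (Q38 → Q25 by default)
with Gaussian per-base jitter (sd 4); substitution errors occur per base
with probability min(10^(−Q/10), error_rate), i.e. the configured error
rate caps the quality-derived rate, and zero disables errors. Errors are
substitution-only; chimeras are not simulated (an optional no-op interface
stands where chimera removal would run). A spike-in utility replaces a
Binomial(n, f) subset of a sample's reads with predator-derived reads for
predator-removal tests.

What the simulator does not emulate: PCR-cycle amplification bias, tag
jumping/mistagging, indel errors, chimera formation, and real per-cycle
error spectra. Passing tests therefore demonstrate the pipeline's
correctness and its behaviour under multinomial and copy-number noise, not
performance on real MiSeq runs.

## Problem sizes and seeds

Fixed-seed runs use master seed 1 throughout the test suite. Simulation
sizes were chosen as the smallest that make the statistical assertions
sharp: 20,000 reads/sample for composition recovery (binomial sd ≈ 0.2–0.35
percentage points), 5,000 reads for the classifier-agreement and
bidirectional comparisons, 10,000 for copy-number stress runs. Every
generator is bit-reproducible under a fixed seed.

## Known limitations

- The copy-number stress behaviour is a single random draw: whether a
  count-dominated sample keeps a high among-taxa correlation under a
  4-order copy-number draw depends on where the dominant taxon's copy
  number falls, so that quantity is intrinsically seed-sensitive (the
  within-taxon view is not).
- The raw number of merged-mode reads is bounded by pair survival of the
  ≤1-overlap-mismatch rule, so bidirectional superiority is a statement
  about per-read rates, not raw counts.
- Identity, primer matching and merging assume substitution-dominated
  error; long-indel reads will semi-globally align but may classify as
  other-combination at diagnostic columns.
- DCA rescaling is a simplified variance standardisation, not the
  segment-wise original.
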