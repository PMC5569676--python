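# Methods

## Coordinates and gene models

Annotation files are read in their on-disk conventions (GFF3/GTF 1-based
inclusive; BED 0-based half-open); every in-memory coordinate is 0-based
half-open, which removes off-by-one drift between modules. A gene model
keeps its individual transcripts plus a *summarized* representation: the
union of all transcripts' exons (merged, disjoint, sorted) and the span.
When a transcript has CDS features but no explicit `three_prime_UTR` rows,
the 3′-UTR is derived as the exonic space strictly 3′ of the CDS span,
strand-aware. Multi-piece UTRs are concatenated 5′→3′ when a single UTR
sequence is needed.

## miRNA classification

Classification uses the **precursor** interval (the miRBase GFF's primary
feature); mature coordinates are not required. The decision rule, applied
to the summarized host model:

* ≥ 1 bp overlap with any merged exon → **exonic** (a boundary-spanning
  precursor is exonic — exon overlap is the stronger evidence, and each
  miRNA must land in exactly one class);
* otherwise, ≥ 1 bp overlap with a gene span → **intronic**, with
  `intron_index` the 5′→3′ ordinal of the merged-model intron containing
  the precursor midpoint (numbered along the gene's strand);
* no overlap with any gene span → **intergenic**.

A precursor straddling a gene boundary is intragenic (inclusive
containment rule); because the span is the min/max over exons, such a
precursor always touches a terminal exon and is therefore exonic. When
several genes overlap the precursor the host is chosen deterministically:
sense-strand host first (cotranscription is the biologically expected
arrangement), then largest overlap, then lexicographically smallest
gene id. This makes classification invariant to gene input order.

## APA calling

Cleavage evidence is a read whose strand-aware 3′ soft clip begins with a
run of ≥ 4 untemplated A (forward) or whose leading soft clip ends in ≥ 4
T (reverse; the reverse-complemented tail). Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `tail_min` | 4 nt | minimum untemplated A/T run |
| `atn_max` | 0.8 | read discarded when (A+T+N)/length ≥ 0.8 |
| `min_support` | 2 reads | minimum cluster support |
| `window` | 40 nt | single-linkage merge distance (inclusive) |
| PAS window | 10–40 nt | hexamer start upstream of cleavage |
| PAS set | AATAAA, ATTAAA | canonical hexamers, configurable |

The A/T/N-content filter is computed on the full read sequence as stored
(whether it should be applied before or after tail trimming is an open
choice; full-read is the implemented one and the threshold is exposed). A
clipped tail counts as *untemplated* unless the reference bases under the
clip form a matching A-run (T-run on the reverse strand); without a
reference the caller can run in a documented lower-stringency mode that
accepts soft clips as-is. Cleavage position is the last aligned base,
strand-aware. Clustering is single linkage per (chrom, strand, gene) with
the 40-nt boundary inclusive — "within 40 nt" could also be read as
distance to a representative; single linkage is the implemented reading.
The representative position is the member with the highest read count,
ties broken toward the 3′ end (robust to tail wobble). Poly(A) indices
number the surviving sites 5′→3′ within each gene. Per-tissue utilization
is the fraction of a site's supporting reads from each read-group tissue.
Set comparison reports the fraction of reference sites with a query site
within the window on the same chrom/strand; an empty reference yields an
undefined (not zero) coverage.

## Seed sites and APA isoforms

The seed is bases 2–7 of the mature sequence; a canonical site is its
exact Watson–Crick reverse complement (DNA) in the sense-strand UTR — no
wobble pairs, no 7mer/8mer subtypes, N never matches. APA cleavage
offsets segment the UTR into nested prefix isoforms; a match's
`min_poly_a_index` is the smallest isoform index whose prefix contains the
*entire* 6-mer (a truncated site cannot pair), and filtering by poly(A)
index keeps matches with `min_poly_a_index ≤ index`. Non-canonical search
is Smith–Waterman local alignment of the reverse-complemented mature
(match +1, mismatch −1, linear gap −2, threshold 14 — explicit, tunable
choices; "high similarity" has no canonical quantitative definition), with
hits that are exactly a canonical 6-mer excluded. Hybridization energy is
not computed internally; an optional field records values from an external
hook.

## Network statistics

`P(S)` multiplies the background probabilities of the **seed's own**
nucleotides, implemented literally; whether the seed's or the target
site's composition was intended is ambiguous, so a `composition="site"`
switch evaluates the complementary bases instead (identical under any
strand-symmetric background). The background distribution defaults to the
frequencies of the submitted set's own UTRs (T counted as U, N excluded);
a genome-wide FASTA can be supplied.

The per-gene hit probability is the binomial upper tail over
`L = N − 6 + 1` placements with `r = 1` by default. `r = 1` uses
`−expm1(L·log1p(−p))`; `r > 1` sums the upper tail of `scipy`'s binomial
pmf so tiny probabilities keep full relative precision (verified against
exact-rational sums to ≤ 1e-12 relative error).

The score is the log-odds ratio of observed vs expected targeted genes,
`ln[(O·(|X|−E)) / (E·(|X|−O))]`: zero exactly at O = E, sign equal to
sign(O − E), antisymmetric under complementing counts around the set.
When any of the four terms is zero the Haldane–Anscombe correction (+0.5
on all four) keeps it finite; E = 0 with O > 0 is reported as +∞. The
correction is applied only when needed so that non-degenerate scores match
the plain formula; as a consequence, an expectation within 0.5 of 0 or
|X| can locally compress the ordering between O = 0 and O = 1 (the strict
monotonicity guarantee is stated for E ∈ [0.5, |X|−0.5]). The natural
logarithm is the default base; base only rescales rankings.

Fisher's exact test is evaluated on `scipy.stats.hypergeom` over the full
support of a margin set in one vectorized call (single tables and
whole-margin sweeps share the code path); the two-sided p-value sums all
outcomes no more probable than the observed one, with a 1e-7 relative
slack for ties. The observed-vs-expected table rounds E half away from
zero (Fisher needs integer counts), raising it to 1 when O > 0 would
otherwise face an empty expectation. Rankings attach Benjamini–Hochberg
adjusted p-values (`fisher_q`) alongside the raw ones as a clearly
labelled extension; the two-sided alternative is the default and
one-sided tests are exposed. Host-gene over/underrepresentation uses the
same machinery on the list-vs-background 2×2 table, with direction taken
from the host-fraction difference. Edge filtering is conjunctive, the
score threshold inclusive (a "minimum score" bound), with self-loops
removed and undirected duplicates collapsed to the maximum score.

## Expression

Spearman's rho is the Pearson correlation of mid-ranks. For n ≤ 8 the
two-sided p-value is exact — the fraction of all n! rank permutations with
|rho| at least the observed (six tissues make this trivially fast); larger
n uses the t-approximation. Missing values are dropped pairwise; fewer
than 3 complete pairs or zero rank variance yields a flagged result rather
than an exception. Expression units are taken as given (no normalization).
Ties in tissue-of-maximum-expression resolve to the first tissue in
canonical (column) order.

## The synthetic study

The generator builds a single toy chromosome with genes laid out
sequentially (three exons, CDS, a terminal-exon 3′-UTR; 30% of genes on
the minus strand), miRNA precursors placed in first introns, middle exons
or intergenic gaps, and everything downstream planted with recorded truth:

* defaults emulate the reported vertebrate ballpark — 60% of 20 miRNAs
  intragenic, 20% of those exonic and 20% antisense; UTRs 200–800 nt with
  uniform base composition; six tissues (brain, cerebellum, heart, kidney,
  liver, testis);
* APA plants write reads with soft-clipped A/T tails at known cleavage
  offsets (two callable sites ≥ 81 nt apart per gene in the first eight
  eligible genes) plus sub-threshold decoys (a single-read site and a
  3-nt-tail site) and high-A/T decoy reads that the content filter must
  remove; a canonical AATAAA is planted 20 nt upstream of every callable
  site and a non-A base guards each cleavage against templated tails;
* seed plants insert the reverse-complement 6-mer of a miRNA's seed into
  60% of gene UTRs (the enrichment scenario); accidental copies of any
  planted motif are scrubbed from the UTRs so manifest counts are exact;
* host-miRNA expression rows are exact monotone transforms of the host
  rows (true rho = 1); intergenic miRNAs get independent rows;
* the PPI table deliberately contains a self-loop and a duplicated pair to
  exercise edge cleaning.

Outputs are byte-identical for identical specs, and inconsistent specs
fail before any file is written.

What passing on these fixtures does **not** show: the generator has no
sequencing errors, no coverage or fragment-length model, no internal
priming artifacts beyond the A/T/N filter, no heteroscedastic expression
noise and no species-realistic base composition — recovery rates here are
upper bounds on real-data behaviour, and the planted-truth exactness is a
property of the simulation, not of any aligner.

## Test and acceptance scales

The test oracles run at sizes chosen to keep the default suite fast while
exhausting the relevant space: the binomial grid covers L ≤ 200 with
p ∈ [1e-4, 0.5] and r ≤ 3; the Fisher sweep enumerates all 635 376 tables
with N ≤ 60 exactly; the score contract samples 10⁴ random (|X|, E)
grids; seed scanning checks 1000 random UTR/mature pairs; enrichment
recovery runs 200 replicates of 50 UTRs with a 60% plant against a < 10%
background rate. The null-calibration check accepts the discreteness of
the exact test (p-values are conservative, not uniform): it bounds the
sub-0.05 mass at 12% and the mean from below at 0.35 over 150 null sets.

## Known limitations

* The classifier assigns one host per miRNA; overlapping-gene ties are
  resolved, not reported as multi-host.
* The APA caller does not model internal priming beyond the content
  filter and does not use paired-end information.
* Non-canonical site scoring is similarity-only; no thermodynamics,
  accessibility or conservation.
* The expected-targets model treats seed placements as independent
  Bernoulli trials, ignoring overlap correlations between adjacent
  windows (negligible for 6-mers at realistic UTR lengths).
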