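# Methods

This note records the models, defaults and numerical choices behind
`dwbiofilm`, and what the synthetic-community tests do and do not
establish.

## Synthetic communities

The generator states a fixed world rather than fitting one.

**Genomes.** Order-0 Markov (i.i.d.) DNA with a configurable GC content.
GC is the only compositional signal, so genomes are given GC values at
least 8 percentage points apart by default; that gap is what makes
tetranucleotide vectors separate genomes and 8-mer profiles separate
genera. Real genomes carry much richer k-mer structure (codon bias,
repeats, mobile elements), so a green separation test here shows the
machinery works on separable inputs, not that any two real genomes are
separable.

**Default community.** Five genomes with lengths
(0.75, 0.6, 0.5, 0.8, 0.5) Mb, fold-coverages (450, 250, 650, 80, 700)
and GC (0.60, 0.40, 0.52, 0.32, 0.68). Abundances are proportional to
coverage × length, which puts the dominant genome at 27.5% of the
sequenced bases at 450× — the "one dominant organism inside the 300–600×
selection window" regime the binning stage targets. The 650× genome sits
deliberately near the window edge: with lognormal coverage noise a few of
its contigs leak into the window, which is exactly the contamination the
composition filter exists to remove.

**Markers.** Each genome carries a 105-locus single-copy marker set
(600 bp loci placed evenly). Marker detection is not modelled — a marker
counts as present in a bin only when its locus is fully contained in one
member contig. Consequence: markers straddling contig boundaries are
lost, so even a perfect bin of a fragmented genome scores below 100%
completeness (~90% with the default 5–15 kb contigs). This is a known,
deliberate bias of the stand-in; real analyses supply an externally
produced hit table.

**Reads.** Shotgun fragments are Normal(180, 20) bp by default, sequenced
from both ends at 100 bp with i.i.d. substitution errors (default 0) and
Phred+33 qualities from Normal(35, 4) clipped to [2, 40] — chosen so the
Q<20 filter has something to act on. Fragments are drawn until the
sequenced bases reach the design total, so realized per-genome coverage
matches abundance × total / length to within edge effects. Amplicons are
barcode + forward primer + a genome fragment of Normal(438, 16) bp
truncated at ≥200. No indels, chimeras, homopolymer errors or strain
microdiversity are simulated; the amplicon error profile is a declared
default, not an inference.

## Amplicon preparation

Demultiplexing assigns a read only when exactly one barcode is within the
mismatch budget (default 0); ties are unassigned, preserving the
partition invariant. Primer matching is IUPAC-aware with a tolerance of
1 mismatch per 10 primer bases — a common amplicon practice chosen to
keep the operation deterministic. Depth normalization takes the first N
reads in file order (N = 8951 by convention); a `shuffle_seed` option
provides random subsampling instead, off by default, and normalization is
applied before clustering/classification.

## Distances and OTU clustering

Covariance-model alignment is out of scope; distances come from pairwise
global alignment (match +1, mismatch −1, gap −2, terminal gaps free, via
Biopython) with distance = differing columns / aligned columns, terminal
gap columns excluded and internal gap columns counted as differences. A
user-supplied multiple alignment is accepted as an alternative.

Complete-linkage clustering is agglomerative: repeatedly merge the pair
of clusters with the smallest maximum inter-point distance while that
distance is ≤ the threshold. Ties break toward the lexicographically
smallest (min-id, min-id) pair, making results order-independent; on
unique-distance instances the partition coincides with scipy's
`linkage(..., 'complete')` cut at the same height (tested). Every emitted
OTU satisfies the diameter constraint and no two emitted OTUs can be
merged without violating it.

## Alpha diversity

Chao1 classic is `S_obs + F1²/(2 F2)`; with no doubletons it is undefined
and falls back to the bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))`
with a warning. Both variants are exposed because the original pipeline's
choice is unrecoverable. Shannon uses natural log (base configurable);
Pielou at `S_obs = 1` is defined as 0 to avoid 0/0. Rarefaction uses the
exact hypergeometric expectation computed with log-gamma functions;
tests confirm agreement with 10,000-draw Monte-Carlo subsampling within
three standard errors.

## Taxonomic classifier

Word size 8, presence-based word likelihood `(m+0.5)/(M+1)`, scores
summed over a read's distinct words, ⌈W/8⌉ words per bootstrap trial,
100 trials, report at the deepest rank with support ≥0.8 — the classic
naive-Bayes rRNA classifier recipe. Both orientations are scored and the
better one used (the strand of an amplicon read is not generally known).
Confidence per rank is the fraction of trials whose winning genus shares
the best genus's taxon at that rank; confidences are raw fractions and
are not forced to be monotone across ranks. Bootstrap sampling is NumPy
`default_rng` seeded per read from a master seed, so fixed seeds give
identical confidences.

## Shotgun preparation

Both filter rules are strict inequalities (exactly 10% N or exactly 50%
low-quality bases is kept), verified by boundary enumeration.
De-replication keys on the forward mate's first 50 bp (mate handling in
the original description is ambiguous; a `both_mates` option concatenates
both prefixes). Merging reverse-complements the reverse mate and scans
all overlap lengths ≥10 bp, keeping the one with the most matching bases
among those with ≤10% mismatches; equal match counts go to the longer
overlap. Only substitution-tolerant overlaps are considered — no indels —
matching the fixed-length short-read regime. Consensus takes the
higher-quality base at disagreements and the max quality at agreements.

## Binning and QC

Tetranucleotide vectors pool each 4-mer with its reverse complement: 120
complementary pairs + 16 palindromes = 136 classes, making composition
strand-independent; windows containing non-ACGT characters are skipped.
Coverage selection is inclusive on both window ends, and the length rule
defaults to ≥300 bp with a flag for the strict reading (>300).

The composition filter's default is a robust-centroid percentile rule:
centroid = length-weighted component-wise median TNF, distance =
Euclidean, retain contigs within the 95th percentile of distances, one
pass. One pass (rather than iterating) is deliberate: each additional
q=95 pass would shave another 5% off an already-pure bin, while a single
pass removes the distant contaminants that the coverage window let
through. K-means (k by silhouette over 2–5, largest cluster by bp kept)
is available as an alternative. Euclidean TNF distance is the default
metric.

Completeness = % of the marker set present at ≥1 copy; redundancy = % of
present markers at >1 copy (0 when none present). Abundance =
100 · coverage · (bin bp / completeness) / total bp, which is
scale-invariant in sequencing depth by construction.

## Profiles and PCA

Rows (samples) are scaled to fractions; optional per-category
z-standardization (population SD, zero-variance categories dropped with a
warning) turns covariance PCA into correlation PCA — both exposed because
the original ordination tool's default is unstated. PCA is a plain SVD of
the column-centered matrix; the sign convention (largest-magnitude
loading entry positive) makes output reproducible across SVD
implementations, and results match scikit-learn's PCA up to that sign.

## Known limitations

* Marker completeness underestimates true bin completeness on fragmented
  assemblies (boundary-straddling loci), inflating the abundance estimate
  by the same factor; the default world stays within ±15% relative.
* The i.i.d. genome model makes composition-based separation easier than
  on real genomes with similar GC.
* The pairwise-alignment distance is O(n²) in reads and is intended for
  depth-normalized, desk-scale inputs, not raw runs.
* No chimera, indel or denoising models; quality strings are synthetic.
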