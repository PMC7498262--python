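# Methods

## Scope and model

cooccupy analyses transcription-factor co-occupancy at enhancers from called
ChIP-seq peaks and processed expression tables. It deliberately starts
*after* read processing: alignment, peak calling and differential-expression
model fitting are upstream tools' jobs, and their outputs (peaks with
summits, coverage tracks, per-stage log2FC/FDR tables, TPM matrices) are this
package's inputs. Within that scope the pipeline is: annotate peaks to genes
by nearest TSS, scan summit windows for Sox and Tcf motifs against a
dinucleotide-shuffled null, classify peaks by motif co-occurrence, intersect
bound and regulated gene sets, and categorize co-regulated genes by their
paired knockdown directions.

## Coordinates and annotation

All coordinates are 0-based half-open (BED). A peak's summit is its anchor:
summit windows are `[summit − w/2, summit + w/2)` with `w = 150` by default,
clipped at chromosome bounds; density windows use ±2000 bp in 50 bp bins.
Interval intersection requires ≥1 shared base — abutting half-open intervals
do not overlap.

Nearest-TSS annotation minimizes |summit − TSS| per chromosome, breaking ties
by lexicographically smaller gene id so results are deterministic. Distances
are signed in gene orientation (negative = upstream). Feature labels are
evaluated at the summit with precedence promoter > exon > intron >
intergenic. The promoter is the symmetric interval strictly within ±1 kb of
the TSS: a summit exactly 1 kb away is distal. The symmetric margin (rather
than an asymmetric upstream-biased one some annotators use) keeps the
definition orientation-free and easy to reason about; exon/intron membership
considers every gene span on the chromosome, not only the nearest gene, so a
peak sitting in one gene's intron but nearest to a neighbour's TSS is still
called intronic.

## Motif scanning

A PWM is a per-position base-probability matrix (A,C,G,T), pseudocount 1e-3
added and rows renormalized at ingestion (HOMER `.motif` and CIS-BP text
dialects are read). A window of length L at offset o scores
`S = Σᵢ log₂(pᵢ(bᵢ)/q(bᵢ))` against a background `q` (uniform by default),
and the *relative score* rescales S between the per-position attainable
minimum and maximum: `rel = (S − S_min)/(S_max − S_min)`. This min–max
convention is scale-free, makes a perfect consensus word score exactly 1,
and is the natural reading of a "70% of maximum" threshold; 0.70 is the
default cut. Both strands are scanned at every offset; windows containing N
are excluded rather than penalized; hits are reported in ascending offset
with + before − at equal offset. Scanning is vectorized (sliding-window
gather over an integer-encoded sequence), and the test suite pins it to a
per-window rescoring oracle at 1e-9.

Per peak, hits from different PWMs of the same TF class are merged by
distinct (offset, strand) — two Sox matrices firing at the same position
count once — and the peak is labelled `sox_and_tcf`, `sox_only`, `tcf_only`
or `neither` by presence/absence. Site spacing is the minimum Sox-to-Tcf
center distance (center = offset + L/2), with a flag at ≤50 bp; the
multi-site statistic is the fraction of peaks with strictly more than 5 Sox
sites.

## The shuffle null and enrichment test

The background for enrichment is built from the peaks' own windows: each
window is shuffled 10 times preserving its exact dinucleotide count vector
(hence mononucleotide counts and GC content), using the Altschul–Erickson
Euler-path construction, which also preserves the first and last base. Runs
of non-ACGT letters act as fixed separators with each ACGT segment shuffled
independently. Each shuffle is scanned and classified identically to a real
window and counted as an independent background sequence (10× the real n);
pooling keeps the 2×2 table structure the exact test needs, which per-peak
averaging would destroy.

Enrichment of a label is then a one-sided (greater) Fisher exact test on
(real with / real without / background with / background without). Sidedness
is one-sided because the scientific question is enrichment over background;
the two-sided variant is available in `cooccupy.stats`. Exact tails are
computed in log-space with `gammaln`, so large backgrounds do not overflow,
and are pinned to a rational-arithmetic enumeration oracle at 1e-12 in the
tests.

RNG contract: a single integer seed plus the sequence's own identifier
(CRC32-hashed) derives each window's stream, so shuffle output is
independent of processing order and bit-reproducible.

## Expression integration

The DE filter keeps a gene when any stage has |log2FC| > log₂(2) = 1
(strictly) and FDR < 0.05 (strictly); direction and the early/late class
come from the earliest significant stage, with NF-style stage labels ordered
numerically (NF9 < NF10 < NF10.5 < …) and the early set defaulting to
{NF9, NF10}. "Down in the knockdown" means the factor activates the gene.
The four regulatory categories are the total function on the two knockdown
directions: (down, down) → activated by both, (up, up) → repressed by both,
and the two mixed pairs; they partition any co-regulated set by
construction.

Tissue enrichment calls a tissue when its expression exceeds 1.5× the mean
across tissues — scale-invariant, so any TPM-like normalized unit works.
Subset-vs-genome pattern comparisons offer both a chi-square goodness-of-fit
on label counts and a two-sample KS on a per-gene ordinal statistic; both
are exposed because practice varies, chi-square being the default.

Bound∩regulated intersections use the upper-tail hypergeometric
P(X ≥ k) over a user-supplied gene universe (there is no privileged
universe; the annotation's gene set is the usual choice). Reporter assays are
summarized as firefly/renilla ratios with mean, sample SD and a two-sided
pooled-variance Student t against a reference condition; a zero pooled
variance is reported with an explicit degenerate flag (p = 0 for differing
means) rather than NaN.

## Synthetic data and what it does (not) show

The generators exist so every stage has a dataset with known truth:

- `simulate_genome`: first-order Markov chain from a 16-entry dinucleotide
  distribution, stationary start, uniform by default.
- `plant_peaks`: 300 bp peaks, summit-centered, with PWM *consensus* words
  written at random non-overlapping offsets/strands inside the 150 bp summit
  window, at class fractions (both, sox-only, tcf-only, neither) =
  (0.5, 0.25, 0, 0.25) by default — the regime where co-occurrence dominates
  and one class is absent — with 2 Sox and 1 Tcf site per labelled peak.
  Counts are round(n·fraction) with the remainder assigned to the largest
  fraction. Because a 0.70 relative-score threshold tolerates a few
  mismatches, random backgrounds occasionally contain chance sites; the
  generator therefore rescans each window after planting and resamples the
  background (dinucleotide shuffles of the original window, then uniform
  redraws) until the detected (offset, strand) sets equal the planted sets
  exactly. The manifest is thereby true by construction at the scan
  threshold, which is what makes 100% class recovery a meaningful check of
  the scanner rather than a statement about real enhancers.
- `simulate_expression`: log-normal baseline TPM over four dissected-tissue
  labels, one assigned tissue multiplied by 3.0 for an enriched 30% of
  genes, multiplicative log-normal noise with CV ≈ `noise_cv` (exactly zero
  noise at 0). With 4 tissues and factor 3, the enriched value (3b) exceeds
  1.5× the mean (2.25b), so zero-noise recovery is exact by arithmetic.
- `simulate_de`: per-gene, per-stage replicate log2 abundances (SD =
  dispersion, 3 replicates), true effects |log2FC| ~ N(2.5, 0.5) with random
  sign and onset stage, p from the pooled t-test, FDR by Benjamini–Hochberg
  within stage. The DE filter consumes only (log2FC, FDR), so a count-level
  model would add nothing the downstream code could see.

What passing these tests shows: the kernels are exact, the pipeline recovers
planted structure perfectly in the noiseless regime, and the tests are
calibrated under the null. What they do not show: behaviour under mapping
artifacts, peak-calling noise, motif-model misspecification, or real
enhancer sequence composition — real data carry all of these.

## Numerical and design notes

- Exact tails in log-space; test oracles use `fractions.Fraction`.
- KS p-values use the asymptotic Kolmogorov distribution with effective
  sample size nm/(n+m); D itself is exact. Small-sample exact p is out of
  scope.
- The two-sided Fisher convention sums all tables no more probable than the
  observed one (with a 1e-7 relative guard against log-space ties).
- Fold-change and FDR boundaries are strict inequalities; a gene at exactly
  2-fold or exactly FDR 0.05 is excluded.
- narrowPeak summit offset −1 (and BED6 peaks generally) default the summit
  to the interval midpoint, floor division.
- Density-matrix rows default to descending total signal (input order
  available); truncated windows average over covered bases only.
- Problem sizes in the test suite and acceptance script (100 kb genomes,
  200 peaks, 20-peak null replicates, 500-gene DE runs) were chosen as the
  smallest sizes at which the binomial tolerances of the calibration checks
  are informative.

## Known limitations

Peak calling, IDR filtering, DE model fitting, GO enrichment and de novo
motif discovery are out of scope by design. The scanner's background model
is the window's own dinucleotide shuffle; it does not model regional GC
isochores or repeat structure. tf_class membership of user-supplied motif
libraries is the user's responsibility. The KS p-value is asymptotic, and
the chi-square test requires merging labels with zero expected counts.
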