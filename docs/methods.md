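# Methods

## Problem and approach

Somatic variant callers compare a tumor sample against the patient's
matched normal and emit candidate mutations. They are tuned for recall, so
their raw output is rich in false positives driven by sample purity,
subclonal structure, sequencing chemistry, alignment error and reference
repetitiveness. somafilt post-processes any caller's VCF with a two-stage
procedure:

1. **Metrics stage.** For every candidate allele, both BAMs are traversed
   and a per-sample panel of read-level statistics is computed. The panel
   is persisted to gzipped TSV chunks so reruns with different thresholds
   never repeat the expensive traversal.
2. **Filter stage.** A configurable, ordered list of named threshold
   filters is evaluated against the panel. The result is an annotated VCF
   (FILTER column = `PASS` or the semicolon-joined failed filter names),
   a per-variant results table, a per-filter summary with a bar chart, and
   a log that records every threshold applied.

Filtering quality is scored as recall = TP/(TP+FN), precision =
TP/(TP+FP) and F1 = 2TP/(2TP+FP+FN), the harmonic mean of the two; any
0/0 ratio is reported as NA rather than 0.

## The metric panel

Per sample and site: depth and ref/alt/other counts (depth is their sum by
construction); VAF = alt/depth; midpoint medians of alt and ref base
quality, of alt mapping quality and of all-read mapping quality; per-strand
alt and ref counts; the median distance of the variant base from the
nearest read end, min(q, L−1−q) for query offset q and read length L; the
raw (unscaled) median absolute deviation of q over alt reads; the fraction
of alt reads with any soft-clip; the mean excess edit distance of alt reads
(NM − 1 for the variant itself, floored at 0); the MQ0 fraction and the
fraction of reads with an indel within ±5 reference bp of the site, both
over all included reads; and the fraction of alt reads not properly paired.

Conventions chosen where more than one defensible option existed:

- **Read inclusion.** Unmapped, secondary, supplementary, QC-fail and
  duplicate reads are excluded. MAPQ-0 reads and improper pairs are
  *included* — otherwise `mq0_frac` and `improper_pair_frac_alt` could
  never fire. Overlapping mates are counted independently (no
  fragment-level dedup), so depth can double-count short fragments.
- **Alt-conditioned statistics** are NA exactly when there are zero alt
  reads; VAF is NA only at zero depth. Reads without a base-quality string
  are dropped from base-quality medians only.
- **Near-indel window** of ±5 bp: indel-adjacent miscalls cluster tightly
  around the indel, and a wider window dilutes the signal at normal depths.
- **Non-SNV candidates** get counts and VAF only (alt defined by exact
  allele match at POS), with all geometry metrics NA; the filter catalogue
  and the validation scope of this tool are SNV-centric.

## The filter catalogue

Each filter reads one metric from one sample; `min` direction fails when
metric < threshold, `max` when metric > threshold, and equality always
passes — one global tie-break rule keeps configs interpretable. NA
resolution: with zero depth a filter is not applicable; with coverage but
no alt evidence, alt-conditioned filters fail (no supporting evidence is
itself disqualifying). The strand filter compares min(alt_fwd, alt_rev) /
alt_count and is evaluated only with ≥ 10 alt reads, below which the minor
fraction is dominated by sampling noise.

Default preset: tumor/normal depth ≥ 10, tumor alt count ≥ 3, tumor VAF ≥
0.05, normal VAF ≤ 0.03, normal alt count ≤ 1, alt median BQ ≥ 30, alt
median MQ ≥ 40, minor-strand fraction ≥ 0.05, median distance to read end ≥
10, MAD of variant position ≥ 3, soft-clip fraction ≤ 0.30, mean excess NM
≤ 2.0, MQ0 fraction ≤ 0.10, near-indel fraction ≤ 0.30, improper-pair
fraction ≤ 0.50. The ICGC preset keeps the same catalogue with deeper
required coverage (25/25), tighter normal evidence (VAF ≤ 0.02, alt count
≤ 0) and relaxed BQ/MQ/strand cuts (25/30/0.01). **Both preset tables are
reconstructed** from the published ICGC-style recommendations and standard
somatic-filtering heuristics rather than copied from any single source;
users are expected to tune them to their own depth, purity and aligner via
the two-column config file, which is also the recommended way to share a
filtering strategy.

Whether strand bias is better judged by a statistical test (e.g. Fisher on
the strand contingency table) than by a minor-fraction cut is a genuinely
open choice; the fraction rule was picked because it is monotone in a
single threshold and therefore composes with the config format like every
other filter.

## Caching and parallelism

Candidates are processed in chunks (default 1000/chunk; the desk-scale
tests use 5–20 to exercise multi-chunk paths). Each chunk is persisted
before the next begins; on restart, chunks present under a matching
fingerprint — VCF record count, tool version, chunk size and column list —
are loaded, never recomputed, and a mismatch invalidates the whole cache
with a logged warning rather than silently reusing stale rows. Chunk
outputs are written with a pinned gzip mtime so identical inputs give
byte-identical files. Because chunk boundaries and ordering are fixed
before dispatch, the final table is invariant to the `--jobs` value.

## Synthetic fixtures

The generator emulates just enough of Illumina-style paired sequencing to
exercise every filter: a uniform-random reference contig; 100-bp ungapped
single-segment reads at depth 80 per sample; per-read base quality ~
N(35, 3) clipped to [2, 41]; MQ 60; alternating strands; proper-pair flags
synthesized without emitting mates. True somatic sites draw their alt count
from Binomial(depth, VAF) with the normal kept clean. One artifact class is
planted per filter, each violating its targeted metric by a deliberate
margin (e.g. alt count 3/80 for the VAF filter so the alt-count filter
stays quiet; all-forward alt reads for the strand filter; a fixed query
position for the MAD filter; 30 % MQ0 reference reads for the MQ0 filter so
the alt MQ median is untouched).

Two deviations from "uniform everywhere" are deliberate:

- Alt-supporting reads place the variant ≥ 10 bp from either read end
  (reference reads span the whole read). With ~8 supporting reads at VAF
  0.10, a fully uniform draw puts the *median* distance below the default
  read-end threshold in a non-trivial fraction of loci, i.e. the clean
  class would trip its own filter by sampling noise rather than by design.
- The VAF-sweep scenario plants 12 replicates per VAF in
  {0.02, 0.05, 0.10, 0.20, 0.40}. Per-site pass probabilities under the
  default preset rise steeply across that grid (≈ 0.08, 0.6, 0.97, 1.0),
  and 12 replicates make the observed pass rate a stable estimate of that
  ordering at desk scale.

What the fixtures do **not** model: sequencing-error profiles, quality
recalibration structure, fragment-length distributions, real mate pairs,
GC/mappability bias, or subclonal copy number. Passing tests therefore
demonstrate that each filter measures and cuts exactly what it claims on
reads with known ground truth — not that the default thresholds are
optimal for any particular real data set.

## Numerical choices and degenerate inputs

Medians use the midpoint convention for even counts; the MAD is unscaled;
both are verified field-for-field against an independent brute-force
recomputation over random pileups. Metrics tables round-trip through
gzipped TSV at 6 significant figures with `NA` as the missing-value
sentinel. Empty pileups give depth 0 and an all-NA panel; an empty filter
config loads with a prominent warning and passes everything; a truth/call
comparison with no shared contigs warns (likely `chr1` vs `1` naming) but
still counts. Multi-allelic records are split per ALT and filtered
independently; the emitted FILTER for the original record is the verdict of
its first ALT, with per-ALT verdicts in the results table, so the output
VCF always has exactly as many data lines as the input (unless
`--pass-only` is requested).

## Limitations

SNV-focused; no panel-of-normals, population-frequency or repeat-track
filters; no realignment, BAQ or overlapping-mate base-quality merging; no
gVCF/BCF-only/structural-variant support; no left-alignment of input
records. Default thresholds were chosen for ~30–90× BWA-aligned Illumina
data — deep targeted panels or other aligners will need adjusted configs.
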