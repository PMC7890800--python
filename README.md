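# somafilt

Reproducible post-call filtering of somatic SNVs from matched tumor/normal
sequencing.

Somatic variant callers are built for recall: their raw VCFs recover most
true mutations but carry a large false-positive load from sample impurity,
subclonality, chemistry artifacts, misalignment and repeats. Most groups
clean this up with ad-hoc in-house scripts, which makes published call sets
hard to reproduce. somafilt replaces that step with a two-stage tool that
works with any caller's VCF:

1. **Metrics** — for every candidate site it traverses the tumor and
   normal BAMs and computes a read-level panel per sample: depth, allele
   counts and VAF; median base/mapping qualities of alt-supporting reads;
   strand counts; median distance of the variant base from the read end and
   the MAD of its position in the read; soft-clip, excess-NM (edit
   distance), MQ0, near-indel and improper-pair fractions. Metrics are
   cached as gzipped TSV chunks, so re-filtering with new thresholds is
   instant.
2. **Filters** — an ordered set of named threshold filters over that
   panel, fully configurable through a two-column tab-delimited file
   (`filter_name<TAB>threshold`) that can be published alongside results.
   Built-in presets: a default set and an ICGC-recommendation set
   (`--icgc`).

Calls are scored against a truth set with recall = TP/(TP+FN), precision =
TP/(TP+FP) and F1 = 2TP/(2TP+FP+FN) (the harmonic mean of the two). A
seeded synthetic fixture generator plants true somatic sites plus one
artifact class per filter, so the whole pipeline is testable without any
external data.

## Worked example

Generate a synthetic tumor/normal pair with 20 true somatic sites and 36
planted artifacts (3 per artifact class), filter it with the default
preset, and score the result:

```sh
somafilt fixtures --scenario artifact_suite --seed 11 --out fx
somafilt run --tumor fx/tumor.bam --normal fx/normal.bam \
             --vcf fx/candidates.vcf --out results
somafilt evaluate --calls results/filtered.vcf --truth fx/truth.tsv
```

The last command prints:

```
TP=20 FP=0 FN=0 recall=1.0000 precision=1.0000 F1=1.0000
```

i.e. all 36 artifacts were removed (each by the filter designed to catch
it) and all 20 true sites were kept. Unfiltered, the same candidate set
scores precision 0.36. `results/` also contains the annotated
`filtered.vcf` (FILTER column `PASS` or the failed filter names, with
every threshold recorded in the header), a per-variant `filter_results.tsv`,
a `filter_summary.tsv` with per-filter pass/fail counts, the matching bar
chart `filter_counts.png`, and a log. Re-running in the same output
directory reuses every cached metrics chunk.

Custom thresholds: copy a preset from `src/somafilt/data/`, edit, and pass
it with `--filters my_filters.tsv` (mutually exclusive with `--icgc`).

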