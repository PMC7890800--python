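"""Stage 2: named threshold filters over the per-variant metric panel.

Each filter in the catalogue reads one metric from one sample and fails a
variant when the metric falls on the wrong side of its threshold
(``min`` direction: fail when metric < threshold; ``max``: fail when
metric > threshold).  Equality always passes, in both directions.  Missing
metrics (no alt evidence) are resolved by each filter's NA policy:
alt-conditioned filters fail on NA whenever there is coverage, since zero
alt evidence is itself disqualifying for a somatic call; at zero depth a
filter is not applicable.  The strand filter is evaluated only when there
are at least 10 alt reads, since a minor-strand fraction over fewer reads is
noise.
"""

from __future__ import annotations

import logging
import math
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .io_formats import FilterConfig, MetricsTable

logger = logging.getLogger("somafilt")

PASS = "pass"
FAIL = "fail"
NOT_APPLICABLE = "not_applicable"

STRAND_MINOR_FRAC = "strand_minor_frac_alt"  # derived from strand counts


class CatalogueMismatchError(ValueError):
    """Raised when a configured filter's metric is absent from the table."""


def _is_na(value: object) -> bool:
    if value is None:
        return True
    try:
        return math.isnan(float(value))
    except (TypeError, ValueError):
        return True


@dataclass(frozen=True)
class FilterSpec:
    """One catalogue entry: which metric to read, from which sample, and how
    to compare it against the user's threshold."""

    name: str
    sample: str  # "tumor" | "normal"
    metric: str
    direction: str  # "min" | "max"
    na_policy: str = "fail_on_na"  # or "pass_on_na"
    description: str = ""
    min_alt_for_eval: int = 0  # evaluate only when alt_count >= this

    def required_columns(self) -> list[str]:
        cols = [f"{self.sample}_depth", f"{self.sample}_alt_count"]
        if self.metric == STRAND_MINOR_FRAC:
            cols += [f"{self.sample}_alt_fwd", f"{self.sample}_alt_rev"]
        else:
            cols.append(f"{self.sample}_{self.metric}")
        return cols

    def value(self, row: Mapping[str, object]) -> float | None:
        if self.metric == STRAND_MINOR_FRAC:
            fwd = row[f"{self.sample}_alt_fwd"]
            rev = row[f"{self.sample}_alt_rev"]
            alt = row[f"{self.sample}_alt_count"]
            if _is_na(fwd) or _is_na(rev) or _is_na(alt) or float(alt) == 0:
                return None
            return min(float(fwd), float(rev)) / float(alt)
        v = row[f"{self.sample}_{self.metric}"]
        return None if _is_na(v) else float(v)


CATALOGUE: dict[str, FilterSpec] = {
    spec.name: spec
    for spec in [
        FilterSpec("min_depth_tumor", "tumor", "depth", "min",
                   description="Minimum tumor depth of coverage at the site"),
        FilterSpec("min_depth_normal", "normal", "depth", "min",
                   description="Minimum normal depth of coverage at the site"),
        FilterSpec("min_alt_count_tumor", "tumor", "alt_count", "min",
                   description="Minimum number of tumor reads supporting the alternate allele"),
        FilterSpec("min_vaf_tumor", "tumor", "vaf", "min",
                   description="Minimum tumor variant allele frequency"),
        FilterSpec("max_vaf_normal", "normal", "vaf", "max", na_policy="pass_on_na",
                   description="Maximum normal variant allele frequency (germline/contamination guard)"),
        FilterSpec("max_alt_count_normal", "normal", "alt_count", "max", na_policy="pass_on_na",
                   description="Maximum number of normal reads supporting the alternate allele"),
        FilterSpec("min_median_bq_alt_tumor", "tumor", "median_bq_alt", "min",
                   description="Minimum median base quality of tumor alt-supporting bases"),
        FilterSpec("min_median_mq_alt_tumor", "tumor", "median_mq_alt", "min",
                   description="Minimum median mapping quality of tumor alt-supporting reads"),
        FilterSpec("strand_minor_frac_alt_tumor", "tumor", STRAND_MINOR_FRAC, "min",
                   min_alt_for_eval=10,
                   description="Minimum minor-strand fraction of tumor alt reads "
                               "(strand-bias guard; evaluated only with >=10 alt reads)"),
        FilterSpec("min_median_dist_readend_alt_tumor", "tumor", "median_dist_readend_alt", "min",
                   description="Minimum median distance of the variant base from the nearest read end"),
        FilterSpec("min_mad_pos_alt_tumor", "tumor", "mad_pos_alt", "min",
                   description="Minimum MAD of variant position within tumor alt reads "
                               "(near-zero flags single-position PCR/alignment artifacts)"),
        FilterSpec("max_softclip_frac_alt_tumor", "tumor", "softclip_frac_alt", "max",
                   description="Maximum fraction of tumor alt reads carrying soft-clips"),
        FilterSpec("max_excess_nm_alt_tumor", "tumor", "mean_excess_nm_alt", "max",
                   description="Maximum mean excess edit distance (NM minus the variant itself) "
                               "of tumor alt reads"),
        FilterSpec("max_mq0_frac_tumor", "tumor", "mq0_frac", "max",
                   description="Maximum fraction of tumor reads with mapping quality zero"),
        FilterSpec("max_near_indel_frac_tumor", "tumor", "near_indel_frac", "max",
                   description="Maximum fraction of tumor reads with an indel within 5 bp of the site"),
        FilterSpec("max_improper_pair_frac_alt_tumor", "tumor", "improper_pair_frac_alt", "max",
                   description="Maximum fraction of tumor alt reads not in a proper pair"),
    ]
}

# Default thresholds; the catalogue names are the stable public API and every
# threshold is overridable by a user config file.
DEFAULT_THRESHOLDS: "OrderedDict[str, float]" = OrderedDict(
    [
        ("min_depth_tumor", 10.0),
        ("min_depth_normal", 10.0),
        ("min_alt_count_tumor", 3.0),
        ("min_vaf_tumor", 0.05),
        ("max_vaf_normal", 0.03),
        ("max_alt_count_normal", 1.0),
        ("min_median_bq_alt_tumor", 30.0),
        ("min_median_mq_alt_tumor", 40.0),
        ("strand_minor_frac_alt_tumor", 0.05),
        ("min_median_dist_readend_alt_tumor", 10.0),
        ("min_mad_pos_alt_tumor", 3.0),
        ("max_softclip_frac_alt_tumor", 0.30),
        ("max_excess_nm_alt_tumor", 2.0),
        ("max_mq0_frac_tumor", 0.10),
        ("max_near_indel_frac_tumor", 0.30),
        ("max_improper_pair_frac_alt_tumor", 0.50),
    ]
)

# ICGC-style preset: deeper required coverage, (near-)zero tolerated normal
# evidence, slightly relaxed quality/strand cuts.  Reconstructed from the
# published recommendations; see docs/methods.md.
ICGC_THRESHOLDS: "OrderedDict[str, float]" = OrderedDict(DEFAULT_THRESHOLDS)
ICGC_THRESHOLDS.update(
    {
        "min_depth_tumor": 25.0,
        "min_depth_normal": 25.0,
        "min_vaf_tumor": 0.05,
        "max_vaf_normal": 0.02,
        "max_alt_count_normal": 0.0,
        "min_median_bq_alt_tumor": 25.0,
        "min_median_mq_alt_tumor": 30.0,
        "strand_minor_frac_alt_tumor": 0.01,
    }
)


@dataclass
class FilterVerdict:
    """Per-filter outcomes for one variant; overall pass iff nothing failed."""

    key: tuple[str, int, str, str]
    outcomes: "OrderedDict[str, str]" = field(default_factory=OrderedDict)

    @property
    def overall(self) -> bool:
        return all(o != FAIL for o in self.outcomes.values())

    @property
    def failed_filters(self) -> list[str]:
        return [n for n, o in self.outcomes.items() if o == FAIL]


@dataclass
class FilterSummary:
    per_filter: "OrderedDict[str, dict[str, int]]"
    total: int
    overall_pass: int

    @classmethod
    def from_verdicts(cls, verdicts: Sequence[FilterVerdict]) -> "FilterSummary":
        per: "OrderedDict[str, dict[str, int]]" = OrderedDict()
        for v in verdicts:
            for name, outcome in v.outcomes.items():
                counts = per.setdefault(name, {PASS: 0, FAIL: 0, NOT_APPLICABLE: 0})
                counts[outcome] += 1
        return cls(
            per_filter=per,
            total=len(verdicts),
            overall_pass=sum(1 for v in verdicts if v.overall),
        )


def evaluate_filter(
    spec: FilterSpec, threshold: float, row: Mapping[str, object]
) -> str:
    """Outcome of one filter on one variant's metric row."""
    depth = row.get(f"{spec.sample}_depth")
    if spec.min_alt_for_eval:
        alt = row.get(f"{spec.sample}_alt_count")
        if _is_na(alt) or float(alt) < spec.min_alt_for_eval:
            return NOT_APPLICABLE
    value = spec.value(row)
    if value is None:
        if _is_na(depth) or float(depth) == 0:
            return NOT_APPLICABLE
        return FAIL if spec.na_policy == "fail_on_na" else PASS
    if spec.direction == "min":
        return FAIL if value < threshold else PASS
    return FAIL if value > threshold else PASS


def apply_filters(config: FilterConfig, table: MetricsTable) -> list[FilterVerdict]:
    """Evaluate every configured filter against every row of the table.

    Verdicts come back in table (i.e. VCF) order; only configured filters
    are evaluated, and an empty config passes everything.
    """
    columns = set(table.df.columns)
    for name in config.names:
        spec = CATALOGUE[name]
        missing = [c for c in spec.required_columns() if c not in columns]
        if missing:
            raise CatalogueMismatchError(
                f"filter {name!r} needs column(s) {missing} absent from the "
                "metrics table; the table was built by an incompatible tool version"
            )
    verdicts: list[FilterVerdict] = []
    for row in table.rows():
        key = (str(row["contig"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        outcomes: "OrderedDict[str, str]" = OrderedDict()
        for name, threshold in config.entries:
            outcomes[name] = evaluate_filter(CATALOGUE[name], threshold, row)
        verdicts.append(FilterVerdict(key=key, outcomes=outcomes))
    return verdicts


def write_results_tsv(
    verdicts: Sequence[FilterVerdict], config: FilterConfig, path: str | Path
) -> Path:
    """Per-variant results file: one row per variant, one column per filter."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["contig", "pos", "ref", "alt", *config.names, "overall"]) + "\n")
        for v in verdicts:
            cells = [str(x) for x in v.key]
            cells += [v.outcomes[n] for n in config.names]
            cells.append(PASS if v.overall else FAIL)
            fh.write("\t".join(cells) + "\n")
    return path


def summarize_and_plot(
    verdicts: Sequence[FilterVerdict], out_dir: str | Path
) -> FilterSummary:
    """Write the per-filter pass/fail summary TSV and bar chart."""
    if not verdicts:
        raise ValueError("cannot summarize an empty verdict list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = FilterSummary.from_verdicts(verdicts)

    tsv_path = out_dir / "filter_summary.tsv"
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("filter\tpass\tfail\tnot_applicable\ttotal\n")
        for name, counts in summary.per_filter.items():
            fh.write(
                f"{name}\t{counts[PASS]}\t{counts[FAIL]}\t{counts[NOT_APPLICABLE]}\t"
                f"{summary.total}\n"
            )
        fh.write(f"overall\t{summary.overall_pass}\t{summary.total - summary.overall_pass}"
                 f"\t0\t{summary.total}\n")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(summary.per_filter)
    passes = [summary.per_filter[n][PASS] for n in names]
    fails = [summary.per_filter[n][FAIL] for n in names]
    nas = [summary.per_filter[n][NOT_APPLICABLE] for n in names]
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(names)), 4.5))
    x = range(len(names))
    ax.bar(x, passes, label="pass", color="#4c72b0")
    ax.bar(x, fails, bottom=passes, label="fail", color="#c44e52")
    ax.bar(x, nas, bottom=[p + f for p, f in zip(passes, fails)],
           label="not applicable", color="#bbbbbb")
    ax.set_xticks(list(x))
    ax.set_xticklabels(names, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("variants")
    ax.set_title("Per-filter pass/fail counts")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "filter_counts.png", dpi=120)
    plt.close(fig)
    return summary
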