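"""Score a filtered call set against a truth set.

Matching is exact on (contig, pos, ref, alt) — SNV-only scope needs no
distance window or normalization.  Recall = TP/(TP+FN), precision =
TP/(TP+FP) and F1 = 2TP/(2TP+FP+FN), the harmonic mean of the two; any 0/0
ratio is reported as NA (None), never as 0.  When the truth set is the raw
(pre-caller) truth, FN counts include variants the caller itself missed,
not only filtering losses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io_formats import CandidateVariant, read_candidate_variants

logger = logging.getLogger("somafilt")

Key = tuple[str, int, str, str]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class EvaluationSummary:
    counts: ConfusionCounts
    recall: float | None
    precision: float | None
    f1: float | None


def _to_keys(calls: Iterable) -> set[Key]:
    keys: set[Key] = set()
    for c in calls:
        if isinstance(c, CandidateVariant):
            keys.add(c.key)
        else:
            contig, pos, ref, alt = c
            keys.add((str(contig), int(pos), str(ref), str(alt)))
    return keys


def match_truth(passing_calls: Iterable, truth_calls: Iterable) -> ConfusionCounts:
    """Confusion counts from exact (contig, pos, ref, alt) matching.

    Accepts CandidateVariant iterables or bare key tuples.  Disjoint contig
    naming between non-empty sets (e.g. ``chr1`` vs ``1``) draws a warning
    but counts are still computed.
    """
    passing = _to_keys(passing_calls)
    truth = _to_keys(truth_calls)
    if passing and truth:
        contigs_p = {k[0] for k in passing}
        contigs_t = {k[0] for k in truth}
        if not contigs_p & contigs_t:
            logger.warning(
                "no contig shared between calls (%s) and truth (%s); "
                "check reference naming",
                sorted(contigs_p)[:5],
                sorted(contigs_t)[:5],
            )
    tp = len(passing & truth)
    return ConfusionCounts(tp=tp, fp=len(passing) - tp, fn=len(truth) - tp)


def score(counts: ConfusionCounts) -> EvaluationSummary:
    """Recall, precision and F1 from confusion counts (0/0 -> NA)."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    recall = tp / (tp + fn) if tp + fn else None
    precision = tp / (tp + fp) if tp + fp else None
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else None
    return EvaluationSummary(counts=counts, recall=recall, precision=precision, f1=f1)


def f1_from_precision_recall(precision: float, recall: float) -> float | None:
    """Harmonic mean of precision and recall; None when both are zero."""
    if precision + recall == 0:
        return None
    return 2 * precision * recall / (precision + recall)


def load_truth(path: str | Path) -> list[CandidateVariant]:
    """Load a truth set from a VCF (PASS records only) or a 4-column TSV."""
    path = Path(path)
    if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        return read_candidate_variants(path, pass_only=True)
    out: list[CandidateVariant] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(
                    f"{path}:{lineno}: truth TSV needs 4 columns (contig, pos, ref, alt)"
                )
            out.append(
                CandidateVariant(
                    contig=parts[0], pos=int(parts[1]), ref=parts[2].upper(),
                    alt=parts[3].upper(),
                )
            )
    return out


def write_summary_tsv(summary: EvaluationSummary, path: str | Path) -> Path:
    path = Path(path)

    def fmt(v: float | None) -> str:
        return "NA" if v is None else f"{v:.6g}"

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("TP\tFP\tFN\trecall\tprecision\tf1\n")
        fh.write(
            f"{summary.counts.tp}\t{summary.counts.fp}\t{summary.counts.fn}\t"
            f"{fmt(summary.recall)}\t{fmt(summary.precision)}\t{fmt(summary.f1)}\n"
        )
    logger.info(
        "evaluation: TP=%d FP=%d FN=%d recall=%s precision=%s F1=%s",
        summary.counts.tp, summary.counts.fp, summary.counts.fn,
        fmt(summary.recall), fmt(summary.precision), fmt(summary.f1),
    )
    return path
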