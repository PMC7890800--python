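"""Stage 1: per-site read-level metrics from tumor and normal alignments.

For every candidate variant the tumor and normal BAMs are traversed and a
panel of read-level statistics is computed per sample — allele counts and
VAF, base/mapping-quality medians, strand counts, position-in-read geometry
(distance to read end, MAD of query position), soft-clip and edit-distance
load, MQ0 and near-indel fractions, and improper-pair rates.  None of these
are recoverable from the caller's VCF alone.

Read inclusion: unmapped, secondary, supplementary, QC-fail and duplicate
reads are excluded; MAPQ-0 reads and improper pairs are included (they feed
``mq0_frac`` and ``improper_pair_frac_alt``).  Overlapping mates are counted
independently.  Medians use the midpoint convention for even counts and the
MAD is the raw (unscaled) median absolute deviation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from joblib import Parallel, delayed

from . import __version__
from .io_formats import (
    KEY_COLUMNS,
    CandidateVariant,
    MetricsTable,
    StaleMetricsError,
    read_candidate_variants,
    read_table_gz,
    write_table_gz,
)

logger = logging.getLogger("somafilt")

DEL_MARKER = "DEL"
REFSKIP_MARKER = "REFSKIP"

NEAR_INDEL_WINDOW = 5  # reference bp either side of the site
DEFAULT_CHUNK_SIZE = 1000

SAMPLE_METRIC_NAMES = [
    "depth",
    "ref_count",
    "alt_count",
    "other_count",
    "vaf",
    "median_bq_alt",
    "median_bq_ref",
    "median_mq_alt",
    "median_mq_all",
    "alt_fwd",
    "alt_rev",
    "ref_fwd",
    "ref_rev",
    "median_dist_readend_alt",
    "mad_pos_alt",
    "softclip_frac_alt",
    "mean_excess_nm_alt",
    "mq0_frac",
    "near_indel_frac",
    "improper_pair_frac_alt",
]

TABLE_COLUMNS = (
    KEY_COLUMNS
    + [f"tumor_{m}" for m in SAMPLE_METRIC_NAMES]
    + [f"normal_{m}" for m in SAMPLE_METRIC_NAMES]
)


class ContigMismatchError(ValueError):
    """Raised when a candidate's contig is absent from an alignment file."""


@dataclass(frozen=True)
class ReadObservation:
    """One included read's evidence at one site.

    ``base`` is the called base at the site, or a DEL/REFSKIP marker when a
    deletion or reference skip spans it; for non-SNV candidates it is the
    matched allele (or ``OTHER``).  ``query_pos`` is the 0-based offset of
    the site within the read's query sequence (None when no base is called).
    ``nm`` is the NM-tag edit distance, None when the tag is absent, and
    ``base_quality`` is None for reads without quality strings.
    """

    base: str
    base_quality: int | None
    mapping_quality: int
    is_reverse: bool
    query_pos: int | None
    read_length: int
    has_softclip: bool
    nm: int | None
    properly_paired: bool
    near_indel: bool


@dataclass
class SampleSiteMetrics:
    depth: int
    ref_count: int
    alt_count: int
    other_count: int
    vaf: float | None
    median_bq_alt: float | None
    median_bq_ref: float | None
    median_mq_alt: float | None
    median_mq_all: float | None
    alt_fwd: int
    alt_rev: int
    ref_fwd: int
    ref_rev: int
    median_dist_readend_alt: float | None
    mad_pos_alt: float | None
    softclip_frac_alt: float | None
    mean_excess_nm_alt: float | None
    mq0_frac: float | None
    near_indel_frac: float | None
    improper_pair_frac_alt: float | None

    def to_row(self, prefix: str) -> dict[str, object]:
        return {f"{prefix}_{m}": getattr(self, m) for m in SAMPLE_METRIC_NAMES}


@dataclass
class PairedSiteMetrics:
    site: CandidateVariant
    tumor: SampleSiteMetrics
    normal: SampleSiteMetrics

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "contig": self.site.contig,
            "pos": self.site.pos,
            "ref": self.site.ref,
            "alt": self.site.alt,
        }
        row.update(self.tumor.to_row("tumor"))
        row.update(self.normal.to_row("normal"))
        return row


# ---------------------------------------------------------------------------
# Pileup traversal
# ---------------------------------------------------------------------------


def _locate_in_read(read: pysam.AlignedSegment, rpos0: int) -> tuple[int | None, str | None]:
    """Find the query offset of reference position ``rpos0`` within a read.

    Returns (query_pos, state) where state is 'M' for an aligned base,
    DEL/REFSKIP markers for spanning D/N ops, or (None, None) when the read
    does not cover the position.
    """
    qpos = 0
    rpos = read.reference_start
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X consume both query and reference
            if rpos <= rpos0 < rpos + length:
                return qpos + (rpos0 - rpos), "M"
            qpos += length
            rpos += length
        elif op == 1:  # I consumes query only
            qpos += length
        elif op == 2:  # D consumes reference only
            if rpos <= rpos0 < rpos + length:
                return None, DEL_MARKER
            rpos += length
        elif op == 3:  # N consumes reference only
            if rpos <= rpos0 < rpos + length:
                return None, REFSKIP_MARKER
            rpos += length
        elif op == 4:  # S consumes query only
            qpos += length
        # H (5) and P (6) consume neither
    return None, None


def _near_indel(read: pysam.AlignedSegment, rpos0: int, window: int = NEAR_INDEL_WINDOW) -> bool:
    """True when the alignment has an I/D op within ±window ref bp of rpos0."""
    rpos = read.reference_start
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8):
            rpos += length
        elif op == 1:
            # insertion sits between rpos-1 and rpos
            if rpos - 1 - window <= rpos0 <= rpos + window:
                return True
        elif op == 2:
            if rpos - window <= rpos0 <= rpos + length - 1 + window:
                return True
            rpos += length
        elif op == 3:
            rpos += length
    return False


def _classify_non_snv(read: pysam.AlignedSegment, qpos: int, site: CandidateVariant) -> str:
    """Exact-allele classification at POS for MNV/indel candidates."""
    seq = read.query_sequence or ""
    lr, la = len(site.ref), len(site.alt)
    if lr == la:  # MNV: compare same-length query substring
        sub = seq[qpos : qpos + la].upper()
        if sub == site.alt:
            return site.alt
        if sub == site.ref:
            return site.ref
        return "OTHER"
    # simple indel in VCF convention: shared anchor base at POS
    indel_op = None
    rpos = read.reference_start
    q = 0
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8):
            rpos += length
            q += length
        elif op == 1:
            if rpos == site.pos:  # insertion immediately after POS (0-based pos+1)
                indel_op = ("I", length, seq[q : q + length].upper())
            q += length
        elif op == 2:
            if rpos == site.pos:
                indel_op = ("D", length, "")
            rpos += length
        elif op == 3:
            rpos += length
        elif op == 4:
            q += length
    anchor_ok = qpos < len(seq) and seq[qpos].upper() == site.ref[0]
    if la > lr:  # insertion candidate
        if indel_op and indel_op[0] == "I" and indel_op[2] == site.alt[1:]:
            return site.alt
        return site.ref if (indel_op is None and anchor_ok) else "OTHER"
    # deletion candidate
    if indel_op and indel_op[0] == "D" and indel_op[1] == lr - la:
        return site.alt
    return site.ref if (indel_op is None and anchor_ok) else "OTHER"


def collect_read_observations(
    alignment: pysam.AlignmentFile, site: CandidateVariant
) -> list[ReadObservation]:
    """One observation per included read overlapping the site.

    Excludes unmapped/secondary/supplementary/QC-fail/duplicate reads;
    includes MAPQ-0 reads and improper pairs.  Reads with a deletion or
    reference skip spanning the site yield DEL/REFSKIP-marked observations
    that count toward ``other_count``.
    """
    if site.contig not in alignment.references:
        raise ContigMismatchError(
            f"contig {site.contig!r} absent from {alignment.filename!r}; "
            f"file contigs: {list(alignment.references)[:20]}"
        )
    rpos0 = site.pos - 1
    out: list[ReadObservation] = []
    for read in alignment.fetch(site.contig, rpos0, rpos0 + 1):
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_qcfail
            or read.is_duplicate
        ):
            continue
        qpos, state = _locate_in_read(read, rpos0)
        if state is None:
            continue
        if state == "M":
            seq = read.query_sequence or ""
            if site.is_snv:
                base = seq[qpos].upper() if qpos < len(seq) else "N"
            else:
                base = _classify_non_snv(read, qpos, site)
            quals = read.query_qualities
            bq = int(quals[qpos]) if quals is not None else None
        else:
            base, bq = state, None
        out.append(
            ReadObservation(
                base=base,
                base_quality=bq,
                mapping_quality=read.mapping_quality,
                is_reverse=read.is_reverse,
                query_pos=qpos,
                read_length=read.query_length or read.infer_query_length() or 0,
                has_softclip=any(op == 4 for op, _ in (read.cigartuples or ())),
                nm=int(read.get_tag("NM")) if read.has_tag("NM") else None,
                properly_paired=read.is_proper_pair,
                near_indel=_near_indel(read, rpos0),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def _median(values: Sequence[float]) -> float | None:
    if not values:
        return None
    return float(np.median(np.asarray(values, dtype=float)))


def _mad(values: Sequence[float]) -> float | None:
    # raw median absolute deviation, no consistency scaling
    if not values:
        return None
    arr = np.asarray(values, dtype=float)
    return float(np.median(np.abs(arr - np.median(arr))))


def summarize_site(
    observations: Sequence[ReadObservation], site: CandidateVariant
) -> SampleSiteMetrics:
    """Reduce one sample's observations at one site to the metric panel.

    Allele classing: base == ALT → alt, base == REF → ref, anything else
    (other bases, N, DEL/REFSKIP markers) → other.  Every alt-conditioned
    statistic is None exactly when there are no alt reads; VAF is None at
    zero depth.  Non-SNV candidates get counts and VAF only, with all
    read-geometry statistics None.
    """
    depth = len(observations)
    alt_obs = [o for o in observations if o.base == site.alt]
    ref_obs = [o for o in observations if o.base == site.ref]
    alt_n, ref_n = len(alt_obs), len(ref_obs)
    other_n = depth - alt_n - ref_n

    vaf = (alt_n / depth) if depth > 0 else None

    if not site.is_snv:
        return SampleSiteMetrics(
            depth=depth,
            ref_count=ref_n,
            alt_count=alt_n,
            other_count=other_n,
            vaf=vaf,
            median_bq_alt=None,
            median_bq_ref=None,
            median_mq_alt=None,
            median_mq_all=None,
            alt_fwd=sum(1 for o in alt_obs if not o.is_reverse),
            alt_rev=sum(1 for o in alt_obs if o.is_reverse),
            ref_fwd=sum(1 for o in ref_obs if not o.is_reverse),
            ref_rev=sum(1 for o in ref_obs if o.is_reverse),
            median_dist_readend_alt=None,
            mad_pos_alt=None,
            softclip_frac_alt=None,
            mean_excess_nm_alt=None,
            mq0_frac=None,
            near_indel_frac=None,
            improper_pair_frac_alt=None,
        )

    alt_bqs = [o.base_quality for o in alt_obs if o.base_quality is not None]
    ref_bqs = [o.base_quality for o in ref_obs if o.base_quality is not None]
    alt_positions = [o.query_pos for o in alt_obs if o.query_pos is not None]
    alt_dists = [
        min(o.query_pos, o.read_length - 1 - o.query_pos)
        for o in alt_obs
        if o.query_pos is not None
    ]
    alt_nms = [max(o.nm - 1, 0) for o in alt_obs if o.nm is not None]

    return SampleSiteMetrics(
        depth=depth,
        ref_count=ref_n,
        alt_count=alt_n,
        other_count=other_n,
        vaf=vaf,
        median_bq_alt=_median(alt_bqs),
        median_bq_ref=_median(ref_bqs),
        median_mq_alt=_median([o.mapping_quality for o in alt_obs]),
        median_mq_all=_median([o.mapping_quality for o in observations]),
        alt_fwd=sum(1 for o in alt_obs if not o.is_reverse),
        alt_rev=sum(1 for o in alt_obs if o.is_reverse),
        ref_fwd=sum(1 for o in ref_obs if not o.is_reverse),
        ref_rev=sum(1 for o in ref_obs if o.is_reverse),
        median_dist_readend_alt=_median(alt_dists),
        mad_pos_alt=_mad(alt_positions),
        softclip_frac_alt=(
            sum(1 for o in alt_obs if o.has_softclip) / alt_n if alt_n else None
        ),
        mean_excess_nm_alt=(sum(alt_nms) / len(alt_nms)) if alt_nms else None,
        mq0_frac=(
            sum(1 for o in observations if o.mapping_quality == 0) / depth
            if depth
            else None
        ),
        near_indel_frac=(
            sum(1 for o in observations if o.near_indel) / depth if depth else None
        ),
        improper_pair_frac_alt=(
            sum(1 for o in alt_obs if not o.properly_paired) / alt_n if alt_n else None
        ),
    )


def compute_pair_metrics(
    tumor: pysam.AlignmentFile, normal: pysam.AlignmentFile, site: CandidateVariant
) -> PairedSiteMetrics:
    """Metric panel for one site across the matched tumor/normal pair."""
    for aln, label in ((tumor, "tumor"), (normal, "normal")):
        if site.contig not in aln.references:
            raise ContigMismatchError(
                f"contig {site.contig!r} absent from {label} BAM "
                f"{aln.filename!r}; tumor contigs: {list(tumor.references)[:20]}, "
                f"normal contigs: {list(normal.references)[:20]}"
            )
    t = summarize_site(collect_read_observations(tumor, site), site)
    n = summarize_site(collect_read_observations(normal, site), site)
    return PairedSiteMetrics(site=site, tumor=t, normal=n)


# ---------------------------------------------------------------------------
# Chunked, cached, parallel metrics stage
# ---------------------------------------------------------------------------


def _compute_chunk(
    tumor_path: str, normal_path: str, chunk: list[CandidateVariant]
) -> pd.DataFrame:
    rows = []
    with pysam.AlignmentFile(tumor_path) as tumor, pysam.AlignmentFile(normal_path) as normal:
        for site in chunk:
            rows.append(compute_pair_metrics(tumor, normal, site).to_row())
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _fingerprint(n_records: int, chunk_size: int) -> dict:
    return {
        "vcf_record_count": n_records,
        "tool_version": __version__,
        "chunk_size": chunk_size,
        "columns": TABLE_COLUMNS,
    }


def run_metrics_stage(
    vcf_path: str | Path,
    tumor_bam: str | Path,
    normal_bam: str | Path,
    cache_dir: str | Path,
    jobs: int = 1,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> MetricsTable:
    """Compute (or reload) the metric panel for every candidate in the VCF.

    Candidates are processed in chunks; each completed chunk is persisted to
    ``cache_dir`` as gzipped TSV before the next begins, so an interrupted
    run resumes where it stopped.  Chunks whose persisted file exists under a
    matching input fingerprint (VCF record count + tool version + chunk size)
    are loaded, never recomputed; a fingerprint mismatch invalidates the
    whole cache with a logged warning.  Row order matches the VCF and the
    output is identical for any ``jobs`` value.
    """
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    candidates = read_candidate_variants(vcf_path)
    n_records = max(c.record_index for c in candidates) + 1

    fp = _fingerprint(n_records, chunk_size)
    fp_path = cache_dir / "fingerprint.json"
    if fp_path.exists():
        try:
            existing = json.loads(fp_path.read_text())
        except ValueError:
            existing = None
        if existing != fp:
            logger.warning(
                "metrics cache %s is stale (fingerprint mismatch); "
                "recomputing all chunks",
                cache_dir,
            )
            for old in cache_dir.glob("metrics.*.tsv.gz"):
                old.unlink()
    fp_path.write_text(json.dumps(fp, indent=1))

    chunks = [candidates[i : i + chunk_size] for i in range(0, len(candidates), chunk_size)]
    chunk_paths = [cache_dir / f"metrics.{i:05d}.tsv.gz" for i in range(len(chunks))]
    missing = [i for i, p in enumerate(chunk_paths) if not p.exists()]

    if missing:
        results = Parallel(n_jobs=jobs)(
            delayed(_compute_chunk)(str(tumor_bam), str(normal_bam), chunks[i])
            for i in missing
        )
        for i, df in zip(missing, results):
            write_table_gz(df, chunk_paths[i])
    reused = len(chunks) - len(missing)
    logger.info(
        "metrics stage: %d chunk(s) computed, %d reused from cache %s",
        len(missing),
        reused,
        cache_dir,
    )

    frames = []
    for path in chunk_paths:
        df = read_table_gz(path)
        if list(df.columns) != TABLE_COLUMNS:
            raise StaleMetricsError(
                f"stale metrics chunk {path}: header does not match tool version"
            )
        frames.append(df)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TABLE_COLUMNS)
    return MetricsTable(df=table, chunks_computed=len(missing), chunks_reused=reused)
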