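"""Seeded, download-free tumor/normal fixtures for every stage of the tool.

Generates a random reference contig, paired tumor/normal BAMs with planted
candidate sites, the matching candidate VCF, a truth TSV of the genuinely
somatic sites, and a JSON manifest.  Besides clean somatic variants, one
artifact class is planted per filter in the catalogue — low VAF, germline
leakage into the normal, low base/mapping quality, strand bias, read-end
and fixed-position support, soft-clip load, noisy (high-NM) reads, MQ0
pileups, indel-adjacent pileups and improper pairing — each violating its
targeted metric threshold by a deliberate margin.

Reads are ungapped 100-bp single-segment alignments with hand-built CIGARs
(soft-clips/indels only where a class requires them); mate flags are
synthesized without emitting real mates.  All randomness flows from one
seed through a named generator per locus, so fixtures are reproducible
independent of generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .io_formats import CandidateVariant

CONTIG = "synth1"
READ_LEN = 100
DEPTH = 80
BASES = "ACGT"

# artifact class -> the default-preset filter it is built to trip
EXPECTED_FILTER = {
    "low_vaf": "min_vaf_tumor",
    "germline_leak": "max_vaf_normal",
    "low_bq": "min_median_bq_alt_tumor",
    "low_mq": "min_median_mq_alt_tumor",
    "strand_artifact": "strand_minor_frac_alt_tumor",
    "readend_artifact": "min_median_dist_readend_alt_tumor",
    "fixed_pos_artifact": "min_mad_pos_alt_tumor",
    "softclip_artifact": "max_softclip_frac_alt_tumor",
    "noisy_read_artifact": "max_excess_nm_alt_tumor",
    "mq0_artifact": "max_mq0_frac_tumor",
    "near_indel_artifact": "max_near_indel_frac_tumor",
    "improper_pair_artifact": "max_improper_pair_frac_alt_tumor",
}
ARTIFACT_CLASSES = list(EXPECTED_FILTER)
ALL_CLASSES = ["true_somatic", *ARTIFACT_CLASSES]

SCENARIOS = ("artifact_suite", "vaf_sweep", "clean")


@dataclass(frozen=True)
class PlantedSite:
    site: CandidateVariant
    klass: str
    params: dict
    expected_failing_filter: str | None

    def __post_init__(self) -> None:
        if (self.expected_failing_filter is None) != (self.klass == "true_somatic"):
            raise ValueError(
                "expected_failing_filter must be None exactly for true_somatic sites"
            )


@dataclass
class FixtureManifest:
    seed: int
    scenario: str
    reference_length: int
    files: dict[str, str]
    sites: list[PlantedSite] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "scenario": self.scenario,
            "reference_length": self.reference_length,
            "files": self.files,
            "sites": [
                {
                    "contig": s.site.contig,
                    "pos": s.site.pos,
                    "ref": s.site.ref,
                    "alt": s.site.alt,
                    "klass": s.klass,
                    "params": s.params,
                    "expected_failing_filter": s.expected_failing_filter,
                }
                for s in self.sites
            ],
        }
        return json.dumps(payload, indent=1)

    def true_sites(self) -> list[PlantedSite]:
        return [s for s in self.sites if s.klass == "true_somatic"]

    def artifact_sites(self) -> list[PlantedSite]:
        return [s for s in self.sites if s.klass != "true_somatic"]


def make_reference(length: int, seed: int, path: str | Path | None = None) -> tuple[str, Path | None]:
    """Deterministic uniform-random A/C/G/T contig, optionally written as
    faidx-indexed FASTA with one contig named ``synth1``."""
    if length < 1000:
        raise ValueError(f"reference length must be >= 1000, got {length}")
    rng = np.random.default_rng([int(seed) % (2**31), 7])
    seq = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
    out = None
    if path is not None:
        out = Path(path)
        with open(out, "w", encoding="utf-8") as fh:
            fh.write(f">{CONTIG}\n")
            for i in range(0, length, 60):
                fh.write(seq[i : i + 60] + "\n")
        pysam.faidx(str(out))
    return seq, out


def _alignment_header(reference_length: int) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": CONTIG, "LN": int(reference_length)}],
        }
    )


def _make_read(
    header: pysam.AlignmentHeader,
    name: str,
    start0: int,
    seq: str,
    bq: int,
    mq: int,
    reverse: bool,
    proper: bool,
    cigartuples: list[tuple[int, int]],
    nm: int,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array(chr(bq + 33) * len(seq))
    a.reference_id = 0
    a.reference_start = start0
    a.mapping_quality = mq
    a.cigartuples = cigartuples
    flag = 1 | 64  # paired, first in pair
    if proper:
        flag |= 2
    if reverse:
        flag |= 16
    a.flag = flag
    a.next_reference_id = 0
    a.next_reference_start = start0
    a.template_length = 0
    a.set_tag("NM", int(nm))
    return a


def plant_site(
    refseq: str,
    pos0: int,
    alt_base: str,
    klass: str,
    seed_key: Sequence[int],
    depth: int = DEPTH,
    vaf: float = 0.4,
    read_len: int = READ_LEN,
    name_prefix: str = "locus",
    header: pysam.AlignmentHeader | None = None,
) -> tuple[list[pysam.AlignedSegment], list[pysam.AlignedSegment], dict]:
    """Reads for the tumor and normal samples at one planted locus.

    ``pos0`` is the 0-based site position on ``refseq``.  Returns
    (tumor_reads, normal_reads, params); ``params`` records the realized
    generator parameters (alt counts per sample, target VAF, depth).
    """
    if klass not in ALL_CLASSES:
        raise ValueError(f"unknown planted-site class {klass!r}; valid: {ALL_CLASSES}")
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf={vaf} outside [0, 1]")
    if depth < 1:
        raise ValueError(f"depth={depth} must be >= 1")
    if not read_len <= pos0 <= len(refseq) - read_len - 2:
        raise ValueError(f"pos0={pos0} leaves no room for {read_len}-bp reads")
    if refseq[pos0] == alt_base:
        raise ValueError(f"alt_base={alt_base} equals the reference base at pos0")
    if header is None:
        header = _alignment_header(len(refseq))
    rng = np.random.default_rng(list(seed_key))

    if klass == "true_somatic":
        tumor_alt = int(rng.binomial(depth, vaf))
        normal_alt = 0
    elif klass == "low_vaf":
        tumor_alt, normal_alt = 3, 0  # VAF 3/80 < 0.05 but alt count passes
    elif klass == "germline_leak":
        tumor_alt, normal_alt = int(round(0.4 * depth)), int(round(0.5 * depth))
    else:
        tumor_alt, normal_alt = int(round(0.4 * depth)), 0

    n_mq0 = int(round(0.3 * depth))  # mq0_artifact: 30% of reads > 10% threshold

    def build(sample: str, alt_count: int) -> list[pysam.AlignedSegment]:
        is_tumor = sample == "tumor"
        reads = []
        for i in range(depth):
            is_alt = i < alt_count
            reverse = i % 2 == 1
            bqv = int(np.clip(round(rng.normal(35.0, 3.0)), 2, 41))
            mq = 60
            proper = True
            nm = 1 if is_alt else 0
            softclip = False
            insertion = False
            # clean geometry: alt support kept >=10 bp from read ends so that
            # small supporting-read counts cannot trip the read-end filter by
            # sampling noise; reference reads span the whole read
            if is_alt:
                q = int(rng.integers(10, read_len - 10))
            else:
                q = int(rng.integers(0, read_len))

            if is_tumor:
                if klass == "low_bq" and is_alt:
                    bqv = 15
                elif klass == "low_mq" and is_alt:
                    mq = 20
                elif klass == "strand_artifact" and is_alt:
                    reverse = False
                elif klass == "readend_artifact" and is_alt:
                    edge = int(rng.integers(0, 6))
                    q = edge if rng.integers(0, 2) == 0 else read_len - 1 - edge
                elif klass == "fixed_pos_artifact" and is_alt:
                    q = 45
                elif klass == "softclip_artifact" and is_alt:
                    softclip = True
                elif klass == "noisy_read_artifact" and is_alt:
                    nm = 6
                elif klass == "mq0_artifact" and not is_alt and i < alt_count + n_mq0:
                    mq = 0
                elif klass == "near_indel_artifact" and i % 2 == 0:
                    insertion = True
                    nm += 1
                elif klass == "improper_pair_artifact" and is_alt:
                    proper = False

            name = f"{name_prefix}_{sample}_{i:03d}"
            if softclip:
                # 10 soft-clipped query bases then 90 aligned
                qoff = int(rng.integers(10, 80))
                start = pos0 - qoff
                junk = "".join(BASES[j] for j in rng.integers(0, 4, size=10))
                body = list(refseq[start : start + read_len - 10])
                body[qoff] = alt_base
                seq = junk + "".join(body)
                cig = [(4, 10), (0, read_len - 10)]
            elif insertion:
                q = min(q, read_len - 6)
                start = pos0 - q
                k = q + 4  # 1-bp insertion planted 3 bp downstream of the site
                body = list(refseq[start : start + read_len - 1])
                if is_alt:
                    body[q] = alt_base
                seq = "".join(body[:k]) + "A" + "".join(body[k:])
                cig = [(0, k), (1, 1), (0, read_len - k - 1)]
            else:
                start = pos0 - q
                body = list(refseq[start : start + read_len])
                if is_alt:
                    body[q] = alt_base
                seq = "".join(body)
                cig = [(0, read_len)]
            reads.append(
                _make_read(header, name, start, seq, bqv, mq, reverse, proper, cig, nm)
            )
        return reads

    tumor_reads = build("tumor", tumor_alt)
    normal_reads = build("normal", normal_alt)
    params = {
        "depth": depth,
        "target_vaf": vaf,
        "tumor_alt_count": tumor_alt,
        "normal_alt_count": normal_alt,
    }
    return tumor_reads, normal_reads, params


def write_bam(
    reads: Sequence[pysam.AlignedSegment],
    path: str | Path,
    reference_length: int,
) -> Path:
    """Write reads as a coordinate-sorted, indexed BAM."""
    path = Path(path)
    header = _alignment_header(reference_length)
    ordered = sorted(reads, key=lambda r: (r.reference_start, r.query_name))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for read in ordered:
            bam.write(read)
    pysam.index(str(path))
    return path


def _site_plan(scenario: str) -> list[tuple[str, float]]:
    """(class, target VAF) per locus, in emission (= coordinate) order."""
    if scenario == "clean":
        return [("true_somatic", v) for v in [0.4] * 6 + [0.2] * 6]
    if scenario == "artifact_suite":
        plan = [("true_somatic", v) for v in [0.4] * 8 + [0.2] * 6 + [0.1] * 6]
        for klass in ARTIFACT_CLASSES:
            plan += [(klass, 0.4)] * 3
        return plan
    if scenario == "vaf_sweep":
        return [
            ("true_somatic", v)
            for v in (0.02, 0.05, 0.10, 0.20, 0.40)
            for _ in range(12)
        ]
    raise ValueError(f"unknown scenario {scenario!r}; valid: {SCENARIOS}")


def generate_pair(
    scenario: str,
    seed: int,
    out_dir: str | Path,
    depth: int = DEPTH,
    read_len: int = READ_LEN,
) -> FixtureManifest:
    """Emit a full fixture: reference FASTA, sorted+indexed tumor/normal
    BAMs, candidate VCF covering every planted site, truth TSV of the true
    somatic sites, and a JSON manifest.  Fully deterministic per seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plan = _site_plan(scenario)
    length = 1000 + 300 * len(plan)
    seed = int(seed) % (2**31)
    refseq, ref_path = make_reference(length, seed, out_dir / "ref.fa")
    header = _alignment_header(length)

    tumor_reads: list[pysam.AlignedSegment] = []
    normal_reads: list[pysam.AlignedSegment] = []
    sites: list[PlantedSite] = []
    for idx, (klass, vaf) in enumerate(plan):
        pos0 = 500 + 300 * idx
        rng = np.random.default_rng([seed, 1000 + idx])
        ref_base = refseq[pos0]
        alt_base = rng.choice([b for b in BASES if b != ref_base])
        t_reads, n_reads, params = plant_site(
            refseq,
            pos0,
            alt_base,
            klass,
            seed_key=[seed, 2000 + idx],
            depth=depth,
            vaf=vaf,
            read_len=read_len,
            name_prefix=f"{klass}_{idx:03d}",
            header=header,
        )
        tumor_reads += t_reads
        normal_reads += n_reads
        sites.append(
            PlantedSite(
                site=CandidateVariant(CONTIG, pos0 + 1, ref_base, str(alt_base)),
                klass=klass,
                params=params,
                expected_failing_filter=EXPECTED_FILTER.get(klass),
            )
        )

    tumor_path = write_bam(tumor_reads, out_dir / "tumor.bam", length)
    normal_path = write_bam(normal_reads, out_dir / "normal.bam", length)

    vcf_path = out_dir / "candidates.vcf"
    vcf_header = pysam.VariantHeader()
    vcf_header.add_line(f"##contig=<ID={CONTIG},length={length}>")
    vcf_header.add_line("##source=somafilt-fixtures")
    with pysam.VariantFile(str(vcf_path), "w", header=vcf_header) as vout:
        for planted in sites:
            rec = vout.new_record(
                contig=CONTIG,
                start=planted.site.pos - 1,
                alleles=(planted.site.ref, planted.site.alt),
            )
            vout.write(rec)

    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w", encoding="utf-8") as fh:
        for planted in sites:
            if planted.klass == "true_somatic":
                s = planted.site
                fh.write(f"{s.contig}\t{s.pos}\t{s.ref}\t{s.alt}\n")

    manifest = FixtureManifest(
        seed=seed,
        scenario=scenario,
        reference_length=length,
        files={
            "reference": str(ref_path),
            "tumor_bam": str(tumor_path),
            "normal_bam": str(normal_path),
            "candidates_vcf": str(vcf_path),
            "truth_tsv": str(truth_path),
        },
        sites=sites,
    )
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
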