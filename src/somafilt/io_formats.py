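"""Readers and writers for every external file the tool touches.

Candidate and truth VCFs, the filtered output VCF, two-column tab-delimited
filter configurations, and the gzipped per-variant metrics tables used for
caching all pass through this module.  Coordinates are 1-based inclusive in
the public data model (the VCF convention); conversion to 0-based half-open
happens only at the alignment-access boundary inside :mod:`somafilt.metrics`.
"""

from __future__ import annotations

import gzip
import io
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from . import __version__

logger = logging.getLogger("somafilt")

NA = "NA"
_ALLELE_CHARS = frozenset("ACGTN")


class VcfParseError(ValueError):
    """Raised when a candidate or truth VCF cannot be interpreted."""


class ConfigError(ValueError):
    """Raised for malformed or invalid filter configuration files."""


class StaleMetricsError(ValueError):
    """Raised when a cached metrics table does not match the current tool."""


@dataclass(frozen=True)
class CandidateVariant:
    """One variant site to adjudicate.

    ``pos`` is the 1-based reference position.  ``record_index`` is the
    0-based index of the source VCF record the candidate came from (several
    candidates share an index when the record was multi-allelic), and
    ``id_line`` keeps an opaque copy of the original record text.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    record_index: int = 0
    id_line: str = field(default="", compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VcfParseError(f"position must be >= 1, got {self.pos}")
        for label, allele in (("REF", self.ref), ("ALT", self.alt)):
            if not allele or not set(allele.upper()) <= _ALLELE_CHARS:
                raise VcfParseError(
                    f"{label} allele {allele!r} at {self.contig}:{self.pos} is not "
                    "a non-empty string over A/C/G/T/N"
                )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def _record_is_pass(rec: "pysam.VariantRecord") -> bool:
    names = list(rec.filter.keys())
    return not names or names == ["PASS"] or names == ["."]


def read_candidate_variants(vcf_path: str | Path, pass_only: bool = False) -> list[CandidateVariant]:
    """Read a VCF into an ordered list of candidates, one per ALT allele.

    Multi-allelic records are split into one candidate per alternate allele,
    preserving record order.  Only CHROM/POS/REF/ALT are interpreted; every
    other column is treated as opaque, so records from any caller load.
    """
    path = str(vcf_path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    out: list[CandidateVariant] = []
    n_records = 0
    try:
        for idx, rec in enumerate(vf):
            n_records += 1
            if pass_only and not _record_is_pass(rec):
                continue
            for alt in rec.alts or ():
                out.append(
                    CandidateVariant(
                        contig=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=alt.upper(),
                        record_index=idx,
                        id_line=str(rec).rstrip("\n"),
                    )
                )
    except (OSError, ValueError) as exc:
        raise VcfParseError(
            f"cannot parse VCF {path} near record {n_records + 1}: {exc}"
        ) from exc
    finally:
        vf.close()
    if n_records == 0:
        raise VcfParseError(f"empty VCF: {path} contains no variant records")
    return out


# ---------------------------------------------------------------------------
# Filter configurations
# ---------------------------------------------------------------------------


@dataclass
class FilterConfig:
    """An ordered list of (filter name, threshold) pairs to apply.

    Equality compares the entries only, not the preset label, so a preset
    saved to disk and re-loaded compares equal to the in-code preset.
    """

    entries: list[tuple[str, float]]
    preset_label: str = "user"

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigError(f"duplicate filter name(s) in config: {sorted(dupes)}")
        from .filters import CATALOGUE  # deferred: filters imports this module

        unknown = [n for n in names if n not in CATALOGUE]
        if unknown:
            raise ConfigError(
                f"unknown filter name(s) {unknown}; valid names are: "
                f"{sorted(CATALOGUE)}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FilterConfig):
            return NotImplemented
        return self.entries == other.entries

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def threshold(self, name: str) -> float:
        for n, t in self.entries:
            if n == name:
                return t
        raise KeyError(name)


def load_filter_config(path: str | Path) -> FilterConfig:
    """Load a two-column tab-delimited filter configuration.

    Lines starting with ``#`` are comments.  Unknown filter names and
    non-numeric thresholds are fatal; an empty config loads with a prominent
    warning that every variant will pass unfiltered.
    """
    entries: list[tuple[str, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ConfigError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            name, value = parts[0].strip(), parts[1].strip()
            try:
                threshold = float(value)
            except ValueError as exc:
                raise ConfigError(
                    f"{path}:{lineno}: non-numeric threshold {value!r} for {name!r}"
                ) from exc
            entries.append((name, threshold))
    if not entries:
        logger.warning(
            "filter config %s is EMPTY: no filters will be applied and every "
            "variant will pass unfiltered",
            path,
        )
    return FilterConfig(entries=entries, preset_label="user")


def save_filter_config(config: FilterConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# somafilt filter configuration (name<TAB>threshold)\n")
        for name, threshold in config.entries:
            fh.write(f"{name}\t{threshold:g}\n")
    return path


def default_preset() -> FilterConfig:
    """The built-in default filter set (documented in docs/methods.md)."""
    from .filters import DEFAULT_THRESHOLDS

    return FilterConfig(entries=list(DEFAULT_THRESHOLDS.items()), preset_label="default")


def icgc_preset() -> FilterConfig:
    """The ICGC-recommendation filter set, invoked by the ``--icgc`` flag."""
    from .filters import ICGC_THRESHOLDS

    return FilterConfig(entries=list(ICGC_THRESHOLDS.items()), preset_label="icgc")


def preset_path(label: str) -> Path:
    """Filesystem path of a shipped preset file (``default`` or ``icgc``)."""
    fname = {"default": "default_filters.tsv", "icgc": "icgc_filters.tsv"}[label]
    return Path(str(resources.files("somafilt").joinpath("data", fname)))


# ---------------------------------------------------------------------------
# Filtered VCF emission
# ---------------------------------------------------------------------------


def write_filtered_vcf(
    vcf_path: str | Path,
    candidates: Sequence[CandidateVariant],
    verdicts: Sequence,
    config: FilterConfig,
    out_path: str | Path,
    pass_only: bool = False,
) -> Path:
    """Re-emit the input VCF with per-record FILTER verdicts.

    One ``##FILTER`` header line is added per applied filter (threshold
    included in the description) plus provenance lines recording the tool
    version and preset label.  The FILTER column reads ``PASS`` when every
    filter passed, otherwise the semicolon-joined failed filter names.
    Multi-allelic records take the verdict of their first ALT; per-ALT
    verdicts live in the per-variant results file.  With ``pass_only`` set,
    failing records are dropped instead of annotated.
    """
    from .filters import CATALOGUE, FilterVerdict  # deferred

    if len(verdicts) != len(candidates):
        raise ValueError(
            f"internal consistency error: {len(candidates)} candidates but "
            f"{len(verdicts)} verdicts"
        )
    first_verdict: dict[int, FilterVerdict] = {}
    for cand, verdict in zip(candidates, verdicts):
        first_verdict.setdefault(cand.record_index, verdict)

    vin = pysam.VariantFile(str(vcf_path))
    header = vin.header.copy()
    for name, threshold in config.entries:
        if name not in header.filters:
            desc = CATALOGUE[name].description
            header.filters.add(name, None, None, f"{desc} [threshold={threshold:g}]")
    header.add_line(f"##somafilt_version={__version__}")
    header.add_line(f"##somafilt_preset={config.preset_label}")
    for name, threshold in config.entries:
        header.add_line(f"##somafilt_threshold={name}={threshold:g}")

    out_path = Path(out_path)
    vout = pysam.VariantFile(str(out_path), "w", header=header)
    try:
        for idx, rec in enumerate(vin):
            if not (rec.alts or ()):
                continue
            if idx not in first_verdict:
                raise ValueError(
                    f"internal consistency error: no verdict for VCF record {idx} "
                    f"at {rec.chrom}:{rec.pos}"
                )
            verdict = first_verdict[idx]
            failed = verdict.failed_filters
            rec.translate(header)
            rec.filter.clear()
            if failed:
                if pass_only:
                    continue
                for name in failed:
                    rec.filter.add(name)
            else:
                rec.filter.add("PASS")
            vout.write(rec)
    finally:
        vout.close()
        vin.close()
    return out_path


# ---------------------------------------------------------------------------
# Metrics tables (gzipped TSV cache format)
# ---------------------------------------------------------------------------

KEY_COLUMNS = ["contig", "pos", "ref", "alt"]


@dataclass
class MetricsTable:
    """Per-variant metric panel, one row per candidate in VCF order.

    ``chunks_computed``/``chunks_reused`` report cache behaviour of the run
    that produced the table (both zero for tables built directly).
    """

    df: pd.DataFrame
    chunks_computed: int = 0
    chunks_reused: int = 0

    def __len__(self) -> int:
        return len(self.df)

    def rows(self) -> Iterable[Mapping[str, object]]:
        return self.df.to_dict("records")


def expected_table_columns() -> list[str]:
    from .metrics import TABLE_COLUMNS  # deferred

    return list(TABLE_COLUMNS)


def write_table_gz(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a DataFrame as deterministic gzipped TSV (mtime pinned to 0)."""
    path = Path(path)
    with open(path, "wb") as raw:
        with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as gz:
            with io.TextIOWrapper(gz, encoding="utf-8", newline="") as text:
                df.to_csv(text, sep="\t", index=False, na_rep=NA, float_format="%.6g")
    return path


def read_table_gz(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        compression="gzip",
        na_values=[NA],
        keep_default_na=False,
        dtype={"contig": str, "ref": str, "alt": str},
    )
    return df


def write_metrics_table(table: MetricsTable, path: str | Path) -> Path:
    expected = expected_table_columns()
    if list(table.df.columns) != expected:
        raise StaleMetricsError(
            "metrics table columns do not match the current tool version; "
            "recompute the metrics stage"
        )
    return write_table_gz(table.df, path)


def read_metrics_table(path: str | Path) -> MetricsTable:
    df = read_table_gz(path)
    expected = expected_table_columns()
    if list(df.columns) != expected:
        raise StaleMetricsError(
            f"stale metrics table {path}: header does not match tool version "
            f"{__version__}; delete the cache and recompute"
        )
    return MetricsTable(df=df)
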