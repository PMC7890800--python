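from collections import OrderedDict

import pytest

from somafilt.filters import apply_filters
from somafilt.fixtures import generate_pair
from somafilt.io_formats import default_preset
from somafilt.metrics import TABLE_COLUMNS, run_metrics_stage

ARTIFACT_SEED = 11
SWEEP_SEED = 23
CLEAN_SEED = 5


@pytest.fixture(scope="session")
def artifact_suite(tmp_path_factory):
    out = tmp_path_factory.mktemp("artifact_suite")
    return generate_pair("artifact_suite", ARTIFACT_SEED, out)


@pytest.fixture(scope="session")
def suite_table(artifact_suite, tmp_path_factory):
    cache = tmp_path_factory.mktemp("suite_cache")
    return run_metrics_stage(
        artifact_suite.files["candidates_vcf"],
        artifact_suite.files["tumor_bam"],
        artifact_suite.files["normal_bam"],
        cache_dir=cache,
        jobs=1,
        chunk_size=20,
    )


@pytest.fixture(scope="session")
def suite_verdicts(suite_table):
    return apply_filters(default_preset(), suite_table)


@pytest.fixture(scope="session")
def vaf_sweep(tmp_path_factory):
    out = tmp_path_factory.mktemp("vaf_sweep")
    return generate_pair("vaf_sweep", SWEEP_SEED, out)


@pytest.fixture(scope="session")
def sweep_table(vaf_sweep, tmp_path_factory):
    cache = tmp_path_factory.mktemp("sweep_cache")
    return run_metrics_stage(
        vaf_sweep.files["candidates_vcf"],
        vaf_sweep.files["tumor_bam"],
        vaf_sweep.files["normal_bam"],
        cache_dir=cache,
        jobs=1,
        chunk_size=10,
    )


@pytest.fixture(scope="session")
def clean_fixture(tmp_path_factory):
    out = tmp_path_factory.mktemp("clean_fixture")
    return generate_pair("clean", CLEAN_SEED, out)


def clean_row(**overrides):
    """A metrics-table row that passes every default filter; override fields
    to construct targeted failures in tests."""
    row = dict.fromkeys(TABLE_COLUMNS)
    row.update(
        contig="synth1", pos=501, ref="A", alt="T",
        tumor_depth=80, tumor_ref_count=48, tumor_alt_count=32, tumor_other_count=0,
        tumor_vaf=0.4, tumor_median_bq_alt=35.0, tumor_median_bq_ref=35.0,
        tumor_median_mq_alt=60.0, tumor_median_mq_all=60.0,
        tumor_alt_fwd=16, tumor_alt_rev=16, tumor_ref_fwd=24, tumor_ref_rev=24,
        tumor_median_dist_readend_alt=30.0, tumor_mad_pos_alt=20.0,
        tumor_softclip_frac_alt=0.0, tumor_mean_excess_nm_alt=0.0,
        tumor_mq0_frac=0.0, tumor_near_indel_frac=0.0,
        tumor_improper_pair_frac_alt=0.0,
        normal_depth=80, normal_ref_count=80, normal_alt_count=0,
        normal_other_count=0, normal_vaf=0.0,
        normal_median_bq_ref=35.0, normal_median_mq_all=60.0,
        normal_alt_fwd=0, normal_alt_rev=0, normal_ref_fwd=40, normal_ref_rev=40,
        normal_mq0_frac=0.0, normal_near_indel_frac=0.0,
    )
    row.update(overrides)
    return row


def hand_vcf(path, records):
    """Write a minimal candidate VCF from (contig, pos, ref, alt_field) rows."""
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=1000000>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for contig, pos, ref, alt in records:
        lines.append(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.")
    path.write_text("\n".join(lines) + "\n")
    return path
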