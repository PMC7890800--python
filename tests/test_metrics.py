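import numpy as np
import pandas as pd
import pysam
import pytest

from oracle import brute_summary, random_pileup
from somafilt.fixtures import make_reference, plant_site, write_bam, _alignment_header, _make_read
from somafilt.io_formats import CandidateVariant
from somafilt.metrics import (
    SAMPLE_METRIC_NAMES,
    ContigMismatchError,
    ReadObservation,
    collect_read_observations,
    compute_pair_metrics,
    run_metrics_stage,
    summarize_site,
)

SITE = CandidateVariant("synth1", 1001, "A", "T")


def _refseq():
    seq, _ = make_reference(3000, seed=3)
    # force the site's reference base so hand-built reads agree with SITE
    return seq[:1000] + "A" + seq[1001:]


def _plain_read(header, refseq, name, start0, flag_extra=0, **kw):
    seq = refseq[start0 : start0 + 100]
    read = _make_read(header, name, start0, seq, bq=35, mq=60, reverse=False,
                      proper=True, cigartuples=[(0, 100)], nm=0, **kw)
    read.flag |= flag_extra
    return read


class TestCollectObservations:
    def test_flagged_reads_are_excluded(self, tmp_path):
        refseq = _refseq()
        header = _alignment_header(len(refseq))
        reads = [_plain_read(header, refseq, f"r{i}", 960) for i in range(10)]
        reads[0].flag |= 0x400  # duplicate
        reads[1].flag |= 0x400  # duplicate
        reads[2].flag |= 0x100  # secondary
        bam = write_bam(reads, tmp_path / "t.bam", len(refseq))
        with pysam.AlignmentFile(str(bam)) as aln:
            obs = collect_read_observations(aln, SITE)
        assert len(obs) == 7

    def test_deletion_spanning_site_counts_as_other(self, tmp_path):
        refseq = _refseq()
        header = _alignment_header(len(refseq))
        # 40M5D55M starting so the deletion spans the site
        start = 1000 - 42
        seq = refseq[start : start + 40] + refseq[start + 45 : start + 100]
        read = _make_read(header, "del_read", start, seq, bq=35, mq=60, reverse=False,
                          proper=True, cigartuples=[(0, 40), (2, 5), (0, 55)], nm=5)
        bam = write_bam([read], tmp_path / "t.bam", len(refseq))
        with pysam.AlignmentFile(str(bam)) as aln:
            (ob,) = collect_read_observations(aln, SITE)
        assert ob.base == "DEL" and ob.near_indel
        m = summarize_site([ob], SITE)
        assert (m.depth, m.other_count, m.ref_count, m.alt_count) == (1, 1, 0, 0)

    def test_deletion_two_bp_downstream_sets_near_indel(self, tmp_path):
        refseq = _refseq()
        header = _alignment_header(len(refseq))
        # site at ref 1000; 3-bp deletion covering ref 1002..1004
        start = 1000 - 40
        seq = refseq[start : start + 42] + refseq[start + 45 : start + 103]
        read = _make_read(header, "near", start, seq, bq=35, mq=60, reverse=False,
                          proper=True, cigartuples=[(0, 42), (2, 3), (0, 58)], nm=3)
        bam = write_bam([read], tmp_path / "t.bam", len(refseq))
        with pysam.AlignmentFile(str(bam)) as aln:
            (ob,) = collect_read_observations(aln, SITE)
        assert ob.base == "A" and ob.near_indel

    def test_empty_region_and_missing_contig(self, tmp_path):
        refseq = _refseq()
        header = _alignment_header(len(refseq))
        bam = write_bam([_plain_read(header, refseq, "r0", 100)], tmp_path / "t.bam", len(refseq))
        with pysam.AlignmentFile(str(bam)) as aln:
            assert collect_read_observations(aln, SITE) == []
            with pytest.raises(ContigMismatchError, match="chr9"):
                collect_read_observations(aln, CandidateVariant("chr9", 1001, "A", "T"))


def _obs(base="T", bq=30, mq=60, rev=False, qpos=50, rlen=100, clip=False,
         nm=1, proper=True, near=False):
    return ReadObservation(base=base, base_quality=bq, mapping_quality=mq,
                           is_reverse=rev, query_pos=qpos, read_length=rlen,
                           has_softclip=clip, nm=nm, properly_paired=proper,
                           near_indel=near)


class TestSummarize:
    def test_no_alt_reads_yields_zero_vaf_and_na_medians(self):
        obs = [_obs(base="A") for _ in range(10)]
        m = summarize_site(obs, SITE)
        assert m.vaf == 0.0 and m.alt_count == 0
        assert m.median_bq_alt is None and m.mad_pos_alt is None
        assert m.depth == m.ref_count + m.alt_count + m.other_count == 10

    def test_midpoint_median_of_even_count(self):
        obs = [_obs(bq=q) for q in (30, 31, 32, 33, 34, 35)]
        assert summarize_site(obs, SITE).median_bq_alt == 32.5

    def test_mad_and_distance_to_read_end(self):
        obs = [_obs(qpos=q, rlen=100) for q in (40, 41, 42, 43)]
        m = summarize_site(obs, SITE)
        assert m.mad_pos_alt == 1.0
        assert m.median_dist_readend_alt == 41.5

    def test_empty_input_gives_depth_zero_all_na(self):
        m = summarize_site([], SITE)
        assert m.depth == 0 and m.vaf is None and m.mq0_frac is None

    def test_excess_nm_floored_at_zero(self):
        obs = [_obs(nm=0), _obs(nm=3)]
        assert summarize_site(obs, SITE).mean_excess_nm_alt == 1.0

    def test_matches_bruteforce_oracle_on_random_pileups(self):
        rng = np.random.default_rng(404)
        for _ in range(40):
            obs = random_pileup(rng)
            m = summarize_site(obs, SITE)
            expected = brute_summary(obs, SITE)
            for name in SAMPLE_METRIC_NAMES:
                assert getattr(m, name) == expected[name], name


class TestPairAndStage:
    def test_identical_bam_as_both_samples_is_symmetric(self, tmp_path):
        refseq, _ = make_reference(3000, seed=9)
        pos0 = 1500
        alt = "A" if refseq[pos0] != "A" else "C"
        t_reads, _, _ = plant_site(refseq, pos0, alt, "true_somatic", [9, 1], vaf=0.3)
        bam = write_bam(t_reads, tmp_path / "same.bam", len(refseq))
        site = CandidateVariant("synth1", pos0 + 1, refseq[pos0], alt)
        with pysam.AlignmentFile(str(bam)) as a, pysam.AlignmentFile(str(bam)) as b:
            pm = compute_pair_metrics(a, b, site)
        assert pm.tumor == pm.normal

    def test_planted_vaf_recovered_within_binomial_error(self, tmp_path):
        # 50 seeded loci at VAF 0.40, depth 80: mean |VAF - 0.4| < 0.06
        n = 50
        refseq, _ = make_reference(1000 + 300 * n + 1000, seed=77)
        reads, sites = [], []
        for i in range(n):
            pos0 = 500 + 300 * i
            alt = "A" if refseq[pos0] != "A" else "C"
            t, _, _ = plant_site(refseq, pos0, alt, "true_somatic", [77, i],
                                 vaf=0.4, name_prefix=f"l{i}")
            reads += t
            sites.append(CandidateVariant("synth1", pos0 + 1, refseq[pos0], alt))
        bam = write_bam(reads, tmp_path / "t.bam", len(refseq))
        devs = []
        with pysam.AlignmentFile(str(bam)) as aln:
            for site in sites:
                m = summarize_site(collect_read_observations(aln, site), site)
                assert m.depth >= 70
                devs.append(abs(m.vaf - 0.4))
        assert float(np.mean(devs)) < 0.06

    def test_cache_resume_and_chunk_recompute(self, clean_fixture, tmp_path):
        args = (
            clean_fixture.files["candidates_vcf"],
            clean_fixture.files["tumor_bam"],
            clean_fixture.files["normal_bam"],
        )
        cache = tmp_path / "cache"
        first = run_metrics_stage(*args, cache_dir=cache, jobs=1, chunk_size=5)
        assert first.chunks_computed == 3 and first.chunks_reused == 0
        second = run_metrics_stage(*args, cache_dir=cache, jobs=1, chunk_size=5)
        assert second.chunks_computed == 0 and second.chunks_reused == 3
        pd.testing.assert_frame_equal(first.df, second.df)
        # deleting one chunk recomputes exactly that chunk
        (cache / "metrics.00001.tsv.gz").unlink()
        third = run_metrics_stage(*args, cache_dir=cache, jobs=1, chunk_size=5)
        assert third.chunks_computed == 1 and third.chunks_reused == 2
        pd.testing.assert_frame_equal(first.df, third.df)

    def test_stale_fingerprint_invalidates_cache(self, clean_fixture, tmp_path, caplog):
        args = (
            clean_fixture.files["candidates_vcf"],
            clean_fixture.files["tumor_bam"],
            clean_fixture.files["normal_bam"],
        )
        cache = tmp_path / "cache"
        run_metrics_stage(*args, cache_dir=cache, jobs=1, chunk_size=5)
        with caplog.at_level("WARNING", logger="somafilt"):
            redone = run_metrics_stage(*args, cache_dir=cache, jobs=1, chunk_size=6)
        assert "stale" in caplog.text
        assert redone.chunks_reused == 0
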