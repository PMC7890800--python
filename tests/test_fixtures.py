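import json

import numpy as np
import pysam
import pytest

from somafilt.evaluation import load_truth, match_truth, score
from somafilt.fixtures import (
    ARTIFACT_CLASSES,
    EXPECTED_FILTER,
    generate_pair,
    make_reference,
    plant_site,
)
from somafilt.io_formats import read_candidate_variants


def _bam_records(path):
    with pysam.AlignmentFile(str(path)) as bam:
        return [
            (r.query_name, r.flag, r.reference_start, r.cigarstring, r.query_sequence)
            for r in bam.fetch()
        ]


class TestReference:
    def test_seeded_determinism_and_length(self):
        a, _ = make_reference(10_000, seed=4)
        b, _ = make_reference(10_000, seed=4)
        assert a == b and len(a) == 10_000
        c, _ = make_reference(10_000, seed=5)
        assert c != a

    def test_base_composition_near_uniform(self):
        seq, _ = make_reference(100_000, seed=4)
        sigma = (100_000 * 0.25 * 0.75) ** 0.5
        for base in "ACGT":
            assert abs(seq.count(base) - 25_000) < 3 * sigma

    def test_fasta_emission_is_indexed(self, tmp_path):
        seq, path = make_reference(2000, seed=4, path=tmp_path / "ref.fa")
        fasta = pysam.FastaFile(str(path))
        assert fasta.fetch("synth1") == seq

    def test_too_short_is_fatal(self):
        with pytest.raises(ValueError, match="1000"):
            make_reference(500, seed=1)


class TestPlantSite:
    def test_unknown_class_is_fatal(self):
        seq, _ = make_reference(2000, seed=1)
        with pytest.raises(ValueError, match="unknown planted-site class"):
            plant_site(seq, 1000, "T" if seq[1000] != "T" else "A", "bogus", [1, 1])

    def test_seeded_alt_count_reproducible(self):
        seq, _ = make_reference(2000, seed=1)
        alt = "T" if seq[1000] != "T" else "A"
        _, _, p1 = plant_site(seq, 1000, alt, "true_somatic", [1, 2], vaf=0.4)
        _, _, p2 = plant_site(seq, 1000, alt, "true_somatic", [1, 2], vaf=0.4)
        assert p1 == p2 and p1["tumor_alt_count"] > 0


class TestGeneratePair:
    def test_manifest_and_bams_deterministic(self, tmp_path):
        m1 = generate_pair("clean", 7, tmp_path / "a")
        m2 = generate_pair("clean", 7, tmp_path / "b")
        d1, d2 = json.loads(m1.to_json()), json.loads(m2.to_json())
        d1.pop("files"), d2.pop("files")  # paths differ by out_dir
        assert d1 == d2
        assert _bam_records(m1.files["tumor_bam"]) == _bam_records(m2.files["tumor_bam"])
        assert _bam_records(m1.files["normal_bam"]) == _bam_records(m2.files["normal_bam"])

    def test_candidate_vcf_covers_every_planted_site(self, artifact_suite):
        cands = read_candidate_variants(artifact_suite.files["candidates_vcf"])
        assert [c.key for c in cands] == [s.site.key for s in artifact_suite.sites]
        assert len(artifact_suite.artifact_sites()) == 3 * len(ARTIFACT_CLASSES)
        assert len(artifact_suite.true_sites()) >= 20

    def test_clean_scenario_unfiltered_precision_is_one(self, clean_fixture):
        cands = read_candidate_variants(clean_fixture.files["candidates_vcf"])
        truth = load_truth(clean_fixture.files["truth_tsv"])
        summary = score(match_truth(cands, truth))
        assert summary.precision == 1.0 and summary.recall == 1.0

    def test_expected_filter_map_is_total(self):
        assert set(EXPECTED_FILTER) == set(ARTIFACT_CLASSES)


class TestArtifactConstruction:
    """Planted artifact classes violate their targeted metric, verified
    through the metrics engine rather than by construction alone."""

    def _rows(self, suite_table, artifact_suite, klass):
        keys = {s.site.key for s in artifact_suite.sites if s.klass == klass}
        return [
            r for r in suite_table.rows()
            if (r["contig"], r["pos"], r["ref"], r["alt"]) in keys
        ]

    def test_strand_artifact_is_single_stranded(self, suite_table, artifact_suite):
        for row in self._rows(suite_table, artifact_suite, "strand_artifact"):
            assert min(row["tumor_alt_fwd"], row["tumor_alt_rev"]) == 0
            assert row["tumor_alt_count"] >= 10

    def test_germline_leak_exceeds_normal_evidence_bounds(self, suite_table, artifact_suite):
        for row in self._rows(suite_table, artifact_suite, "germline_leak"):
            assert row["normal_alt_count"] > 1
            assert row["normal_vaf"] > 0.03

    def test_fixed_pos_artifact_has_zero_mad(self, suite_table, artifact_suite):
        for row in self._rows(suite_table, artifact_suite, "fixed_pos_artifact"):
            assert row["tumor_mad_pos_alt"] == 0.0

    def test_true_sites_recover_target_vaf(self, suite_table, artifact_suite):
        devs = []
        for planted in artifact_suite.true_sites():
            row = next(
                r for r in suite_table.rows()
                if (r["contig"], r["pos"]) == (planted.site.contig, planted.site.pos)
            )
            assert row["normal_alt_count"] == 0
            devs.append(abs(row["tumor_vaf"] - planted.params["target_vaf"]))
        assert float(np.mean(devs)) < 0.06

    def test_vaf_sweep_pass_rate_monotone_in_planted_vaf(self, vaf_sweep, sweep_table):
        from somafilt.filters import apply_filters
        from somafilt.io_formats import default_preset

        verdicts = {v.key: v for v in apply_filters(default_preset(), sweep_table)}
        rates = []
        for vaf in (0.02, 0.05, 0.10, 0.20, 0.40):
            sites = [s for s in vaf_sweep.sites if s.params["target_vaf"] == vaf]
            rates.append(
                sum(verdicts[s.site.key].overall for s in sites) / len(sites)
            )
        assert rates == sorted(rates)
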