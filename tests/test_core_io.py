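"""Format I/O: BED panels, VCF indel extraction, feature tables, model JSON."""

import json

import numpy as np
import pytest

from msikit import (
    IndelCall,
    MsiLocus,
    ParseError,
    ValidationError,
    VcfFilters,
    read_feature_table,
    read_indel_vcf,
    read_locus_bed,
    read_manifest,
    read_model,
    write_feature_table,
    write_locus_bed,
    write_manifest,
    write_model,
    SampleManifestEntry,
)
from msikit.classifier import CentroidModel, decision_statistic

from conftest import write_vcf_text


class TestLocusBed:
    def test_panel_round_trip_assigns_feature_index_by_file_order(self, tmp_path, panel):
        path = tmp_path / "panel.bed"
        write_locus_bed(panel, path)
        loci = read_locus_bed(path)
        assert len(loci) == 29
        assert [l.feature_index for l in loci] == list(range(29))
        assert [l.name for l in loci] == [l.name for l in panel]

    def test_empty_file_gives_empty_panel(self, tmp_path):
        path = tmp_path / "empty.bed"
        path.write_text("")
        assert read_locus_bed(path) == []

    def test_duplicate_locus_name_rejected(self, tmp_path):
        line = "chr2\t47641559\t47641586\tBAT-26\n"
        path = tmp_path / "dup.bed"
        path.write_text(line + line)
        with pytest.raises(ValidationError, match="BAT-26"):
            read_locus_bed(path)

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\t200\tok\nchr1\tnotanint\t300\tbad\n")
        with pytest.raises(ParseError, match=":2"):
            read_locus_bed(path)

    def test_too_few_columns_rejected(self, tmp_path):
        path = tmp_path / "short.bed"
        path.write_text("chr1 100 200\n")  # spaces, not tabs
        with pytest.raises(ParseError):
            read_locus_bed(path)

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValidationError):
            MsiLocus("chr1", 200, 100, "X", 0)


class TestIndelCall:
    def test_length_delta_must_match_alleles(self):
        with pytest.raises(ValidationError):
            IndelCall("chr1", 5, "ATT", "AT", -2)

    def test_zero_delta_rejected(self):
        with pytest.raises(ValidationError):
            IndelCall("chr1", 5, "AT", "GC", 0)


@pytest.fixture
def single_locus():
    return [MsiLocus("chr1", 99, 121, "HP-1", 0)]


class TestReadIndelVcf:
    def test_deletion_yields_negative_delta(self, tmp_path, single_locus):
        vcf = write_vcf_text(tmp_path / "a.vcf", ["chr1\t100\t.\tATTTTT\tATTT\t.\tPASS\tDP=500"])
        calls = read_indel_vcf(vcf, single_locus)
        (call,) = calls["HP-1"]
        assert call.length_delta == -2
        assert call.depth == 500

    def test_snv_only_vcf_gives_empty_lists_for_every_locus(self, tmp_path, panel):
        vcf = write_vcf_text(tmp_path / "snv.vcf", ["chr1\t100\t.\tA\tG\t.\tPASS\t."])
        calls = read_indel_vcf(vcf, panel)
        assert set(calls) == {l.name for l in panel}
        assert all(v == [] for v in calls.values())

    def test_multiallelic_record_splits_per_alt(self, tmp_path, single_locus):
        # oracle: manual split of REF=ATTTTT against ALTs ATTT, ATT
        vcf = write_vcf_text(tmp_path / "ma.vcf", ["chr1\t100\t.\tATTTTT\tATTT,ATT\t.\tPASS\t."])
        calls = read_indel_vcf(vcf, single_locus)
        assert sorted(c.length_delta for c in calls["HP-1"]) == [-3, -2]

    def test_symbolic_and_spanning_alts_skipped(self, tmp_path, single_locus):
        vcf = write_vcf_text(
            tmp_path / "sym.vcf",
            ["chr1\t100\t.\tATT\t<DEL>\t.\tPASS\t.",
             "chr1\t101\t.\tAT\t*\t.\tPASS\t."],
        )
        calls = read_indel_vcf(vcf, single_locus)
        assert calls["HP-1"] == []

    def test_filter_and_depth_exclusions(self, tmp_path, single_locus):
        vcf = write_vcf_text(
            tmp_path / "filt.vcf",
            ["chr1\t100\t.\tATT\tA\t.\tLowQual\tDP=500",
             "chr1\t102\t.\tATT\tA\t.\tPASS\tDP=5"],
        )
        default = read_indel_vcf(vcf, single_locus)
        assert len(default["HP-1"]) == 1  # LowQual dropped, shallow kept
        strict = read_indel_vcf(vcf, single_locus, VcfFilters(min_depth=50))
        assert strict["HP-1"] == []
        lax = read_indel_vcf(vcf, single_locus, VcfFilters(pass_only=False))
        assert len(lax["HP-1"]) == 2

    def test_calls_outside_all_loci_dropped_and_tallied(self, tmp_path, single_locus):
        vcf = write_vcf_text(
            tmp_path / "out.vcf",
            ["chr1\t500\t.\tATT\tA\t.\tPASS\t.",     # far from locus
             "chr1\t100\t.\tATT\tA\t.\tPASS\t."],
        )
        calls = read_indel_vcf(vcf, single_locus)
        assert len(calls["HP-1"]) == 1
        assert calls.n_dropped_outside == 1

    @pytest.mark.parametrize("padding", [0, 2, 5])
    def test_locus_assignment_matches_brute_force_interval_check(
        self, tmp_path, padding
    ):
        """BED (0-based half-open) + VCF (1-based) conversion agrees with a
        direct interval check for positions straddling locus edges."""
        locus = MsiLocus("chr1", 100, 110, "L", 0)
        positions = list(range(92, 120))
        lines = [f"chr1\t{p}\t.\tAT\tA\t.\tPASS\t." for p in positions]
        vcf = write_vcf_text(tmp_path / f"pad{padding}.vcf", lines)
        calls = read_indel_vcf(vcf, [locus], VcfFilters(locus_padding=padding))
        got = sorted(c.pos for c in calls["L"])
        expected = [
            p for p in positions
            if locus.start + 1 - padding <= p <= locus.end + padding
        ]
        assert got == expected

    def test_empty_panel_rejected(self, tmp_path):
        vcf = write_vcf_text(tmp_path / "x.vcf", [])
        with pytest.raises(ValidationError):
            read_indel_vcf(vcf, [])

    def test_unreadable_vcf_raises_parse_error(self, tmp_path, single_locus):
        bad = tmp_path / "bad.vcf"
        bad.write_text("this is not a vcf\n")
        with pytest.raises(ParseError):
            read_indel_vcf(bad, single_locus)


class TestFeatureTable:
    def test_round_trip_is_bit_identical(self, tmp_path, panel):
        rng = np.random.default_rng(0)
        matrix = rng.normal(size=(2, 58))
        path = tmp_path / "features.tsv"
        write_feature_table(["s1", "s2"], panel, matrix, path)
        header = path.read_text().splitlines()[0]
        assert len(header.split("\t")) == 59  # sample_id + 2 x 29
        sample_ids, back, locus_names = read_feature_table(path, panel)
        assert sample_ids == ["s1", "s2"]
        assert locus_names == [l.name for l in panel]
        assert np.array_equal(back, matrix)

    def test_missing_column_named_in_error(self, tmp_path, panel):
        path = tmp_path / "features.tsv"
        write_feature_table(["s1"], panel, np.zeros((1, 58)), path)
        lines = path.read_text().splitlines()
        cols = lines[0].split("\t")
        drop = cols.index("BAT-26_meanlen")
        new = "\n".join(
            "\t".join(v for i, v in enumerate(line.split("\t")) if i != drop)
            for line in lines
        )
        path.write_text(new + "\n")
        with pytest.raises(ValidationError, match="BAT-26_meanlen"):
            read_feature_table(path, panel)

    def test_shape_mismatch_rejected(self, tmp_path, panel):
        with pytest.raises(ValidationError):
            write_feature_table(["s1"], panel, np.zeros((1, 10)), tmp_path / "x.tsv")


class TestModelJson:
    @pytest.fixture
    def model(self, panel):
        rng = np.random.default_rng(1)
        return CentroidModel(
            k=3,
            centroids=rng.normal(size=(3, 58)),
            cluster_labels=["MSI-H", "MSI-H", "MSS"],
            loci=[l.name for l in panel],
            tau=3.0,
            seed=42,
        )

    def test_round_trip_preserves_decision_statistic(self, tmp_path, model):
        path = tmp_path / "model.json"
        write_model(model, path)
        back = read_model(path)
        probe = np.linspace(-1, 1, 58)
        assert decision_statistic(probe, back) == decision_statistic(probe, model)
        assert back.cluster_labels == model.cluster_labels
        payload = json.loads(path.read_text())
        assert np.asarray(payload["centroids"]).shape == (3, 58)

    def test_unknown_version_refused(self, tmp_path, model):
        path = tmp_path / "model.json"
        write_model(model, path)
        payload = json.loads(path.read_text())
        payload["version"] = "99"
        path.write_text(json.dumps(payload))
        with pytest.raises(ValidationError, match="version"):
            read_model(path)

    def test_truncated_json_refused(self, tmp_path, model):
        path = tmp_path / "model.json"
        write_model(model, path)
        path.write_text(path.read_text()[:-40])
        with pytest.raises(ParseError):
            read_model(path)


class TestManifest:
    def test_round_trip_and_relative_path_resolution(self, tmp_path):
        entries = [
            SampleManifestEntry("s1", "s1.vcf", truth_label="MSI-H", role="train"),
            SampleManifestEntry("s2", "s2.vcf", truth_label="MSS", role="test"),
        ]
        path = tmp_path / "manifest.tsv"
        write_manifest(entries, path)
        back = read_manifest(path)
        assert [e.sample_id for e in back] == ["s1", "s2"]
        assert back[0].vcf_path == str(tmp_path / "s1.vcf")
        assert back[0].truth_label == "MSI-H"

    def test_duplicate_sample_rejected(self, tmp_path):
        path = tmp_path / "manifest.tsv"
        path.write_text("sample_id\tvcf_path\ns1\ta.vcf\ns1\tb.vcf\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_manifest(path)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            SampleManifestEntry("s1", "x.vcf", truth_label="weird")
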