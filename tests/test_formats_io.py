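"""Domain types, descriptor arithmetic, panel I/O and QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hornmap import (
    MISSING,
    GenomicInterval,
    HaplotypePanel,
    MarkerMap,
    ParseError,
    PedigreeRecord,
    PhasingError,
    QCConfig,
    VariantKind,
    parse_descriptor,
    qc_filter,
    read_haplotype_panel,
    write_haplotype_panel,
)
from hornmap.errors import DegenerateInputError
from hornmap.formats_io import check_pedigree

from conftest import make_map, make_panel


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------


class TestGenomicInterval:
    def test_one_based_conversion_round_trip(self):
        iv = GenomicInterval.from_1based("1", 1_693_164, 2_018_403)
        assert (iv.start, iv.end) == (1_693_163, 2_018_403)
        assert (iv.start_1based, iv.end_1based) == (1_693_164, 2_018_403)
        assert iv.length == 2_018_403 - 1_693_164 + 1

    @given(start=st.integers(1, 10**8), length=st.integers(1, 10**6))
    @settings(max_examples=50, deadline=None)
    def test_inclusive_length_equals_half_open_length(self, start, length):
        iv = GenomicInterval.from_1based("1", start, start + length - 1)
        assert iv.length == length
        assert iv.end_1based - iv.start_1based + 1 == iv.end - iv.start

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("1", 10, 10)

    def test_bed_export_is_half_open(self):
        iv = GenomicInterval.from_1based("1", 101, 200)
        assert iv.to_bed_line("x") == "1\t100\t200\tx"


class TestMarkerMap:
    def test_rejects_unsorted_positions(self):
        with pytest.raises(ValueError):
            MarkerMap("1", (("a", 100), ("b", 100)))

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError):
            MarkerMap("1", (("a", 100), ("a", 200)))


def test_pedigree_cycle_detected():
    with pytest.raises(ValueError, match="cycle"):
        check_pedigree(
            [
                PedigreeRecord("a", "b", None, "X"),
                PedigreeRecord("b", "a", None, "X"),
            ]
        )


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------


class TestDescriptors:
    def test_celtic_delins_dup_arithmetic(self):
        """The 212-bp duplicated segment replacing a 10-bp segment."""
        v = parse_descriptor("g.1706051_1706060 delins 1705834_1706045 dup")
        assert v.kind == VariantKind.DELINS_DUP
        assert v.inserted_length == 212
        assert v.replaced_length == 10
        assert v.position_bp == 1706051

    @pytest.mark.parametrize(
        "descriptor, kind, position",
        [
            ("g.1855898G>A", VariantKind.SNV, 1855898),
            ("g.1764239T>C", VariantKind.SNV, 1764239),
            ("g.1909352_1989480dup", VariantKind.DUPLICATION, 1909352),
            ("g.1909390_1909391del", VariantKind.DELETION, 1909390),
            ("g.100_100dup", VariantKind.DUPLICATION, 100),
        ],
    )
    def test_supported_forms(self, descriptor, kind, position):
        v = parse_descriptor(descriptor)
        assert v.kind == kind
        assert v.position_bp == position

    def test_single_base_duplication_length(self):
        assert parse_descriptor("g.100_100dup").inserted_length == 1

    def test_inclusive_duplication_length(self):
        assert parse_descriptor("g.1909352_1989480dup").inserted_length == 80_129

    def test_round_trip_through_parser(self):
        for d in ["g.1855898G>A", "g.1706051_1706060delins1705834_1706045dup", "g.5_9del"]:
            v = parse_descriptor(d)
            assert parse_descriptor(v.descriptor) == v

    @pytest.mark.parametrize(
        "bad", ["g.100A>", "g.ins100", "g.100_90dup", "c.100A>G", "g.100_200invdup"]
    )
    def test_unsupported_grammar_raises(self, bad):
        with pytest.raises(ParseError):
            parse_descriptor(bad)


# ---------------------------------------------------------------------------
# panel I/O
# ---------------------------------------------------------------------------


@pytest.fixture
def small_panel():
    return make_panel(
        [[0, 1, 1], [1, 0, MISSING], [0, 0, 1], [1, 1, 0]], breed="CHA"
    )


class TestPanelIO:
    @pytest.mark.parametrize("dialect", ["phased-vcf", "hapmatrix-tsv"])
    def test_write_read_round_trip(self, small_panel, dialect, tmp_path):
        path = tmp_path / "panel.txt"
        write_haplotype_panel(small_panel, path, dialect)
        back = read_haplotype_panel(path, dialect)
        assert back.breed == small_panel.breed
        assert back.individual_ids == small_panel.individual_ids
        assert back.marker_map == small_panel.marker_map
        np.testing.assert_array_equal(back.haplotypes, small_panel.haplotypes)

    def test_dialect_equivalence(self, small_panel, tmp_path):
        write_haplotype_panel(small_panel, tmp_path / "a.vcf", "phased-vcf")
        write_haplotype_panel(small_panel, tmp_path / "b.tsv", "hapmatrix-tsv")
        v = read_haplotype_panel(tmp_path / "a.vcf", "phased-vcf")
        t = read_haplotype_panel(tmp_path / "b.tsv", "hapmatrix-tsv")
        np.testing.assert_array_equal(v.haplotypes, t.haplotypes)
        assert v.marker_map == t.marker_map

    def test_two_sample_three_marker_vcf_shape(self, small_panel, tmp_path):
        path = tmp_path / "p.vcf"
        write_haplotype_panel(small_panel, path, "phased-vcf")
        panel = read_haplotype_panel(path, "phased-vcf")
        assert panel.haplotypes.shape == (4, 3)

    def test_unphased_genotype_raises(self, tmp_path):
        path = tmp_path / "unphased.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t100\tM1\tA\tC\t.\t.\t.\tGT\t0/1\n"
        )
        with pytest.raises(PhasingError, match="unphased"):
            read_haplotype_panel(path, "phased-vcf")

    def test_malformed_hapmatrix_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("individual_id\tphase\tM1\ns1\tA\t0\ns1\tB\t2\n")
        with pytest.raises(ParseError, match="bad.tsv:3"):
            read_haplotype_panel(path, "hapmatrix-tsv")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


class TestQCFilter:
    def test_marker_below_call_rate_removed(self):
        # 10 individuals x 20 markers, all heterozygous; marker 0 has an 80%
        # genotype call rate (below 0.90) while every sample stays above 0.95
        H = np.tile(np.array([[0], [1]], dtype=np.uint8), (10, 20))
        H[0, 0] = MISSING
        H[2, 0] = MISSING
        panel = make_panel(H, breed="QC")
        filtered, report = qc_filter(panel, (), QCConfig(hwe_alpha=1e-12))
        assert "M0000" not in filtered.marker_map.marker_ids
        assert filtered.n_individuals == 10
        assert any(
            e["reason"] == "marker_call_rate" and e["target"] == "M0000"
            for e in report.entries
        )

    def test_monomorphic_marker_removed(self):
        H = np.array([[0, 0], [0, 1], [0, 0], [0, 1]], dtype=np.uint8)
        filtered, report = qc_filter(make_panel(H), ())
        assert filtered.marker_map.marker_ids == ("M0001",)
        assert report.entries[0]["reason"] == "monomorphic"

    def test_sample_below_call_rate_removed(self):
        H = np.zeros((4, 10), dtype=np.uint8)
        H[1::2, :] = 1  # keep markers polymorphic, all individuals het
        H[0, :3] = MISSING  # sample 0 call rate 0.7
        panel = make_panel(H)
        filtered, report = qc_filter(panel, ())
        assert filtered.individual_ids == [panel.individual_ids[1]]
        assert report.removed_samples() == [panel.individual_ids[0]]

    def test_mendelian_inconsistency_set_missing_and_logged(self):
        # offspring 0/0 with sire 1/1 at marker 0
        H = np.array(
            [
                [1, 0], [1, 1],  # sire: 1/1 at M0
                [0, 0], [0, 1],  # child: 0/0 at M0 -> impossible
                [0, 0], [1, 1],
            ],
            dtype=np.uint8,
        )
        panel = make_panel(H, breed="FAM")
        ped = [PedigreeRecord("FAM_1", "FAM_0", None, "FAM")]
        filtered, report = qc_filter(
            panel, ped, QCConfig(marker_call_rate=0.0, sample_call_rate=0.0)
        )
        edits = report.mendelian_edits()
        assert len(edits) == 1 and edits[0]["target"] == "FAM_1"
        i = filtered.individual_ids.index("FAM_1")
        assert filtered.haplotypes[2 * i, 0] == MISSING
        assert filtered.haplotypes[2 * i + 1, 0] == MISSING

    def test_hwe_violation_removed(self):
        # 40 individuals all heterozygous: strong HWE departure
        H = np.tile(np.array([[0, 0], [1, 1]], dtype=np.uint8), (40, 1))
        H[:, 1] = np.array([0, 1] * 40, dtype=np.uint8)  # control marker, also het
        # marker 0: all het; marker 1: identical -> both all-het; instead make
        # marker 1 HWE-consistent by random genotypes
        rng = np.random.default_rng(0)
        H[:, 1] = rng.integers(0, 2, size=80).astype(np.uint8)
        filtered, report = qc_filter(make_panel(H), (), QCConfig(hwe_alpha=1e-4))
        assert "M0000" not in filtered.marker_map.marker_ids
        assert any(e["reason"] == "hwe" for e in report.entries)

    def test_idempotent(self, rng):
        H = rng.integers(0, 2, size=(60, 40)).astype(np.uint8)
        H[rng.random(H.shape) < 0.02] = MISSING
        panel = make_panel(H)
        once, _ = qc_filter(panel, ())
        twice, rep2 = qc_filter(once, ())
        np.testing.assert_array_equal(once.haplotypes, twice.haplotypes)
        assert once.marker_map == twice.marker_map
        assert once.individual_ids == twice.individual_ids

    def test_everything_filtered_raises(self):
        H = np.zeros((4, 2), dtype=np.uint8)  # all monomorphic
        with pytest.raises(DegenerateInputError):
            qc_filter(make_panel(H), ())
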