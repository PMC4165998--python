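"""Read-pair classification and evidence counting against planted fixtures."""

import numpy as np
import pysam
import pytest

from svaf.evidence import (
    ReadClass,
    classify_read_pair,
    count_evidence,
    filter_bins,
)
from svaf.types import BinCount, GCRateTable, LibraryParams, SVCall

from conftest import make_params

HEADER = pysam.AlignmentHeader.from_dict(
    {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": "chr1", "LN": 1_000_000}, {"SN": "chr2", "LN": 1_000_000}],
    }
)


def make_read(
    pos,
    cigar="100M",
    chrom="chr1",
    reverse=False,
    mate_chrom="chr1",
    mate_pos=None,
    mate_reverse=True,
    tlen=None,
    flags=0,
    mapq=60,
):
    """One synthetic primary alignment with mate fields set."""
    a = pysam.AlignedSegment(HEADER)
    a.query_name = "q"
    a.query_sequence = "A" * 100
    a.reference_id = HEADER.get_tid(chrom)
    a.reference_start = pos
    a.cigarstring = cigar
    a.mapping_quality = mapq
    mate_pos = pos + 400 if mate_pos is None else mate_pos
    a.next_reference_id = HEADER.get_tid(mate_chrom)
    a.next_reference_start = mate_pos
    a.flag = 0x1 | 0x40 | flags | (0x10 if reverse else 0) | (0x20 if mate_reverse else 0)
    if tlen is None and mate_chrom == chrom:
        tlen = mate_pos + 100 - pos
    a.template_length = tlen or 0
    return a


PARAMS = LibraryParams(
    read_length_r=100, insert_median_t=500, insert_spread=50, inserts_per_bp_c=0.15
)
DEL = SVCall("chr1", 100_001, "chr1", 105_001, "DEL")  # 0-based bps 100000/105000


class TestClassify:
    def test_proper_fr_pair_is_normal(self):
        read = make_read(50_000)  # insert 500, FR
        assert classify_read_pair(read, PARAMS, DEL) == ReadClass.NORMAL

    def test_cross_contig_pair_matches_translocation(self):
        tra = SVCall("chr1", 100_001, "chr2", 200_001, "TRA")
        read = make_read(99_900, mate_chrom="chr2", mate_pos=200_100, tlen=0)
        assert classify_read_pair(read, PARAMS, tra) == ReadClass.DISCORDANT
        # same pair is unexplained by a deletion on chr1
        assert classify_read_pair(read, PARAMS, DEL) == ReadClass.EXCLUDED

    def test_clip_at_breakpoint_is_softclip(self):
        read = make_read(100_000 - 80, cigar="80M20S")
        assert classify_read_pair(read, PARAMS, DEL) == ReadClass.SOFTCLIP

    def test_short_or_distant_clip_does_not_count(self):
        tiny = make_read(100_000 - 97, cigar="97M3S")  # below min_clip
        far = make_read(90_000 - 80, cigar="80M20S")  # clip far from breakpoint
        assert classify_read_pair(tiny, PARAMS, DEL) == ReadClass.NORMAL
        assert classify_read_pair(far, PARAMS, DEL) == ReadClass.NORMAL

    def test_enlarged_insert_spanning_deletion_is_discordant(self):
        read = make_read(99_800, mate_pos=105_200, tlen=5500)
        assert classify_read_pair(read, PARAMS, DEL) == ReadClass.DISCORDANT

    def test_enlarged_insert_elsewhere_is_excluded(self):
        read = make_read(50_000, mate_pos=51_500, tlen=1600)
        assert classify_read_pair(read, PARAMS, DEL) == ReadClass.EXCLUDED

    def test_everted_pair_matches_duplication(self):
        dup = SVCall("chr1", 100_001, "chr1", 105_001, "DUP")
        read = make_read(100_200, reverse=True, mate_reverse=False, mate_pos=104_800)
        assert classify_read_pair(read, PARAMS, dup) == ReadClass.DISCORDANT
        assert classify_read_pair(read, PARAMS, DEL) == ReadClass.EXCLUDED

    def test_same_strand_pair_matches_inversion(self):
        inv = SVCall("chr1", 100_001, "chr1", 105_001, "INV")
        read = make_read(99_900, reverse=False, mate_reverse=False, mate_pos=104_700)
        assert classify_read_pair(read, PARAMS, inv) == ReadClass.DISCORDANT

    @pytest.mark.parametrize("flags", [0x400, 0x100, 0x800, 0x200, 0x8])
    def test_flagged_reads_excluded(self, flags):
        read = make_read(50_000, flags=flags)
        assert classify_read_pair(read, PARAMS, DEL) == ReadClass.EXCLUDED


class TestFilterBins:
    def test_threshold_is_inclusive(self):
        bins = [
            BinCount(50, 100, 5, mq0_fraction=0.0),
            BinCount(50, 100, 5, mq0_fraction=0.6),
            BinCount(50, 100, 5, mq0_fraction=0.5),
        ]
        kept = filter_bins(bins, 0.5)
        assert kept == [bins[0], bins[2]]

    def test_identity_and_empty(self):
        bins = [BinCount(50, 100, 2)]
        assert filter_bins(bins, 0.5) == bins
        assert filter_bins([], 0.5) == []


class TestCountEvidence:
    def test_bin_tiling_covers_interval_exactly(self, multi_sv_fixture):
        params = multi_sv_fixture["params"]
        gc = GCRateTable.flat(params.inserts_per_bp_c)
        sv = SVCall("chr1", 40_001, "chr1", 41_051, "DEL")  # inside the het DEL
        oc = count_evidence(multi_sv_fixture["bam"], sv, params, gc, bin_width=100)
        widths = [b.width for b in oc.bins]
        assert widths == [100] * 10 + [50]
        assert sum(widths) == sv.size
        assert len(oc.junctions) == 1

    def test_het_deletion_counts_near_planted_rates(self, multi_sv_fixture):
        params = multi_sv_fixture["params"]
        c = params.inserts_per_bp_c
        gc = GCRateTable.flat(c)
        sv = multi_sv_fixture["svs"][0][0]  # het DEL, p=0.5
        oc = count_evidence(
            multi_sv_fixture["bam"], sv, params, gc, reference=multi_sv_fixture["fasta"]
        )
        exp_n = c * sv.size * 0.5
        assert abs(oc.total_normal - exp_n) <= 3 * np.sqrt(exp_n)
        d, s = oc.junctions[0]
        exp_d = params.offset_vd * c * (500 - 200) * 0.5
        exp_s = params.offset_vs * c * 200 * 0.5
        assert abs(d - exp_d) <= 3 * np.sqrt(exp_d) + 1
        assert abs(s - exp_s) <= 3 * np.sqrt(exp_s) + 1

    def test_homozygous_deletion_empties_depth(self, multi_sv_fixture):
        params = multi_sv_fixture["params"]
        gc = GCRateTable.flat(params.inserts_per_bp_c)
        sv = multi_sv_fixture["svs"][1][0]  # hom DEL
        oc = count_evidence(multi_sv_fixture["bam"], sv, params, gc)
        assert oc.total_normal == 0
        assert oc.junctions[0][0] > 0

    def test_null_locus_has_no_junction_evidence(self, multi_sv_fixture):
        params = multi_sv_fixture["params"]
        gc = GCRateTable.flat(params.inserts_per_bp_c)
        sv = SVCall("chr1", 15_001, "chr1", 20_001, "DEL")  # no SV planted here
        oc = count_evidence(multi_sv_fixture["bam"], sv, params, gc)
        assert oc.junctions == [(0, 0)]
        exp_n = params.inserts_per_bp_c * sv.size
        assert abs(oc.total_normal - exp_n) <= 3 * np.sqrt(exp_n)

    @pytest.mark.parametrize("idx,junctions", [(3, 2), (4, 2)])
    def test_balanced_svs_have_two_junctions_no_bins(
        self, multi_sv_fixture, idx, junctions
    ):
        params = multi_sv_fixture["params"]
        gc = GCRateTable.flat(params.inserts_per_bp_c)
        sv = multi_sv_fixture["svs"][idx][0]
        oc = count_evidence(multi_sv_fixture["bam"], sv, params, gc)
        assert oc.bins == []
        assert len(oc.junctions) == junctions
        assert all(d > 0 for d, _ in oc.junctions)

    def test_out_of_bounds_breakpoint_errors(self, multi_sv_fixture):
        params = multi_sv_fixture["params"]
        gc = GCRateTable.flat(params.inserts_per_bp_c)
        sv = SVCall("chr1", 190_000, "chr1", 400_000, "DEL")
        with pytest.raises(ValueError, match="contig bounds"):
            count_evidence(multi_sv_fixture["bam"], sv, params, gc)

    def test_each_discordant_pair_counted_once(self, multi_sv_fixture):
        """The two mates of a planted discordant pair must not be double
        counted even though both fall inside evidence windows."""
        params = multi_sv_fixture["params"]
        gc = GCRateTable.flat(params.inserts_per_bp_c)
        sv = multi_sv_fixture["svs"][0][0]
        oc = count_evidence(multi_sv_fixture["bam"], sv, params, gc)
        with pysam.AlignmentFile(multi_sv_fixture["bam"]) as aln:
            planted = {
                r.query_name
                for r in aln.fetch(sv.chrom1, sv.pos1 - 700, sv.pos2 + 700)
                if r.query_name.startswith("drp")
            }
        assert oc.junctions[0][0] == len(planted)
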