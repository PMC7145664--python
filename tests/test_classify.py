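"""PAF parsing, best-hit selection, the valid-read rule, tallies, and the
in-line-repeat inference."""

import io

import pytest

from plastidhap.classify import (
    PafRecord,
    RejectionReason,
    TallyTable,
    ValidCall,
    call_read,
    detect_inline_repeats,
    parse_paf,
    read_calls_tsv,
    select_alignment,
    tally,
    write_calls_tsv,
)
from plastidhap.haplotypes import Structure
from plastidhap.references import build_reference


def _paf_line(qname="r1", qlen=5000, qstart=0, qend=5000, strand="+",
              tname="LSC_IR_SSC_IRrc", tlen=24000, tstart=4000, tend=9000,
              nmatch=5000, alnlen=5000, mapq=60, tags=("tp:A:P",)):
    cols = [qname, qlen, qstart, qend, strand, tname, tlen, tstart, tend,
            nmatch, alnlen, mapq, *tags]
    return "\t".join(str(c) for c in cols)


class TestParsePaf:
    def test_empty_input(self):
        records, skipped = parse_paf(io.StringIO(""))
        assert records == [] and skipped == 0

    def test_well_formed_line(self):
        records, skipped = parse_paf(io.StringIO(_paf_line() + "\n"))
        assert skipped == 0
        (rec,) = records
        assert rec.qname == "r1" and rec.tstart == 4000 and rec.tend == 9000
        assert rec.type_tag == "P" and rec.is_primary

    @pytest.mark.parametrize(
        "line",
        [
            _paf_line(qstart=5000, qend=5000),        # qend <= qstart
            _paf_line(tend=30000),                    # tend > tlen
            _paf_line(nmatch=6000),                   # nmatch > alnlen
            _paf_line(strand="*"),
            "r1\t100\t0\t50",                         # too few columns
            _paf_line(qlen="abc"),                    # non-integer field
        ],
    )
    def test_malformed_lines_skipped_with_count(self, line):
        records, skipped = parse_paf(io.StringIO(line + "\n" + _paf_line() + "\n"))
        assert skipped == 1
        assert len(records) == 1

    def test_unknown_target_dropped(self):
        stream = io.StringIO(_paf_line(tname="chr1") + "\n")
        records, skipped = parse_paf(stream, known_targets={"LSC_IR_SSC_IRrc"})
        assert records == [] and skipped == 1


class TestSelectAlignment:
    def _rec(self, **kw):
        (rec,), _ = parse_paf(io.StringIO(_paf_line(**kw) + "\n"))
        return rec

    def test_primary_beats_secondary(self):
        p = self._rec(tags=("tp:A:P",))
        s = self._rec(nmatch=5000, tags=("tp:A:S",))
        assert select_alignment([s, p]) is p

    def test_highest_nmatch_wins(self):
        lo = self._rec(nmatch=880, alnlen=5000)
        hi = self._rec(nmatch=900, alnlen=5000)
        assert select_alignment([lo, hi]) is hi

    def test_tie_broken_by_target_name(self):
        a = self._rec(tname="LSC_IR_SSC_IRrc")
        b = self._rec(tname="LSC_IRrc_SSC_IR")
        assert select_alignment([b, a]).tname == "LSC_IR_SSC_IRrc"

    def test_untagged_records_count_as_primary(self):
        rec = self._rec(tags=())
        assert select_alignment([rec]) is rec

    def test_no_primary_returns_none(self):
        assert select_alignment([self._rec(tags=("tp:A:S",))]) is None


class TestCallRead:
    """Block arithmetic on the toy reference (LSC 5000, IR 2000, SSC 3000):
    doubled blocks are LSC[0,5000) IR[5000,7000) SSC[7000,10000)
    IR[10000,12000) LSC[12000,17000) IR[17000,19000) SSC[19000,22000)
    IR[22000,24000)."""

    @pytest.fixture()
    def ref(self, toy_regions):
        return build_reference(toy_regions, Structure.from_name("LSC_IR_SSC_IRrc"))

    def _rec(self, tstart, tend, tname="LSC_IR_SSC_IRrc"):
        line = _paf_line(qlen=tend - tstart, qend=tend - tstart,
                         tstart=tstart, tend=tend, tname=tname,
                         nmatch=tend - tstart, alnlen=tend - tstart)
        (rec,), _ = parse_paf(io.StringIO(line + "\n"))
        return rec

    def test_valid_call_with_flanks(self, ref):
        call = call_read(self._rec(4000, 9001), ref)
        assert isinstance(call, ValidCall)
        assert call.ir_instance == 1
        assert call.left_flank == 1000 and call.right_flank == 2001

    def test_flank_boundary_is_inclusive(self, ref):
        # IR block [5000,7000): left flank exactly 1000 qualifies ...
        call = call_read(self._rec(4000, 8000), ref)
        assert isinstance(call, ValidCall)
        # ... one bp less does not
        assert call_read(self._rec(4001, 8000), ref) is RejectionReason.FLANK_TOO_SHORT

    def test_alignment_inside_single_copy_region(self, ref):
        assert call_read(self._rec(0, 4500), ref) is RejectionReason.NO_IR_COVERED

    def test_partial_ir_coverage_rejected(self, ref):
        assert call_read(self._rec(4000, 6999), ref) is RejectionReason.NO_IR_COVERED

    def test_edge_ir_cannot_be_called(self, ref):
        # last IR instance [22000,24000) has no high-side neighbour
        assert call_read(self._rec(21000, 24000), ref) is RejectionReason.IR_AT_EDGE

    def test_second_and_third_instances(self, ref):
        assert call_read(self._rec(9000, 13000), ref).ir_instance == 2
        assert call_read(self._rec(16000, 20500), ref).ir_instance == 3

    def test_read_longer_than_monomer_called_once_lowest_instance(self, ref):
        call = call_read(self._rec(4000, 16000), ref)
        assert isinstance(call, ValidCall)
        assert call.ir_instance == 1

    def test_ir_slack_tolerates_ragged_ends(self, ref):
        # 10 bp short of the full-flank span [4000, 8000] at both ends
        rec = self._rec(4010, 7995)
        assert call_read(rec, ref) is RejectionReason.FLANK_TOO_SHORT
        call = call_read(rec, ref, ir_slack=10)
        assert isinstance(call, ValidCall)
        assert call.left_flank == 990 and call.right_flank == 995
        # slack does not excuse a missing IR chunk beyond the tolerance
        assert call_read(self._rec(4000, 6900), ref, ir_slack=10) is RejectionReason.NO_IR_COVERED

    def test_target_mismatch_is_fatal(self, ref):
        with pytest.raises(ValueError, match="does not match"):
            call_read(self._rec(4000, 9001, tname="LSC_IRrc_SSC_IR"), ref)


class TestTally:
    def _calls(self, spec):
        return [
            ValidCall(f"r{i}", name, inst, 1000, 1000)
            for i, (name, inst) in enumerate(spec)
        ]

    def test_counts_by_structure_and_instance(self):
        calls = self._calls(
            [("LSC_IR_SSC_IRrc", 1)] * 31 + [("LSC_IR_SSCrc_IRrc", 2)] * 31
        )
        t = tally(calls)
        assert t.counts == {"LSC_IR_SSC_IRrc": 31, "LSC_IR_SSCrc_IRrc": 31}
        assert t.total_valid == 62
        assert t.instance_counts[("LSC_IR_SSC_IRrc", 1)] == 31

    def test_empty(self):
        t = tally([])
        assert t.counts == {} and t.total_valid == 0

    def test_order_invariance(self):
        calls = self._calls([("LSC_IR_SSC_IRrc", 1), ("LSC_IRrc_SSC_IR", 2)] * 5)
        assert tally(calls).counts == tally(list(reversed(calls))).counts

    def test_duplicate_read_is_fatal(self):
        c = ValidCall("r1", "LSC_IR_SSC_IRrc", 1, 1000, 1000)
        with pytest.raises(ValueError, match="duplicate"):
            tally([c, c])

    def test_calls_tsv_round_trip(self, tmp_path):
        calls = self._calls([("LSC_IR_SSC_IRrc", 1), ("LSC_IRrc_SSC_IR", 2)])
        path = tmp_path / "calls.tsv"
        write_calls_tsv(calls, path)
        assert read_calls_tsv(path) == calls


class TestInlineDetection:
    def _table(self, instance_counts):
        t = TallyTable()
        for (name, inst), n in instance_counts.items():
            t.instance_counts[(name, inst)] = n
            t.counts[name] = t.counts.get(name, 0) + n
            t.total_valid += n
        return t

    def test_diagnostic_pattern_triggers(self):
        t = self._table({
            ("LSC_IR_SSC_IRrc", 1): 10,
            ("LSC_IR_SSC_IRrc", 3): 4,
            ("LSC_IRrc_SSC_IR", 2): 8,
        })
        ev = detect_inline_repeats(t, min_reads=5)
        assert ev.triggered and ev.supporting_reads == 22

    def test_off_pattern_instance_blocks_trigger(self):
        t = self._table({
            ("LSC_IR_SSC_IRrc", 1): 10,
            ("LSC_IR_SSC_IRrc", 2): 1,  # complementary instance must be empty
            ("LSC_IRrc_SSC_IR", 2): 8,
        })
        assert not detect_inline_repeats(t, min_reads=5).triggered

    def test_calls_on_other_structures_block_trigger(self):
        t = self._table({
            ("LSC_IR_SSC_IRrc", 1): 10,
            ("LSC_IRrc_SSC_IR", 2): 8,
            ("LSC_IR_SSCrc_IRrc", 1): 1,
        })
        assert not detect_inline_repeats(t, min_reads=5).triggered

    def test_support_must_exceed_threshold(self):
        t = self._table({("LSC_IR_SSC_IRrc", 1): 3, ("LSC_IRrc_SSC_IR", 2): 2})
        assert not detect_inline_repeats(t, min_reads=5).triggered
        assert detect_inline_repeats(t, min_reads=4).triggered

    def test_empty_tally(self):
        assert not detect_inline_repeats(TallyTable(), min_reads=5).triggered
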