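import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circscan.orf import (
    CircularORF,
    OrfParams,
    best_orf,
    filter_orfs,
    find_circular_orfs,
    translate,
    write_orf_table,
)
from circscan.seq_io import CircRNARecord

from _oracles import oracle_circular_orfs, oracle_translate, random_circle


def _scan_tuples(rec, max_cycles=3):
    orfs = find_circular_orfs(rec, OrfParams(max_cycles=max_cycles))
    return {(o.start_nt, o.orf_len_nt, o.peptide) for o in orfs}


def _infinite_starts(rec, max_cycles=3):
    orfs = find_circular_orfs(rec, OrfParams(max_cycles=max_cycles), include_infinite=True)
    return {o.start_nt for o in orfs if o.is_infinite}


class TestTranslate:
    def test_simple(self):
        assert translate("ATGAAAGGG") == "MKG"

    def test_n_yields_x(self):
        assert translate("ATGNNN") == "MX"

    def test_length_not_multiple_of_3(self):
        with pytest.raises(ValueError):
            translate("ATGA")

    def test_against_biopython_oracle(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=900))
        assert translate(seq) == oracle_translate(seq)

    @given(st.text(alphabet="ACGT", min_size=3, max_size=120).filter(lambda s: len(s) % 3 == 0))
    def test_property_against_oracle(self, seq):
        assert translate(seq) == oracle_translate(seq)


class TestFindCircularOrfs:
    def test_linear_orf(self, simple_circle):
        (orf,) = find_circular_orfs(simple_circle)
        assert orf.start_nt == 0
        assert orf.orf_len_nt == 12
        assert orf.peptide == "MKG"
        assert not orf.spans_junction
        assert orf.overlay_bp == 0
        assert orf.is_complete

    def test_wrapping_orf(self, wrapping_circle):
        (orf,) = find_circular_orfs(wrapping_circle)
        assert orf.start_nt == 8
        assert orf.orf_len_nt == 12
        assert orf.peptide == "MKG"
        assert orf.spans_junction
        assert orf.overlay_bp == 0

    def test_infinite_orf_excluded(self):
        # L = 12 (multiple of 3), single ATG, no stop anywhere in its frame
        rec = CircRNARecord(circ_id="inf", sequence="ATGAAAGGGAAA")
        assert find_circular_orfs(rec) == []
        diag = find_circular_orfs(rec, include_infinite=True)
        assert len(diag) == 1
        assert diag[0].is_infinite and not diag[0].is_complete

    def test_short_circle_rejected(self):
        rec = CircRNARecord(circ_id="tiny", sequence="AT")
        with pytest.raises(ValueError):
            find_circular_orfs(rec)

    def test_sorted_by_peptide_length_then_start(self):
        # two ATGs sharing one stop: nested starts both reported
        rec = CircRNARecord(circ_id="nested", sequence="ATGCCCATGAAATAGGGGGGG")
        orfs = find_circular_orfs(rec)
        peps = [o.pep_len_aa for o in orfs]
        assert peps == sorted(peps, reverse=True)
        assert orfs[0].start_nt == 0 and orfs[1].start_nt == 6

    def test_oracle_equivalence_small_random(self, rng):
        for _ in range(300):
            seq = random_circle(rng, 3, 15)
            rec = CircRNARecord(circ_id="r", sequence=seq)
            expected_complete, expected_infinite = oracle_circular_orfs(seq)
            assert _scan_tuples(rec) == expected_complete, seq
            assert _infinite_starts(rec) == expected_infinite, seq

    def test_oracle_equivalence_medium_random(self, rng):
        for _ in range(100):
            seq = random_circle(rng, 16, 60)
            rec = CircRNARecord(circ_id="r", sequence=seq)
            expected_complete, expected_infinite = oracle_circular_orfs(seq)
            assert _scan_tuples(rec) == expected_complete, seq
            assert _infinite_starts(rec) == expected_infinite, seq

    @given(st.text(alphabet="ACGT", min_size=3, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_property_oracle_equivalence(self, seq):
        rec = CircRNARecord(circ_id="h", sequence=seq)
        expected_complete, expected_infinite = oracle_circular_orfs(seq)
        assert _scan_tuples(rec) == expected_complete
        assert _infinite_starts(rec) == expected_infinite


class TestOrfInvariants:
    def test_rotation_covariance(self, rng):
        for _ in range(50):
            seq = random_circle(rng, 6, 40)
            L = len(seq)
            r = int(rng.integers(1, L))
            rotated = seq[r:] + seq[:r]
            base = find_circular_orfs(CircRNARecord(circ_id="a", sequence=seq))
            rot = find_circular_orfs(CircRNARecord(circ_id="b", sequence=rotated))
            key = lambda orfs: sorted((o.peptide, o.orf_len_nt, o.is_complete) for o in orfs)
            assert key(base) == key(rot)
            # removing the first r bases shifts every start by -r mod L
            assert sorted((o.start_nt + r) % L for o in rot) == sorted(o.start_nt for o in base)

    def test_linear_consistency(self, rng):
        # non-wrapping ORFs equal a plain linear scan of the string
        for _ in range(50):
            seq = random_circle(rng, 9, 60)
            orfs = find_circular_orfs(CircRNARecord(circ_id="l", sequence=seq))
            for o in orfs:
                if o.start_nt + o.orf_len_nt <= len(seq):
                    segment = seq[o.start_nt : o.start_nt + o.orf_len_nt]
                    assert translate(segment[:-3]) == o.peptide

    def test_frame_cycle_bound_three_cycles_suffice(self, rng):
        checked = 0
        while checked < 100:
            seq = random_circle(rng, 4, 40)
            if len(seq) % 3 == 0:
                continue
            checked += 1
            rec = CircRNARecord(circ_id="f", sequence=seq)
            assert _scan_tuples(rec, max_cycles=3) == _scan_tuples(rec, max_cycles=6)
            assert _infinite_starts(rec, max_cycles=3) == _infinite_starts(rec, max_cycles=6)

    def test_multiple_of_three_one_cycle_suffices(self, rng):
        checked = 0
        while checked < 50:
            seq = random_circle(rng, 3, 42)
            if len(seq) % 3 != 0:
                continue
            checked += 1
            rec = CircRNARecord(circ_id="f", sequence=seq)
            assert _scan_tuples(rec, max_cycles=1) == _scan_tuples(rec, max_cycles=3)

    def test_overlay_identity(self, rng):
        for _ in range(100):
            seq = random_circle(rng, 3, 30)
            rec = CircRNARecord(circ_id="o", sequence=seq)
            for o in find_circular_orfs(rec):
                assert o.overlay_bp == max(0, o.orf_len_nt - len(seq))
                assert o.spans_junction == (o.start_nt + o.orf_len_nt > len(seq))
                assert o.orf_len_nt % 3 == 0
                assert o.pep_len_aa == o.orf_len_nt // 3 - 1
                assert "*" not in o.peptide


class TestFilterOrfs:
    def _orf(self, pep_len, overlay, spans, L=10_000):
        orf_len = 3 * (pep_len + 1)
        circle_len = orf_len - overlay if overlay > 0 else L
        start = circle_len - 1 if spans else 0
        if overlay > 0:
            start = 0  # whole-circle wrap implies junction anyway
        return CircularORF(
            circ_id="x",
            start_nt=start,
            orf_len_nt=orf_len,
            peptide="A" * pep_len,
            circle_len=circle_len,
            is_complete=True,
        )

    def test_exactly_50_aa_rejected(self):
        orf = self._orf(50, 0, True)
        assert orf.spans_junction
        kept, rejected = filter_orfs([orf], return_rejections=True)
        assert kept == []
        assert rejected[0][1] == "pep_len"

    def test_51_aa_kept(self):
        orf = self._orf(51, 0, True)
        assert filter_orfs([orf]) == [orf]

    def test_overlay_exactly_50_rejected(self):
        orf = self._orf(60, 50, True)
        assert orf.overlay_bp == 50
        kept, rejected = filter_orfs([orf], return_rejections=True)
        assert kept == []
        assert rejected[0][1] == "overlay"

    def test_overlay_49_kept(self):
        orf = self._orf(60, 49, True)
        assert orf.overlay_bp == 49
        assert filter_orfs([orf]) == [orf]

    def test_junction_required(self):
        orf = self._orf(60, 0, False)
        assert not orf.spans_junction
        kept, rejected = filter_orfs([orf], return_rejections=True)
        assert kept == []
        assert rejected[0][1] == "orf_junction"
        assert filter_orfs([orf], OrfParams(require_junction=False)) == [orf]

    def test_planted_qualifier_kept(self, planted_pass):
        rec, truth, _ = planted_pass
        orfs = find_circular_orfs(rec)
        kept = filter_orfs(orfs)
        assert [o.start_nt for o in kept] == [truth.start_nt]


class TestBestOrf:
    def test_longest_then_smallest_start(self):
        a = CircularORF("x", 5, 30, "A" * 9, 100, True)
        b = CircularORF("x", 2, 30, "C" * 9, 100, True)
        c = CircularORF("x", 0, 15, "G" * 4, 100, True)
        assert best_orf([a, b, c]) is b

    def test_empty(self):
        assert best_orf([]) is None


def test_write_orf_table(tmp_path, simple_circle):
    orfs = find_circular_orfs(simple_circle)
    path = tmp_path / "orfs.tsv"
    write_orf_table(orfs, path)
    lines = path.read_text().splitlines()
    assert lines[0].split("\t")[0] == "circ_id"
    assert lines[1].split("\t") == [
        "toy1", "0", "0", "12", "3", "false", "0", "true", "false", "MKG",
    ]
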