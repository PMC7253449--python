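"""uORF detection, Kozak scoring, enumeration and diff-based annotation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uorfkit.annotation import (
    CSQ_CDS_ELONGATION,
    CSQ_OORF_OUT_OF_FRAME,
    CSQ_UORF_CREATED,
    CSQ_UORF_ELONGATED,
    KIND_UAUG_CREATED,
    KIND_UORF_FRAMESHIFTED,
    KIND_USTOP_REMOVED,
    annotate_variant,
    classify_kozak,
    enumerate_stop_removing_snvs,
    enumerate_uaug_deletions,
    enumerate_uaug_snvs,
    find_uorfs,
    is_high_impact,
    records_to_frame,
)
from uorfkit.transcripts import TranscriptError, TranscriptRecord, TranscriptVariant

from .conftest import random_transcript
from .oracles import oracle_uaug_deletions


class TestKozak:
    @pytest.mark.parametrize(
        "seq,aug,expected,m3,p3",
        [
            ("AAGATGGCC", 3, "strong", "A", "G"),
            ("GCCATGTTT", 3, "moderate", "G", "T"),
            ("ATGGTTTTT", 0, "moderate", None, "G"),
            ("ATGTTTTTT", 0, "weak", None, "T"),
            ("TTTATGCCC", 3, "weak", "T", "C"),
        ],
    )
    def test_rule(self, seq, aug, expected, m3, p3):
        k = classify_kozak(seq, aug)
        assert (k.value, k.minus3, k.plus3) == (expected, m3, p3)

    def test_plus_base_beyond_sequence_is_error(self):
        with pytest.raises(TranscriptError, match="Kozak"):
            classify_kozak("ATG", 0)

    def test_configurable_plus_offset(self):
        # with the classical +4 column the scored base moves one to the right
        assert classify_kozak("ATGGTT", 0, plus_offset=3).value == "moderate"
        assert classify_kozak("ATGGTT", 0, plus_offset=4).value == "weak"

    @settings(derandomize=True, max_examples=150)
    @given(st.text(alphabet="ACGT", min_size=7, max_size=7))
    def test_trichotomy(self, seq):
        k = classify_kozak(seq + "ATG", 3)
        assert k.value in ("strong", "moderate", "weak")
        strong = k.minus3 in ("A", "G") and k.plus3 == "G"
        weak = k.minus3 not in ("A", "G") and k.plus3 != "G"
        assert k.value == ("strong" if strong else "weak" if weak else "moderate")


class TestFindUorfs:
    def test_uorf_plus_existing_oorf(self, two_uorf_transcript):
        uorfs = find_uorfs(two_uorf_transcript)
        by_start = {u.start: u for u in uorfs}
        assert set(by_start) == {0, 5}
        u0 = by_start[0]
        assert (u0.stop_start, u0.start_kozak.value, u0.is_oorf) == (6, "weak", False)
        o = by_start[5]
        assert o.is_oorf and o.frame_vs_cds == 0
        assert o.start_kozak.value == "moderate"  # -3=G, +3=A

    def test_empty_utr(self):
        t = TranscriptRecord("G", "T", "", "ATGGCT")
        assert find_uorfs(t) == []

    def test_strong_kozak_uorf(self, strong_kozak_transcript):
        (u,) = find_uorfs(strong_kozak_transcript)
        assert (u.start, u.stop_start, u.start_kozak.value) == (4, 10, "strong")

    def test_converging_starts_share_strongest_kozak(self):
        # two in-frame ATGs (3 and 6) converge on the TAG stop at 12; the
        # downstream start is strong (-3=A at 3, +3=G at 9), the upstream
        # one only moderate
        utr = "AAGATGATGGACTAGCC"
        t = TranscriptRecord("G", "T", utr, "ATGGCT")
        uorfs = [u for u in find_uorfs(t) if not u.is_oorf]
        stops = {u.stop_start for u in uorfs}
        assert stops == {12}
        assert {u.start for u in uorfs} == {3, 6}
        strengths = {u.start: (u.start_kozak.value, u.kozak.value) for u in uorfs}
        assert strengths[3][0] == "moderate"
        assert strengths[6][0] == "strong"
        # both records report the strongest converging Kozak
        assert strengths[3][1] == strengths[6][1] == "strong"

    def test_evidence_flag_from_stop_coordinate(self, strong_kozak_transcript):
        (u,) = find_uorfs(strong_kozak_transcript, evidence={("T3", 10)})
        assert u.has_translation_evidence

    def test_alt_stop_starts_recorded(self):
        t = TranscriptRecord("G", "T", "ATGAAATGAAAATGATAA", "ATGGCT")
        u = next(x for x in find_uorfs(t) if x.start == 0)
        assert u.stop_start == 6
        assert u.alt_stop_starts == (12, 15)


class TestEnumerateUaugSnvs:
    def test_worked_fixture(self, simple_transcript):
        recs = enumerate_uaug_snvs(simple_transcript)
        as_tuples = {
            (r.variant.pos, r.variant.ref, r.variant.alt, r.uaug_start,
             r.distance_to_cds, r.frame_vs_cds, r.consequence, r.kozak.value)
            for r in recs
        }
        assert as_tuples == {
            (1, "C", "T", 0, 7, 1, CSQ_OORF_OUT_OF_FRAME, "weak"),
            (4, "T", "A", 4, 3, 0, CSQ_CDS_ELONGATION, "weak"),
        }

    def test_existing_atg_yields_nothing(self):
        t = TranscriptRecord("G", "T", "ATG", "ATGGCT")
        assert enumerate_uaug_snvs(t) == []

    def test_n_windows_skipped(self):
        t = TranscriptRecord("G", "T", "ANGTTT", "ATGGCT")
        positions = {r.variant.pos for r in enumerate_uaug_snvs(t)}
        assert 1 not in positions  # the N-containing window is not asserted


class TestEnumerateStopRemoving:
    @pytest.mark.parametrize("codon,expected", [("TAA", 7), ("TGA", 8), ("TAG", 8)])
    def test_count_law(self, codon, expected):
        t = TranscriptRecord("G", "T", "ATGAAA" + codon + "CC", "ATGGCT")
        recs = enumerate_stop_removing_snvs(t, find_uorfs(t))
        assert len(recs) == expected
        assert all(r.kind == KIND_USTOP_REMOVED for r in recs)

    def test_no_rescue_gives_oorf_by_frame(self, two_uorf_transcript):
        uorfs = find_uorfs(two_uorf_transcript)
        recs = enumerate_stop_removing_snvs(two_uorf_transcript, uorfs)
        # uORF(0, 6): (11-0) % 3 == 2 and no later UTR stop -> out-of-frame oORF
        assert len(recs) == 8
        assert {r.consequence for r in recs} == {CSQ_OORF_OUT_OF_FRAME}

    def test_rescue_stop_gives_uorf_elongated(self):
        t = TranscriptRecord("G", "T", "ATGAAATGAAAATGACC", "ATGGCT")
        recs = enumerate_stop_removing_snvs(t, find_uorfs(t))
        first_stop_recs = [r for r in recs if 6 <= r.variant.pos < 9]
        assert first_stop_recs
        assert {r.consequence for r in first_stop_recs} == {CSQ_UORF_ELONGATED}

    def test_converging_starts_counted_once_per_stop(self):
        utr = "AAGATGATGGACTAGCC"  # two starts, one shared TAG stop
        t = TranscriptRecord("G", "T", utr, "ATGGCT")
        recs = enumerate_stop_removing_snvs(t, find_uorfs(t))
        assert len(recs) == 8  # one TAG stop, not 16
        # anchored on the strongest-Kozak start (position 6)
        assert {r.uaug_start for r in recs} == {6}
        assert {r.kozak.value for r in recs} == {"strong"}


class TestEnumerateDeletions:
    def test_no_creatable_atg(self):
        t = TranscriptRecord("G", "T", "CCCCCC", "ATGGCT")
        assert enumerate_uaug_deletions(t) == []

    def test_shifted_existing_atg_excluded(self):
        # deleting the leading C shifts the existing ATG without creating one
        t = TranscriptRecord("G", "T", "CATGAA", "ATGGCT")
        recs = enumerate_uaug_deletions(t, max_len=1)
        assert all(
            not (r.variant.pos == 0 and r.uaug_start == 0) for r in recs
        )

    @pytest.mark.parametrize("utr_seed", range(6))
    def test_matches_alignment_diff_oracle(self, utr_seed):
        rng = np.random.default_rng(900 + utr_seed)
        t = random_transcript(rng, min_len=15, max_len=80, tag=str(utr_seed))
        got = {
            (r.variant.pos, r.variant.ref, r.uaug_start)
            for r in enumerate_uaug_deletions(t, max_len=5)
        }
        assert got == oracle_uaug_deletions(t.utr_seq, max_len=5)


class TestAnnotateVariant:
    def test_frameshift_bypasses_existing_stop(self, strong_kozak_transcript):
        v = TranscriptVariant("T3", 9, "", "T")
        (r,) = annotate_variant(strong_kozak_transcript, v)
        assert r.kind == KIND_UORF_FRAMESHIFTED
        assert r.consequence == CSQ_OORF_OUT_OF_FRAME
        assert r.kozak.value == "strong"
        assert (r.distance_to_cds, r.frame_vs_cds) == (13, 1)
        assert r.high_impact

    def test_matches_snv_enumerators(self, random_transcripts):
        for t in random_transcripts[:12]:
            uorfs = find_uorfs(t)
            enumerated = enumerate_uaug_snvs(t) + enumerate_stop_removing_snvs(t, uorfs)
            for rec in enumerated:
                again = annotate_variant(t, rec.variant)
                keys = {r.key() for r in again}
                assert rec.key() in keys, (t.utr_seq, rec)
                match = next(r for r in again if r.key() == rec.key())
                assert match.consequence == rec.consequence
                assert match.kozak == rec.kozak
                assert match.high_impact == rec.high_impact

    def test_irrelevant_snv_is_silent(self):
        t = TranscriptRecord("G", "T", "CCCCCCCCC", "ATGGCT")
        assert annotate_variant(t, TranscriptVariant("T", 4, "C", "G")) == []

    def test_inframe_deletion_keeps_uorf_silent(self, strong_kozak_transcript):
        # deleting a whole codon inside the uORF keeps the stop in frame
        v = TranscriptVariant("T3", 7, "GAC", "")
        assert annotate_variant(strong_kozak_transcript, v) == []

    def test_stop_codon_snv_creating_atg_emits_two_kinds(self):
        # uORF start 0 with TAA stop at 6; the SNV 6 T->G both destroys the
        # stop (GAA) and completes a new ATG in the overlapping window 4..7
        t = TranscriptRecord("G", "T", "ATGAATTAACC", "ATGGCT")
        recs = annotate_variant(t, TranscriptVariant("T", 6, "T", "G"))
        kinds = {r.kind for r in recs}
        assert kinds == {KIND_USTOP_REMOVED, KIND_UAUG_CREATED}
        created = next(r for r in recs if r.kind == KIND_UAUG_CREATED)
        assert created.uaug_start == 4


class TestHighImpact:
    @pytest.mark.parametrize(
        "kind,csq,kozak,evidence,expected",
        [
            (KIND_UAUG_CREATED, CSQ_OORF_OUT_OF_FRAME, "strong", False, True),
            (KIND_UAUG_CREATED, CSQ_CDS_ELONGATION, "moderate", False, True),
            (KIND_UAUG_CREATED, CSQ_OORF_OUT_OF_FRAME, "weak", False, False),
            (KIND_UAUG_CREATED, CSQ_UORF_CREATED, "strong", False, False),
            (KIND_USTOP_REMOVED, CSQ_OORF_OUT_OF_FRAME, "weak", True, True),
            (KIND_USTOP_REMOVED, CSQ_OORF_OUT_OF_FRAME, "weak", False, False),
            (KIND_UORF_FRAMESHIFTED, CSQ_CDS_ELONGATION, "moderate", False, True),
            (KIND_USTOP_REMOVED, CSQ_UORF_ELONGATED, "strong", True, False),
        ],
    )
    def test_rule(self, kind, csq, kozak, evidence, expected):
        from uorfkit.annotation import KozakStrength

        k = KozakStrength(kozak, "A", "G")
        assert is_high_impact(kind, csq, k, evidence) is expected


class TestInvariants:
    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 10_000))
    def test_partition_and_trichotomy(self, seed):
        rng = np.random.default_rng(seed)
        t = random_transcript(rng, min_len=10, max_len=120, tag="h")
        uorfs = find_uorfs(t)
        recs = enumerate_uaug_snvs(t) + enumerate_stop_removing_snvs(t, uorfs)
        for r in recs:
            assert r.consequence in (
                CSQ_UORF_CREATED, CSQ_OORF_OUT_OF_FRAME,
                CSQ_CDS_ELONGATION, CSQ_UORF_ELONGATED,
            )
            # CDS elongation iff frame 0 and no UTR stop
            if r.consequence == CSQ_CDS_ELONGATION:
                assert r.frame_vs_cds == 0
            if r.consequence == CSQ_OORF_OUT_OF_FRAME:
                assert r.frame_vs_cds != 0
            assert r.kozak.value in ("strong", "moderate", "weak")
            assert r.within_50bp == (r.distance_to_cds <= 50)

    def test_tsv_export_column_order(self, simple_transcript):
        df = records_to_frame(enumerate_uaug_snvs(simple_transcript))
        assert list(df.columns) == [
            "transcript_id", "pos", "ref", "alt", "kind", "consequence",
            "kozak", "minus3", "plus3", "distance_to_cds", "frame",
            "evidence", "high_impact",
        ]
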