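"""Detection and classification of uORF-perturbing 5'UTR variants.

An upstream ORF (uORF) is an ATG within the 5'UTR with an in-frame stop codon
(TAA/TGA/TAG) entirely within the UTR.  A uAUG lacking such a stop reads into
the coding sequence: in-frame it elongates the CDS, out-of-frame it forms an
overlapping ORF (oORF).  This module detects existing uORFs/oORFs, enumerates
every SNV that creates an upstream ATG or destroys a uORF stop, enumerates
small ATG-creating deletions, and annotates arbitrary supplied variants by a
before/after diff (catching frameshifts that let an existing uORF bypass its
stop).

Kozak context is scored from the -3 and +3 positions relative to the A of the
ATG: Strong when -3 is A/G *and* +3 is G, Moderate when exactly one holds,
Weak otherwise.  "+3" here is the base at index ``aug_start + 3`` (first base
after the G); the offset is configurable via ``plus_offset``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from .transcripts import (
    TranscriptError,
    TranscriptRecord,
    TranscriptVariant,
    apply_variant,
)

STOP_CODONS = frozenset({"TAA", "TGA", "TAG"})

STRONG, MODERATE, WEAK = "strong", "moderate", "weak"

KIND_UAUG_CREATED = "uAUG_created"
KIND_USTOP_REMOVED = "uSTOP_removed"
KIND_UORF_FRAMESHIFTED = "uORF_frameshifted"

CSQ_UORF_CREATED = "uORF_created"
CSQ_OORF_OUT_OF_FRAME = "oORF_out_of_frame"
CSQ_CDS_ELONGATION = "CDS_elongation"
CSQ_UORF_ELONGATED = "uORF_elongated"

_RANK = {WEAK: 0, MODERATE: 1, STRONG: 2}


@dataclass(frozen=True)
class KozakStrength:
    value: str  # strong | moderate | weak
    minus3: Optional[str]
    plus3: Optional[str]

    def __post_init__(self) -> None:
        assert self.value in (STRONG, MODERATE, WEAK)

    @property
    def rank(self) -> int:
        return _RANK[self.value]

    @property
    def moderate_or_strong(self) -> bool:
        return self.value in (STRONG, MODERATE)


def classify_kozak(seq: str, aug_start: int, plus_offset: int = 3) -> KozakStrength:
    """Score Kozak strength of the ATG at ``aug_start`` within ``seq``.

    ``seq`` is the full transcript substrate (UTR + CDS prefix) so the +3 base
    may be drawn from the CDS.  A -3 position before the transcript start
    counts as non-matching; a missing +3 base is a contract error (CDS prefix
    too short).
    """
    minus3 = seq[aug_start - 3] if aug_start >= 3 else None
    plus_idx = aug_start + plus_offset
    if plus_idx >= len(seq):
        raise TranscriptError(
            f"cannot score Kozak at {aug_start}: sequence ends before +{plus_offset}"
        )
    plus3 = seq[plus_idx]
    m3_ok = minus3 in ("A", "G")
    p3_ok = plus3 == "G"
    value = STRONG if (m3_ok and p3_ok) else MODERATE if (m3_ok or p3_ok) else WEAK
    return KozakStrength(value, minus3, plus3)


@dataclass(frozen=True)
class UORF:
    """An existing upstream ORF, or (with ``stop_start=None``) an existing oORF."""

    transcript_id: str
    start: int
    stop_start: Optional[int]
    start_kozak: KozakStrength
    kozak: KozakStrength  # strongest over all uAUGs converging on this stop
    frame_vs_cds: int
    has_translation_evidence: bool = False
    alt_stop_starts: tuple[int, ...] = ()

    @property
    def is_oorf(self) -> bool:
        return self.stop_start is None


@dataclass(frozen=True)
class ConsequenceRecord:
    """One candidate or observed uORF-perturbing variant, fully annotated."""

    transcript_id: str
    variant: TranscriptVariant
    kind: str  # uAUG_created | uSTOP_removed | uORF_frameshifted
    consequence: str  # uORF_created | oORF_out_of_frame | CDS_elongation | uORF_elongated
    kozak: KozakStrength
    distance_to_cds: int
    frame_vs_cds: int
    evidence: bool = False
    high_impact: bool = field(default=False)
    uaug_start: int = -1  # post-edit position of the affected ATG

    @property
    def within_50bp(self) -> bool:
        return self.distance_to_cds <= 50

    def key(self) -> tuple:
        v = self.variant
        return (self.transcript_id, v.pos, v.ref, v.alt, self.kind, self.uaug_start)


def is_high_impact(kind: str, consequence: str, kozak: KozakStrength, evidence: bool) -> bool:
    """High-impact: the perturbation yields an oORF/CDS elongation driven by a
    strong/moderate-Kozak (or, for existing uORFs, translation-evidenced) start."""
    if consequence not in (CSQ_OORF_OUT_OF_FRAME, CSQ_CDS_ELONGATION):
        return False
    if kind == KIND_UAUG_CREATED:
        return kozak.moderate_or_strong
    if kind in (KIND_USTOP_REMOVED, KIND_UORF_FRAMESHIFTED):
        return kozak.moderate_or_strong or evidence
    return False


def _finish(
    t_id: str,
    variant: TranscriptVariant,
    kind: str,
    kozak: KozakStrength,
    L: int,
    start: int,
    stop_exists: bool,
    evidence: bool,
    created: bool,
) -> ConsequenceRecord:
    d = L - start
    frame = d % 3
    if stop_exists:
        consequence = CSQ_UORF_CREATED if created else CSQ_UORF_ELONGATED
    else:
        consequence = CSQ_CDS_ELONGATION if frame == 0 else CSQ_OORF_OUT_OF_FRAME
    return ConsequenceRecord(
        transcript_id=t_id,
        variant=variant,
        kind=kind,
        consequence=consequence,
        kozak=kozak,
        distance_to_cds=d,
        frame_vs_cds=frame,
        evidence=evidence,
        high_impact=is_high_impact(kind, consequence, kozak, evidence),
        uaug_start=start,
    )


def _first_inframe_stop(utr: str, start: int) -> Optional[int]:
    """First in-frame stop codon downstream of the ATG at ``start``, fully
    within the UTR, or None."""
    L = len(utr)
    for j in range(start + 3, L - 2, 3):
        if utr[j : j + 3] in STOP_CODONS:
            return j
    return None


def _inframe_stops(utr: str, start: int) -> list[int]:
    L = len(utr)
    return [
        j for j in range(start + 3, L - 2, 3) if utr[j : j + 3] in STOP_CODONS
    ]


def find_uorfs(
    t: TranscriptRecord,
    evidence: Optional[set[tuple[str, int]]] = None,
    plus_offset: int = 3,
) -> list[UORF]:
    """Scan the UTR for existing uORFs and oORFs.

    Returns one record per (uAUG, first in-frame UTR stop) pair, plus one
    record per uAUG lacking an in-frame UTR stop (existing oORF, flagged via
    ``stop_start=None``).  Per shared stop, ``kozak`` is the strongest among
    converging starts; ``start_kozak`` is the start's own score.
    """
    utr = t.utr_seq
    full = t.full_seq
    L = len(utr)
    evidence = evidence or set()

    raw: list[tuple[int, Optional[int], KozakStrength, list[int]]] = []
    i = utr.find("ATG")
    while i != -1:
        if i + 3 <= L:
            koz = classify_kozak(full, i, plus_offset)
            stops = _inframe_stops(utr, i)
            stop0 = stops[0] if stops else None
            raw.append((i, stop0, koz, stops[1:]))
        i = utr.find("ATG", i + 1)

    # strongest Kozak among starts converging on the same first stop
    best_by_stop: dict[int, KozakStrength] = {}
    for start, stop0, koz, _ in raw:
        if stop0 is not None:
            prev = best_by_stop.get(stop0)
            if prev is None or koz.rank > prev.rank:
                best_by_stop[stop0] = koz

    out = []
    for start, stop0, koz, alts in raw:
        shared = best_by_stop[stop0] if stop0 is not None else koz
        out.append(
            UORF(
                transcript_id=t.transcript_id,
                start=start,
                stop_start=stop0,
                start_kozak=koz,
                kozak=shared,
                frame_vs_cds=(L - start) % 3,
                has_translation_evidence=(
                    stop0 is not None and (t.transcript_id, stop0) in evidence
                ),
                alt_stop_starts=tuple(alts),
            )
        )
    return out


def enumerate_uaug_snvs(
    t: TranscriptRecord, plus_offset: int = 3
) -> list[ConsequenceRecord]:
    """Every SNV turning a UTR trinucleotide window into a new ATG.

    A window differing from ATG at exactly one position yields one record;
    windows containing N are skipped (codon identity cannot be asserted).
    Each record is annotated on the post-edit sequence.
    """
    utr = t.utr_seq
    L = len(utr)
    target = "ATG"
    out = []
    for i in range(L - 2):
        window = utr[i : i + 3]
        if "N" in window:
            continue
        mismatches = [k for k in range(3) if window[k] != target[k]]
        if len(mismatches) != 1:
            continue
        k = mismatches[0]
        pos = i + k
        v = TranscriptVariant(t.transcript_id, pos, window[k], target[k])
        post = apply_variant(t, v)
        koz = classify_kozak(post.full_seq, i, plus_offset)
        stop0 = _first_inframe_stop(post.utr_seq, i)
        out.append(
            _finish(
                t.transcript_id, v, KIND_UAUG_CREATED, koz, L, i,
                stop_exists=stop0 is not None, evidence=False, created=True,
            )
        )
    return out


def _representative_per_stop(uorfs: Iterable[UORF]) -> dict[int, UORF]:
    """Collapse converging uORFs to one representative per stop codon:
    strongest own-Kozak start, tie broken 5'-most."""
    reps: dict[int, UORF] = {}
    for u in uorfs:
        if u.stop_start is None:
            continue
        cur = reps.get(u.stop_start)
        if (
            cur is None
            or u.start_kozak.rank > cur.start_kozak.rank
            or (u.start_kozak.rank == cur.start_kozak.rank and u.start < cur.start)
        ):
            reps[u.stop_start] = u
    return reps


def enumerate_stop_removing_snvs(
    t: TranscriptRecord, uorfs: Sequence[UORF]
) -> list[ConsequenceRecord]:
    """Every SNV that changes a uORF stop codon into a non-stop codon.

    One record set per distinct stop codon (converging starts collapsed);
    TAA admits 7 removing SNVs, TGA and TAG 8 each.  The consequence follows
    the uORF's frame when no downstream in-frame UTR stop rescues it.
    """
    utr = t.utr_seq
    L = len(utr)
    out = []
    for stop_start, u in sorted(_representative_per_stop(uorfs).items()):
        codon = utr[stop_start : stop_start + 3]
        has_rescue = len(u.alt_stop_starts) > 0
        for k in range(3):
            for alt in "ACGT":
                if alt == codon[k]:
                    continue
                new_codon = codon[:k] + alt + codon[k + 1 :]
                if new_codon in STOP_CODONS:
                    continue
                v = TranscriptVariant(t.transcript_id, stop_start + k, codon[k], alt)
                out.append(
                    _finish(
                        t.transcript_id, v, KIND_USTOP_REMOVED, u.kozak, L, u.start,
                        stop_exists=has_rescue,
                        evidence=u.has_translation_evidence, created=False,
                    )
                )
    return out


def enumerate_uaug_deletions(
    t: TranscriptRecord, max_len: int = 5, plus_offset: int = 3
) -> list[ConsequenceRecord]:
    """Every 1..max_len bp UTR deletion creating a new ATG.

    A post-edit ATG counts as new unless it aligns base-for-base with a
    pre-edit ATG on one side of the deletion (a merely shifted ATG is not
    new).  Insertions are deliberately not enumerated.
    """
    utr = t.utr_seq
    L = len(utr)
    pre_atg = _atg_positions(utr)
    out = []
    for k in range(1, max_len + 1):
        for p in range(0, L - k + 1):
            post_utr = utr[:p] + utr[p + k :]
            v = TranscriptVariant(t.transcript_id, p, utr[p : p + k], "")
            for q in _new_atg_positions(pre_atg, post_utr, p, shift=-k, inserted_len=0):
                post = apply_variant(t, v)
                koz = classify_kozak(post.full_seq, q, plus_offset)
                stop0 = _first_inframe_stop(post_utr, q)
                out.append(
                    _finish(
                        t.transcript_id, v, KIND_UAUG_CREATED, koz, L - k, q,
                        stop_exists=stop0 is not None, evidence=False, created=True,
                    )
                )
    return out


def _atg_positions(seq: str) -> set[int]:
    pos, i = set(), seq.find("ATG")
    while i != -1:
        pos.add(i)
        i = seq.find("ATG", i + 1)
    return pos


def _new_atg_positions(
    pre_atg: set[int], post_utr: str, edit_pos: int, shift: int,
    inserted_len: int = 0,
) -> list[int]:
    """ATG positions in the post-edit UTR that are new relative to pre-edit.

    ``shift`` = len(alt) - len(ref).  For a length-preserving edit the
    alignment is the identity.  For an indel, a post window entirely left of
    the edit aligns to the same pre index; entirely right of the inserted
    segment it aligns to ``q - shift``; a window touching the edited segment
    is newly composed and always counts as new (a merely shifted pre-existing
    ATG is excluded by the alignment).
    """
    posts = sorted(_atg_positions(post_utr))
    if shift == 0:
        return [q for q in posts if q not in pre_atg]
    right_edge = edit_pos + inserted_len  # first post index right of the edit
    new = []
    for q in posts:
        if q + 3 <= edit_pos:  # entirely left of the edit
            if q not in pre_atg:
                new.append(q)
        elif q >= right_edge:  # entirely right of the edited segment
            if (q - shift) not in pre_atg:
                new.append(q)
        else:  # touches the edited segment: newly composed
            new.append(q)
    return new


def annotate_variant(
    t: TranscriptRecord,
    v: TranscriptVariant,
    evidence: Optional[set[tuple[str, int]]] = None,
    plus_offset: int = 3,
) -> list[ConsequenceRecord]:
    """Diff-based annotation of any supplied UTR SNV or small indel.

    Compares uORF structure before and after applying the variant and emits:

    * ``uAUG_created`` for each genuinely new upstream ATG;
    * ``uSTOP_removed`` when a variant mutates an existing uORF's stop codon
      away from TAA/TGA/TAG;
    * ``uORF_frameshifted`` when an indel inside an existing uORF changes its
      frame so the old stop is bypassed and the ORF runs into the CDS — a
      mechanism by which a single 5'UTR base insertion can act as
      loss-of-function.

    A single variant may emit multiple records.
    """
    evidence = evidence or set()
    pre_uorfs = find_uorfs(t, evidence, plus_offset)
    post = apply_variant(t, v)
    L_pre, L_post = t.utr_length, post.utr_length
    shift = v.length_change
    out: list[ConsequenceRecord] = []

    if v.pos >= L_pre and v.ref:
        return []  # edit entirely within the CDS prefix: no UTR consequence

    # --- new upstream ATGs -------------------------------------------------
    pre_atg = _atg_positions(t.utr_seq)
    for q in _new_atg_positions(
        pre_atg, post.utr_seq, v.pos, shift, inserted_len=len(v.alt)
    ):
        if q + 3 > L_post:
            continue
        koz = classify_kozak(post.full_seq, q, plus_offset)
        stop0 = _first_inframe_stop(post.utr_seq, q)
        out.append(
            _finish(
                t.transcript_id, v, KIND_UAUG_CREATED, koz, L_post, q,
                stop_exists=stop0 is not None, evidence=False, created=True,
            )
        )

    # --- existing uORFs losing their stop -----------------------------------
    def _map_to_post(pre_idx: int) -> Optional[int]:
        if pre_idx + 3 <= v.pos:  # window entirely left of the edit
            return pre_idx
        if pre_idx >= v.pos + len(v.ref):  # entirely right
            return pre_idx + shift
        return None  # window overlaps the edited bases

    for stop_start, u in sorted(_representative_per_stop(pre_uorfs).items()):
        start_post = _map_to_post(u.start)
        if start_post is None:
            continue  # the uAUG itself was edited; any surviving ATG is "new"
        if post.utr_seq[start_post : start_post + 3] != "ATG":
            continue
        stop_post = _map_to_post(stop_start)
        stop_mutated = stop_post is None or (
            post.utr_seq[stop_post : stop_post + 3] not in STOP_CODONS
        )
        new_stop0 = _first_inframe_stop(post.utr_seq, start_post)
        stop_still_terminates = (
            not stop_mutated
            and stop_post is not None
            and (stop_post - start_post) % 3 == 0
            and stop_post + 3 <= L_post
            and (new_stop0 is not None and new_stop0 <= stop_post)
        )
        if stop_still_terminates:
            continue
        if stop_mutated:
            kind = KIND_USTOP_REMOVED
        elif shift % 3 != 0:
            kind = KIND_UORF_FRAMESHIFTED
        else:
            continue  # in-frame indel keeps the stop in frame; handled above
        out.append(
            _finish(
                t.transcript_id, v, kind, u.kozak, L_post, start_post,
                stop_exists=new_stop0 is not None,
                evidence=u.has_translation_evidence, created=False,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "transcript_id", "pos", "ref", "alt", "kind", "consequence", "kozak",
    "minus3", "plus3", "distance_to_cds", "frame", "evidence", "high_impact",
]


def records_to_frame(records: Iterable[ConsequenceRecord]):
    """ConsequenceRecords as a pandas DataFrame with a stable column order."""
    import pandas as pd

    rows = []
    for r in records:
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "pos": r.variant.pos,
                "ref": r.variant.ref or "-",
                "alt": r.variant.alt or "-",
                "kind": r.kind,
                "consequence": r.consequence,
                "kozak": r.kozak.value,
                "minus3": r.kozak.minus3 or ".",
                "plus3": r.kozak.plus3 or ".",
                "distance_to_cds": r.distance_to_cds,
                "frame": r.frame_vs_cds,
                "evidence": r.evidence,
                "high_impact": r.high_impact,
            }
        )
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def record_info_string(r: ConsequenceRecord) -> str:
    """Compact VCF-INFO-style annotation for passthrough."""
    return (
        f"UORF_KIND={r.kind};UORF_CSQ={r.consequence};KOZAK={r.kozak.value};"
        f"DIST={r.distance_to_cds};FRAME={r.frame_vs_cds};"
        f"EVIDENCE={int(r.evidence)};HIGH_IMPACT={int(r.high_impact)}"
    )
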