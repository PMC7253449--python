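"""Transcript/5'UTR data model, readers, and sequence editing.

Coordinates are 0-based, half-open, in *spliced transcript space* on the
sense strand: the 5'UTR occupies ``[0, L)`` and the CDS starts at ``L``
(``L == len(utr_seq)``).  All annotation downstream of the loaders works on
this spliced representation; genomic strand handling is confined to the
GFF3/VCF readers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class TranscriptError(ValueError):
    """Raised for violations of the transcript data contract."""


@dataclass(frozen=True)
class ExonBlock:
    """One genomic block of the spliced transcript (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise TranscriptError(f"empty/inverted exon block {self}")
        if self.strand not in ("+", "-"):
            raise TranscriptError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptRecord:
    """A canonical transcript reduced to its 5'UTR plus a CDS prefix.

    ``utr_seq`` is the spliced 5'UTR, 5'->3' on the sense strand;
    ``cds_prefix`` is the first >=3 bases of the CDS beginning with the
    canonical ATG (when ``canonical_complete``).  ``exon_blocks`` optionally
    map transcript coordinates back to the genome.
    """

    gene_id: str
    transcript_id: str
    utr_seq: str
    cds_prefix: str
    exon_blocks: Optional[tuple[ExonBlock, ...]] = None
    canonical_complete: bool = True
    no_utr: bool = field(default=False)

    def __post_init__(self) -> None:
        for name, seq in (("utr_seq", self.utr_seq), ("cds_prefix", self.cds_prefix)):
            if set(seq) - VALID_BASES:
                bad = sorted(set(seq) - VALID_BASES)
                raise TranscriptError(
                    f"{self.transcript_id}: {name} contains non-IUPAC characters {bad}"
                )
        if self.canonical_complete:
            if len(self.cds_prefix) < 3:
                raise TranscriptError(
                    f"{self.transcript_id}: cds_prefix shorter than one codon"
                )
            if self.cds_prefix[:3] != "ATG":
                raise TranscriptError(
                    f"{self.transcript_id}: cds_prefix does not begin with ATG "
                    f"(found {self.cds_prefix[:3]!r})"
                )
        if self.exon_blocks is not None:
            mapped = sum(len(b) for b in self.exon_blocks)
            expect = len(self.utr_seq) + len(self.cds_prefix)
            if mapped != expect:
                raise TranscriptError(
                    f"{self.transcript_id}: exon blocks map {mapped} bases, "
                    f"sequence has {expect}"
                )
        if self.no_utr != (len(self.utr_seq) == 0):
            object.__setattr__(self, "no_utr", len(self.utr_seq) == 0)

    @property
    def utr_length(self) -> int:
        return len(self.utr_seq)

    @property
    def full_seq(self) -> str:
        """Spliced UTR + CDS-prefix sequence, the annotation substrate."""
        return self.utr_seq + self.cds_prefix

    def genomic_to_transcript(self, chrom: str, gpos: int) -> Optional[int]:
        """Map a 0-based genomic position to transcript space (or None)."""
        if self.exon_blocks is None:
            raise TranscriptError(f"{self.transcript_id}: no exon blocks available")
        offset = 0
        for block in self.exon_blocks:
            if block.chrom == chrom and block.start <= gpos < block.end:
                if block.strand == "+":
                    return offset + (gpos - block.start)
                return offset + (block.end - 1 - gpos)
            offset += len(block)
        return None


@dataclass(frozen=True)
class TranscriptVariant:
    """A variant in transcript coordinates.

    ``pos`` is the 0-based index of the first affected base; ``ref`` is empty
    for a pure insertion (inserted before ``pos``) and ``alt`` empty for a
    pure deletion.
    """

    transcript_id: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref and not self.alt:
            raise TranscriptError("variant with empty ref and alt")
        for name, seq in (("ref", self.ref), ("alt", self.alt)):
            if set(seq) - VALID_BASES:
                raise TranscriptError(f"variant {name} has non-IUPAC characters")
        if self.pos < 0:
            raise TranscriptError(f"negative variant position {self.pos}")

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)

    def inverse(self) -> "TranscriptVariant":
        return TranscriptVariant(self.transcript_id, self.pos, self.alt, self.ref)


def validate_variant(t: TranscriptRecord, v: TranscriptVariant) -> None:
    full = t.full_seq
    if not (0 <= v.pos < len(full)) and not (v.pos == len(full) and not v.ref):
        raise TranscriptError(
            f"{t.transcript_id}: variant position {v.pos} outside sequence "
            f"of length {len(full)}"
        )
    found = full[v.pos : v.pos + len(v.ref)]
    if found != v.ref:
        raise TranscriptError(
            f"{t.transcript_id}: ref mismatch at {v.pos}: expected {v.ref!r}, "
            f"found {found!r}"
        )
    L = t.utr_length
    if v.ref and v.pos < L < v.pos + len(v.ref):
        raise TranscriptError(
            f"{t.transcript_id}: variant spans the UTR/CDS junction (unsupported)"
        )


def apply_variant(t: TranscriptRecord, v: TranscriptVariant) -> TranscriptRecord:
    """Return a new record with ``ref`` replaced by ``alt`` at ``v.pos``.

    Indels entirely inside the UTR shift the UTR/CDS boundary; the CDS prefix
    is never resized.  Variants spanning the junction are rejected.
    """
    validate_variant(t, v)
    L = t.utr_length
    full = t.full_seq
    edited = full[: v.pos] + v.alt + full[v.pos + len(v.ref) :]
    # pure insertions at the UTR/CDS boundary belong to the UTR (5' of the
    # canonical ATG), so deletions at the UTR's 3' end invert cleanly
    if v.pos < L or (v.pos == L and not v.ref):
        new_L = L + v.length_change
    else:
        new_L = L
    return replace(
        t,
        utr_seq=edited[:new_L],
        cds_prefix=edited[new_L:],
        exon_blocks=None if v.length_change and t.exon_blocks else t.exon_blocks,
    )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_transcripts(
    path_fasta: str | Path, path_table: str | Path
) -> list[TranscriptRecord]:
    """Load transcripts from a FASTA of spliced sequences plus a TSV table.

    The table must carry columns ``gene_id, transcript_id, utr_length,
    cds_prefix_length``.  Each FASTA record holds UTR followed by CDS prefix.
    Zero-length-UTR transcripts are retained and flagged ``no_utr`` (they feed
    gene class 0).
    """
    seqs = _read_fasta(path_fasta)
    records: list[TranscriptRecord] = []
    with open(path_table, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "transcript_id", "utr_length", "cds_prefix_length"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise TranscriptError(
                f"transcript table missing columns {sorted(required)}"
            )
        for row in reader:
            tid = row["transcript_id"]
            if tid not in seqs:
                raise TranscriptError(f"FASTA record missing for transcript {tid}")
            seq = seqs[tid]
            utr_len = int(row["utr_length"])
            cds_len = int(row["cds_prefix_length"])
            if len(seq) < utr_len + cds_len:
                raise TranscriptError(
                    f"{tid}: sequence shorter than annotation "
                    f"({len(seq)} < {utr_len + cds_len})"
                )
            records.append(
                TranscriptRecord(
                    gene_id=row["gene_id"],
                    transcript_id=tid,
                    utr_seq=seq[:utr_len],
                    cds_prefix=seq[utr_len : utr_len + cds_len],
                )
            )
    return records


def load_transcripts_gff3(
    path_gff3: str | Path, path_genome_fasta: str | Path
) -> list[TranscriptRecord]:
    """Alternate reader: GFF3 ``five_prime_UTR``/``CDS`` features + genome FASTA.

    UTR and CDS blocks are spliced in transcript order; minus-strand input is
    reverse-complemented so ``utr_seq`` is always sense, 5'->3'.  Only the
    first CDS feature contributes the CDS prefix.
    """
    import gffutils

    genome = _read_fasta(path_genome_fasta)
    db = gffutils.create_db(
        str(path_gff3), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    by_tx: dict[str, dict[str, list]] = {}
    gene_of: dict[str, str] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("five_prime_UTR", "CDS"):
            continue
        parents = feat.attributes.get("Parent", [feat.id])
        for parent in parents:
            tid = parent.split(":")[-1]
            by_tx.setdefault(tid, {"five_prime_UTR": [], "CDS": []})
            by_tx[tid][feat.featuretype].append(feat)
            gid = feat.attributes.get("gene_id", [tid])[0]
            gene_of[tid] = gid

    records = []
    for tid, feats in sorted(by_tx.items()):
        utr_feats = feats["five_prime_UTR"]
        cds_feats = feats["CDS"]
        if not cds_feats:
            raise TranscriptError(f"{tid}: no CDS feature in GFF3")
        strand = cds_feats[0].strand
        # transcript order: ascending genomic for +, descending for -
        rev = strand == "-"
        utr_feats.sort(key=lambda f: f.start, reverse=rev)
        cds_feats.sort(key=lambda f: f.start, reverse=rev)

        def _fetch(f) -> str:
            seq = genome[f.seqid][f.start - 1 : f.end]  # GFF3 is 1-based closed
            return reverse_complement(seq.upper()) if rev else seq.upper()

        utr_seq = "".join(_fetch(f) for f in utr_feats)
        first_cds = cds_feats[0]
        cds_prefix = _fetch(first_cds)[:30]
        if len(cds_prefix) < 3:
            raise TranscriptError(f"{tid}: first CDS block shorter than one codon")
        blocks = tuple(
            ExonBlock(f.seqid, f.start - 1, f.end, f.strand) for f in utr_feats
        ) + (
            ExonBlock(
                first_cds.seqid,
                first_cds.start - 1 if not rev else first_cds.end - len(cds_prefix),
                first_cds.start - 1 + len(cds_prefix) if not rev else first_cds.end,
                first_cds.strand,
            ),
        )
        records.append(
            TranscriptRecord(
                gene_id=gene_of.get(tid, tid),
                transcript_id=tid,
                utr_seq=utr_seq,
                cds_prefix=cds_prefix,
                exon_blocks=blocks if not rev else blocks,
            )
        )
    return records


def read_variants_tsv(path: str | Path) -> list[TranscriptVariant]:
    """Read transcript-space variants from TSV (transcript_id, pos, ref, alt).

    '-' or '.' denote an empty allele (pure insertion/deletion).
    """
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            ref = row["ref"].strip()
            alt = row["alt"].strip()
            ref = "" if ref in ("-", ".") else ref.upper()
            alt = "" if alt in ("-", ".") else alt.upper()
            out.append(
                TranscriptVariant(row["transcript_id"], int(row["pos"]), ref, alt)
            )
    return out


def read_variants_vcf(
    path: str | Path, transcripts: Iterable[TranscriptRecord]
) -> list[TranscriptVariant]:
    """Map genomic VCF records onto transcripts carrying exon blocks.

    VCF alleles are left-anchored; the shared anchor base of indels is
    stripped so transcript variants are minimal.  Minus-strand transcripts get
    reverse-complemented alleles.  Records falling outside every transcript's
    mapped blocks are skipped.
    """
    import pysam

    tx_with_blocks = [t for t in transcripts if t.exon_blocks]
    out: list[TranscriptVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                ref, alt_a, gpos = rec.ref.upper(), alt.upper(), rec.pos - 1
                # minimal representation: strip the shared prefix (the classic
                # VCF indel anchor base included)
                while ref and alt_a and ref[0] == alt_a[0]:
                    ref, alt_a, gpos = ref[1:], alt_a[1:], gpos + 1
                if not ref and not alt_a:
                    continue  # monomorphic record
                for t in tx_with_blocks:
                    strand = t.exon_blocks[0].strand
                    tpos = t.genomic_to_transcript(rec.chrom, gpos)
                    if tpos is None:
                        continue
                    if strand == "+":
                        out.append(TranscriptVariant(t.transcript_id, tpos, ref, alt_a))
                    else:
                        r = reverse_complement(ref)
                        a = reverse_complement(alt_a)
                        # on minus strand the mapped position is of the last ref base
                        start = tpos - (len(ref) - 1) if ref else tpos + 1
                        out.append(TranscriptVariant(t.transcript_id, start, r, a))
    return out
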