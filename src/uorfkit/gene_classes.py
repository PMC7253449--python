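"""Gene-level triage of uORF-perturbation sensitivity.

Genes are assigned to nine mutually exclusive classes, evaluated in a fixed
order (0, 1, 2, 3, 4, 5, 8, 7, 6 — known-LoF-disease genes take precedence
over LoF-intolerant ones), then grouped into a low / moderate / high
likelihood that high-impact uORF-perturbing variants are deleterious:

* 0 - no annotated 5'UTR on the canonical transcript
* 1 - no possible uAUG-creating or stop-removing SNVs
* 2 - remaining genes with no possible high-impact SNVs
* 3 - remaining genes with a high-confidence existing oORF
      (strong/moderate Kozak or prior translation evidence)
* 4 - remaining genes with a high-impact SNV at appreciable population
      frequency (allele count above ``ac_threshold``)
* 5 - remaining LoF-tolerant genes (most tolerant LOEUF sextile)
* 8 - remaining curated-haploinsufficient / dominant-LoF / ClinVar-LoF genes
* 7 - remaining LoF-intolerant genes (most intolerant sextile) or genes with
      >= 2 high-confidence pathogenic LoF variants in ClinVar
* 6 - everything else

Grouping: low = {2, 3, 4, 5}, moderate = {6}, high = {7, 8};
classes 0 and 1 are unclassified.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .annotation import ConsequenceRecord, UORF
from .transcripts import TranscriptRecord

LIKELIHOOD_OF_CLASS = {
    0: "unclassified",
    1: "unclassified",
    2: "low",
    3: "low",
    4: "low",
    5: "low",
    6: "moderate",
    7: "high",
    8: "high",
}

CLASS_ORDER = (0, 1, 2, 3, 4, 5, 8, 7, 6)


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    has_utr: bool
    n_possible_perturbing: int
    n_possible_high_impact: int
    has_high_confidence_oorf: bool
    max_high_impact_ac: int
    loeuf_sextile: Optional[int]  # 1 = most LoF intolerant, 6 = most tolerant
    curated_hi: bool
    ddg2p_lof: bool
    clinvar_lof_count: int


@dataclass(frozen=True)
class GeneClassification:
    gene_id: str
    gene_class: int
    likelihood: str


def classify_gene(a: GeneAnnotation, ac_threshold: int = 15) -> GeneClassification:
    """First matching rule in the fixed evaluation order wins.

    ``ac_threshold`` encodes "appreciable frequency"; the default 15 is
    AF > 0.1% at a 15,708-genome cohort and should be rescaled for other
    cohort sizes.
    """
    if a.loeuf_sextile is None:
        warnings.warn(f"{a.gene_id}: missing LOEUF sextile treated as mid-range",
                      stacklevel=2)
    sextile = a.loeuf_sextile

    if not a.has_utr:
        cls = 0
    elif a.n_possible_perturbing == 0:
        cls = 1
    elif a.n_possible_high_impact == 0:
        cls = 2
    elif a.has_high_confidence_oorf:
        cls = 3
    elif a.max_high_impact_ac > ac_threshold:
        cls = 4
    elif sextile == 6:
        cls = 5
    elif a.curated_hi or a.ddg2p_lof or a.clinvar_lof_count >= 10:
        cls = 8
    elif sextile == 1 or a.clinvar_lof_count >= 2:
        cls = 7
    else:
        cls = 6
    return GeneClassification(a.gene_id, cls, LIKELIHOOD_OF_CLASS[cls])


def likelihood_summary(
    classifications: Iterable[GeneClassification],
) -> dict[str, int]:
    """Gene counts per likelihood group (always reporting all four groups)."""
    counts = Counter(c.likelihood for c in classifications)
    return {
        group: counts.get(group, 0)
        for group in ("unclassified", "low", "moderate", "high")
    }


def class_summary(classifications: Iterable[GeneClassification]) -> dict[int, int]:
    counts = Counter(c.gene_class for c in classifications)
    return {cls: counts.get(cls, 0) for cls in range(9)}


def build_gene_annotations(
    transcripts: Sequence[TranscriptRecord],
    records: Sequence[ConsequenceRecord],
    uorfs: Sequence[UORF],
    metadata: Optional[Mapping[str, Mapping]] = None,
    population_ac: Optional[Mapping[tuple, int]] = None,
) -> list[GeneAnnotation]:
    """Assemble per-gene annotations from enumerated variants and metadata.

    ``metadata`` maps gene_id -> dict with loeuf_sextile, curated_hi,
    ddg2p_lof, clinvar_lof_count (missing genes default to False/0 with a
    warning).  ``population_ac`` maps a variant record key
    (transcript_id, pos, ref, alt) to its cohort allele count.
    """
    metadata = metadata or {}
    population_ac = population_ac or {}
    gene_of_tx = {t.transcript_id: t.gene_id for t in transcripts}

    per_gene: dict[str, dict] = {
        t.gene_id: {
            "has_utr": t.utr_length > 0,
            "n_perturbing": 0,
            "n_high_impact": 0,
            "hc_oorf": False,
            "max_ac": 0,
        }
        for t in transcripts
    }
    for r in records:
        g = per_gene[gene_of_tx[r.transcript_id]]
        if not r.variant.ref or not r.variant.alt:
            continue  # gene triage counts SNVs only
        g["n_perturbing"] += 1
        if r.high_impact:
            g["n_high_impact"] += 1
            v = r.variant
            ac = population_ac.get((r.transcript_id, v.pos, v.ref, v.alt), 0)
            g["max_ac"] = max(g["max_ac"], ac)
    for u in uorfs:
        if u.is_oorf and (u.kozak.moderate_or_strong or u.has_translation_evidence):
            per_gene[gene_of_tx[u.transcript_id]]["hc_oorf"] = True

    missing_meta = [g for g in per_gene if g not in metadata]
    if metadata and missing_meta:
        warnings.warn(
            f"{len(missing_meta)} genes lack metadata; defaulting to False/0",
            stacklevel=2,
        )
    out = []
    for gene_id, g in per_gene.items():
        meta = metadata.get(gene_id, {})
        out.append(
            GeneAnnotation(
                gene_id=gene_id,
                has_utr=g["has_utr"],
                n_possible_perturbing=g["n_perturbing"],
                n_possible_high_impact=g["n_high_impact"],
                has_high_confidence_oorf=g["hc_oorf"],
                max_high_impact_ac=g["max_ac"],
                loeuf_sextile=meta.get("loeuf_sextile"),
                curated_hi=bool(meta.get("curated_hi", False)),
                ddg2p_lof=bool(meta.get("ddg2p_lof", False)),
                clinvar_lof_count=int(meta.get("clinvar_lof_count", 0)),
            )
        )
    return out
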