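"""Base-level conservation comparisons and disease-variant enrichment tests.

Conserved bases are defined by a phyloP-style score threshold (default
score >= 2).  uORF stop sites are compared against control UTR bases matched
on gene and distance from the CDS (the three bases flanking the stop on each
side).  Group comparisons use Fisher's exact test on conserved/total counts,
a Wilcoxon rank-sum test on the full score distributions, and a one-sided
binomial test for enrichment of disease variants in annotation categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .annotation import (
    CSQ_CDS_ELONGATION,
    CSQ_OORF_OUT_OF_FRAME,
    ConsequenceRecord,
    UORF,
)
from .transcripts import TranscriptRecord

ROLES = ("uorf_stop", "uaug_site", "utr_other", "coding", "matched_control")


@dataclass(frozen=True)
class ScoredBase:
    transcript_id: str
    pos: int
    score: float
    role: str


@dataclass(frozen=True)
class ProportionResult:
    n_conserved: int
    n_total: int
    proportion: float
    ci95: tuple[float, float]


def conserved_proportion(
    bases: Sequence[ScoredBase] | Iterable[float],
    threshold: float = 2.0,
    strict: bool = False,
    ci_method: str = "beta",
) -> ProportionResult:
    """Fraction of bases with score >= threshold (or > with ``strict``),
    with a Clopper-Pearson-style binomial interval (``ci_method`` passes
    through to statsmodels ``proportion_confint``)."""
    scores = np.asarray(
        [b.score if isinstance(b, ScoredBase) else float(b) for b in bases], float
    )
    if scores.size == 0:
        raise ValueError("conserved_proportion requires a non-empty input")
    hits = int((scores > threshold).sum() if strict else (scores >= threshold).sum())
    low, high = proportion_confint(hits, scores.size, alpha=0.05, method=ci_method)
    return ProportionResult(hits, int(scores.size), hits / scores.size, (float(low), float(high)))


def matched_stop_controls(
    uorfs: Sequence[UORF], transcripts: Sequence[TranscriptRecord]
) -> list[tuple[str, int]]:
    """Control base positions matched to uORF stops: the 3 bases immediately
    upstream and downstream of each stop codon, clipped at UTR bounds and
    deduplicated per (transcript, position).  Bases belonging to any uORF
    stop codon are never included (controls must not overlap the test
    group)."""
    utr_len = {t.transcript_id: t.utr_length for t in transcripts}
    stop_bases = set(stop_site_positions(uorfs))
    seen: set[tuple[str, int]] = set()
    out: list[tuple[str, int]] = []
    for u in uorfs:
        if u.stop_start is None:
            continue
        L = utr_len[u.transcript_id]
        flanks = list(range(u.stop_start - 3, u.stop_start)) + list(
            range(u.stop_start + 3, u.stop_start + 6)
        )
        for pos in flanks:
            key = (u.transcript_id, pos)
            if 0 <= pos < L and key not in seen and key not in stop_bases:
                seen.add(key)
                out.append(key)
    return out


def stop_site_positions(uorfs: Sequence[UORF]) -> list[tuple[str, int]]:
    """The three bases of every distinct uORF stop codon."""
    seen: set[tuple[str, int]] = set()
    out = []
    for u in uorfs:
        if u.stop_start is None:
            continue
        for pos in range(u.stop_start, u.stop_start + 3):
            key = (u.transcript_id, pos)
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int


def fisher_2x2(a_hits: int, a_total: int, b_hits: int, b_total: int) -> TestResult:
    """Two-sided Fisher's exact test on conserved/total counts of two groups.

    The odds ratio uses a Haldane correction (add 0.5 to each cell) when any
    cell is zero, so it stays finite.
    """
    if a_total <= 0 or b_total <= 0:
        raise ValueError("fisher_2x2 requires positive totals")
    if not (0 <= a_hits <= a_total and 0 <= b_hits <= b_total):
        raise ValueError("hits must lie in [0, total]")
    table = np.array(
        [[a_hits, a_total - a_hits], [b_hits, b_total - b_hits]], dtype=float
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        table = table + 0.5
    odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    return TestResult("fisher_2x2", float(odds), float(p), a_total, b_total)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 25
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) with tie correction.

    The exact null distribution is used when both samples are small and
    tie-free; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum requires non-empty samples")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and max(x.size, y.size) <= exact_max_n) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("wilcoxon_rank_sum", float(res.statistic), float(res.pvalue),
                      int(x.size), int(y.size))


PREDICATES: dict[str, Callable[[ConsequenceRecord], bool]] = {
    "kozak_moderate_or_strong": lambda r: r.kozak.moderate_or_strong,
    "oorf_out_of_frame": lambda r: r.consequence == CSQ_OORF_OUT_OF_FRAME,
    "oorf_or_elongation": lambda r: r.consequence
    in (CSQ_OORF_OUT_OF_FRAME, CSQ_CDS_ELONGATION),
    "within_50bp": lambda r: r.within_50bp,
    "high_impact": lambda r: r.high_impact,
}


@dataclass(frozen=True)
class EnrichmentResult:
    predicate: str
    disease_proportion: float
    background_proportion: float
    k: int
    n: int
    p_value: float


def binomial_enrichment(
    disease: Sequence[ConsequenceRecord],
    background: Sequence[ConsequenceRecord],
    predicate: str,
) -> EnrichmentResult:
    """One-sided binomial enrichment of a property among disease variants.

    The background proportion pi is the fraction of all possible variants
    satisfying the predicate; p = P(X >= k | n, pi) for k of n disease
    variants satisfying it.
    """
    if predicate not in PREDICATES:
        raise ValueError(
            f"unknown predicate {predicate!r}; choose from {sorted(PREDICATES)}"
        )
    if len(background) == 0:
        raise ValueError("binomial_enrichment requires a non-empty background")
    fn = PREDICATES[predicate]
    pi = sum(fn(r) for r in background) / len(background)
    n = len(disease)
    k = sum(fn(r) for r in disease)
    p = float(stats.binomtest(k, n, pi, alternative="greater").pvalue) if n else 1.0
    return EnrichmentResult(predicate, k / n if n else float("nan"), pi, k, n, p)
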