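"""Independent brute-force oracles used to validate the enumerators and the
statistical tests.  Deliberately naive: every candidate variant is applied to
the sequence and the result re-scanned from scratch; exact test p-values are
computed by direct combinatorial summation."""

from __future__ import annotations

import math
from itertools import combinations

STOPS = {"TAA", "TGA", "TAG"}
BASES = "ACGT"


def _atg_positions(utr: str) -> list[int]:
    return [i for i in range(len(utr) - 2) if utr[i : i + 3] == "ATG"]


def _first_stop(utr: str, start: int):
    for j in range(start + 3, len(utr) - 2, 3):
        if utr[j : j + 3] in STOPS:
            return j
    return None


def _kozak(full: str, aug: int) -> str:
    m3 = full[aug - 3] if aug >= 3 else None
    p3 = full[aug + 3]
    a = m3 in ("A", "G")
    b = p3 == "G"
    return "strong" if a and b else "moderate" if a or b else "weak"


def _consequence(utr: str, start: int, created: bool):
    L = len(utr)
    stop = _first_stop(utr, start)
    if stop is not None:
        return "uORF_created" if created else "uORF_elongated"
    return "CDS_elongation" if (L - start) % 3 == 0 else "oORF_out_of_frame"


def oracle_uaug_snvs(utr: str, cds_prefix: str) -> set[tuple]:
    """Apply every possible UTR SNV, rescan, and report each newly created
    upstream ATG with its full annotation."""
    L = len(utr)
    out = set()
    for pos in range(L):
        ref = utr[pos]
        if ref == "N":
            continue
        for alt in BASES:
            if alt == ref:
                continue
            post = utr[:pos] + alt + utr[pos + 1 :]
            for q in _atg_positions(post):
                if utr[q : q + 3] == "ATG" or "N" in utr[q : q + 3]:
                    continue
                full = post + cds_prefix
                out.add(
                    (
                        pos, ref, alt, q, L - q, (L - q) % 3,
                        _consequence(post, q, created=True), _kozak(full, q),
                    )
                )
    return out


def oracle_stop_removing_snvs(utr: str, cds_prefix: str) -> set[tuple]:
    """For every distinct uORF stop codon, try all 9 SNVs inside it and keep
    those whose resulting codon is no longer a stop."""
    L = len(utr)
    # distinct first-stops and their converging starts
    starts_of_stop: dict[int, list[int]] = {}
    for s in _atg_positions(utr):
        stop = _first_stop(utr, s)
        if stop is not None:
            starts_of_stop.setdefault(stop, []).append(s)
    full = utr + cds_prefix
    rank = {"weak": 0, "moderate": 1, "strong": 2}
    out = set()
    for stop, starts in starts_of_stop.items():
        rep = min(starts, key=lambda s: (-rank[_kozak(full, s)], s))
        kozak = max((_kozak(full, s) for s in starts), key=lambda k: rank[k])
        rescue = any(
            utr[j : j + 3] in STOPS for j in range(stop + 3, L - 2, 3)
            if (j - rep) % 3 == 0
        )
        codon = utr[stop : stop + 3]
        for k in range(3):
            for alt in BASES:
                if alt == codon[k]:
                    continue
                if codon[:k] + alt + codon[k + 1 :] in STOPS:
                    continue
                if rescue:
                    csq = "uORF_elongated"
                elif (L - rep) % 3 == 0:
                    csq = "CDS_elongation"
                else:
                    csq = "oORF_out_of_frame"
                out.add(
                    (stop + k, codon[k], alt, rep, L - rep, (L - rep) % 3, csq, kozak)
                )
    return out


def oracle_uaug_deletions(utr: str, max_len: int = 5) -> set[tuple]:
    """All 1..max_len bp deletions creating a genuinely new upstream ATG,
    by alignment-aware diff of the ATG sets."""
    pre = set(_atg_positions(utr))
    L = len(utr)
    out = set()
    for k in range(1, max_len + 1):
        for p in range(0, L - k + 1):
            post = utr[:p] + utr[p + k :]
            for q in _atg_positions(post):
                if q + 3 <= p:
                    new = q not in pre
                elif q >= p:
                    new = (q + k) not in pre
                else:
                    new = True  # window spans the deletion junction
                if new:
                    out.add((p, utr[p : p + k], q))
    return out


# ---------------------------------------------------------------------------
# Exact statistical-test oracles (n small)
# ---------------------------------------------------------------------------

def oracle_fisher_two_sided(a_hits: int, a_total: int, b_hits: int, b_total: int) -> float:
    """Two-sided Fisher p by summing hypergeometric point probabilities not
    exceeding that of the observed table."""
    n = a_total + b_total
    K = a_hits + b_hits  # total hits

    def pmf(x: int) -> float:
        if x < 0 or x > a_total or K - x < 0 or K - x > b_total:
            return 0.0
        return (
            math.comb(a_total, x) * math.comb(b_total, K - x) / math.comb(n, K)
        )

    p_obs = pmf(a_hits)
    return sum(pmf(x) for x in range(K + 1) if pmf(x) <= p_obs * (1 + 1e-9))


def oracle_mwu_exact_two_sided(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all assignments of the
    pooled sample (tie-free inputs only)."""
    pooled = list(x) + list(y)
    n_x = len(x)
    idx = range(len(pooled))

    def u_stat(x_idx) -> int:
        xs = [pooled[i] for i in x_idx]
        ys = [pooled[i] for i in idx if i not in set(x_idx)]
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(tuple(range(n_x)))
    us = [u_stat(c) for c in combinations(idx, n_x)]
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / total
    p_ge = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2 * min(p_le, p_ge))


def oracle_binomial_tail(k: int, n: int, pi: float) -> float:
    """P(X >= k | n, pi) by direct summation."""
    return sum(
        math.comb(n, x) * pi**x * (1 - pi) ** (n - x) for x in range(k, n + 1)
    )
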