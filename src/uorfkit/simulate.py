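"""Synthetic inputs for the whole pipeline.

Emulates, at desk scale, the data the analysis consumes in the wild:
canonical-transcript 5'UTR sequences with controlled uORF content, a
population variant corpus generated under a context-dependent mutation model
with tunable selection, phyloP-like conservation scores, translation-evidence
lists, and gene metadata tables.

Selection is modelled phenomenologically as an inflation ``delta`` of the
singleton proportion of a variant class — exactly the quantity MAPS measures —
rather than through an explicit population-genetic model.  The baseline
singleton probability decreases with mutability (the confounder MAPS exists
to remove); its default functional form is linear in the mutation rate, which
makes the linear singleton calibration exact and turns parameter recovery
into an exact check (a logit-linear form is available via
``singleton_model="logit"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import STOP_CODONS, UORF, find_uorfs
from .conservation import ScoredBase
from .maps import MEAN_MUTATION_RATE, CalibrationModel, MutabilityTable, _class_key
from .transcripts import TranscriptRecord

BASES = "ACGT"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedUorfSpec:
    """What upstream structure to plant per gene.

    ``uorf_probability`` / ``oorf_probability``: chance a gene gets a planted
    uORF (ATG + in-frame UTR stop) or an existing oORF (ATG with the UTR tail
    scrubbed of in-frame stops).  ``kozak`` forces the planted start's
    context ("strong"/"moderate"/"weak") or samples uniformly when None.
    ``evidence_probability``: fraction of planted uORF stops that appear in
    the translation-evidence list.
    """

    uorf_probability: float = 0.6
    oorf_probability: float = 0.1
    kozak: Optional[str] = None
    evidence_probability: float = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genes: int = 200
    utr_length_meanlog: float = 5.0  # exp(5) ~ 148 nt, a typical human 5'UTR
    utr_length_sdlog: float = 0.55
    min_utr_length: int = 12
    max_utr_length: int = 1500
    zero_utr_fraction: float = 0.05
    gc_content: float = 0.6  # human 5'UTRs are GC-rich
    cds_prefix_length: int = 12
    planted: PlantedUorfSpec = field(default_factory=PlantedUorfSpec)

    cohort_alleles: int = 2 * 15_708
    # mean fraction of possible sites observed in the cohort
    mean_observation_rate: float = 0.027
    # baseline singleton proportion and its decrease with mutability
    singleton_intercept: float = 0.58
    singleton_slope: float = 2.0e6  # per unit mutation rate
    singleton_model: str = "linear"  # or "logit"
    # per-class singleton-proportion inflation (the selection signal)
    singleton_inflation: dict = field(
        default_factory=lambda: {
            "neutral": 0.0,
            "weak_selection": 0.05,
            "moderate_selection": 0.1,
            "strong_selection": 0.2,
        }
    )
    rate_jitter_sdlog: float = 0.2
    x_chrom_fraction: float = 0.04
    fail_filter_fraction: float = 0.02

    conservation_effect: float = 0.6  # score shift at planted functional bases
    conservation_background_sd: float = 1.6


# ---------------------------------------------------------------------------
# Mutation model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationModel:
    """Ground-truth per-class mutation rates and possible-site weights."""

    classes: pd.DataFrame  # context, alt, methylation_bin, mu, weight

    @property
    def keys(self) -> pd.Series:
        return _class_key(self.classes)

    def observation_probs(self, cfg: SimulationConfig) -> np.ndarray:
        """P(site observed in cohort), increasing in mu, scaled so the
        weight-averaged probability equals ``mean_observation_rate``."""
        mu = self.classes["mu"].to_numpy()
        w = self.classes["weight"].to_numpy()
        raw = mu / MEAN_MUTATION_RATE
        scale = cfg.mean_observation_rate / float((raw * w).sum() / w.sum())
        return np.clip(raw * scale, 0.0, 0.95)

    def singleton_probs(self, cfg: SimulationConfig, delta: float) -> np.ndarray:
        """P(singleton | observed) per class: baseline decreasing in mu,
        plus the class's selection inflation ``delta``."""
        mu = self.classes["mu"].to_numpy()
        if cfg.singleton_model == "linear":
            p0 = cfg.singleton_intercept - cfg.singleton_slope * mu
        elif cfg.singleton_model == "logit":
            eta = math.log(cfg.singleton_intercept / (1 - cfg.singleton_intercept))
            p0 = 1.0 / (1.0 + np.exp(-(eta - 4.0 * cfg.singleton_slope * mu)))
        else:
            raise SimulationError(f"unknown singleton_model {cfg.singleton_model!r}")
        return np.clip(p0 + delta, 0.0, 1.0)


def default_mutation_model(cfg: SimulationConfig) -> MutationModel:
    """Trinucleotide mutation model: transitions faster than transversions,
    C>T at CpG sites much faster still and split into three methylation bins,
    with a seeded lognormal jitter so every class has a distinct rate."""
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA11E1E]))
    rows = []
    for left in BASES:
        for mid in BASES:
            for right in BASES:
                ctx = left + mid + right
                for alt in BASES:
                    if alt == mid:
                        continue
                    is_cpg_ct = mid == "C" and right == "G" and alt == "T"
                    if is_cpg_ct:
                        for b, mu, wfrac in ((0, 2e-8, 0.2), (1, 6e-8, 0.3),
                                             (2, 12e-8, 0.5)):
                            rows.append((ctx, alt, b, mu, 0.25 * wfrac))
                    else:
                        base = 1.5e-8 if (mid, alt) in transitions else 0.4e-8
                        weight = 0.25 if (mid == "C" and right == "G") else 1.0
                        rows.append((ctx, alt, 0, base, weight))
    df = pd.DataFrame(rows, columns=["context", "alt", "methylation_bin", "mu", "weight"])
    df["mu"] = df["mu"] * rng.lognormal(0.0, cfg.rate_jitter_sdlog, len(df))
    return MutationModel(classes=df)


# ---------------------------------------------------------------------------
# Transcripts
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(list("ACGT"), size=n, p=p)


def _plant_uorf(
    seq: np.ndarray, L: int, rng: np.random.Generator, kozak: str
) -> tuple[int, int]:
    """Write an ATG + in-frame stop into the UTR; returns (start, stop_start)."""
    if L < 12:
        raise SimulationError(f"UTR of length {L} too short to plant a uORF")
    start = int(rng.integers(3, L - 8))
    max_codons = (L - 3 - start) // 3 - 1
    n_codons = int(rng.integers(2, max(3, min(11, max_codons + 1))))
    stop_start = start + 3 * n_codons
    if stop_start + 3 > L:
        stop_start = start + 6
    seq[start : start + 3] = list("ATG")
    seq[stop_start : stop_start + 3] = list(
        ["TAA", "TGA", "TAG"][int(rng.integers(3))]
    )
    _set_kozak(seq, L, start, kozak, rng)
    return start, stop_start


def _plant_oorf(seq: np.ndarray, L: int, rng: np.random.Generator, kozak: str) -> int:
    """Write an ATG whose frame has no in-frame stop left in the UTR."""
    if L < 9:
        raise SimulationError(f"UTR of length {L} too short to plant an oORF")
    start = int(rng.integers(3, L - 5))
    seq[start : start + 3] = list("ATG")
    _set_kozak(seq, L, start, kozak, rng)
    for j in range(start + 3, L - 2, 3):
        if "".join(seq[j : j + 3]) in STOP_CODONS:
            seq[j] = "C"  # scrub in-frame UTR stops so the ORF runs into the CDS
    return start


def _set_kozak(
    seq: np.ndarray, L: int, start: int, kozak: str, rng: np.random.Generator
) -> None:
    # only touch +3 when it stays inside the UTR; the CDS prefix starts ATG
    # so a uAUG ending at the UTR/CDS boundary sees +3 == 'A' (non-matching).
    def set_plus(base: str) -> None:
        if start + 3 < L:
            seq[start + 3] = base

    if kozak == "strong":
        seq[start - 3] = "AG"[int(rng.integers(2))]
        set_plus("G")
    elif kozak == "moderate":
        if rng.random() < 0.5:
            seq[start - 3] = "AG"[int(rng.integers(2))]
            set_plus("CT"[int(rng.integers(2))])
        else:
            seq[start - 3] = "CT"[int(rng.integers(2))]
            set_plus("G")
    else:
        seq[start - 3] = "CT"[int(rng.integers(2))]
        set_plus("ACT"[int(rng.integers(3))])


def generate_transcripts(
    cfg: SimulationConfig,
) -> tuple[list[TranscriptRecord], set[tuple[str, int]]]:
    """Random transcripts with planted upstream structure plus the
    translation-evidence list (transcript_id, stop coordinate).

    Planted structure is self-verified: every requested uORF/oORF must be
    re-detected by :func:`uorfkit.annotation.find_uorfs`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7137]))
    spec = cfg.planted
    records: list[TranscriptRecord] = []
    evidence: set[tuple[str, int]] = set()
    for i in range(cfg.n_genes):
        gene_id, tx_id = f"G{i:05d}", f"T{i:05d}"
        if rng.random() < cfg.zero_utr_fraction:
            L = 0
        else:
            L = int(
                np.clip(
                    round(rng.lognormal(cfg.utr_length_meanlog, cfg.utr_length_sdlog)),
                    cfg.min_utr_length,
                    cfg.max_utr_length,
                )
            )
        seq = _random_seq(rng, L, cfg.gc_content)
        cds = np.concatenate(
            [list("ATG"), _random_seq(rng, cfg.cds_prefix_length - 3, cfg.gc_content)]
        )
        planted_stop: Optional[int] = None
        if L >= 12:
            kozak = spec.kozak or ("strong", "moderate", "weak")[int(rng.integers(3))]
            u = rng.random()
            if u < spec.uorf_probability:
                for _ in range(10):
                    trial = seq.copy()
                    start, stop = _plant_uorf(trial, L, rng, kozak)
                    rec = TranscriptRecord(gene_id, tx_id, "".join(trial), "".join(cds))
                    found = [
                        x for x in find_uorfs(rec)
                        if x.start == start and x.stop_start is not None
                    ]
                    if found and found[0].start_kozak.value == kozak:
                        seq, planted_stop = trial, found[0].stop_start
                        break
                else:
                    raise SimulationError(f"{tx_id}: failed to plant uORF")
            elif u < spec.uorf_probability + spec.oorf_probability:
                for _ in range(10):
                    trial = seq.copy()
                    start = _plant_oorf(trial, L, rng, kozak)
                    rec = TranscriptRecord(gene_id, tx_id, "".join(trial), "".join(cds))
                    found = [x for x in find_uorfs(rec) if x.start == start and x.is_oorf]
                    if found and found[0].start_kozak.value == kozak:
                        seq = trial
                        break
                else:
                    raise SimulationError(f"{tx_id}: failed to plant oORF")
        rec = TranscriptRecord(gene_id, tx_id, "".join(seq), "".join(cds))
        if planted_stop is not None and rng.random() < spec.evidence_probability:
            evidence.add((tx_id, planted_stop))
        records.append(rec)
    return records, evidence


def write_transcripts(
    records: Sequence[TranscriptRecord], fasta_path, table_path
) -> None:
    """Write the FASTA + TSV pair the standard reader consumes."""
    with open(fasta_path, "w") as fa:
        for t in records:
            fa.write(f">{t.transcript_id}\n{t.full_seq}\n")
    with open(table_path, "w") as tb:
        tb.write("gene_id\ttranscript_id\tutr_length\tcds_prefix_length\n")
        for t in records:
            tb.write(
                f"{t.gene_id}\t{t.transcript_id}\t{t.utr_length}\t{len(t.cds_prefix)}\n"
            )


# ---------------------------------------------------------------------------
# Population variant corpus
# ---------------------------------------------------------------------------

def simulate_population(
    cfg: SimulationConfig,
    model: Optional[MutationModel] = None,
    n_observed: Optional[dict[str, int]] = None,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, MutationModel]:
    """Simulate a population variant corpus plus possible-site counts.

    Emits one labelled class per entry of ``n_observed`` (defaults: a
    100k-variant neutral intergenic/intronic corpus for table building, a
    50k synonymous calibration class, and one 50k UTR class per entry of
    ``cfg.singleton_inflation``).  Returns (observations, possible-site
    counts for the neutral corpus, the ground-truth mutation model).
    """
    model = model or default_mutation_model(cfg)
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 0x909])
    )
    if n_observed is None:
        n_observed = {"intergenic_intronic": 100_000, "synonymous": 50_000}
        n_observed.update({name: 50_000 for name in cfg.singleton_inflation})

    p_obs = model.observation_probs(cfg)
    w = model.classes["weight"].to_numpy()
    w = w / w.sum()
    mean_p_obs = float((p_obs * w).sum())
    keys = model.keys.to_numpy()

    frames = []
    neutral_possible = None
    for region, n_target in n_observed.items():
        delta = cfg.singleton_inflation.get(region, 0.0)
        p_sing = model.singleton_probs(cfg, delta)
        # oversize slightly so post-filter counts stay near the target
        m_total = int(round(n_target / mean_p_obs * 1.12))
        m_per_class = rng.multinomial(m_total, w)
        n_obs = rng.binomial(m_per_class, p_obs)
        n_sing = rng.binomial(n_obs, p_sing)
        if region == "intergenic_intronic":
            neutral_possible = model.classes.assign(n_possible=m_per_class)[
                ["context", "alt", "methylation_bin", "n_possible"]
            ]
        total = int(n_obs.sum())
        if total == 0:
            continue
        ctx = np.repeat(model.classes["context"].to_numpy(), n_obs)
        alt = np.repeat(model.classes["alt"].to_numpy(), n_obs)
        mbin = np.repeat(model.classes["methylation_bin"].to_numpy(), n_obs)
        singleton = np.zeros(total, dtype=bool)
        offset = 0
        for cnt, s in zip(n_obs, n_sing):
            singleton[offset : offset + s] = True
            offset += cnt
        ac = np.where(
            singleton, 1, 2 + rng.geometric(0.3, size=total)
        ).astype(int)
        coverage = rng.normal(30.0, 7.0, size=total).clip(1.0, 80.0)
        low_mask = rng.random(total) < 0.03
        coverage[low_mask] = rng.uniform(5.0, 15.0, size=int(low_mask.sum()))
        gerp = rng.normal(0.0, 1.5, size=total)
        chrom = rng.integers(1, 23, size=total).astype(str)
        x_mask = rng.random(total) < cfg.x_chrom_fraction
        chrom[x_mask] = "X"
        frames.append(
            pd.DataFrame(
                {
                    "variant_id": [f"{region}:{i}" for i in range(total)],
                    "context": ctx,
                    "alt": alt,
                    "methylation_bin": mbin,
                    "allele_count": ac,
                    "coverage": coverage,
                    "gerp": gerp,
                    "region": region,
                    "chrom": chrom,
                    "pass_filters": rng.random(total) > cfg.fail_filter_fraction,
                }
            )
        )
    obs = pd.concat(frames, ignore_index=True)
    if neutral_possible is None:
        neutral_possible = model.classes.assign(
            n_possible=rng.multinomial(int(1e5), w)
        )[["context", "alt", "methylation_bin", "n_possible"]]
    return obs, neutral_possible, model


def expected_maps(
    cfg: SimulationConfig,
    model: MutationModel,
    delta: float,
    calibration: CalibrationModel,
    table: MutabilityTable,
) -> float:
    """Analytic expectation of MAPS for a class with inflation ``delta``
    under the generator's ground truth, given a fitted calibration — the
    oracle value a well-calibrated bootstrap interval should cover."""
    p_obs = model.observation_probs(cfg)
    w = model.classes["weight"].to_numpy()
    w_obs = w * p_obs
    w_obs = w_obs / w_obs.sum()
    p_sing = model.singleton_probs(cfg, delta)
    rates = table.rates.reindex(model.keys.to_numpy()).to_numpy()
    p_hat = calibration.predict(rates)
    return float((w_obs * (p_sing - p_hat)).sum())


# ---------------------------------------------------------------------------
# Conservation scores and gene metadata
# ---------------------------------------------------------------------------

def simulate_scores(
    cfg: SimulationConfig,
    transcripts: Sequence[TranscriptRecord],
    functional_sites: Iterable[tuple[str, int]],
    role: str = "uorf_stop",
    seed: Optional[int] = None,
) -> list[ScoredBase]:
    """phyloP-like scores for every UTR base: Gaussian background with the
    functional sites shifted up by ``cfg.conservation_effect``."""
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 0x5C0])
    )
    functional = set(functional_sites)
    out = []
    for t in transcripts:
        scores = rng.normal(0.0, cfg.conservation_background_sd, size=t.utr_length)
        for pos in range(t.utr_length):
            key = (t.transcript_id, pos)
            is_fn = key in functional
            out.append(
                ScoredBase(
                    transcript_id=t.transcript_id,
                    pos=pos,
                    score=float(scores[pos] + (cfg.conservation_effect if is_fn else 0.0)),
                    role=role if is_fn else "utr_other",
                )
            )
    return out


def generate_gene_table(
    cfg: SimulationConfig,
    transcripts: Sequence[TranscriptRecord],
    records,
    uorfs,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Gene metadata table: LOEUF sextiles by quantile of a latent constraint
    score, sampled curation flags, and cohort allele counts for high-impact
    variants (annotation-derived fields are computed, not sampled)."""
    from .gene_classes import build_gene_annotations

    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 0x6E6E])
    )
    genes = [t.gene_id for t in transcripts]
    n = len(genes)
    order = rng.permutation(n)
    sextile = np.empty(n, dtype=int)
    for s, chunk in enumerate(np.array_split(order, 6)):
        sextile[chunk] = s + 1

    curated = rng.random(n) < 0.04
    ddg2p = rng.random(n) < 0.03
    clinvar = np.where(rng.random(n) < 0.15, rng.poisson(6, size=n), 0)

    population_ac: dict[tuple, int] = {}
    for r in records:
        if not r.high_impact or not r.variant.ref or not r.variant.alt:
            continue
        if rng.random() < cfg.mean_observation_rate:
            ac = 1 if rng.random() < 0.5 else 2 + int(rng.geometric(0.3))
            if rng.random() < 0.05:
                ac = int(rng.integers(16, 120))
            v = r.variant
            population_ac[(r.transcript_id, v.pos, v.ref, v.alt)] = ac

    metadata = {
        g: {
            "loeuf_sextile": int(sextile[i]),
            "curated_hi": bool(curated[i]),
            "ddg2p_lof": bool(ddg2p[i]),
            "clinvar_lof_count": int(clinvar[i]),
        }
        for i, g in enumerate(genes)
    }
    annotations = build_gene_annotations(
        transcripts, records, uorfs, metadata=metadata, population_ac=population_ac
    )
    return pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in annotations],
            "has_utr": [a.has_utr for a in annotations],
            "n_possible_perturbing": [a.n_possible_perturbing for a in annotations],
            "n_possible_high_impact": [a.n_possible_high_impact for a in annotations],
            "has_high_confidence_oorf": [a.has_high_confidence_oorf for a in annotations],
            "max_high_impact_ac": [a.max_high_impact_ac for a in annotations],
            "loeuf_sextile": [a.loeuf_sextile for a in annotations],
            "curated_hi": [a.curated_hi for a in annotations],
            "ddg2p_lof": [a.ddg2p_lof for a in annotations],
            "clinvar_lof_count": [a.clinvar_lof_count for a in annotations],
        }
    )
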