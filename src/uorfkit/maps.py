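"""Mutability-adjusted proportion of singletons (MAPS).

MAPS measures negative selection on a variant class from the site frequency
spectrum: classes under selection carry an excess of singletons (allele count
1) over what their sequence-context mutability predicts.  The pipeline is:

1. build a context-dependent mutability table from a neutral variant corpus
   (proportion of possible sites observed, per trinucleotide substitution
   class, with C>T at CpG split into three methylation bins), scaled so the
   possible-site-weighted mean is the per-base per-generation mutation rate
   (1.2e-8);
2. calibrate a linear map from mutability to expected singleton proportion on
   synonymous variants (a near-neutral class distinct from the corpus used to
   build the table);
3. for any variant class, MAPS = (observed singletons - expected singletons)
   / total observed variants, with bootstrap percentile intervals and
   bootstrap-permutation p-values for class contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

MEAN_MUTATION_RATE = 1.2e-8  # human per-base, per-generation

OBS_COLUMNS = [
    "variant_id", "context", "alt", "methylation_bin", "allele_count",
    "coverage", "gerp", "region", "chrom",
]

AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}

GERP_LOW, GERP_HIGH = -3.9885, 2.6607
COVERAGE_LOW, COVERAGE_HIGH = 15.0, 60.0


class MapsError(ValueError):
    pass


def _class_key(df: pd.DataFrame) -> pd.Series:
    """Substitution-class key: trinucleotide context, alt of the middle base,
    and methylation bin (0 for non-CpG)."""
    return (
        df["context"].astype(str)
        + ">"
        + df["alt"].astype(str)
        + "@"
        + df["methylation_bin"].fillna(0).astype(int).astype(str)
    )


def filter_observations(obs: pd.DataFrame, purpose: str) -> pd.DataFrame:
    """Quality filters applied before any MAPS computation.

    ``maps_eval`` keeps autosomal, filter-passing variants with mean coverage
    in (15, 60).  ``table_build`` additionally restricts to the neutral
    GERP window (-3.9885, 2.6607) and intergenic/intronic regions.
    """
    if purpose not in ("table_build", "maps_eval"):
        raise MapsError(f"unknown filtering purpose {purpose!r}")
    mask = (
        obs["chrom"].astype(str).isin(AUTOSOMES)
        & obs["pass_filters"].astype(bool)
        & (obs["coverage"] > COVERAGE_LOW)
        & (obs["coverage"] < COVERAGE_HIGH)
    )
    if purpose == "table_build":
        mask &= (
            (obs["gerp"] > GERP_LOW)
            & (obs["gerp"] < GERP_HIGH)
            & (obs["region"] == "intergenic_intronic")
        )
    out = obs.loc[mask].copy()
    if out.empty:
        warnings.warn("all observations removed by filters", stacklevel=2)
    return out


@dataclass(frozen=True)
class MutabilityTable:
    """Scaled per-base, per-generation mutation rates keyed by substitution
    class (trinucleotide context + alt + methylation bin)."""

    rates: pd.Series  # index: class key, values: scaled rates

    def __post_init__(self) -> None:
        if (self.rates <= 0).any():
            raise MapsError("mutability table contains non-positive rates")

    def lookup(self, obs: pd.DataFrame) -> np.ndarray:
        keys = _class_key(obs)
        missing = sorted(set(keys) - set(self.rates.index))
        if missing:
            raise MapsError(
                f"observations with unknown substitution class: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        return self.rates.loc[keys].to_numpy()


def build_mutability_table(
    neutral: pd.DataFrame,
    possible_counts: pd.DataFrame,
    pseudocount: float = 0.5,
) -> MutabilityTable:
    """Observed/possible proportion per substitution class, rescaled so the
    possible-site-weighted mean rate is 1.2e-8.

    ``possible_counts`` needs columns context, alt, methylation_bin,
    n_possible.  Classes with zero possible sites are excluded with a
    warning; zero observed counts get a small-count floor (``pseudocount``).
    """
    pc = possible_counts.copy()
    pc_key = _class_key(pc)
    zero = pc["n_possible"] <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} substitution classes have zero possible sites; excluded",
            stacklevel=2,
        )
        pc, pc_key = pc.loc[~zero], pc_key.loc[~zero]
    n_possible = pd.Series(pc["n_possible"].to_numpy(float), index=pc_key.to_numpy())

    observed = _class_key(neutral).value_counts()
    observed = observed.reindex(n_possible.index, fill_value=0).astype(float)
    observed = observed.clip(lower=pseudocount)

    raw = observed / n_possible
    weighted_mean = float((raw * n_possible).sum() / n_possible.sum())
    scaled = raw * (MEAN_MUTATION_RATE / weighted_mean)
    scaled.index.name = "class"
    return MutabilityTable(rates=scaled)


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from mutability to expected singleton proportion, fit on
    synonymous variants; predictions are clipped to [0, 1]."""

    intercept: float
    slope: float
    n_groups: int

    def predict(self, rates: np.ndarray) -> np.ndarray:
        return np.clip(self.intercept + self.slope * np.asarray(rates, float), 0.0, 1.0)


def calibrate_singleton_model(
    synonymous: pd.DataFrame,
    table: MutabilityTable,
    weighted: bool = False,
) -> CalibrationModel:
    """Regress per-class singleton proportion on mutation rate.

    Ordinary least squares over substitution-class groups (unweighted by
    default; ``weighted=True`` weights groups by observation count).
    """
    df = synonymous.copy()
    df["_key"] = _class_key(df)
    df["_singleton"] = (df["allele_count"] == 1).astype(float)
    grp = df.groupby("_key")["_singleton"].agg(["mean", "size"])
    grp["rate"] = table.rates.reindex(grp.index)
    grp = grp.dropna(subset=["rate"])
    if grp["rate"].nunique() < 2:
        raise MapsError("calibration requires >= 2 distinct mutation rates")
    w = grp["size"].to_numpy(float) if weighted else None
    slope, intercept = np.polyfit(
        grp["rate"].to_numpy(float), grp["mean"].to_numpy(float), 1, w=w
    )
    return CalibrationModel(intercept=float(intercept), slope=float(slope),
                            n_groups=len(grp))


@dataclass(frozen=True)
class MapsResult:
    n_observed: int
    n_singletons: int
    expected_singletons: float
    maps: float
    ci90: Optional[tuple[float, float]] = None
    n_boot: int = 0
    seed: Optional[int] = None

    def __str__(self) -> str:
        s = f"MAPS = {self.maps:+.4f} (n={self.n_observed}, singletons={self.n_singletons})"
        if self.ci90 is not None:
            s += f", 90% CI [{self.ci90[0]:+.4f}, {self.ci90[1]:+.4f}]"
        return s


def _maps_arrays(
    obs: pd.DataFrame, model: CalibrationModel, table: MutabilityTable
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant singleton flags and predicted singleton probabilities."""
    if len(obs) == 0:
        raise MapsError("MAPS undefined for an empty variant set")
    singleton = (obs["allele_count"].to_numpy(int) == 1).astype(float)
    expected = model.predict(table.lookup(obs))
    return singleton, expected


def compute_maps(
    obs: pd.DataFrame, model: CalibrationModel, table: MutabilityTable
) -> MapsResult:
    """Point estimate: (observed singletons - expected singletons) / n."""
    singleton, expected = _maps_arrays(obs, model, table)
    n = len(singleton)
    n_singletons = int(singleton.sum())
    exp = float(expected.sum())
    return MapsResult(
        n_observed=n,
        n_singletons=n_singletons,
        expected_singletons=exp,
        maps=(n_singletons - exp) / n,
    )


def _bootstrap_maps(
    delta: np.ndarray, n_boot: int, rng: np.random.Generator, chunk: int = 500
) -> np.ndarray:
    """Bootstrap distribution of mean(singleton - expected) by resampling
    variants with replacement; chunked to bound memory."""
    n = delta.size
    out = np.empty(n_boot)
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(m, n))
        out[done : done + m] = delta[idx].mean(axis=1)
        done += m
    return out


def bootstrap_ci(
    obs: pd.DataFrame,
    model: CalibrationModel,
    table: MutabilityTable,
    n_boot: int = 10_000,
    seed: int = 0,
) -> MapsResult:
    """MAPS with a 90% percentile bootstrap interval (5th and 95th
    percentiles of the resampled MAPS distribution)."""
    singleton, expected = _maps_arrays(obs, model, table)
    delta = singleton - expected
    rng = np.random.default_rng(seed)
    boots = _bootstrap_maps(delta, n_boot, rng)
    low, high = np.percentile(boots, [5.0, 95.0])
    point = compute_maps(obs, model, table)
    return MapsResult(
        n_observed=point.n_observed,
        n_singletons=point.n_singletons,
        expected_singletons=point.expected_singletons,
        maps=point.maps,
        ci90=(float(low), float(high)),
        n_boot=n_boot,
        seed=seed,
    )


@dataclass(frozen=True)
class PermutationResult:
    p_value: float
    n_perm: int
    maps_a: float
    maps_b: float

    @property
    def display(self) -> str:
        if self.p_value == 0.0:
            return f"< {1.0 / self.n_perm:g}"
        return f"{self.p_value:g}"


def permutation_pvalue(
    obs_a: pd.DataFrame,
    obs_b: pd.DataFrame,
    model: CalibrationModel,
    table: MutabilityTable,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Bootstrap-permutation p-value for the contrast MAPS(B) > MAPS(A).

    Per permutation both sets are resampled with replacement and MAPS
    recomputed; p is the proportion of permutations where
    MAPS(B) - MAPS(A) < 0.  A zero count is reported as "< 1/n_perm" via
    :attr:`PermutationResult.display`.
    """
    sa, ea = _maps_arrays(obs_a, model, table)
    sb, eb = _maps_arrays(obs_b, model, table)
    da, db = sa - ea, sb - eb
    rng = np.random.default_rng(seed)
    boots_a = _bootstrap_maps(da, n_perm, rng)
    boots_b = _bootstrap_maps(db, n_perm, rng)
    p = float(np.mean((boots_b - boots_a) < 0.0))
    return PermutationResult(
        p_value=p,
        n_perm=n_perm,
        maps_a=float(da.mean()),
        maps_b=float(db.mean()),
    )
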