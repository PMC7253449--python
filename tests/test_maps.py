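"""MAPS machinery: filters, mutability table, calibration, estimator,
bootstrap and permutation inference."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from uorfkit.maps import (
    MEAN_MUTATION_RATE,
    CalibrationModel,
    MapsError,
    MutabilityTable,
    bootstrap_ci,
    build_mutability_table,
    calibrate_singleton_model,
    compute_maps,
    filter_observations,
    permutation_pvalue,
)


def _obs(rows: list[dict]) -> pd.DataFrame:
    base = {
        "variant_id": "v",
        "context": "ACG",
        "alt": "T",
        "methylation_bin": 0,
        "allele_count": 1,
        "coverage": 30.0,
        "gerp": 0.0,
        "region": "utr",
        "chrom": "1",
        "pass_filters": True,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


def _uniform_possible(contexts, n=1000) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"context": c, "alt": a, "methylation_bin": b, "n_possible": n}
            for c, a, b in contexts
        ]
    )


class TestFilters:
    def test_coverage_outlier_dropped(self):
        obs = _obs([{"coverage": 10.0}, {"coverage": 30.0}])
        assert len(filter_observations(obs, "maps_eval")) == 1

    def test_sex_chromosome_dropped(self):
        obs = _obs([{"chrom": "X"}, {"chrom": "21"}])
        kept = filter_observations(obs, "maps_eval")
        assert kept["chrom"].tolist() == ["21"]

    def test_gerp_window_only_for_table_build(self):
        obs = _obs([{"gerp": 3.0, "region": "intergenic_intronic"}])
        assert len(filter_observations(obs, "maps_eval")) == 1
        with pytest.warns(UserWarning, match="all observations removed"):
            assert len(filter_observations(obs, "table_build")) == 0

    def test_table_build_requires_neutral_region(self):
        obs = _obs([{"region": "utr"}, {"region": "intergenic_intronic"}])
        kept = filter_observations(obs, "table_build")
        assert kept["region"].tolist() == ["intergenic_intronic"]

    def test_unknown_purpose(self):
        with pytest.raises(MapsError):
            filter_observations(_obs([{}]), "banana")


class TestMutabilityTable:
    def test_equal_proportions_scale_to_mean_rate(self):
        contexts = [("ACG", "T", 0), ("TTA", "C", 0), ("GGC", "A", 0)]
        possible = _uniform_possible(contexts, n=200)
        # 2 observed in each class -> identical raw proportions
        neutral = _obs(
            [{"context": c, "alt": a, "region": "intergenic_intronic"}
             for c, a, _ in contexts for _ in range(2)]
        )
        table = build_mutability_table(neutral, possible)
        assert np.allclose(table.rates.to_numpy(), MEAN_MUTATION_RATE)

    def test_proportionality_preserved(self):
        contexts = [("ACG", "T", 0), ("TTA", "C", 0)]
        possible = _uniform_possible(contexts, n=100)
        neutral = _obs(
            [{"context": "ACG", "alt": "T"}] * 8 + [{"context": "TTA", "alt": "C"}] * 4
        )
        neutral["region"] = "intergenic_intronic"
        table = build_mutability_table(neutral, possible)
        r = table.rates
        assert r["ACG>T@0"] / r["TTA>C@0"] == pytest.approx(2.0)

    def test_weighted_mean_invariant(self):
        rng = np.random.default_rng(5)
        contexts = [("ACG", "T", 0), ("TTA", "C", 0), ("CCG", "T", 1), ("CCG", "T", 2)]
        possible = pd.DataFrame(
            [
                {"context": c, "alt": a, "methylation_bin": b,
                 "n_possible": int(rng.integers(50, 500))}
                for c, a, b in contexts
            ]
        )
        rows = []
        for c, a, b in contexts:
            rows += [{"context": c, "alt": a, "methylation_bin": b}] * int(
                rng.integers(1, 40)
            )
        neutral = _obs(rows)
        table = build_mutability_table(neutral, possible)
        w = possible["n_possible"].to_numpy(float)
        keys = possible["context"] + ">" + possible["alt"] + "@" + possible[
            "methylation_bin"
        ].astype(str)
        mean = float((table.rates.loc[keys].to_numpy() * w).sum() / w.sum())
        assert mean == pytest.approx(MEAN_MUTATION_RATE, rel=1e-12)

    def test_zero_observed_gets_floor_not_zero(self):
        contexts = [("ACG", "T", 0), ("TTA", "C", 0)]
        possible = _uniform_possible(contexts, n=100)
        neutral = _obs([{"context": "ACG", "alt": "T"}] * 10)
        neutral["region"] = "intergenic_intronic"
        table = build_mutability_table(neutral, possible)
        assert table.rates["TTA>C@0"] > 0

    def test_zero_possible_excluded_with_warning(self):
        possible = pd.DataFrame(
            [
                {"context": "ACG", "alt": "T", "methylation_bin": 0, "n_possible": 100},
                {"context": "TTA", "alt": "C", "methylation_bin": 0, "n_possible": 0},
            ]
        )
        neutral = _obs([{"context": "ACG", "alt": "T"}] * 5)
        with pytest.warns(UserWarning, match="zero possible"):
            table = build_mutability_table(neutral, possible)
        assert "TTA>C@0" not in table.rates.index


class TestCalibration:
    def test_exact_linear_recovery(self):
        # group proportions lying exactly on p = 0.6 - 1e6*rate
        rates = {f"A{m}G>T@0": r for m, r in zip("ACGT", [1e-8, 2e-8, 3e-8, 4e-8])}
        table = MutabilityTable(rates=pd.Series(rates))
        rows = []
        for key, rate in rates.items():
            context = key.split(">")[0]
            k = round((0.6 - 1e6 * rate) * 1000)  # 590, 580, 570, 560
            for i in range(1000):
                rows.append(
                    {"context": context, "alt": "T", "allele_count": 1 if i < k else 5}
                )
        model = calibrate_singleton_model(_obs(rows), table)
        assert model.intercept == pytest.approx(0.6, abs=1e-9)
        assert model.slope == pytest.approx(-1e6, rel=1e-9)

    def test_constant_proportion_gives_zero_slope(self):
        contexts = [("ACG", "T", 0), ("TTA", "C", 0)]
        possible = _uniform_possible(contexts, n=1000)
        neutral = _obs(
            [{"context": "ACG", "alt": "T"}] * 30 + [{"context": "TTA", "alt": "C"}] * 10
        )
        neutral["region"] = "intergenic_intronic"
        table = build_mutability_table(neutral, possible)
        rows = []
        for c, a, _ in contexts:
            for i in range(100):
                rows.append(
                    {"context": c, "alt": a, "allele_count": 1 if i < 40 else 3}
                )
        model = calibrate_singleton_model(_obs(rows), table)
        assert model.slope == pytest.approx(0.0, abs=1e-6)
        assert model.intercept == pytest.approx(0.4, abs=1e-9)

    def test_degenerate_single_rate_errors(self):
        table = MutabilityTable(rates=pd.Series({"ACG>T@0": 1.2e-8}))
        obs = _obs([{"context": "ACG", "alt": "T"}] * 5)
        with pytest.raises(MapsError, match="distinct"):
            calibrate_singleton_model(obs, table)


class TestComputeMaps:
    def _fixture(self):
        table = MutabilityTable(
            rates=pd.Series({"ACG>T@0": 1e-8, "TTA>C@0": 2e-8})
        )
        model = CalibrationModel(intercept=0.25, slope=0.0, n_groups=2)
        return table, model

    def test_eq1_arithmetic(self):
        table, model = self._fixture()
        obs = _obs(
            [{"allele_count": 1}, {"allele_count": 1},
             {"allele_count": 4}, {"allele_count": 9}]
        )
        res = compute_maps(obs, model, table)
        assert res.n_observed == 4 and res.n_singletons == 2
        assert res.expected_singletons == pytest.approx(1.0)
        assert res.maps == pytest.approx(0.25)

    def test_balanced_expectations_give_zero(self):
        table, model = self._fixture()
        obs = _obs(
            [{"allele_count": 1}] + [{"allele_count": 3}] * 3
        )
        res = compute_maps(obs, model, table)
        assert res.maps == pytest.approx(0.0)

    def test_unknown_context_listed(self):
        table, model = self._fixture()
        obs = _obs([{"context": "NNN"}])
        with pytest.raises(MapsError, match="NNN"):
            compute_maps(obs, model, table)

    def test_empty_set_refused(self):
        table, model = self._fixture()
        with pytest.raises(MapsError, match="empty"):
            compute_maps(_obs([]).iloc[:0], model, table)

    def test_scale_invariance(self):
        # multiplying all raw rates by a constant before scaling leaves the
        # scaled table (and hence MAPS) unchanged
        contexts = [("ACG", "T", 0), ("TTA", "C", 0)]
        possible = _uniform_possible(contexts, n=100)
        neutral = _obs(
            [{"context": "ACG", "alt": "T"}] * 8 + [{"context": "TTA", "alt": "C"}] * 4
        )
        neutral["region"] = "intergenic_intronic"
        t1 = build_mutability_table(neutral, possible)
        doubled = possible.assign(n_possible=possible["n_possible"] * 2)
        dup = pd.concat([neutral, neutral], ignore_index=True)
        t2 = build_mutability_table(dup, doubled)
        assert np.allclose(t1.rates.to_numpy(), t2.rates.to_numpy())


class TestResampling:
    def _fixture(self, n=400, seed=3):
        rng = np.random.default_rng(seed)
        table = MutabilityTable(rates=pd.Series({"ACG>T@0": 1.2e-8}))
        model = CalibrationModel(intercept=0.5, slope=0.0, n_groups=1)
        obs = _obs(
            [{"allele_count": 1 if rng.random() < 0.5 else 3} for _ in range(n)]
        )
        return obs, model, table

    def test_degenerate_identical_observations(self):
        table = MutabilityTable(rates=pd.Series({"ACG>T@0": 1.2e-8}))
        model = CalibrationModel(intercept=0.25, slope=0.0, n_groups=1)
        obs = _obs([{"allele_count": 1}] * 20)
        res = bootstrap_ci(obs, model, table, n_boot=200, seed=1)
        assert res.ci90[0] == res.ci90[1] == pytest.approx(res.maps)

    def test_point_estimate_within_interval(self):
        obs, model, table = self._fixture()
        res = bootstrap_ci(obs, model, table, n_boot=500, seed=7)
        assert res.ci90[0] <= res.maps <= res.ci90[1]

    def test_fixed_seed_bit_identical(self):
        obs, model, table = self._fixture()
        r1 = bootstrap_ci(obs, model, table, n_boot=300, seed=42)
        r2 = bootstrap_ci(obs, model, table, n_boot=300, seed=42)
        assert r1 == r2

    def test_permutation_symmetric_for_identical_sets(self):
        obs, model, table = self._fixture(n=600)
        res = permutation_pvalue(obs, obs, model, table, n_perm=2000, seed=5)
        assert 0.4 < res.p_value < 0.6

    def test_permutation_strict_ordering(self):
        table = MutabilityTable(rates=pd.Series({"ACG>T@0": 1.2e-8}))
        model = CalibrationModel(intercept=0.5, slope=0.0, n_groups=1)
        a = _obs([{"allele_count": 3}] * 50)  # no singletons
        b = _obs([{"allele_count": 1}] * 50)  # all singletons
        res = permutation_pvalue(a, b, model, table, n_perm=500, seed=2)
        assert res.p_value == 0.0
        assert res.display == "< 0.002"
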