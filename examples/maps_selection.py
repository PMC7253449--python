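"""Measure selection on variant classes with MAPS on a synthetic cohort.

Simulates a population variant corpus in which four UTR variant classes carry
increasing singleton-proportion inflation (0, 0.05, 0.10, 0.20 - the
signature of progressively stronger negative selection), then recovers those
signals: a mutability table is built from the neutral intergenic/intronic
corpus, a singleton model is calibrated on synonymous variants, and MAPS with
a 90% bootstrap interval is computed per class.
"""

from uorfkit import (
    SimulationConfig,
    bootstrap_ci,
    build_mutability_table,
    calibrate_singleton_model,
    filter_observations,
    permutation_pvalue,
    simulate_population,
)

cfg = SimulationConfig(seed=1)
obs, possible, _ = simulate_population(
    cfg,
    n_observed={
        "intergenic_intronic": 40_000,
        "synonymous": 20_000,
        **{k: 20_000 for k in cfg.singleton_inflation},
    },
)

table = build_mutability_table(
    filter_observations(obs[obs.region == "intergenic_intronic"], "table_build"),
    possible,
)
calibration = calibrate_singleton_model(
    filter_observations(obs[obs.region == "synonymous"], "maps_eval"), table
)

print("class                 injected    MAPS      90% CI")
class_obs = {}
for region, delta in cfg.singleton_inflation.items():
    sub = filter_observations(obs[obs.region == region], "maps_eval")
    class_obs[region] = sub
    res = bootstrap_ci(sub, calibration, table, n_boot=2_000, seed=cfg.seed)
    print(
        f"{region:<22}{delta:>6.2f}  {res.maps:+.4f}  "
        f"[{res.ci90[0]:+.4f}, {res.ci90[1]:+.4f}]"
    )

pr = permutation_pvalue(
    class_obs["neutral"], class_obs["strong_selection"],
    calibration, table, n_perm=2_000, seed=cfg.seed,
)
print(
    f"\npermutation P (strong_selection > neutral): {pr.display} "
    f"({pr.n_perm} permutations)"
)
print(
    "\nMAPS ~ 0 for the neutral class and ~ delta for each inflated class:"
    " the statistic removes the mutability confounder and reads out the"
    " injected selection signal directly."
)
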