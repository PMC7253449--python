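"""Compare base-level conservation at uORF stop sites against matched controls.

Generates transcripts with planted uORFs and phyloP-like scores in which the
stop-site bases carry a planted conservation shift, then compares the
proportion of conserved bases (score >= 2) at stop sites versus the three
flanking bases on each side, with Fisher and Wilcoxon tests.
"""

from uorfkit import (
    SimulationConfig,
    conserved_proportion,
    find_uorfs,
    fisher_2x2,
    generate_transcripts,
    matched_stop_controls,
    simulate_scores,
    wilcoxon_rank_sum,
)
from uorfkit.conservation import stop_site_positions

cfg = SimulationConfig(seed=1, n_genes=400)
transcripts, evidence = generate_transcripts(cfg)
uorfs = [u for t in transcripts for u in find_uorfs(t, evidence)]

stop_sites = stop_site_positions(uorfs)
scores = simulate_scores(cfg, transcripts, stop_sites)
by_key = {(s.transcript_id, s.pos): s.score for s in scores}

stop_scores = [by_key[k] for k in stop_sites]
control_scores = [by_key[k] for k in matched_stop_controls(uorfs, transcripts)]

p_stop = conserved_proportion(stop_scores)
p_ctrl = conserved_proportion(control_scores)
fisher = fisher_2x2(
    p_stop.n_conserved, p_stop.n_total, p_ctrl.n_conserved, p_ctrl.n_total
)
wil = wilcoxon_rank_sum(stop_scores, control_scores)

print(
    f"uORF stop sites:   {p_stop.proportion:.1%} conserved "
    f"(n={p_stop.n_total}, 95% CI {p_stop.ci95[0]:.1%}-{p_stop.ci95[1]:.1%})"
)
print(
    f"matched controls:  {p_ctrl.proportion:.1%} conserved "
    f"(n={p_ctrl.n_total}, 95% CI {p_ctrl.ci95[0]:.1%}-{p_ctrl.ci95[1]:.1%})"
)
print(f"Fisher exact: OR = {fisher.statistic:.2f}, P = {fisher.p_value:.2e}")
print(f"Wilcoxon rank-sum on full score distributions: P = {wil.p_value:.2e}")
print(
    "\nStop-site bases are conserved in excess of their flanking controls,"
    " reflecting the planted purifying signal at functional positions."
)
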