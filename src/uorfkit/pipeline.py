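"""End-to-end orchestration: simulate/load -> enumerate -> annotate -> MAPS ->
conservation -> gene triage -> enrichment, with a reproducibility manifest.

Each stage reads and writes plain TSV/JSON so partial runs can be resumed and
outputs joined with external tooling.  Given the same config and seed the run
is byte-reproducible for every deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    enumerate_stop_removing_snvs,
    enumerate_uaug_deletions,
    enumerate_uaug_snvs,
    find_uorfs,
    records_to_frame,
)
from .conservation import (
    binomial_enrichment,
    conserved_proportion,
    fisher_2x2,
    matched_stop_controls,
    stop_site_positions,
    wilcoxon_rank_sum,
)
from .gene_classes import (
    GeneAnnotation,
    class_summary,
    classify_gene,
    likelihood_summary,
)
from .maps import (
    MapsError,
    bootstrap_ci,
    build_mutability_table,
    calibrate_singleton_model,
    filter_observations,
    permutation_pvalue,
)
from .simulate import (
    SimulationConfig,
    generate_gene_table,
    generate_transcripts,
    simulate_population,
    simulate_scores,
    write_transcripts,
)
from .transcripts import load_transcripts

log = logging.getLogger("uorfkit")

DEFAULTS = {
    "seed": 0,
    "n_genes": 200,
    "n_boot": 10_000,
    "n_perm": 10_000,
    "kozak_plus_offset": 3,
    "phylop_threshold": 2.0,
    "ac_threshold": 15,
    "max_deletion_len": 5,
    "n_observed_per_class": 20_000,
}

STAGES = (
    "simulate", "enumerate", "maps", "conservation", "classify_genes", "enrich",
)


@dataclass
class RunManifest:
    config: dict
    seed: int
    tool_version: str
    input_digests: dict = field(default_factory=dict)
    row_counts: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def load_config(path: Optional[str]) -> dict:
    cfg = dict(DEFAULTS)
    if path:
        import yaml

        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg.update(user)
    return cfg


def run_pipeline(config: dict, out_dir: str | Path, dry_run: bool = False) -> RunManifest:
    """Run every stage, writing TSV/JSON reports plus ``manifest.json``.

    A stage failure aborts the run with the failing stage named; files written
    before the failure remain on disk and are listed in the exception message.
    """
    cfg = dict(DEFAULTS)
    cfg.update(config)
    out = Path(out_dir)
    if dry_run:
        for s in STAGES:
            print(f"would run stage: {s}")
        return RunManifest(config=cfg, seed=cfg["seed"], tool_version=__version__)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=cfg["seed"], tool_version=__version__)
    written: list[str] = []
    stage = "simulate"
    try:
        sim = SimulationConfig(seed=cfg["seed"], n_genes=cfg["n_genes"])

        # --- transcripts -----------------------------------------------------
        if cfg.get("transcripts_fasta"):
            transcripts = load_transcripts(
                cfg["transcripts_fasta"], cfg["transcripts_table"]
            )
            evidence = _read_evidence(cfg.get("evidence_tsv"))
            for key in ("transcripts_fasta", "transcripts_table"):
                manifest.input_digests[key] = _digest(Path(cfg[key]))
        else:
            transcripts, evidence = generate_transcripts(sim)
            write_transcripts(
                transcripts, out / "transcripts.fa", out / "transcripts.tsv"
            )
            written += ["transcripts.fa", "transcripts.tsv"]
        manifest.row_counts["transcripts"] = len(transcripts)
        log.info("simulate: %d transcripts", len(transcripts))

        # --- enumeration ------------------------------------------------------
        stage = "enumerate"
        uorfs_by_tx = {
            t.transcript_id: find_uorfs(t, evidence, cfg["kozak_plus_offset"])
            for t in transcripts
        }
        all_uorfs = [u for us in uorfs_by_tx.values() for u in us]
        records = []
        for t in transcripts:
            records += enumerate_uaug_snvs(t, cfg["kozak_plus_offset"])
            records += enumerate_stop_removing_snvs(t, uorfs_by_tx[t.transcript_id])
            records += enumerate_uaug_deletions(
                t, cfg["max_deletion_len"], cfg["kozak_plus_offset"]
            )
        frame = records_to_frame(records)
        frame.to_csv(out / "consequences.tsv", sep="\t", index=False)
        written.append("consequences.tsv")
        manifest.row_counts["consequences"] = len(frame)
        manifest.row_counts["uorfs"] = sum(
            1 for u in all_uorfs if u.stop_start is not None
        )
        manifest.row_counts["existing_oorfs"] = sum(1 for u in all_uorfs if u.is_oorf)
        log.info("enumerate: %d consequence records", len(frame))

        # --- MAPS ------------------------------------------------------------
        stage = "maps"
        if cfg.get("observations_tsv"):
            obs = pd.read_csv(cfg["observations_tsv"], sep="\t")
            possible = pd.read_csv(cfg["possible_sites_tsv"], sep="\t")
            manifest.input_digests["observations_tsv"] = _digest(
                Path(cfg["observations_tsv"])
            )
        else:
            n_per = cfg["n_observed_per_class"]
            targets = {"intergenic_intronic": 2 * n_per, "synonymous": n_per}
            targets.update({k: n_per for k in sim.singleton_inflation})
            obs, possible, _ = simulate_population(sim, n_observed=targets)
        table = build_mutability_table(
            filter_observations(obs[obs.region == "intergenic_intronic"], "table_build"),
            possible,
        )
        synonymous = filter_observations(
            obs[obs.region == "synonymous"], "maps_eval"
        )
        calibration = calibrate_singleton_model(synonymous, table)
        maps_rows = []
        class_obs = {}
        for region in sorted(obs.region.unique()):
            if region == "intergenic_intronic":
                continue
            sub = filter_observations(obs[obs.region == region], "maps_eval")
            class_obs[region] = sub
            res = bootstrap_ci(
                sub, calibration, table, n_boot=cfg["n_boot"], seed=cfg["seed"]
            )
            maps_rows.append(
                {
                    "class": region,
                    "n_observed": res.n_observed,
                    "n_singletons": res.n_singletons,
                    "expected_singletons": round(res.expected_singletons, 3),
                    "maps": round(res.maps, 5),
                    "ci90_low": round(res.ci90[0], 5),
                    "ci90_high": round(res.ci90[1], 5),
                }
            )
        maps_df = pd.DataFrame(maps_rows)
        maps_df.to_csv(out / "maps.tsv", sep="\t", index=False)
        written.append("maps.tsv")
        perms = {}
        baseline = class_obs.get("neutral")
        if baseline is None:
            baseline = class_obs.get("synonymous")
        if baseline is not None:
            for region, sub in class_obs.items():
                if region in ("neutral", "synonymous"):
                    continue
                pr = permutation_pvalue(
                    baseline, sub, calibration, table,
                    n_perm=cfg["n_perm"], seed=cfg["seed"],
                )
                perms[region] = {"p": pr.p_value, "display": pr.display}
        (out / "maps.json").write_text(
            json.dumps(
                {"classes": maps_rows, "permutation_vs_neutral": perms}, indent=2
            )
            + "\n"
        )
        written.append("maps.json")
        manifest.row_counts["maps_classes"] = len(maps_rows)
        log.info("maps: %d classes", len(maps_rows))

        # --- conservation ----------------------------------------------------
        stage = "conservation"
        stop_sites = stop_site_positions(all_uorfs)
        scores = simulate_scores(sim, transcripts, stop_sites)
        by_key = {(s.transcript_id, s.pos): s for s in scores}
        stop_scores = [by_key[k].score for k in stop_sites if k in by_key]
        control_keys = matched_stop_controls(all_uorfs, transcripts)
        control_scores = [by_key[k].score for k in control_keys if k in by_key]
        cons = {}
        if stop_scores and control_scores:
            thr = cfg["phylop_threshold"]
            p_stop = conserved_proportion(stop_scores, thr)
            p_ctrl = conserved_proportion(control_scores, thr)
            fisher = fisher_2x2(
                p_stop.n_conserved, p_stop.n_total,
                p_ctrl.n_conserved, p_ctrl.n_total,
            )
            wil = wilcoxon_rank_sum(stop_scores, control_scores)
            cons = {
                "stop_sites": {"proportion": p_stop.proportion, "n": p_stop.n_total,
                                "ci95": p_stop.ci95},
                "matched_controls": {"proportion": p_ctrl.proportion,
                                      "n": p_ctrl.n_total, "ci95": p_ctrl.ci95},
                "fisher": {"odds_ratio": fisher.statistic, "p": fisher.p_value},
                "wilcoxon": {"statistic": wil.statistic, "p": wil.p_value},
            }
        (out / "conservation.json").write_text(json.dumps(cons, indent=2) + "\n")
        written.append("conservation.json")
        manifest.row_counts["scored_bases"] = len(scores)

        # --- gene triage -------------------------------------------------------
        stage = "classify_genes"
        if cfg.get("gene_metadata_tsv"):
            gene_df = pd.read_csv(cfg["gene_metadata_tsv"], sep="\t")
            manifest.input_digests["gene_metadata_tsv"] = _digest(
                Path(cfg["gene_metadata_tsv"])
            )
        else:
            gene_df = generate_gene_table(sim, transcripts, records, all_uorfs)
        classifications = [
            classify_gene(_row_to_annotation(row), ac_threshold=cfg["ac_threshold"])
            for row in gene_df.to_dict("records")
        ]
        cls_df = pd.DataFrame(
            {
                "gene_id": [c.gene_id for c in classifications],
                "gene_class": [c.gene_class for c in classifications],
                "likelihood": [c.likelihood for c in classifications],
            }
        )
        cls_df.to_csv(out / "gene_classes.tsv", sep="\t", index=False)
        written.append("gene_classes.tsv")
        summary = {
            "likelihood": likelihood_summary(classifications),
            "classes": {str(k): v for k, v in class_summary(classifications).items()},
        }
        (out / "likelihood_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        written.append("likelihood_summary.json")
        manifest.row_counts["genes_classified"] = len(classifications)
        log.info("classify_genes: %s", summary["likelihood"])

        # --- enrichment --------------------------------------------------------
        stage = "enrich"
        high_impact = [r for r in records if r.high_impact]
        rng = np.random.default_rng(np.random.SeedSequence([cfg["seed"], 0xD15EA5E]))
        if high_impact:
            # a synthetic "disease set": high-impact variants are enriched,
            # emulating the skew of reported pathogenic variants
            n_dis = min(40, max(4, len(high_impact) // 10))
            idx = rng.choice(len(high_impact), size=n_dis, replace=False)
            disease = [high_impact[i] for i in idx]
            enrich = {}
            for pred in ("kozak_moderate_or_strong", "oorf_out_of_frame", "within_50bp"):
                er = binomial_enrichment(disease, records, pred)
                enrich[pred] = {
                    "disease_proportion": er.disease_proportion,
                    "background_proportion": er.background_proportion,
                    "k": er.k,
                    "n": er.n,
                    "p": er.p_value,
                }
        else:
            enrich = {}
        (out / "enrichment.json").write_text(json.dumps(enrich, indent=2) + "\n")
        written.append("enrichment.json")
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(
            f"pipeline stage {stage!r} failed ({exc}); partial outputs: {written}"
        ) from exc

    for name in written:
        manifest.input_digests.setdefault(f"out:{name}", _digest(out / name))
    manifest.write(out / "manifest.json")
    return manifest


def _read_evidence(path: Optional[str]) -> set[tuple[str, int]]:
    if not path:
        return set()
    df = pd.read_csv(path, sep="\t")
    return {(r["transcript_id"], int(r["stop_start"])) for _, r in df.iterrows()}


def _row_to_annotation(row: dict) -> GeneAnnotation:
    return GeneAnnotation(
        gene_id=row["gene_id"],
        has_utr=bool(row["has_utr"]),
        n_possible_perturbing=int(row["n_possible_perturbing"]),
        n_possible_high_impact=int(row["n_possible_high_impact"]),
        has_high_confidence_oorf=bool(row["has_high_confidence_oorf"]),
        max_high_impact_ac=int(row["max_high_impact_ac"]),
        loeuf_sextile=(
            int(row["loeuf_sextile"]) if pd.notna(row.get("loeuf_sextile")) else None
        ),
        curated_hi=bool(row.get("curated_hi", False)),
        ddg2p_lof=bool(row.get("ddg2p_lof", False)),
        clinvar_lof_count=int(row.get("clinvar_lof_count", 0)),
    )
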