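"""End-to-end orchestration: simulate → discover → score → define-test →
evaluate.

Each stage reads its inputs from, and writes its artifacts to, a run
directory, so any prefix of the pipeline can be run (or re-run) alone.  A
single top-level seed derives per-stage sub-seeds; identical configuration
and seed give a byte-identical report bundle (no timestamps enter any
artifact).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .discovery import (
    BetaMatrix,
    CandidateRegion,
    discover_regions,
    estimate_immune_fractions,
    region_score,
)
from .evaluation import (
    confusion,
    delong_test,
    mcnemar_exact,
    roc_auc,
    round_percent,
    stratified_performance,
    summarize,
    time_stratified_sensitivity,
)
from .io import (
    read_beta_matrix,
    read_qpcr_csv,
    read_sample_sheet,
    read_scores_csv,
    read_thresholds_json,
    write_beta_matrix,
    write_qpcr_csv,
    write_regions_bed,
    write_report_json,
    write_sample_sheet,
    write_scores_csv,
    write_thresholds_json,
)
from .scoring import qc_report, score_plate
from .synthetic import (
    REFERENCE_ASSAY,
    SimulationConfig,
    generate_reference_profiles,
    pmr_truth_from_regions,
    simulate_beta_matrix,
    simulate_comparators,
    simulate_qpcr_plate,
)
from .thresholds import classify_scores, fix_thresholds

logger = logging.getLogger(__name__)

ARTIFACTS = {
    "profiles": "reference_profiles.csv",
    "beta": "beta_matrix.csv",
    "annotation": "cpg_annotation.csv",
    "sheet": "sample_sheet.csv",
    "truth_bed": "truth_regions.bed",
    "truth_json": "truth_regions.json",
    "immune_truth": "immune_fractions_truth.csv",
    "candidates_bed": "candidate_regions.bed",
    "panel_json": "panel_regions.json",
    "immune_est": "immune_fractions_estimated.csv",
    "plate": "qpcr_plate.csv",
    "scores": "scores.csv",
    "qc": "qc_report.json",
    "thresholds": "thresholds.json",
    "report": "report.json",
}


def _path(outdir: str | Path, key: str) -> Path:
    return Path(outdir) / ARTIFACTS[key]


def _regions_to_json(regions: list[CandidateRegion]) -> list[dict]:
    return [
        {"chrom": r.chrom, "start": r.start, "end": r.end,
         "members": list(r.member_cpg_ids),
         "auc": None if np.isnan(r.auc) else r.auc}
        for r in regions
    ]


def _regions_from_json(data: list[dict]) -> list[CandidateRegion]:
    return [
        CandidateRegion(chrom=d["chrom"], start=d["start"], end=d["end"],
                        member_cpg_ids=tuple(d["members"]),
                        auc=float("nan") if d["auc"] is None else d["auc"])
        for d in data
    ]


def stage_simulate(cfg: RunConfig, outdir: str | Path) -> None:
    """Generate the cohort: reference profiles, beta matrix, sample sheet
    (with comparator modalities), planted-region truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = cfg.stage_seeds()
    sim = dataclasses.replace(cfg.simulation, seed=seeds["simulate"])
    logger.info("simulate: widqec %s seed=%d sub-seed=%d n=%d cpgs=%d",
                __version__, cfg.seed, sim.seed,
                sim.n_cases + sim.n_controls, sim.n_cpgs)

    profiles = generate_reference_profiles(sim.n_cpgs, sim.seed)
    beta, meta, truth, immune = simulate_beta_matrix(
        sim, profiles, predictive=cfg.predictive
    )
    meta = simulate_comparators(meta, seeds["comparators"])

    pd.DataFrame({
        "id": profiles.cpg_ids, "chrom": profiles.chrom, "pos": profiles.pos,
        "epithelial_mean": profiles.epithelial_mean,
        "immune_mean": profiles.immune_mean,
        "cluster_id": profiles.cluster_id,
    }).to_csv(_path(outdir, "profiles"), index=False)
    write_beta_matrix(beta, _path(outdir, "beta"), _path(outdir, "annotation"))
    write_sample_sheet(meta, _path(outdir, "sheet"))
    write_regions_bed(truth, _path(outdir, "truth_bed"))
    _path(outdir, "truth_json").write_text(
        json.dumps(_regions_to_json(truth), indent=2) + "\n"
    )
    pd.DataFrame({"sample_id": beta.sample_ids, "immune_fraction": immune}) \
        .to_csv(_path(outdir, "immune_truth"), index=False)


def stage_discover(cfg: RunConfig, outdir: str | Path) -> list[CandidateRegion]:
    """Immune-fraction estimation, CpG ranking, region building, AUC
    ranking; persists all candidates and the top-k panel."""
    outdir = Path(outdir)
    beta = read_beta_matrix(_path(outdir, "beta"), _path(outdir, "annotation"))
    meta = read_sample_sheet(_path(outdir, "sheet"))
    profiles = pd.read_csv(_path(outdir, "profiles"))

    immune = estimate_immune_fractions(
        beta, profiles["epithelial_mean"].to_numpy(),
        profiles["immune_mean"].to_numpy(),
    )
    pd.DataFrame({"sample_id": beta.sample_ids, "immune_fraction": immune}) \
        .to_csv(_path(outdir, "immune_est"), index=False)

    d = cfg.discovery
    candidates = discover_regions(
        beta, meta["group"].to_numpy(), immune,
        top_n_cpgs=d["top_n_cpgs"], window_bp=d["window_bp"],
        min_cpgs=d["min_cpgs"], immune_cap=d["immune_cap"],
        control_cap=d["control_cap"],
    )
    write_regions_bed(candidates, _path(outdir, "candidates_bed"))
    panel = candidates[: d["top_k"]]
    _path(outdir, "panel_json").write_text(
        json.dumps(_regions_to_json(panel), indent=2) + "\n"
    )
    logger.info("discover: %d candidates, panel of %d", len(candidates), len(panel))
    return panel


def stage_score(cfg: RunConfig, outdir: str | Path) -> pd.DataFrame:
    """Simulate the MethyLight plate for the discovered panel and score it."""
    outdir = Path(outdir)
    beta = read_beta_matrix(_path(outdir, "beta"), _path(outdir, "annotation"))
    meta = read_sample_sheet(_path(outdir, "sheet"))
    panel = _regions_from_json(json.loads(_path(outdir, "panel_json").read_text()))
    if not panel:
        raise RuntimeError("discover produced no panel regions")

    s = cfg.scoring
    true_pmr = pmr_truth_from_regions(beta, panel)
    plate = simulate_qpcr_plate(
        true_pmr, ref_ct_range=tuple(s["ref_ct_range"]),
        ct_noise_sd=s["ct_noise_sd"], dropout_rate=s["dropout_rate"],
        seed=cfg.stage_seeds()["plate"], max_ref_ct=s["max_ref_ct"],
    )
    write_qpcr_csv(plate, _path(outdir, "plate"))

    plate = read_qpcr_csv(_path(outdir, "plate"))  # round-trip closure
    scores = score_plate(
        plate, panel_assays=list(true_pmr.columns),
        reference_assay=REFERENCE_ASSAY,
        efficiency=s["efficiency"], max_ref_ct=s["max_ref_ct"],
    )

    # development split: the first k cases and controls in cohort order
    # stand in for the pilot set on which thresholds are frozen
    t = cfg.thresholds
    order = meta.set_index("sample_id").loc[scores["sample_id"]]
    is_case = (order["group"] == "case").to_numpy()
    rank_in_group = np.zeros(len(scores), dtype=int)
    rank_in_group[is_case] = np.arange(int(is_case.sum()))
    rank_in_group[~is_case] = np.arange(int((~is_case).sum()))
    dev = np.where(
        is_case, rank_in_group < t["n_dev_cases"],
        rank_in_group < t["n_dev_controls"],
    )
    scores["cohort"] = np.where(dev, "development", "validation")

    write_scores_csv(scores, _path(outdir, "scores"))
    with open(_path(outdir, "qc"), "w") as fh:
        json.dump(qc_report(scores), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return scores


def stage_define_test(cfg: RunConfig, outdir: str | Path):
    """Freeze the dual thresholds on the development split."""
    outdir = Path(outdir)
    scores = read_scores_csv(_path(outdir, "scores"))
    meta = read_sample_sheet(_path(outdir, "sheet"))
    merged = scores.merge(meta[["sample_id", "group"]], on="sample_id")
    dev = merged[(merged["cohort"] == "development") & merged["valid"]]

    t = cfg.thresholds
    thresholds = fix_thresholds(
        dev["sum_pmr"].to_numpy(), dev["group"].to_numpy(),
        target_sensitivity=t["target_sensitivity"],
        target_specificity=t["target_specificity"],
        dev_set_id="synthetic-pilot",
    )
    write_thresholds_json(thresholds, _path(outdir, "thresholds"))
    logger.info("define-test: threshold1=%.4f threshold2=%.4f",
                thresholds.threshold1, thresholds.threshold2)
    return thresholds


def stage_evaluate(cfg: RunConfig, outdir: str | Path) -> dict:
    """Evaluate the frozen test on the validation split and write the
    report bundle."""
    outdir = Path(outdir)
    scores = read_scores_csv(_path(outdir, "scores"))
    meta = read_sample_sheet(_path(outdir, "sheet"))
    thresholds = read_thresholds_json(_path(outdir, "thresholds"))
    truth_regions = json.loads(_path(outdir, "truth_json").read_text())
    panel = json.loads(_path(outdir, "panel_json").read_text())

    merged = scores.merge(meta, on="sample_id")
    val = merged[(merged["cohort"] == "validation") & merged["valid"]].reset_index(drop=True)
    truth = val["group"].to_numpy()
    sum_pmr = val["sum_pmr"].to_numpy()
    e = cfg.evaluation

    # symptomatic-setting rule (high-sensitivity threshold 1)
    cutoff = thresholds.threshold2 if cfg.predictive else thresholds.threshold1
    pred = classify_scores(sum_pmr, cutoff)
    cm = confusion(pred, truth)
    summary = summarize(cm, prevalence=e["prevalence"], conf=e["conf"])

    report: dict = {
        "widqec_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "thresholds": thresholds.to_dict(),
        "applied_threshold": "threshold2" if cfg.predictive else "threshold1",
        "n_validation": int(len(val)),
        "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        "performance": summary.to_dict(),
        "performance_percent": {
            "sensitivity": round_percent(summary.sensitivity),
            "specificity": round_percent(summary.specificity),
            "ppv": round_percent(summary.ppv, 0),
            "npv": round_percent(summary.npv, 0),
        },
        "roc": {"auc": roc_auc(sum_pmr, truth).auc},
        "panel_regions": panel,
        "planted_regions": truth_regions,
        "panel_recovers_truth": _panel_matches_truth(panel, truth_regions),
    }

    # comparator modalities where available
    comparisons: dict = {}
    if "ultrasound_mm" in val.columns and val["ultrasound_mm"].notna().all():
        us = val["ultrasound_mm"].to_numpy(dtype=float)
        dl = delong_test(sum_pmr, us, truth)
        us_pred = np.where(us >= e["ultrasound_cutoff_mm"], "positive", "negative")
        comparisons["ultrasound"] = {
            "auc_widqec": dl.auc_a, "auc_comparator": dl.auc_b,
            "delong_z": dl.z, "delong_p": dl.p_value,
            "mcnemar_p": mcnemar_exact(pred, us_pred),
        }
    if "n_mutations" in val.columns and val["n_mutations"].notna().all():
        mut = val["n_mutations"].to_numpy(dtype=float)
        dl = delong_test(sum_pmr, mut, truth)
        mut_pred = np.where(mut >= e["mutation_cutoff"], "positive", "negative")
        comparisons["dna_mutation"] = {
            "auc_widqec": dl.auc_a, "auc_comparator": dl.auc_b,
            "delong_z": dl.z, "delong_p": dl.p_value,
            "mcnemar_p": mcnemar_exact(pred, mut_pred),
        }
    report["comparators"] = comparisons

    strata = stratified_performance(
        pred, truth, val["menopausal_status"].to_numpy(),
        prevalence=e["prevalence"], conf=e["conf"],
    )
    report["stratified_menopause"] = {k: v.to_dict() for k, v in strata.items()}

    if val["months_to_event"].notna().any():
        report["time_stratified"] = time_stratified_sensitivity(
            pred, truth, val["months_to_event"].to_numpy(),
            cutpoint_months=e["cutpoint_months"], conf=e["conf"],
        )

    write_report_json(report, _path(outdir, "report"))
    return report


def _panel_matches_truth(panel: list[dict], truth: list[dict]) -> bool:
    key = lambda r: (r["chrom"], r["start"], r["end"])
    return sorted(map(key, panel)) == sorted(map(key, truth))


STAGES = ["simulate", "discover", "score", "define-test", "evaluate"]


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run every stage in order and return the evaluation report."""
    stage_simulate(cfg, outdir)
    stage_discover(cfg, outdir)
    stage_score(cfg, outdir)
    stage_define_test(cfg, outdir)
    return stage_evaluate(cfg, outdir)


def run_stage(name: str, cfg: RunConfig, outdir: str | Path):
    fn = {
        "simulate": stage_simulate,
        "discover": stage_discover,
        "score": stage_score,
        "define-test": stage_define_test,
        "evaluate": stage_evaluate,
    }[name]
    return fn(cfg, outdir)
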