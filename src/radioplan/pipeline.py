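"""Stage orchestration: simulate -> evaluate -> compare -> report.

Each stage reads only the previous stage's on-disk outputs, so a run can be
resumed: a stage whose outputs already exist is skipped (unless forced).
The run manifest records the resolved config, every seed, and a sha256 per
output file.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    CONDITIONS,
    Cohort,
    CohortConfig,
    ConditionEffect,
    _default_effects,
    cohort_metric_table,
    generate_cohort,
)
from .dvh import grid_to_differential_dvh
from .io import file_sha256, read_json, read_volumetric, write_json, write_volumetric
from .radiobiology import (
    DEFAULT_GAMMA50,
    FractionationScheme,
    evaluate_outcomes,
    load_registry,
)
from .stats import compare_cohort

log = logging.getLogger("radioplan")

DEFAULT_METRICS = (
    "PTV_Min",
    "PTV_Max",
    "PTV_Mean",
    "PTV_Median",
    "PTV_Mode",
    "PTV_STD",
    "PTV_CI",
    "PTV_GM",
    "PTV_D2",
    "PTV_D50",
    "PTV_D98",
    "Lungs_Mean",
    "Lungs_V2000",
    "Lungs_V3000",
    "Heart_V3000",
    "Heart_V4000",
    "Esophagus_Mean",
    "Esophagus_D2",
)


def cohort_config_from_dict(cfg: dict) -> CohortConfig:
    effects = _default_effects()
    for name, override in (cfg.get("effects") or {}).items():
        if name not in CONDITIONS:
            raise ValueError(f"unknown condition {name!r} in effects config")
        base = effects[name]
        effects[name] = ConditionEffect(
            name,
            override.get("global_scale", base.global_scale),
            override.get("target_min_shift_cgy", base.target_min_shift_cgy),
            override.get("low_dose_scale", base.low_dose_scale),
            override.get("noise_sd_cgy", base.noise_sd_cgy),
        )
    kwargs = {}
    if "grid_shape" in cfg:
        kwargs["shape"] = tuple(cfg["grid_shape"])
    if "spacing_mm" in cfg:
        kwargs["spacing"] = tuple(cfg["spacing_mm"])
    if "falloff_mm" in cfg:
        kwargs["falloff_mm"] = float(cfg["falloff_mm"])
    return CohortConfig(
        n_patients=cfg.get("n_patients", 20),
        prescription_cgy=cfg.get("prescription_cgy", 5400.0),
        n_fractions=cfg.get("n_fractions", 30),
        effects=effects,
        master_seed=cfg.get("seed", 0),
        **kwargs,
    )


def simulate_stage(cfg: dict, outdir: Path, force: bool = False) -> dict:
    outdir = Path(outdir)
    volumes = outdir / "volumes"
    manifest_path = outdir / "cohort_manifest.json"
    if manifest_path.exists() and not force:
        log.info("simulate: outputs exist, skipping")
        return read_json(manifest_path)
    volumes.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    cohort = generate_cohort(cohort_config_from_dict(cfg))
    files = {}
    for pat in cohort.patients:
        for cond, grid in pat.conditions.items():
            path = volumes / f"{pat.patient}_{cond}.npz"
            write_volumetric(path, grid, pat.phantom.masks)
            files[f"{pat.patient}/{cond}"] = path.name
    manifest = dict(cohort.manifest)
    manifest["files"] = files
    write_json(manifest_path, manifest)
    log.info("simulate: %d patients x %d conditions in %.1fs",
             len(cohort.patients), len(CONDITIONS), time.time() - t0)
    return manifest


def evaluate_stage(cfg: dict, outdir: Path, force: bool = False) -> None:
    outdir = Path(outdir)
    metrics_path = outdir / "metrics.csv"
    outcomes_path = outdir / "outcomes.csv"
    if metrics_path.exists() and outcomes_path.exists() and not force:
        log.info("evaluate: outputs exist, skipping")
        return
    t0 = time.time()
    manifest = read_json(outdir / "cohort_manifest.json")
    registry = load_registry(overrides=cfg.get("model_overrides"))
    scheme = FractionationScheme(manifest["prescription_cgy"], manifest["n_fractions"])
    gamma50_default = cfg.get("gamma50_default", DEFAULT_GAMMA50)
    metric_names = tuple(cfg.get("metrics", DEFAULT_METRICS))
    model_structures = sorted({m.structure for m in registry})

    metric_rows = []
    cohort_dvhs = {}
    # rebuild a lightweight in-memory cohort view from the volumetric files
    from .cohort import PatientPlans, Phantom, PhantomSpec  # local to avoid cycle noise

    patients = []
    by_patient: dict[str, dict] = {}
    for key, fname in manifest["files"].items():
        patient, cond = key.split("/")
        grid, masks = read_volumetric(outdir / "volumes" / fname)
        by_patient.setdefault(patient, {"masks": masks, "conditions": {}})
        by_patient[patient]["conditions"][cond] = grid
        cohort_dvhs[(patient, cond)] = {
            s: grid_to_differential_dvh(grid, masks[s]) for s in model_structures if s in masks
        }
    for patient, rec in sorted(by_patient.items()):
        spec = PhantomSpec(
            shape=next(iter(rec["conditions"].values())).shape,
            spacing=next(iter(rec["masks"].values())).spacing,
        )
        patients.append(
            PatientPlans(patient, Phantom(spec, rec["masks"]),
                         next(iter(rec["conditions"].values())), rec["conditions"])
        )
    cfg_resolved = dict(cfg)
    cfg_resolved.update(
        n_patients=manifest["n_patients"],
        prescription_cgy=manifest["prescription_cgy"],
        n_fractions=manifest["n_fractions"],
        seed=manifest["master_seed"],
    )
    cohort = Cohort(cohort_config_from_dict(cfg_resolved), patients, manifest)
    table = cohort_metric_table(cohort, metric_names)
    table.to_csv(metrics_path, index=False)

    outcomes = evaluate_outcomes(cohort_dvhs, registry, scheme, gamma50_default)
    outcomes.to_csv(outcomes_path, index=False)
    log.info("evaluate: %d metric rows, %d outcome rows in %.1fs",
             len(table), len(outcomes), time.time() - t0)


def compare_stage(cfg: dict, outdir: Path, force: bool = False) -> None:
    outdir = Path(outdir)
    out_metrics = outdir / "comparison_metrics.csv"
    out_outcomes = outdir / "comparison_outcomes.csv"
    if out_metrics.exists() and out_outcomes.exists() and not force:
        log.info("compare: outputs exist, skipping")
        return
    t0 = time.time()
    kwargs = dict(
        control=cfg.get("control", "AAA"),
        pairs=[tuple(p) for p in cfg["pairs"]] if cfg.get("pairs") else None,
        alpha=cfg.get("alpha", 0.05),
        method=cfg.get("posthoc_method", "mvt"),
        mc_reps=cfg.get("mc_reps", 200_000),
        seed=cfg.get("seed", 0),
    )
    metrics = pd.read_csv(outdir / "metrics.csv")
    compare_cohort(metrics, **kwargs).to_csv(out_metrics, index=False)

    outcomes = pd.read_csv(outdir / "outcomes.csv")
    outcomes = outcomes[outcomes["probability"].notna()].copy()
    outcomes["metric"] = outcomes["structure"] + " | " + outcomes["endpoint"]
    tidy = outcomes.rename(columns={"probability": "value"})[
        ["patient", "condition", "metric", "value"]
    ]
    compare_cohort(tidy, **kwargs).to_csv(out_outcomes, index=False)
    log.info("compare: done in %.1fs", time.time() - t0)


def report_stage(cfg: dict, outdir: Path, force: bool = False) -> None:
    """Render summary tables and simple figures from earlier outputs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    report = outdir / "report"
    summary_path = report / "summary.txt"
    if summary_path.exists() and not force:
        log.info("report: outputs exist, skipping")
        return
    report.mkdir(parents=True, exist_ok=True)

    comparison = pd.read_csv(outdir / "comparison_metrics.csv")
    lines = ["Per-metric comparison (Friedman omnibus + adjusted post hoc)", ""]
    for metric, sub in comparison.groupby("metric"):
        omnibus = sub[sub["kind"] == "friedman"].iloc[0]
        lines.append(
            f"{metric}: chi2={omnibus['statistic']:.3f} p={omnibus['raw_p']:.4g} "
            f"[{omnibus['stars']}]"
        )
        for _, row in sub[sub["kind"] == "posthoc"].iterrows():
            lines.append(
                f"    {row['pair_a']} vs {row['pair_b']}: "
                f"adj p={row['adjusted_p']:.4g} [{row['stars']}]"
            )
    summary_path.write_text("\n".join(lines) + "\n")

    metrics = pd.read_csv(outdir / "metrics.csv")
    for metric, sub in metrics.groupby("metric"):
        fig, ax = plt.subplots(figsize=(6, 4))
        groups = [g["value"].to_numpy() for _, g in sub.groupby("condition")]
        labels = [c for c, _ in sub.groupby("condition")]
        ax.boxplot(groups, tick_labels=labels)
        ax.set_title(metric)
        ax.set_ylabel("value")
        ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        fig.savefig(report / f"box_{metric}.png", dpi=100)
        plt.close(fig)
    log.info("report: written to %s", report)


STAGES = {
    "simulate": simulate_stage,
    "evaluate": evaluate_stage,
    "compare": compare_stage,
    "report": report_stage,
}


def run_pipeline(cfg: dict, outdir, force: bool = False, stages=None) -> dict:
    """Run the full pipeline; returns the run manifest (also written last)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "radioplan",
        "version": __version__,
        "config": cfg,
        "stages": {},
    }
    manifest_path = outdir / "run_manifest.json"
    for name in stages or list(STAGES):
        t0 = time.time()
        try:
            STAGES[name](cfg, outdir, force=force)
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            write_json(manifest_path, manifest)
            raise
        outputs = {}
        for pattern in ("*.csv", "*.json", "report/*.txt"):
            for path in sorted(outdir.glob(pattern)):
                if path.name != "run_manifest.json":
                    outputs[str(path.relative_to(outdir))] = file_sha256(path)
        manifest["stages"][name] = {
            "status": "ok",
            "elapsed_s": round(time.time() - t0, 3),
            "outputs": outputs,
        }
    write_json(manifest_path, manifest)
    return manifest
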