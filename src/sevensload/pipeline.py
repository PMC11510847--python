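"""Pipeline stages tying simulation, kinematics, modelling and evaluation
into one reproducible run.

Each stage is a plain function over the library; the CLI wraps them. Every
run is deterministic given the seed in its :class:`RunConfig`, and every
artifact directory receives a JSON manifest stamped with the seed, a config
hash and the package version. Logging (stage names, record counts in/out)
goes to the standard ``logging`` machinery, which the CLI routes to stderr.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import SUMMARY_REFERENCE, ZONE_DISTANCE_REFERENCE_M
from .config import RunConfig
from .errors import SchemaError
from .evaluation import (
    evaluation_summary,
    make_long_table,
    pairwise_type_by_game,
    rm_anova,
    tukey_game,
)
from .features import StudyDataset, drop_incomplete
from .kinematics import (
    SpeedTrace,
    ZoneThresholds,
    accumulate_zone_distances,
    compute_acceleration,
)
from .model import WorkloadModelFit, adjusted_r2, fit_lmm
from .synthetic import simulate_study

logger = logging.getLogger(__name__)


def _manifest(config: RunConfig, stage: str, extra: dict) -> dict:
    return {
        "stage": stage,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "package_version": __version__,
        **extra,
    }


def _write_manifest(path: Path, manifest: dict) -> None:
    path.write_text(json.dumps(manifest, indent=2, default=str))


def run_simulate(config: RunConfig, out_dir: str | Path) -> StudyDataset:
    """Simulate the study; write roster, records (and optionally traces)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sink = None
    if config.write_traces:
        traces_dir = out / "traces"
        traces_dir.mkdir(exist_ok=True)

        def sink(trace: SpeedTrace) -> None:
            trace.to_csv(traces_dir / f"{trace.match_id}_{trace.athlete_id}.csv")

    dataset = simulate_study(config.study, config.seed, trace_sink=sink)
    roster = pd.DataFrame(
        {
            "athlete_id": [p.athlete_id for p in dataset.roster],
            "mass_kg": [p.mass_kg for p in dataset.roster],
            "sprint_entry_mps": [p.sprint_entry_mps for p in dataset.roster],
        }
    )
    roster.to_csv(out / "roster.csv", index=False)
    dataset.to_csv(out / "records.csv")
    logger.info("simulate: %d records written", len(dataset))
    _write_manifest(
        out / "simulate_manifest.json",
        _manifest(config, "simulate", {"n_records": len(dataset)}),
    )
    return dataset


def run_extract(config: RunConfig, traces_dir: str | Path, roster_path: str | Path,
                out_path: str | Path) -> pd.DataFrame:
    """Run the zone kinematics over a directory of trace CSVs."""
    traces_dir = Path(traces_dir)
    files = sorted(traces_dir.glob("*.csv")) if traces_dir.is_dir() else []
    if not files:
        raise FileNotFoundError(f"no trace CSV files found in {traces_dir}")
    roster_path = Path(roster_path)
    if not roster_path.exists():
        raise FileNotFoundError(f"roster file not found: {roster_path}")
    roster = pd.read_csv(roster_path)
    if "sprint_entry_mps" not in roster.columns:
        raise SchemaError("roster missing column: sprint_entry_mps")
    thresholds = dict(zip(roster["athlete_id"], roster["sprint_entry_mps"]))
    rows = []
    for f in files:
        match_id, athlete_id = f.stem.split("_", 1)
        trace = SpeedTrace.from_csv(f, athlete_id=athlete_id, match_id=match_id)
        accel = compute_acceleration(trace)
        zones = accumulate_zone_distances(
            trace, accel, ZoneThresholds(sprint_entry_mps=thresholds[athlete_id])
        )
        row = {"athlete_id": athlete_id, "match_id": match_id}
        row.update(zones.as_series().to_dict())
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(out_path, index=False)
    logger.info("extract: %d traces -> %s", len(files), out_path)
    return table


def run_fit(config: RunConfig, dataset: StudyDataset, out_dir: str | Path) -> WorkloadModelFit:
    """Drop incomplete records, fit the workload model, write the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    complete = drop_incomplete(dataset)
    logger.info("fit: %d complete of %d records", len(complete), len(dataset))
    fit = fit_lmm(complete, config.model)
    fit.to_json(out / "model_fit.json")
    fit.coefficients_to_csv(out / "coefficients.csv")
    r2_cond = adjusted_r2(fit, complete, conditional=True)
    r2_marg = adjusted_r2(fit, complete, conditional=False)
    (out / "model_r2.json").write_text(
        json.dumps(
            {"r2_adjusted_conditional": r2_cond, "r2_adjusted_marginal": r2_marg},
            indent=2,
        )
    )
    _write_manifest(
        out / "fit_manifest.json",
        _manifest(config, "fit", {"n_complete": len(complete)}),
    )
    return fit


def load_records(path: str | Path) -> StudyDataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"records file not found: {path}")
    df = pd.read_csv(path)
    if "rpe_au" not in df.columns:
        raise SchemaError("records missing column: rpe_au")
    return StudyDataset(records=df)


def run_evaluate(config: RunConfig, dataset: StudyDataset, fit: WorkloadModelFit,
                 out_dir: str | Path) -> dict:
    """Game-number evaluation of actual vs. predicted sRPE; writes reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    complete = drop_incomplete(dataset)
    table = make_long_table(complete, fit)
    anova = rm_anova(table)
    tukey = tukey_game(table, alpha=config.evaluation.alpha)
    pairwise = pairwise_type_by_game(table, alpha=config.evaluation.alpha)
    anova.table.rename_axis("term").to_csv(out / "anova.csv")
    tukey.comparisons.to_csv(out / "tukey_game.csv", index=False)
    pairwise.comparisons.to_csv(out / "pairwise_type_by_game.csv", index=False)
    summary = evaluation_summary(anova, tukey, pairwise)
    (out / "evaluation_summary.txt").write_text(summary + "\n")
    logger.info("evaluate: ANOVA game p = %.3g", anova.p("game_number"))
    return {"anova": anova, "tukey": tukey, "pairwise": pairwise, "summary": summary}


def study_summary(complete: StudyDataset, r2_adjusted: float) -> dict:
    """Measured study-level quantities next to their calibration references."""
    df = complete.records
    measured = {
        "contacts_mean": float(df["contacts"].mean()),
        "playing_time_min_mean": float(df["playing_time_min"].mean()),
        "rpe_mean": float(df["rpe_au"].mean()),
        "srpe_mean": float(df["srpe_au"].mean()),
        "complete_records": int(len(df)),
        "r2_adjusted": float(r2_adjusted),
    }
    zones = {c: float(df[c].mean()) for c in ZONE_DISTANCE_REFERENCE_M}
    return {
        "summary": {
            k: {"measured": v, "reference": SUMMARY_REFERENCE[k]}
            for k, v in measured.items()
        },
        "zone_distance_means_m": {
            k: {"measured": zones[k], "reference": ZONE_DISTANCE_REFERENCE_M[k]}
            for k in zones
        },
    }


def run_reproduce(config: RunConfig, out_dir: str | Path) -> dict:
    """Run all stages end to end and write a single calibration report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = run_simulate(config, out)
    complete = drop_incomplete(dataset)
    fit = run_fit(config, dataset, out)
    r2 = adjusted_r2(fit, complete, conditional=True)
    run_evaluate(config, dataset, fit, out)
    report = study_summary(complete, r2)
    report["manifest"] = _manifest(
        config, "reproduce", {"n_records": len(dataset), "n_complete": len(complete)}
    )
    (out / "study_report.json").write_text(json.dumps(report, indent=2))
    logger.info("reproduce: report written to %s", out / "study_report.json")
    return report
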