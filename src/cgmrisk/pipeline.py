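"""End-to-end orchestration: simulate or ingest a cohort with CGM traces,
then metrics -> densities -> clinical criteria -> incidence -> model ->
report tables, with reproducible seeding and a run manifest.

A single pipeline seed fans out to per-stage child seeds by fixed
offsets (cohort = seed, traces = seed + 1, permutation test = seed + 2,
causal outcomes = seed + 3) so that a stage rerun in isolation
reproduces its output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    GeneratorConfig,
    generate_cohort,
    generate_traces,
    write_cohort_csv,
    write_traces_csv,
)
from .criteria import annotate_cohort
from .density import (
    estimate_glucodensity,
    permutation_mean_test,
    write_density_csv,
    write_test_json,
)
from .epi import compare_groups, fit_logistic, person_years, poisson_rate_ci
from .metrics import range_metrics_table, read_cgm_csv

__all__ = ["PipelineConfig", "ReportBundle", "PipelineError", "run_pipeline"]

COHORT_COLUMNS = (
    "subject_id",
    "outcome_t2d_5y",
    "age",
    "sex",
    "sex_male",
    "family_history_dm",
    "bmi",
    "waist",
    "fpg",
    "hba1c",
    "fasting_insulin",
    "triglycerides",
    "hdl",
    "sbp",
    "dbp",
    "antihypertensive_use",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # simulate | analyze
    out_dir: str = "cgmrisk_out"
    cohort_path: str | None = None
    traces_path: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    completeness_fraction: float = 0.8
    min_days: int = 2
    grid_step: float = 1.0
    n_permutations: int = 500
    horizon_years: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in {"simulate", "analyze"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "analyze":
            for name in ("cohort_path", "traces_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} missing or not found: {p}")
        if self.mode == "simulate" and self.seed is None:
            raise ValueError("simulate mode requires a seed")


@dataclass
class ReportBundle:
    """All analysis artifacts of one run, plus where they were written."""

    cohort: pd.DataFrame
    metrics: pd.DataFrame
    wear_table: pd.DataFrame
    baseline_table: pd.DataFrame
    ranges_table: pd.DataFrame
    incidence: dict
    model: dict
    density_test: dict
    manifest: dict
    out_dir: Path


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


@_stage("inputs")
def _load_inputs(config: PipelineConfig):
    if config.mode == "simulate":
        gen = config.generator
        gen.seed = config.seed
        cohort = generate_cohort(gen)
        records = generate_traces(cohort, gen, seed=config.seed + 1)
    else:
        cohort = pd.read_csv(config.cohort_path)
        missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
        if missing:
            raise ValueError(f"cohort CSV missing columns: {missing}")
        records = read_cgm_csv(config.traces_path)
        unknown = set(records) - set(cohort["subject_id"].astype(str))
        if unknown:
            raise ValueError(
                f"traces present for subjects absent from cohort: {sorted(unknown)[:5]}"
            )
    return cohort, records


@_stage("metrics")
def _metrics_stage(records, config):
    return range_metrics_table(
        records, config.completeness_fraction, config.min_days
    )


@_stage("densities")
def _density_stage(records, merged, config):
    eligible_ids = merged["subject_id"].astype(str).tolist()
    densities = {
        sid: estimate_glucodensity(records[sid], grid_step=config.grid_step)
        for sid in eligible_ids
    }
    outcome = dict(zip(merged["subject_id"].astype(str), merged["outcome_t2d_5y"]))
    group_b = [densities[s] for s in eligible_ids if outcome[s]]
    group_a = [densities[s] for s in eligible_ids if not outcome[s]]
    result = permutation_mean_test(
        group_a, group_b, n_permutations=config.n_permutations, seed=config.seed + 2
    )
    return list(densities.values()), result


@_stage("incidence")
def _incidence_stage(merged, config):
    events = int(merged["outcome_t2d_5y"].sum())
    n = len(merged)
    py = person_years(n, events, config.horizon_years)
    res = poisson_rate_ci(events, py, n_at_risk=n)
    return {
        "events": res.events,
        "n_at_risk": res.n_at_risk,
        "person_years": res.person_years,
        "cumulative_incidence_pct": res.cumulative_incidence_pct,
        "rate_per_1000py": res.rate_per_1000py,
        "ci95": list(res.ci95),
    }


@_stage("model")
def _model_stage(merged):
    return fit_logistic(merged).to_dict()


@_stage("report")
def _report_stage(merged, metrics):
    wear = pd.crosstab(
        merged["complete_days"], merged["outcome_t2d_5y"].map({False: "non_progressor", True: "progressor"})
    )
    baseline = compare_groups(
        merged,
        continuous=("age", "bmi", "fpg", "hba1c", "homa_ir"),
        categorical=(
            "sex_male",
            "family_history_dm",
            "abdominal_obesity",
            "hypertriglyceridaemia",
            "low_hdl",
            "high_bp",
            "hyperglycaemia",
            "metabolic_syndrome",
        ),
        pearson_pairs=(("tar_pct", "fpg"), ("tar_pct", "hba1c")),
    )
    ranges = compare_groups(
        merged, continuous=("tbr_pct", "tir_pct", "tar_pct")
    )
    return wear, baseline, ranges


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages in order and write every artifact under
    ``config.out_dir``.  Identical config + seed gives identical outputs;
    any stage failure raises :class:`PipelineError` naming the stage."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort, records = _load_inputs(config)
    metrics = _metrics_stage(records, config)
    eligible = metrics[metrics["eligible"]]
    merged = cohort.merge(eligible, on="subject_id", how="inner")
    if merged.empty:
        raise PipelineError("metrics", "no eligible subjects after wear-time filter")
    merged = annotate_cohort(merged)

    densities, density_result = _density_stage(records, merged, config)
    incidence = _incidence_stage(merged, config)
    model = _model_stage(merged)
    wear, baseline, ranges = _report_stage(merged, metrics)

    gen_dict = json.dumps(_jsonable(asdict(config.generator)), sort_keys=True)
    manifest = {
        "mode": config.mode,
        "seed": config.seed,
        "stage_seeds": {
            "cohort": config.seed,
            "traces": config.seed + 1,
            "permutation": config.seed + 2,
        },
        "config_sha256": hashlib.sha256(gen_dict.encode()).hexdigest(),
        "n_subjects": len(cohort),
        "n_eligible": len(merged),
        "versions": {
            "cgmrisk": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }

    write_cohort_csv(cohort, out / "cohort.csv")
    write_traces_csv(records, out / "traces.csv")
    metrics.to_csv(out / "metrics.csv", index=False)
    write_density_csv(densities, out / "density_matrix.csv")
    write_test_json(density_result, out / "density_test.json")
    (out / "incidence.json").write_text(json.dumps(incidence, indent=2))
    (out / "model_summary.json").write_text(json.dumps(model, indent=2))
    wear.to_csv(out / "table_wear.tsv", sep="\t")
    baseline.to_csv(out / "table_baseline.tsv", sep="\t", index=False)
    ranges.to_csv(out / "table_ranges.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return ReportBundle(
        cohort=cohort,
        metrics=metrics,
        wear_table=wear,
        baseline_table=baseline,
        ranges_table=ranges,
        incidence=incidence,
        model=model,
        density_test={
            "observed_statistic": density_result.observed_statistic,
            "n_permutations": density_result.n_permutations,
            "p_value": density_result.p_value,
            "seed": density_result.seed,
        },
        manifest=manifest,
        out_dir=out,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
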