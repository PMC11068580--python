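"""File formats, configuration and the end-to-end pipeline.

Formats
-------
* expression: TSV, samples as rows, first column = sample id, header = gene
  names (TSV because gene annotations may contain commas);
* survival: CSV with header ``sample_id,time,event[,group]``;
* fitted model: JSON (coefficients, baseline arrays, cutoffs, penalty);
* predictions / gene tables / KM curves: CSV.

``run_pipeline`` ties the stages together: optional simulation, penalty
cross-validation, EM fit, prediction, KM stratification and evaluation,
with a manifest (seed, config hash, versions) so equal manifests imply
equal outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .em import (
    FittedMCM,
    EMTrace,
    cross_validate,
    default_lambda_grid,
    em_fit,
    selected_genes,
)
from .evaluate import evaluate_model
from .model import BaselineHazard, MCMParameters, SurvivalDataset
from .solvers import PenaltyConfig
from .stratify import classify_training, km_by_group, km_estimate, predict
from .synthetic import GeneratorConfig, simulate_cohort

logger = logging.getLogger("curemix")


class InputFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path) -> pd.DataFrame:
    """Read a samples-by-genes TSV (first column = sample id)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set = set()
    dupes = sorted({g for g in header if g in seen or seen.add(g)})
    if dupes:
        raise InputFormatError(f"duplicated gene column(s): {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise InputFormatError(f"duplicated sample id(s): {dupes}")
    if df.isna().any().any():
        cells = [
            (str(i), str(c))
            for i, row in df.iterrows()
            for c in df.columns[row.isna()]
        ]
        raise InputFormatError(f"missing values at (sample, gene): {cells[:10]}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise InputFormatError(f"non-numeric expression values: {exc}") from exc
    if not np.all(np.isfinite(values)):
        raise InputFormatError("expression matrix contains non-finite values")
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return df.astype(float)


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_survival(path) -> pd.DataFrame:
    """Read a survival CSV with columns sample_id, time, event[, group]."""
    df = pd.read_csv(path)
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise InputFormatError(f"survival table must have columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise InputFormatError("duplicated sample ids in survival table")
    times = pd.to_numeric(df["time"], errors="coerce")
    if times.isna().any() or (times <= 0).any():
        bad = df.loc[times.isna() | (times <= 0), "sample_id"].tolist()
        raise InputFormatError(f"non-positive or missing times for samples: {bad[:10]}")
    if not df["event"].isin((0, 1)).all():
        bad = df.loc[~df["event"].isin((0, 1)), "sample_id"].tolist()
        raise InputFormatError(f"event indicator outside {{0,1}} for samples: {bad[:10]}")
    out = df.set_index(df["sample_id"].astype(str)).drop(columns="sample_id")
    out["time"] = times.to_numpy()
    out["event"] = out["event"].astype(int)
    out.index.name = "sample_id"
    return out


def write_survival(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="sample_id")


def build_dataset(expression: pd.DataFrame, survival: pd.DataFrame) -> SurvivalDataset:
    """Align expression and survival tables on sample id (strict join)."""
    expr_ids = set(expression.index)
    surv_ids = set(survival.index)
    if not (expr_ids & surv_ids) and (surv_ids & set(map(str, expression.columns))):
        raise InputFormatError(
            "no sample ids shared between expression rows and survival table, "
            "but survival ids match expression *columns*: the expression file "
            "appears transposed (genes as rows); transpose it so samples are rows"
        )
    unmatched = sorted(expr_ids ^ surv_ids)
    if unmatched:
        raise InputFormatError(
            f"{len(unmatched)} sample id(s) not present in both files: {unmatched[:10]}"
        )
    surv = survival.loc[expression.index]
    return SurvivalDataset(
        sample_ids=expression.index.to_numpy(dtype=object),
        times=surv["time"].to_numpy(dtype=float),
        events=surv["event"].to_numpy(),
        expression=expression.to_numpy(dtype=float),
        gene_names=expression.columns.to_numpy(dtype=object),
        group=surv["group"].to_numpy(dtype=object) if "group" in surv.columns else None,
    )


def load_dataset(expression_path, survival_path) -> SurvivalDataset:
    return build_dataset(read_expression(expression_path), read_survival(survival_path))


def dataset_to_frames(data: SurvivalDataset):
    expr = pd.DataFrame(data.expression, index=pd.Index(data.sample_ids, name="sample_id"), columns=data.gene_names)
    surv = pd.DataFrame(
        {"time": data.times, "event": data.events},
        index=pd.Index(data.sample_ids, name="sample_id"),
    )
    if data.group is not None:
        surv["group"] = data.group
    return expr, surv


def write_dataset(data: SurvivalDataset, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    expr, surv = dataset_to_frames(data)
    write_expression(expr, out_dir / "expression.tsv")
    write_survival(surv, out_dir / "survival.csv")


# ---------------------------------------------------------------------------
# model serialization


def save_model(fit: FittedMCM, path) -> None:
    payload = {
        "curemix_version": __version__,
        "incidence_intercept": fit.parameters.incidence_intercept,
        "incidence_coefficients": fit.parameters.incidence_coefficients.tolist(),
        "latency_coefficients": fit.parameters.latency_coefficients.tolist(),
        "baseline_event_times": fit.parameters.baseline.event_times.tolist(),
        "baseline_increments": fit.parameters.baseline.increments.tolist(),
        "gene_names": [str(g) for g in fit.gene_names],
        "training_risk_score_cutoff": fit.training_risk_score_cutoff,
        "cure_threshold": fit.cure_threshold,
        "penalty": dataclasses.asdict(fit.penalty),
        "trace": {
            "penalized_loglik": fit.trace.penalized_loglik,
            "max_param_change": fit.trace.max_param_change,
            "converged": fit.trace.converged,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> FittedMCM:
    with open(path) as fh:
        payload = json.load(fh)
    params = MCMParameters(
        incidence_intercept=payload["incidence_intercept"],
        incidence_coefficients=np.asarray(payload["incidence_coefficients"], dtype=float),
        latency_coefficients=np.asarray(payload["latency_coefficients"], dtype=float),
        baseline=BaselineHazard(
            event_times=np.asarray(payload["baseline_event_times"], dtype=float),
            increments=np.asarray(payload["baseline_increments"], dtype=float),
        ),
    )
    trace = EMTrace(
        penalized_loglik=payload["trace"]["penalized_loglik"],
        max_param_change=payload["trace"]["max_param_change"],
        converged=payload["trace"]["converged"],
    )
    return FittedMCM(
        parameters=params,
        penalty=PenaltyConfig(**payload["penalty"]),
        trace=trace,
        training_risk_score_cutoff=payload["training_risk_score_cutoff"],
        cure_threshold=payload["cure_threshold"],
        gene_names=np.asarray(payload["gene_names"], dtype=object),
    )


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """Everything one run needs; see README for the YAML schema."""

    seed: int = 0
    out_dir: str = "curemix_run"
    expression_path: Optional[str] = None
    survival_path: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    grid_points: int = 4
    grid_max_ratio: float = 0.5
    grid_min_ratio: float = 0.05
    k_folds: int = 5
    lambda_incidence: Optional[float] = None  # set both to skip CV
    lambda_latency: Optional[float] = None
    cure_threshold: float = 0.5
    horizon: float = 5.0
    solver_tolerance: float = 1e-8
    solver_max_iterations: int = 200
    em_tolerance: float = 1e-4
    em_max_iterations: int = 100
    cv_em_max_iterations: int = 25
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            cfg.generator = GeneratorConfig(**gen)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def penalty(self, lam_inc: float, lam_lat: float, em_max: Optional[int] = None) -> PenaltyConfig:
        return PenaltyConfig(
            lambda_incidence=lam_inc,
            lambda_latency=lam_lat,
            tolerance=self.solver_tolerance,
            max_iterations=self.solver_max_iterations,
            em_tolerance=self.em_tolerance,
            em_max_iterations=em_max if em_max is not None else self.em_max_iterations,
        )


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate (optional) -> cv -> fit -> predict -> km -> evaluate.

    Returns a dict of artifact paths; every run writes a manifest carrying
    the seed, a hash of the configuration and package versions.  Outputs are
    byte-identical across reruns with the same config and seed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    if config.generator is not None:
        logger.info("stage simulate: drawing synthetic cohort (seed %d)", config.generator.seed)
        data, truth = simulate_cohort(config.generator)
        write_dataset(data, out)
        truth.to_json(out / "truth.json")
        artifacts["expression"] = str(out / "expression.tsv")
        artifacts["survival"] = str(out / "survival.csv")
        artifacts["truth"] = str(out / "truth.json")
    elif config.expression_path and config.survival_path:
        logger.info("stage load: %s / %s", config.expression_path, config.survival_path)
        data = load_dataset(config.expression_path, config.survival_path)
    else:
        raise InputFormatError("config must provide either a generator block or input paths")

    if config.lambda_incidence is not None and config.lambda_latency is not None:
        best = config.penalty(config.lambda_incidence, config.lambda_latency)
        cv_table = None
    else:
        logger.info("stage cv: %d-fold over a %d x %d grid", config.k_folds, config.grid_points, config.grid_points)
        grid = default_lambda_grid(
            data, config.grid_points, config.grid_max_ratio, config.grid_min_ratio
        )
        best, cv_table = cross_validate(
            data,
            grid,
            k_folds=config.k_folds,
            seed=config.seed,
            penalty_template=config.penalty(0.0, 0.0, em_max=config.cv_em_max_iterations),
            cure_threshold=config.cure_threshold,
        )
        best = config.penalty(best.lambda_incidence, best.lambda_latency)
        cv_table.to_csv(out / "cv_table.csv", index=False)
        artifacts["cv_table"] = str(out / "cv_table.csv")

    logger.info(
        "stage fit: lambda_incidence=%.4g lambda_latency=%.4g",
        best.lambda_incidence,
        best.lambda_latency,
    )
    fit = em_fit(data, best, cure_threshold=config.cure_threshold)
    save_model(fit, out / "model.json")
    artifacts["model"] = str(out / "model.json")

    cure_tab, lat_tab = selected_genes(fit)
    cure_tab.to_csv(out / "cure_genes.csv", index=False)
    lat_tab.to_csv(out / "latency_genes.csv", index=False)
    artifacts["cure_genes"] = str(out / "cure_genes.csv")
    artifacts["latency_genes"] = str(out / "latency_genes.csv")

    expr_df, _ = dataset_to_frames(data)
    logger.info("stage predict: horizon %.3g", config.horizon)
    preds = predict(fit, expr_df, config.horizon)
    preds.to_csv(out / "predictions.csv")
    artifacts["predictions"] = str(out / "predictions.csv")
    training = classify_training(fit, data, config.horizon)
    training.to_csv(out / "training_classification.csv")
    artifacts["training_classification"] = str(out / "training_classification.csv")

    # KM stratification of the fitted cohort uses the posterior-based labels
    km_dir = out / "km"
    km_dir.mkdir(exist_ok=True)
    overall = km_estimate(data.times, data.events, label="all")
    overall.to_frame().to_csv(km_dir / "all.csv", index=False)
    for by in ("cure_label", "risk_group"):
        for curve in km_by_group(data, training[by].to_numpy()):
            curve.to_frame().to_csv(km_dir / f"{by}_{curve.group_label}.csv", index=False)
    artifacts["km_dir"] = str(km_dir)

    logger.info("stage evaluate")
    report = evaluate_model(fit, data, config.horizon)
    with open(out / "report.json", "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=1)
    artifacts["report"] = str(out / "report.json")

    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "versions": {"curemix": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "artifacts": sorted(artifacts),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts
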