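"""End-to-end run orchestration: data in, optimized model + reports out.

The full procedure: load and align genotype/phenotype CSVs, build the
grouped feature encoding and the joint hyperparameter + group-integer
search space, run the MSSA maximizer with mean cross-validated R² as
fitness, decode the best particle, and write four artifacts to the output
directory:

* ``r2_history.csv`` — best fitness, PD/SD schedule and stagnation counter
  per iteration;
* ``optimized_params.json`` — the five tuned hyperparameters, group
  integers, selected markers and the statistical summary (per-fold R²,
  correlations, p-values, 95% t-interval of the fold R² values);
* ``selected_genotype.csv`` — the genotype matrix restricted to the
  selected marker columns;
* ``run.log`` — the configuration echo and per-iteration progress.

A failure at any stage removes the partial outputs and re-raises.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codec import FeatureGrouping, SelectionMask, build_grouping
from .data import (
    GenoPhenoDataset,
    align_samples,
    read_genotype_csv,
    read_phenotype_csv,
    write_selected_genotype,
)
from .mssa import IterationRecord, MSSAConfig, optimize
from .objective import (
    EvalResult,
    GPFitness,
    HyperparameterBounds,
    r2_confidence_interval,
)

__all__ = ["RunConfig", "RunResult", "run", "run_on_dataset", "HISTORY_FILE",
           "PARAMS_FILE", "SELECTED_GENO_FILE", "LOG_FILE"]

logger = logging.getLogger(__name__)

HISTORY_FILE = "r2_history.csv"
PARAMS_FILE = "optimized_params.json"
SELECTED_GENO_FILE = "selected_genotype.csv"
LOG_FILE = "run.log"


@dataclass
class RunConfig:
    """Everything needed to reproduce one optimization run."""

    genotype_path: str | Path
    phenotype_path: str | Path
    output_dir: str | Path
    population_size: int = 50
    max_iterations: int = 50
    folds: int = 5
    step: int = 10
    seed: int = 0
    alert_threshold: float = 0.8
    elite_rate: float = 0.1
    early_stop_patience: int | None = None
    n_estimators: int = 100
    max_code: int | None = None
    bounds: HyperparameterBounds = field(default_factory=HyperparameterBounds)

    def mssa_config(self) -> MSSAConfig:
        return MSSAConfig(
            population_size=self.population_size,
            max_iterations=self.max_iterations,
            alert_threshold=self.alert_threshold,
            elite_rate=self.elite_rate,
            early_stop_patience=self.early_stop_patience,
            seed=self.seed,
        )

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["genotype_path"] = str(self.genotype_path)
        d["phenotype_path"] = str(self.phenotype_path)
        d["output_dir"] = str(self.output_dir)
        return d


@dataclass
class RunResult:
    """Decoded optimum and evaluation summary of one run."""

    hyperparameters: dict
    group_values: tuple[int, ...]
    mask: SelectionMask
    selected_marker_ids: list[str]
    best_fitness: float
    history: list[IterationRecord]
    evaluation: EvalResult
    r2_ci: tuple[float, float, float]
    stopped_early: bool


def run_on_dataset(
    dataset: GenoPhenoDataset, config: RunConfig, output_dir: Path | None = None
) -> RunResult:
    """Optimize on an in-memory dataset; write artifacts when a dir is given."""
    grouping = build_grouping(dataset.n_markers, config.step)
    fitness = GPFitness(
        dataset,
        grouping,
        bounds=config.bounds,
        folds=config.folds,
        n_estimators=config.n_estimators,
        model_seed=config.seed,
        fold_seed=config.seed,
    )
    logger.info(
        "search space: %d dims (5 hyperparameters + %d marker groups), "
        "%d samples x %d markers",
        fitness.search_space.dim, grouping.n_groups,
        dataset.n_samples, dataset.n_markers,
    )
    opt = optimize(fitness, fitness.search_space, config.mssa_config())
    for rec in opt.history:
        logger.info(
            "iter %3d  best R2 %.6f  pd %.3f  sd %.3f  stagnation %d",
            rec.iteration, rec.best_fitness, rec.pd, rec.sd, rec.stagnation_counter,
        )
    decoding = fitness.decode(opt.best_position)
    evaluation = fitness.evaluate(opt.best_position)
    ci = r2_confidence_interval(evaluation.per_fold_r2)
    result = RunResult(
        hyperparameters=decoding.hyperparameters,
        group_values=decoding.group_values,
        mask=decoding.mask,
        selected_marker_ids=[
            m for m, keep in zip(dataset.marker_ids, decoding.mask.flags) if keep
        ],
        best_fitness=opt.best_fitness,
        history=opt.history,
        evaluation=evaluation,
        r2_ci=ci,
        stopped_early=opt.stopped_early,
    )
    logger.info(
        "finished: mean R2 %.4f, mean cor %.4f, %d/%d markers selected%s",
        evaluation.mean_r2, evaluation.mean_cor,
        decoding.mask.n_selected, dataset.n_markers,
        " (early stop)" if opt.stopped_early else "",
    )
    if output_dir is not None:
        _write_artifacts(dataset, config, result, output_dir)
    return result


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline from CSV inputs to the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / LOG_FILE, mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("msxfgp")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("config: %s", json.dumps(config.echo(), default=str))
        geno = read_genotype_csv(config.genotype_path, max_code=config.max_code)
        pheno = read_phenotype_csv(config.phenotype_path)
        dataset = align_samples(geno, pheno)
        return run_on_dataset(dataset, config, output_dir=out)
    except Exception:
        logger.exception("run failed; removing partial outputs")
        for name in (HISTORY_FILE, PARAMS_FILE, SELECTED_GENO_FILE):
            path = out / name
            if path.exists():
                path.unlink()
        raise
    finally:
        handler.close()
        root.removeHandler(handler)


def _write_artifacts(
    dataset: GenoPhenoDataset, config: RunConfig, result: RunResult, out: Path
) -> None:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    history = pd.DataFrame(
        [dataclasses.asdict(rec) for rec in result.history],
        columns=["iteration", "best_fitness", "pd", "sd", "stagnation_counter"],
    )
    history.to_csv(out / HISTORY_FILE, index=False)

    low, high, mean = result.r2_ci
    report = {
        "seed": config.seed,
        "hyperparameters": result.hyperparameters,
        "group_values": list(result.group_values),
        "n_selected_markers": result.mask.n_selected,
        "selected_marker_indices_1based": result.mask.selected_indices,
        "selected_marker_ids": result.selected_marker_ids,
        "best_fitness_mean_r2": result.best_fitness,
        "mean_r2": result.evaluation.mean_r2,
        "mean_cor": result.evaluation.mean_cor,
        "per_fold_r2": result.evaluation.per_fold_r2.tolist(),
        "per_fold_cor": result.evaluation.per_fold_cor.tolist(),
        "per_fold_p_value": result.evaluation.per_fold_p.tolist(),
        "r2_confidence_interval_95": {"low": low, "high": high, "mean": mean},
        "stopped_early": result.stopped_early,
        "config": config.echo(),
    }
    with open(out / PARAMS_FILE, "w") as fh:
        json.dump(report, fh, indent=2, default=str)

    write_selected_genotype(dataset, result.mask, out / SELECTED_GENO_FILE)
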