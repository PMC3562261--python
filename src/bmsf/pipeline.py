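"""End-to-end selection pipeline: prescreen -> filtering -> fine evaluation
-> importance ordering -> significance -> accuracy evaluation.

``run_pipeline`` ties the stages together, logs per-round progress, and
writes a manifest sufficient to reproduce the run exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import ExpressionDataset, GeneSubset, SelectionResult
from .filter import (
    DEFAULT_K_FLOOR,
    DEFAULT_K_START,
    DEFAULT_K_STEP,
    TrainingCounter,
    count_trainings,
    run_filtering,
)
from .io import read_dataset, write_round_log, write_selection_report
from .metrics import CVConfig, loocv_accuracy, prescreen_ttest, repeated_kfold_accuracy
from .refine import fine_evaluate, order_importance, significance

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    matrix_path: str | None = None
    labels_path: str | None = None
    orientation: str = "samples_by_genes"
    prescreen: bool = False
    prescreen_alpha: float = 0.05
    k_start: int = DEFAULT_K_START
    k_step: int = DEFAULT_K_STEP
    k_floor: int = DEFAULT_K_FLOOR
    max_rounds: int = 30
    seed: int = 0
    filter_folds: int = 5
    fine_folds: int = 10
    classifiers: tuple[str, ...] = ("svm",)
    evaluation: str = "loocv"  # or "repeated_kfold"
    output_dir: str = "bmsf_output"

    def __post_init__(self) -> None:
        if self.k_start < self.k_floor or self.k_floor < 2:
            raise ValueError("schedule must satisfy start >= floor >= 2")
        if self.k_start % 2 or self.k_floor % 2:
            raise ValueError("K values must be even")


def run_pipeline(
    cfg: RunConfig, dataset: ExpressionDataset | None = None
) -> SelectionResult:
    """Execute the full pipeline and write reports under cfg.output_dir."""
    if dataset is None:
        if cfg.matrix_path is None or cfg.labels_path is None:
            raise ValueError("need either a dataset or matrix/labels paths")
        dataset = read_dataset(cfg.matrix_path, cfg.labels_path, cfg.orientation)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes = GeneSubset.all_genes(dataset)
    if cfg.prescreen:
        genes = prescreen_ttest(dataset, cfg.prescreen_alpha)
        logger.info("prescreen kept %d / %d genes", len(genes), dataset.n_genes)
        if len(genes) < 2:
            raise RuntimeError("prescreen left fewer than 2 genes; raise alpha")

    counter = TrainingCounter()
    filter_cfg = CVConfig(n_folds=cfg.filter_folds, seed=cfg.seed)
    survivors, records = run_filtering(
        dataset,
        genes,
        seed=cfg.seed,
        cfg=filter_cfg,
        k_start=cfg.k_start,
        k_step=cfg.k_step,
        k_floor=cfg.k_floor,
        max_rounds=cfg.max_rounds,
        counter=counter,
    )
    write_round_log(records, out / "rounds.tsv")

    fine_cfg = CVConfig(n_folds=cfg.fine_folds, seed=cfg.seed)
    final = fine_evaluate(dataset, survivors, fine_cfg, seed=cfg.seed)
    order = order_importance(dataset, final, fine_cfg, seed=cfg.seed)
    if len(final) >= 2:
        p_map = significance(dataset, final, seed=cfg.seed, cfg=fine_cfg)
    else:
        p_map = {}

    ordered = order.ordered_genes
    result = SelectionResult(
        genes=dataset.gene_names(ordered),
        indices=list(ordered),
        p_values=[p_map.get(g, float("nan")) for g in ordered] if p_map else [],
        round_log=[
            {
                "round": r.round_index,
                "K": r.K_used,
                "genes_in": len(r.eliminated) + len(r.survivors),
                "genes_out": len(r.survivors),
                "mu_before": r.mu_before,
                "mu_after": r.mu_after,
            }
            for r in records
        ],
    )
    write_selection_report(result, out / "selection.tsv")

    evaluation: dict[str, dict] = {}
    for clf in cfg.classifiers:
        try:
            if cfg.evaluation == "loocv":
                acc = loocv_accuracy(
                    dataset, final, classifier=clf, seed=cfg.seed
                )
                evaluation[clf] = {"loocv_accuracy": acc}
            else:
                mean, sd = repeated_kfold_accuracy(
                    dataset, final, classifier=clf, seed=cfg.seed
                )
                evaluation[clf] = {"kfold_mean": mean, "kfold_sd": sd}
        except ValueError as exc:  # e.g. qda with too few samples per class
            evaluation[clf] = {"error": str(exc)}
    (out / "evaluation.json").write_text(json.dumps(evaluation, indent=2))

    schedule = [r.K_used for r in records]
    budget = count_trainings(schedule)
    manifest = {
        "seed": cfg.seed,
        "prescreen": cfg.prescreen,
        "prescreen_alpha": cfg.prescreen_alpha,
        "schedule": schedule,
        "k_start": cfg.k_start,
        "k_step": cfg.k_step,
        "k_floor": cfg.k_floor,
        "filter_folds": cfg.filter_folds,
        "fine_folds": cfg.fine_folds,
        "classifiers": list(cfg.classifiers),
        "n_samples": dataset.n_samples,
        "n_genes": dataset.n_genes,
        "n_selected": len(result.genes),
        "budget": {
            "classification": budget.classification,
            "regression": budget.regression,
            "total": budget.total,
        },
        "counter": {
            "classification": counter.classification,
            "regression": counter.regression,
            "checkpoint": counter.checkpoint,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if int(np.sum([counter.classification, counter.regression])) != budget.total:
        logger.warning("instrumented counter disagrees with the schedule budget")
    return result
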