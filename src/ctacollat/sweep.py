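"""Hyperparameter grid enumeration and sweep orchestration.

Enumerates the Cartesian (K, F, N_conv, fc, batch) grid — 192 points at
the default option sets — and, for each point, runs patient-level
five-fold cross-validation: train/validate on four folds (3:1 split,
tenfold-augmented training images only), predict the held-out fold, pool
the per-patient probabilities across folds, and summarize with
ROC/Youden/overall-performance metrics.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import archfactory, evalstats
from .archfactory import HyperParams, TrainConfig
from .phantom import PatientRecord

__all__ = [
    "GridConfig",
    "SweepResult",
    "enumerate_grid",
    "segment_cohort",
    "run_sweep",
    "cross_validate",
    "filter_subset",
    "rank_top_models",
    "model_id",
]


def segment_cohort(records: list[PatientRecord]) -> list[PatientRecord]:
    """Replace raw grayscale slices with pipeline-segmented vessel masks.

    Runs brain extraction followed by triangle-threshold vessel
    segmentation on both levels of every patient; records whose images
    are already boolean masks pass through unchanged.
    """
    from dataclasses import replace as drep

    from . import preprocess, vesselseg

    out = []
    for rec in records:
        levels = {}
        for name in ("ganglionic", "supraganglionic"):
            img = getattr(rec, name)
            if np.asarray(img).dtype == bool:
                levels[name] = img
                continue
            brain = preprocess.extract_brain_region(img)
            levels[name] = vesselseg.segment_vessels(img, brain)
        out.append(drep(rec, **levels))
    return out

HP_COLUMNS = ["kernel_size", "first_filters", "n_conv", "fc_nodes", "batch_size"]
METRIC_COLUMNS = [
    "auc",
    "optimal_youden",
    "sensitivity",
    "specificity",
    "accuracy",
    "overall_performance",
    "cutoff",
]


@dataclass(frozen=True)
class GridConfig:
    """Option sets of the hyperparameter grid plus sweep-level settings."""

    kernel_options: tuple[int, ...] = archfactory.KERNEL_OPTIONS
    filter_options: tuple[int, ...] = archfactory.FILTER_OPTIONS
    depth_options: tuple[int, ...] = archfactory.DEPTH_OPTIONS
    fc_options: tuple[int, ...] = archfactory.FC_OPTIONS
    batch_options: tuple[int, ...] = archfactory.BATCH_OPTIONS
    train: TrainConfig = field(default_factory=TrainConfig)
    cv_folds: int = 5
    cv_seed: int = 0
    scale: float = 1.0  # fraction of the grid for desk-scale smoke runs

    def validate(self) -> None:
        for name in ("kernel", "filter", "depth", "fc", "batch"):
            if not getattr(self, f"{name}_options"):
                raise ValueError(f"empty {name} option set")
        if not 0 < self.scale <= 1:
            raise ValueError("scale must be in (0, 1]")


def enumerate_grid(cfg: GridConfig | None = None) -> list[HyperParams]:
    """Full Cartesian product in deterministic lexicographic order."""
    cfg = cfg if cfg is not None else GridConfig()
    cfg.validate()
    grid = [
        HyperParams(*combo)
        for combo in itertools.product(
            sorted(cfg.kernel_options),
            sorted(cfg.filter_options),
            sorted(cfg.depth_options),
            sorted(cfg.fc_options),
            sorted(cfg.batch_options),
        )
    ]
    if cfg.scale < 1.0:
        rng = np.random.default_rng(cfg.cv_seed)
        keep = max(1, int(round(len(grid) * cfg.scale)))
        idx = np.sort(rng.choice(len(grid), size=keep, replace=False))
        grid = [grid[i] for i in idx]
    return grid


def model_id(hp: HyperParams, cfg: GridConfig) -> str:
    """Stable hash of the grid point plus the governing seeds."""
    payload = json.dumps(
        {
            "hp": [hp.kernel_size, hp.first_filters, hp.n_conv, hp.fc_nodes, hp.batch_size],
            "cv_seed": cfg.cv_seed,
            "train_seed": cfg.train.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class SweepResult:
    """One row per attempted grid point plus pooled per-patient predictions."""

    summaries: pd.DataFrame
    predictions: pd.DataFrame

    def __len__(self) -> int:
        return len(self.summaries)


def cross_validate(
    cohort: list[PatientRecord], hp: HyperParams, cfg: GridConfig
) -> tuple[evalstats.PerformanceSummary, pd.DataFrame]:
    """Five-fold patient-level CV for one grid point.

    Returns the pooled-probability summary and a per-patient prediction
    table (patient_id, label, probability, fold).
    """
    arch = archfactory.build_architecture(hp, grid=cfg)
    assignment = evalstats.assign_folds(cohort, k=cfg.cv_folds, seed=cfg.cv_seed)
    rows = []
    for fold in range(cfg.cv_folds):
        test = [r for r in cohort if assignment.folds[r.patient_id] == fold]
        rest = [r for r in cohort if assignment.folds[r.patient_id] != fold]
        train_recs, val_recs = evalstats.split_train_val(
            rest, seed=cfg.cv_seed * 31 + fold
        )
        fold_cfg = replace(cfg.train, seed=cfg.train.seed * 101 + fold)
        model = archfactory.train_model(arch, train_recs, val_recs, fold_cfg)
        probs = archfactory.predict(model, test)
        for rec, p in zip(test, probs):
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "label": rec.label,
                    "probability": float(p),
                    "fold": fold,
                }
            )
    preds = pd.DataFrame(rows)
    summary = evalstats.summarize_predictions(
        preds["label"].to_numpy(), preds["probability"].to_numpy()
    )
    return summary, preds


def run_sweep(
    cohort: list[PatientRecord],
    cfg: GridConfig | None = None,
    grid: list[HyperParams] | None = None,
) -> SweepResult:
    """Run cross-validation over every grid point; failures are logged rows.

    A failed configuration is recorded with status ``failed`` and
    excluded from metric statistics rather than aborting the sweep.
    """
    cfg = cfg if cfg is not None else GridConfig()
    cfg.validate()
    if not cohort:
        raise ValueError("empty cohort")
    if len({r.label for r in cohort}) < 2:
        raise ValueError("cohort must contain both classes")
    grid = grid if grid is not None else enumerate_grid(cfg)
    summary_rows = []
    pred_frames = []
    for hp in grid:
        mid = model_id(hp, cfg)
        t0 = time.perf_counter()
        row = {
            "model_id": mid,
            "kernel_size": hp.kernel_size,
            "first_filters": hp.first_filters,
            "n_conv": hp.n_conv,
            "fc_nodes": hp.fc_nodes,
            "batch_size": hp.batch_size,
        }
        try:
            summary, preds = cross_validate(cohort, hp, cfg)
            preds.insert(0, "model_id", mid)
            pred_frames.append(preds)
            row.update(
                status="completed",
                auc=summary.auc,
                optimal_youden=summary.optimal_youden,
                sensitivity=summary.sensitivity,
                specificity=summary.specificity,
                accuracy=summary.accuracy,
                overall_performance=summary.overall_performance,
                cutoff=summary.cutoff,
            )
        except Exception as exc:  # sweep robustness: record and continue
            warnings.warn(f"configuration {hp} failed: {exc}", stacklevel=2)
            row.update(status="failed", error=str(exc))
        row["seconds"] = time.perf_counter() - t0
        summary_rows.append(row)
    preds = (
        pd.concat(pred_frames, ignore_index=True)
        if pred_frames
        else pd.DataFrame(columns=["model_id", "patient_id", "label", "probability", "fold"])
    )
    return SweepResult(summaries=pd.DataFrame(summary_rows), predictions=preds)


def filter_subset(results: SweepResult | pd.DataFrame, min_auc: float = 0.7):
    """Rows with acceptable discrimination (AUC >= ``min_auc``, inclusive)."""
    df = results.summaries if isinstance(results, SweepResult) else results
    completed = df[df.get("status", "completed") == "completed"] if "status" in df else df
    kept = completed[completed["auc"] >= min_auc]
    if isinstance(results, SweepResult):
        preds = results.predictions
        return SweepResult(
            summaries=kept.reset_index(drop=True),
            predictions=preds[preds["model_id"].isin(kept.get("model_id", []))].reset_index(drop=True),
        )
    return kept.reset_index(drop=True)


def rank_top_models(results: SweepResult | pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Top ``k`` completed rows by overall performance, ties by higher AUC."""
    df = results.summaries if isinstance(results, SweepResult) else results
    if "status" in df:
        df = df[df["status"] == "completed"]
    if len(df) < k:
        warnings.warn(f"only {len(df)} completed rows for top-{k} ranking", stacklevel=2)
    ranked = df.sort_values(
        ["overall_performance", "auc"], ascending=[False, False], kind="mergesort"
    )
    return ranked.head(k).reset_index(drop=True)
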