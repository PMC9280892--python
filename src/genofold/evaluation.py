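"""Stratified splitting, classification metrics, and the kernel comparison.

``compare_kernels`` runs the full benchmark protocol: one shared stratified
outer 5-fold assignment; per outer fold the genetic-folding search evolves a
kernel on the training portion only (its fitness uses an inner CV nested
inside that portion), and the evolved kernel plus the linear, RBF and
polynomial baselines are all scored on the same held-out portion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import data as _data
from .kernel_lang import GFChromosome, KernelExpression, GramMatrix, gram, repair_gram

__all__ = [
    "MetricsReport",
    "ComparisonReport",
    "stratified_kfold",
    "metrics",
    "compare_kernels",
    "MODEL_NAMES",
]

MODEL_NAMES = ("gfs", "linear", "rbf", "poly")


def stratified_kfold(labels, k: int, seed: int = 0):
    """Deterministic stratified k-fold index pairs over +-1 labels."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"class {classes[np.argmin(counts)]} has {counts.min()} members, "
            f"fewer than k={k}"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train.copy(), test.copy())
        for train, test in splitter.split(np.zeros(len(labels)), labels)
    ]


@dataclass
class MetricsReport:
    """Classification metrics for one evaluation.

    ``mse`` is the mean squared error of 0/1-coded predictions against
    0/1-coded truth, which for hard +-1 predictions equals the
    misclassification rate (1 - accuracy).  ``auc`` is absent (None) when
    the evaluated labels contain a single class.
    """

    accuracy: float
    auc: Optional[float]
    mse: float
    confusion: np.ndarray  # rows: true (-1, +1); cols: predicted (-1, +1)
    n: int
    complexity: Optional[int] = None


def metrics(y_true, scores, y_pred) -> MetricsReport:
    """Compute accuracy, ROC AUC, 0/1 MSE and the confusion matrix."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    y_pred = np.asarray(y_pred)
    if not (len(y_true) == len(scores) == len(y_pred)):
        raise ValueError("y_true, scores and y_pred must have equal length")
    accuracy = float(np.mean(y_pred == y_true))
    if len(np.unique(y_true)) < 2:
        auc = None
    else:
        auc = float(roc_auc_score(y_true, scores))
    t01 = (y_true == 1).astype(float)
    p01 = (y_pred == 1).astype(float)
    mse = float(np.mean((p01 - t01) ** 2))
    conf = confusion_matrix(y_true, y_pred, labels=[-1, 1])
    return MetricsReport(accuracy, auc, mse, conf, len(y_true))


def _mean_sd(values) -> tuple[float, float]:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


@dataclass
class ComparisonReport:
    """Per-model outer-fold metrics plus the winning evolved kernel."""

    per_fold: dict[str, list[MetricsReport]]
    folds: list[tuple[np.ndarray, np.ndarray]]
    best_chromosome: GFChromosome
    best_expression: KernelExpression
    roc_data: dict[str, tuple[np.ndarray, np.ndarray]]  # pooled (y_true, score)
    config: dict = field(default_factory=dict)

    def summary(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for model, reports in self.per_fold.items():
            acc_m, acc_s = _mean_sd(r.accuracy for r in reports)
            auc_m, auc_s = _mean_sd(r.auc for r in reports)
            mse_m, mse_s = _mean_sd(r.mse for r in reports)
            out[model] = {
                "accuracy_mean": acc_m,
                "accuracy_sd": acc_s,
                "auc_mean": auc_m,
                "auc_sd": auc_s,
                "mse_mean": mse_m,
                "mse_sd": mse_s,
            }
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for model, reports in self.per_fold.items():
            row: dict[str, object] = {"model": model}
            for i, r in enumerate(reports, 1):
                row[f"fold{i}_accuracy"] = r.accuracy
            row.update(self.summary()[model])
            rows.append(row)
        return pd.DataFrame(rows)

    def summary_text(self) -> str:
        lines = [
            f"{'model':<8} {'accuracy':>10} {'+-SD':>8} {'AUC':>8} {'MSE':>8}",
            "-" * 46,
        ]
        for model, s in self.summary().items():
            lines.append(
                f"{model:<8} {s['accuracy_mean']:>10.3f} {s['accuracy_sd']:>8.3f} "
                f"{s['auc_mean']:>8.3f} {s['mse_mean']:>8.3f}"
            )
        lines.append("")
        lines.append(f"best evolved kernel: {self.best_expression}")
        lines.append(self.best_chromosome.to_text())
        return "\n".join(lines)


def _evolved_fold_report(expr, Xtr, ytr, Xte, yte, svm_cfg, repair_mode):
    from .kernel_lang import gram_unit_scale
    from .svm_bridge import train_eval_precomputed

    Gtr = gram(expr, Xtr)
    # evolved kernels are trained at unit mean-diagonal scale (the same
    # convention the fitness function uses); the test block shares the factor
    scale = gram_unit_scale((Gtr.values + Gtr.values.T) / 2.0)
    Gtr = repair_gram(GramMatrix(Gtr.values / scale, valid=Gtr.valid), repair_mode)
    Gte_raw = gram(expr, Xte, Xtr)
    Gte = GramMatrix(Gte_raw.values / scale, valid=Gte_raw.valid)
    return train_eval_precomputed(Gtr, ytr, Gte, yte, svm_cfg)


def compare_kernels(
    dataset: _data.Dataset,
    evo_cfg=None,
    svm_cfg=None,
    n_outer_folds: int = 5,
    balance: str = "none",
) -> ComparisonReport:
    """Benchmark the evolved kernel against linear/RBF/polynomial baselines.

    All four models share one stratified outer fold assignment.  Features
    are re-standardized inside each outer fold from its training rows so no
    scaling information leaks from the held-out portion.  ``balance`` is
    ``none`` (default), ``weights`` (class-weighted SVM losses) or
    ``oversample`` (random minority oversampling of the training split).
    """
    from .evolution import EvolutionConfig, evolve
    from .svm_bridge import SVMConfig, baseline_gram, train_eval_precomputed

    evo_cfg = evo_cfg if evo_cfg is not None else EvolutionConfig()
    svm_cfg = svm_cfg if svm_cfg is not None else SVMConfig(C=evo_cfg.svm_C)
    if balance not in ("none", "weights", "oversample"):
        raise ValueError(f"unknown balance mode {balance!r}")
    if balance == "weights":
        svm_cfg = replace(svm_cfg, class_weight="balanced")
        evo_cfg = replace(evo_cfg, class_weight="balanced")

    y = dataset.y
    folds = stratified_kfold(y, n_outer_folds, seed=evo_cfg.seed)
    per_fold: dict[str, list[MetricsReport]] = {m: [] for m in MODEL_NAMES}
    roc_pool: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {
        m: [] for m in MODEL_NAMES
    }
    best: tuple[float, float, GFChromosome, KernelExpression] | None = None

    for i, (tr, te) in enumerate(folds):
        Xall, _, _ = _data.standardize(dataset.raw, tr)
        Xtr, Xte = Xall[tr], Xall[te]
        ytr, yte = y[tr], y[te]
        if balance == "oversample":
            rng = np.random.default_rng(evo_cfg.seed + 7919 * (i + 1))
            Xtr, ytr = _data.oversample_minority(Xtr, ytr, rng)

        fold_cfg = replace(evo_cfg, seed=evo_cfg.seed + 9973 * (i + 1))
        train_ds = _data.dataset_from_arrays(Xtr, ytr, dataset.feature_names)
        result = evolve(train_ds, fold_cfg)
        expr = result.best_expression

        report = _evolved_fold_report(
            expr, Xtr, ytr, Xte, yte, svm_cfg, evo_cfg.repair
        )
        report.complexity = expr.complexity
        per_fold["gfs"].append(report)
        roc_pool["gfs"].append((yte, report._scores))  # type: ignore[attr-defined]
        key = (report.accuracy, result.best.fitness)
        if best is None or key > (best[0], best[1]):
            best = (*key, result.best.chromosome, expr)

        for kind in ("linear", "rbf", "poly"):
            cfg_k = replace(svm_cfg, kernel_kind=kind)
            Gtr = baseline_gram(kind, Xtr, cfg=cfg_k)
            Gte = baseline_gram(kind, Xte, Xtr, cfg=cfg_k)
            rep = train_eval_precomputed(
                repair_gram(Gtr, "symmetrize"), ytr, Gte, yte, cfg_k
            )
            per_fold[kind].append(rep)
            roc_pool[kind].append((yte, rep._scores))  # type: ignore[attr-defined]

    assert best is not None
    roc_data = {
        m: (
            np.concatenate([y_ for y_, _ in chunks]),
            np.concatenate([s for _, s in chunks]),
        )
        for m, chunks in roc_pool.items()
    }
    config = {
        "n_outer_folds": n_outer_folds,
        "balance": balance,
        "evolution": evo_cfg.to_dict(),
        "svm": svm_cfg.to_dict(),
    }
    return ComparisonReport(per_fold, folds, best[2], best[3], roc_data, config)
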