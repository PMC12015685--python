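"""Classification metrics (OA, F1, ROC/AUC) and the annotation-budget sweep.

The positive class is "plant with visible panicles".  OA = (TP+TN)/total;
F1 = TP / (TP + (FP+FN)/2); the ROC curve thresholds at every distinct
score and AUC is the trapezoid-rule area (equal to the tie-corrected
Mann-Whitney statistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .chipio import ChipDataset, SplitSpec, split_dataset, subsample_budget

#: A model runner: (labeled, unlabeled, val, test, seed) -> positive-class
#: scores for the test chips, one value in [0, 1] per chip.
ModelRunner = Callable[[ChipDataset, ChipDataset, ChipDataset, ChipDataset, int],
                       np.ndarray]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _check_binary(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v)
    if not np.isin(v, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1")
    return v.astype(int)


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))))


def overall_accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("cannot compute accuracy of zero evaluations")
    return (c.tp + c.tn) / c.total


def f1_score(c: ConfusionCounts) -> float:
    denom = c.tp + 0.5 * (c.fp + c.fn)
    if denom == 0:
        warnings.warn("F1 undefined (no positives predicted or present); "
                      "returning 0", stacklevel=2)
        return 0.0
    return c.tp / denom


def roc_points(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC curve points [(fpr, tpr), ...] from (0,0) to (1,1) and its AUC."""
    y_true = _check_binary(y_true, "y_true")
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y_true, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def hard_labels(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Probability -> class decision; ties at the threshold go to class 0."""
    return (np.asarray(scores, dtype=float) > threshold).astype(int)


def evaluate_scores(y_true, scores) -> dict[str, float]:
    c = confusion(y_true, hard_labels(scores))
    _, auc = roc_points(y_true, scores)
    return {"oa": overall_accuracy(c), "f1": f1_score(c), "auc": auc}


# ---------------------------------------------------------------------------
# Annotation-budget sweep


@dataclass
class SweepResult:
    """Per-(model, budget, repeat) records plus a mean/sd summary."""

    records: pd.DataFrame

    @property
    def summary(self) -> pd.DataFrame:
        ok = self.records[self.records["error"].isna()]
        return (ok.groupby(["model", "budget"])[["oa", "f1", "auc"]]
                  .agg(["mean", lambda s: s.std(ddof=1)])
                  .rename(columns={"<lambda_0>": "sd"}))

    def to_csv(self, records_path, summary_path=None) -> None:
        self.records.to_csv(records_path, index=False)
        if summary_path is not None:
            flat = self.summary.copy()
            flat.columns = ["_".join(c) for c in flat.columns]
            flat.reset_index().to_csv(summary_path, index=False)


def run_sweep(models: dict[str, ModelRunner], dataset: ChipDataset,
              budgets: list[float], repeats: int = 3, seed: int = 0
              ) -> SweepResult:
    """The label-efficiency experiment.

    For each repeat a fresh 80:20(:20) split is drawn; within a repeat the
    test (and validation) sets stay fixed while the training pool's labels
    are subsampled to each budget.  Every model sees the same labeled set;
    runners are free to also use the masked remainder (the semi-supervised
    case).  Failures are recorded per cell and the sweep continues.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if not all(0.0 < b <= 1.0 for b in budgets):
        raise ValueError("budgets must lie in (0, 1]")
    master = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        rep_seed = int(master.integers(0, 2**31 - 1))
        train, val, test = split_dataset(dataset, SplitSpec(seed=rep_seed))
        for budget in budgets:
            bud_seed = int(master.integers(0, 2**31 - 1))
            labeled, unlabeled = subsample_budget(train, budget, bud_seed)
            for name in sorted(models):
                row = {"model": name, "budget": budget, "repeat": rep,
                       "seed": bud_seed, "n_labeled": len(labeled),
                       "oa": np.nan, "f1": np.nan, "auc": np.nan, "error": None}
                try:
                    scores = np.asarray(
                        models[name](labeled, unlabeled, val, test, bud_seed))
                    row.update(evaluate_scores(test.labels, scores))
                except Exception as exc:  # noqa: BLE001 - recorded per cell
                    row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
    records = pd.DataFrame(rows).sort_values(
        ["model", "budget", "repeat"]).reset_index(drop=True)
    return SweepResult(records=records)


def plot_sweep(result: SweepResult, path, metric: str = "oa") -> None:
    """Budget-vs-metric curves with +/- sd error bars, one line per model."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ok = result.records[result.records["error"].isna()]
    for name, sub in ok.groupby("model"):
        agg = sub.groupby("budget")[metric].agg(["mean", "std"])
        ax.errorbar(agg.index, agg["mean"], yerr=agg["std"].fillna(0),
                    marker="o", capsize=3, label=name)
    ax.set_xscale("log")
    ax.set_xlabel("annotation budget (fraction of training pool labeled)")
    ax.set_ylabel(metric.upper())
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
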