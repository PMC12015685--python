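"""Tabular baselines: 18 per-band statistical descriptors + KNN / RF.

Each chip is summarised by six order/dispersion statistics per RGB band
(median, range, standard deviation, 75th/95th/99th percentiles), giving an
18-value feature vector that feeds a k-nearest-neighbour classifier (k = 10)
and a grid-searched random forest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier

from .chipio import ChipDataset, ImageChip

_BANDS = ("R", "G", "B")
_DESCRIPTORS = ("median", "range", "sd", "p75", "p95", "p99")

#: Column order of the feature vector: band-major, descriptor-minor.
FEATURE_NAMES = tuple(f"{b}_{d}" for b in _BANDS for d in _DESCRIPTORS)

DEFAULT_RF_GRID = {"n_estimators": [100, 300, 500],
                   "max_depth": [4, 8, 16, None]}


def extract_descriptors(chip: ImageChip) -> np.ndarray:
    """18 descriptors, ordered per FEATURE_NAMES.

    Percentiles use linear interpolation between order statistics and the
    standard deviation is the population (ddof=0) one.
    """
    if chip.value_range != (0.0, 1.0):
        raise ValueError("descriptors are defined on chips in [0, 1]")
    out = np.empty(18, dtype=np.float64)
    for b in range(3):
        band = chip.pixels[:, :, b].ravel().astype(np.float64)
        out[6 * b:6 * b + 6] = (
            np.median(band),
            band.max() - band.min(),
            band.std(ddof=0),
            np.percentile(band, 75),
            np.percentile(band, 95),
            np.percentile(band, 99),
        )
    return out


def extract_features(ds: ChipDataset) -> pd.DataFrame:
    """Feature table (one row per chip, 18 named columns, id index)."""
    rows = np.stack([extract_descriptors(c) for c in ds.chips])
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES), index=list(ds.ids))


def fit_knn(features: np.ndarray | pd.DataFrame, labels, k: int = 10
            ) -> KNeighborsClassifier:
    """K-nearest-neighbour classifier on descriptor vectors (default k=10)."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if len(X) < k:
        raise ValueError(f"need at least k={k} labeled examples, got {len(X)}")
    model = KNeighborsClassifier(n_neighbors=k)
    model.fit(X, y)
    return model


def fit_rf(features, labels, grid: dict | None = None, cv_folds: int = 5,
           seed: int = 0) -> tuple[RandomForestClassifier, dict]:
    """Random forest with hyperparameters grid-searched by cross-validated
    accuracy; returns (fitted best model, selected hyperparameters)."""
    grid = DEFAULT_RF_GRID if grid is None else grid
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("hyperparameter grid must be non-empty")
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < cv_folds:
        raise ValueError(f"each class needs >= cv_folds={cv_folds} examples")
    search = GridSearchCV(RandomForestClassifier(random_state=seed),
                          grid, cv=cv_folds, scoring="accuracy", n_jobs=1)
    search.fit(X, y)
    return search.best_estimator_, dict(search.best_params_)
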