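"""Attention and stress detector training, comparison and selection.

Five model families are compared — logistic regression (LR), k-nearest
neighbours (KNN), random forest (RF), a one-hidden-layer neural network
(ANN, optimized with L2 regularization instead of a grid), and gradient
boosted decision trees (GBDT) — on an 80:20 stratified split, with 5-fold
cross-validated grid search on the training side.  Attention detection is
binary (weighted F1); stress detection is 3-class (macro F1).  Per-sample
inference time is timed because the detectors run on-device at 1 Hz; model
selection is argmax accuracy with ties broken by speed.

Caregiver corrections ("wrong prediction cases") are appended to the
training table and counted per session for the evaluation module.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .types import FEATURE_NAMES, ValidationError

__all__ = [
    "MODEL_FAMILIES",
    "DEFAULT_GRIDS",
    "ModelReport",
    "CorrectionEvent",
    "split_dataset",
    "train_models",
    "evaluate_model",
    "select_model",
    "ingest_correction",
    "wrong_prediction_counts",
]

#: Fixed family order; also the final tie-break in model selection.
MODEL_FAMILIES = ("LR", "KNN", "RF", "ANN", "GBDT")

#: Small, standard hyperparameter grids (configurable per call).
DEFAULT_GRIDS = {
    "LR": {"model__C": [0.01, 0.1, 1.0, 10.0]},
    "KNN": {"model__n_neighbors": [3, 5, 7, 11]},
    "RF": {"model__n_estimators": [100, 300], "model__max_depth": [None, 5, 10]},
    "GBDT": {
        "model__n_estimators": [100, 300],
        "model__learning_rate": [0.05, 0.1],
        "model__max_depth": [2, 3],
    },
}

#: ANN settings: one hidden layer, L2 penalty lambda = 1e-3, no grid search.
ANN_HIDDEN = (32,)
ANN_ALPHA = 1e-3


@dataclass
class ModelReport:
    """Held-out performance of one trained family."""

    family: str
    best_params: dict
    accuracy: float
    f1: float
    f1_averaging: str  # {"weighted", "macro"}
    inference_time_ms: float
    n_test: int
    missing_test_classes: tuple = ()

    def as_dict(self) -> dict:
        return {
            "family": self.family,
            "best_params": self.best_params,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "f1_averaging": self.f1_averaging,
            "inference_time_ms": self.inference_time_ms,
            "n_test": self.n_test,
        }


@dataclass(frozen=True)
class CorrectionEvent:
    """A caregiver's real-time correction of one prediction."""

    session_id: str
    timestamp: int
    target: str  # {"attention", "stress"}
    predicted: str
    corrected: str

    def __post_init__(self) -> None:
        if self.target not in ("attention", "stress"):
            raise ValidationError(f"target must be 'attention' or 'stress', got {self.target!r}")
        if self.corrected == self.predicted:
            raise ValidationError("a correction must change the label")


def _make_estimator(family: str, seed: Optional[int]):
    if family == "LR":
        model = LogisticRegression(max_iter=5000, random_state=seed)
    elif family == "KNN":
        model = KNeighborsClassifier()
    elif family == "RF":
        model = RandomForestClassifier(random_state=seed)
    elif family == "ANN":
        model = MLPClassifier(
            hidden_layer_sizes=ANN_HIDDEN, alpha=ANN_ALPHA, max_iter=3000, random_state=seed
        )
    elif family == "GBDT":
        model = GradientBoostingClassifier(random_state=seed)
    else:
        raise ValidationError(f"unknown model family {family!r}")
    return Pipeline([("scale", StandardScaler()), ("model", model)])


def _xy(dataset: pd.DataFrame, target: str) -> tuple[np.ndarray, np.ndarray]:
    label_col = f"{target}_label"
    if label_col not in dataset.columns:
        raise ValidationError(f"dataset has no column {label_col!r}")
    rows = dataset.dropna(subset=[label_col])
    X = rows[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = rows[label_col].to_numpy(dtype=object)
    return X, y


def split_dataset(
    dataset: pd.DataFrame, target: str = "attention", ratio: float = 0.8, seed: Optional[int] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split of the labelled rows (default 80:20)."""
    label_col = f"{target}_label"
    rows = dataset.dropna(subset=[label_col]).reset_index(drop=True)
    if len(rows) < 10:
        raise ValidationError(f"need at least 10 labelled rows, got {len(rows)}")
    counts = rows[label_col].value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValidationError(f"cannot stratify: class(es) {small} have fewer than 2 members")
    train, test = train_test_split(
        rows, train_size=ratio, stratify=rows[label_col], random_state=seed, shuffle=True
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def train_models(
    train: pd.DataFrame,
    target: str = "attention",
    grids: Optional[dict] = None,
    k: int = 5,
    seed: Optional[int] = None,
    families: Sequence[str] = MODEL_FAMILIES,
) -> dict[str, object]:
    """Fit every family on the training split.

    LR, KNN, RF and GBDT get ``k``-fold cross-validated grid search (argmax
    mean CV accuracy) and are refit on the full training split; the ANN is
    fit directly with its L2 penalty.  Returns family -> fitted estimator
    (each with a ``best_params_like`` attribute).
    """
    grids = dict(DEFAULT_GRIDS if grids is None else grids)
    X, y = _xy(train, target)
    fitted: dict[str, object] = {}
    for family in families:
        est = _make_estimator(family, seed)
        if family == "ANN":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # convergence chatter on tiny folds
                est.fit(X, y)
            est.best_params_like = {"hidden_layer_sizes": ANN_HIDDEN, "alpha": ANN_ALPHA}
        else:
            grid = grids.get(family)
            if not grid:
                raise ValidationError(f"no hyperparameter grid configured for {family}")
            search = GridSearchCV(est, grid, cv=k, scoring="accuracy", n_jobs=1, refit=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                search.fit(X, y)
            est = search.best_estimator_
            est.best_params_like = {
                key.removeprefix("model__"): value for key, value in search.best_params_.items()
            }
        fitted[family] = est
    return fitted


def evaluate_model(
    model,
    test: pd.DataFrame,
    target: str = "attention",
    averaging: Optional[str] = None,
    family: str = "",
    timing_repeats: int = 1000,
) -> ModelReport:
    """Held-out metrics: accuracy, F1 with the stated averaging (weighted for
    binary attention, macro for 3-class stress), and per-sample inference
    time in ms averaged over repeated scoring passes (single passes at small
    n are timer-noise dominated)."""
    X, y = _xy(test, target)
    if len(y) == 0:
        raise ValidationError("test split is empty")
    averaging = averaging or ("weighted" if target == "attention" else "macro")
    if averaging not in ("weighted", "macro"):
        raise ValidationError(f"averaging must be 'weighted' or 'macro', got {averaging!r}")

    pred = model.predict(X)
    acc = float(accuracy_score(y, pred))
    missing: tuple = ()
    if averaging == "macro":
        model_classes = getattr(model, "classes_", np.unique(np.concatenate([y, pred])))
        missing = tuple(sorted(set(model_classes) - set(y)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # absent-class F1 counted as 0, flagged above
        f1 = float(f1_score(y, pred, average=averaging, zero_division=0))

    start = time.perf_counter()
    for _ in range(timing_repeats):
        model.predict(X)
    elapsed = time.perf_counter() - start
    per_sample_ms = 1000.0 * elapsed / (timing_repeats * len(y))

    return ModelReport(
        family=family or type(model).__name__,
        best_params=getattr(model, "best_params_like", {}),
        accuracy=acc,
        f1=f1,
        f1_averaging=averaging,
        inference_time_ms=per_sample_ms,
        n_test=len(y),
        missing_test_classes=missing,
    )


def select_model(reports: Sequence[ModelReport]) -> str:
    """Deployment choice: argmax accuracy, ties to the faster model, then to
    the fixed family order."""
    if not reports:
        raise ValidationError("select_model needs at least one report")

    def order(r: ModelReport) -> int:
        return MODEL_FAMILIES.index(r.family) if r.family in MODEL_FAMILIES else len(MODEL_FAMILIES)

    best = min(reports, key=lambda r: (-r.accuracy, r.inference_time_ms, order(r)))
    return best.family


def ingest_correction(dataset: pd.DataFrame, event: CorrectionEvent) -> pd.DataFrame:
    """Append a caregiver-corrected label as a new training row.

    The new row copies the session's features, carries the corrected label
    for the event's target, and is flagged ``source='caregiver'``.  The
    original rows are never modified (append-only), so retraining after
    corrections can only grow the training set.
    """
    rows = dataset[dataset["session_id"] == event.session_id]
    if rows.empty:
        raise KeyError(f"unknown session {event.session_id!r}")
    dataset = dataset.copy()
    for column in ("correction_target", "correction_timestamp"):
        if column not in dataset.columns:
            dataset[column] = pd.Series([None] * len(dataset), dtype=object)
    row = rows.iloc[0].copy()
    row[f"{event.target}_label"] = event.corrected
    row["source"] = "caregiver"
    row["correction_target"] = event.target
    row["correction_timestamp"] = event.timestamp
    dataset.loc[len(dataset)] = row
    return dataset.reset_index(drop=True)


def wrong_prediction_counts(dataset: pd.DataFrame) -> pd.DataFrame:
    """Wrong-prediction cases per session: corrections grouped by session and
    target (the caregiver-reported error tally used in the evaluation)."""
    corrections = dataset[dataset.get("source") == "caregiver"]
    if corrections.empty:
        return pd.DataFrame(columns=["session_id", "attention", "stress"]).set_index("session_id")
    out = []
    for session_id, group in corrections.groupby("session_id"):
        tallies = group["correction_target"].value_counts()
        out.append(
            {
                "session_id": session_id,
                "attention": int(tallies.get("attention", 0)),
                "stress": int(tallies.get("stress", 0)),
            }
        )
    return pd.DataFrame(out).set_index("session_id")
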