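"""Class-weighted SVM scoring with percentile-based three-way calls.

The classifier is trained on the expanded driver/passenger set with
inverse-class-frequency weights (drivers are far rarer than passengers).
The SVM decision value is the mutation score; higher is more driver-like.
Calls follow empirical training-score percentiles:

* **driver** — score strictly above the 90th percentile of training
  passenger scores;
* **passenger** — score strictly below the 10th percentile of training
  driver scores;
* **no-call** — otherwise.

Each driver/passenger call carries an empirical confidence: the fraction
of same-class training mutations with more extreme scores, a de facto
empirical tail P value (0.05 means only 5% of training drivers score
higher).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .catalog import DriverCall
from .features import FeatureTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Support-vector-machine settings.

    ``class_weights`` of None means inverse class frequency,
    w_c = N_total / (2 * N_c), which equals sklearn's "balanced" mode and
    has mean 1 over samples.
    """

    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    class_weights: Mapping[int, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError(f"kernel must be rbf or linear, got {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.class_weights is not None and any(
            w <= 0 for w in self.class_weights.values()
        ):
            raise ValueError("class_weights must be positive")


def inverse_frequency_weights(labels: Sequence[int]) -> dict[int, float]:
    """w_c = N_total / (n_classes * N_c); mean weight over samples is 1."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    n = len(y)
    return {int(c): n / (len(classes) * k) for c, k in zip(classes, counts)}


def build_estimator(spec: ModelSpec | None = None) -> Pipeline:
    """Standardization + weighted SVC pipeline used for both CV and final fit."""
    spec = spec or ModelSpec()
    weights = "balanced" if spec.class_weights is None else dict(spec.class_weights)
    svc = SVC(
        kernel=spec.kernel,
        C=spec.C,
        gamma=spec.gamma,
        class_weight=weights,
        random_state=spec.seed,
    )
    return Pipeline([("scale", StandardScaler()), ("svm", svc)])


@dataclass
class TrainedModel:
    """A fitted scorer plus the training-score distributions for calls.

    ``q90_passenger`` / ``q10_driver`` are the call thresholds;
    ``driver_scores`` / ``passenger_scores`` are sorted training decision
    values kept so confidence is reproducible without retraining.
    """

    spec: ModelSpec
    selected_features: tuple[str, ...]
    pipeline: Pipeline
    q90_passenger: float
    q10_driver: float
    driver_scores: np.ndarray
    passenger_scores: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite([self.q90_passenger, self.q10_driver]).all():
            raise ValueError("call thresholds must be finite")


def _check_labels(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if not set(classes.tolist()) <= {0, 1}:
        raise ValueError("labels must be 0 (passenger) / 1 (driver)")


def _feature_matrix(table: FeatureTable, features: Sequence[str]) -> np.ndarray:
    missing = [f for f in features if f not in table.values.columns]
    if missing:
        raise KeyError(f"selected feature(s) absent from table: {', '.join(missing)}")
    X = table.values[list(features)].to_numpy()
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values; impute first")
    return X


def train(
    table: FeatureTable,
    labels: Mapping[str, int] | pd.Series,
    selected_features: Sequence[str],
    spec: ModelSpec | None = None,
) -> TrainedModel:
    """Fit the weighted SVM and record training-score percentiles.

    ``labels`` maps mutation_id -> 1 (driver) or 0 (passenger) for every
    row of ``table``.  Percentiles use linear interpolation between order
    statistics (numpy default).
    """
    spec = spec or ModelSpec()
    labels = pd.Series(labels)
    labels = labels.loc[table.values.index]
    y = labels.to_numpy(dtype=int)
    _check_labels(y)
    X = _feature_matrix(table, selected_features)
    pipe = build_estimator(spec)
    pipe.fit(X, y)
    scores = pipe.decision_function(X)
    driver_scores = np.sort(scores[y == 1])
    passenger_scores = np.sort(scores[y == 0])
    q90_passenger = float(np.percentile(passenger_scores, 90))
    q10_driver = float(np.percentile(driver_scores, 10))
    if q10_driver > q90_passenger:
        # scores in (q90_passenger, q10_driver) satisfy both call rules;
        # the driver rule takes precedence
        logger.info(
            "call thresholds overlap (q90 passenger %.4f < q10 driver %.4f): "
            "scores between them pass both rules; driver precedence applies",
            q90_passenger,
            q10_driver,
        )
    return TrainedModel(
        spec=spec,
        selected_features=tuple(selected_features),
        pipeline=pipe,
        q90_passenger=q90_passenger,
        q10_driver=q10_driver,
        driver_scores=driver_scores,
        passenger_scores=passenger_scores,
    )


def score(model: TrainedModel, table: FeatureTable) -> pd.Series:
    """Signed decision values for every mutation; higher = more driver-like."""
    X = _feature_matrix(table, model.selected_features)
    return pd.Series(
        model.pipeline.decision_function(X), index=table.values.index, name="score"
    )


def categorize(model: TrainedModel, score_value: float) -> str:
    """Three-way call: driver test first, then passenger, else no-call.

    Both comparisons are strict; a score exactly at a threshold falls
    through to the next rule.
    """
    if score_value > model.q90_passenger:
        return "driver"
    if score_value < model.q10_driver:
        return "passenger"
    return "no-call"


def confidence(model: TrainedModel, score_value: float, category: str) -> float | None:
    """Fraction of same-class training mutations with more extreme scores.

    Drivers: fraction of training drivers scoring strictly higher.
    Passengers: fraction of training passengers scoring strictly lower.
    No-call: None.  Ties count as not more extreme.
    """
    if category == "no-call":
        return None
    if category == "driver":
        ref = model.driver_scores
        n_extreme = int(np.searchsorted(ref, score_value, side="right"))
        return float((len(ref) - n_extreme) / len(ref))
    if category == "passenger":
        ref = model.passenger_scores
        return float(np.searchsorted(ref, score_value, side="left") / len(ref))
    raise ValueError(f"bad category {category!r}")


def predict(model: TrainedModel, table: FeatureTable) -> list[DriverCall]:
    """Score, categorize, and attach confidence for every mutation in order."""
    scores = score(model, table)
    calls = []
    for mid, s in scores.items():
        cat = categorize(model, float(s))
        calls.append(
            DriverCall(
                mutation_id=str(mid),
                score=float(s),
                category=cat,
                confidence=confidence(model, float(s), cat),
            )
        )
    return calls


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist the model (metadata + fitted pipeline) as a joblib archive."""
    payload = {
        "format": "drivercall-model-v1",
        "meta": {
            "kernel": model.spec.kernel,
            "C": model.spec.C,
            "gamma": model.spec.gamma,
            "class_weights": None
            if model.spec.class_weights is None
            else dict(model.spec.class_weights),
            "seed": model.spec.seed,
            "selected_features": list(model.selected_features),
            "q90_passenger": model.q90_passenger,
            "q10_driver": model.q10_driver,
            "percentile_method": "linear",
        },
        "pipeline": model.pipeline,
        "driver_scores": model.driver_scores,
        "passenger_scores": model.passenger_scores,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format") != "drivercall-model-v1":
        raise ValueError(f"{path}: not a drivercall model archive")
    m = payload["meta"]
    spec = ModelSpec(
        kernel=m["kernel"],
        C=m["C"],
        gamma=m["gamma"],
        class_weights=m["class_weights"],
        seed=m["seed"],
    )
    return TrainedModel(
        spec=spec,
        selected_features=tuple(m["selected_features"]),
        pipeline=payload["pipeline"],
        q90_passenger=m["q90_passenger"],
        q10_driver=m["q10_driver"],
        driver_scores=np.asarray(payload["driver_scores"]),
        passenger_scores=np.asarray(payload["passenger_scores"]),
    )
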