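"""Per-feature screening and hybrid combinatorial feature selection.

Screening keeps features that separate drivers from passengers by two
criteria: a Bonferroni-corrected two-sided Mann-Whitney U test and a
margin on the single-feature ROC AUC, |AUC - 0.5| > margin (features may
be protective or deleterious, so the margin is two-sided and the raw
feature enters the model unflipped).

The combination search then runs in two steps under repeated stratified
10-fold cross-validated AUC of the weighted SVM:

1. **enumeration** — every subset of fewer than 4 screened features is
   evaluated and the best becomes the core set;
2. **hill climbing** — the core is grown one feature at a time, always
   adding the feature that maximizes the cross-validated AUC of the
   augmented set, until all screened features are included; the optimal
   set is the path prefix with maximum AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.model_selection import RepeatedStratifiedKFold

from .classifier import ModelSpec, build_estimator
from .features import FeatureTable


@dataclass(frozen=True)
class CVConfig:
    """Repeated stratified k-fold settings for combination evaluation."""

    folds: int = 10
    repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class ScreenResult:
    """Single-feature screening outcome."""

    feature_name: str
    auc: float
    u_pvalue: float
    p_bonferroni: float
    passed: bool
    direction: int  # sign of (auc - 0.5)


@dataclass(frozen=True)
class SelectionTrace:
    """Full incremental-selection path and its optimum.

    ``path`` lists (feature_added, cv_auc_of_prefix) from the first core
    feature to exhaustion; ``optimal_set`` is the shortest prefix whose CV
    AUC equals the path maximum.
    """

    core_set: tuple[str, ...]
    path: tuple[tuple[str, float], ...]
    optimal_set: tuple[str, ...]
    optimal_cv_auc: float


def feature_auc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """Rank-sum ROC AUC: P(pos > neg) + 0.5 P(pos = neg).

    Equals the Mann-Whitney U statistic divided by n_pos * n_neg, with
    half credit for ties.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def mann_whitney_p(
    group_a: Sequence[float], group_b: Sequence[float], exact_max_n: int = 20
) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact null distribution when both groups have <= ``exact_max_n``
    observations and no ties span the groups; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size <= exact_max_n and b.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def _split_by_label(
    table: FeatureTable, labels: Mapping[str, int] | pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    labels = pd.Series(labels).loc[table.values.index]
    y = labels.to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    return table.values.loc[y == 1], table.values.loc[y == 0]


def screen_features(
    table: FeatureTable,
    labels: Mapping[str, int] | pd.Series,
    alpha: float = 0.05,
    auc_margin: float = 0.05,
    exclude: Sequence[str] = (),
) -> list[ScreenResult]:
    """Screen each feature by Mann-Whitney p (Bonferroni) and AUC margin.

    ``exclude`` drops features that may carry dataset/population-specific
    biases before screening; the Bonferroni multiplier is the number of
    features actually screened.
    """
    pos, neg = _split_by_label(table, labels)
    screened = [f for f in table.feature_names if f not in set(exclude)]
    n_tests = len(screened)
    results = []
    for f in screened:
        auc = feature_auc(pos[f].to_numpy(), neg[f].to_numpy())
        p = mann_whitney_p(pos[f].to_numpy(), neg[f].to_numpy())
        p_bonf = min(1.0, p * n_tests)
        passed = (p_bonf < alpha) and (abs(auc - 0.5) > auc_margin)
        results.append(
            ScreenResult(
                feature_name=f,
                auc=auc,
                u_pvalue=p,
                p_bonferroni=p_bonf,
                passed=passed,
                direction=int(np.sign(auc - 0.5)),
            )
        )
    return results


def cv_auc(
    table: FeatureTable,
    labels: Mapping[str, int] | pd.Series,
    feature_subset: Sequence[str],
    cv: CVConfig | None = None,
    model_spec: ModelSpec | None = None,
) -> float:
    """Mean ROC AUC of the weighted SVM over folds x repeats.

    Standardization is fit inside each training fold.  Deterministic for a
    fixed ``cv.seed``.
    """
    if not feature_subset:
        raise ValueError("feature_subset must be non-empty")
    cv = cv or CVConfig()
    labels = pd.Series(labels).loc[table.values.index]
    y = labels.to_numpy(dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < cv.folds:
        raise ValueError(
            f"smallest class has {counts.min()} members < folds={cv.folds}; "
            "reduce the number of folds"
        )
    X = table.values[list(feature_subset)].to_numpy()
    splitter = RepeatedStratifiedKFold(
        n_splits=cv.folds, n_repeats=cv.repeats, random_state=cv.seed
    )
    aucs = []
    for train_idx, test_idx in splitter.split(X, y):
        est = build_estimator(model_spec)
        est.fit(X[train_idx], y[train_idx])
        s = est.decision_function(X[test_idx])
        y_test = y[test_idx]
        aucs.append(feature_auc(s[y_test == 1], s[y_test == 0]))
    return float(np.mean(aucs))


def enumerate_core(
    table: FeatureTable,
    labels: Mapping[str, int] | pd.Series,
    screened_features: Sequence[str],
    cv: CVConfig | None = None,
    model_spec: ModelSpec | None = None,
    max_size: int = 3,
) -> tuple[str, ...]:
    """Exhaustively evaluate all subsets of size 1..``max_size``.

    Returns the subset with maximum cross-validated AUC; ties favor the
    smaller subset, then lexicographic order.
    """
    if not screened_features:
        raise ValueError("screened_features must be non-empty")
    feats = sorted(screened_features)
    best: tuple[str, ...] | None = None
    best_auc = -np.inf
    for size in range(1, min(max_size, len(feats)) + 1):
        for combo in combinations(feats, size):
            auc = cv_auc(table, labels, combo, cv, model_spec)
            if auc > best_auc:  # strict: first (smaller, lex-earlier) wins ties
                best, best_auc = combo, auc
    assert best is not None
    return best


def hill_climb(
    table: FeatureTable,
    labels: Mapping[str, int] | pd.Series,
    core_set: Sequence[str],
    remaining_features: Sequence[str],
    cv: CVConfig | None = None,
    model_spec: ModelSpec | None = None,
) -> SelectionTrace:
    """Grow the core set greedily to exhaustion and pick the best prefix.

    At each step the feature whose addition maximizes the cross-validated
    AUC joins the set (ties -> lexicographically first).  The full path is
    recorded; the optimal set is the shortest prefix attaining the maximum
    AUC.
    """
    core = tuple(sorted(core_set))
    remaining = sorted(set(remaining_features) - set(core))
    path: list[tuple[str, float]] = []
    current: list[str] = []
    for f in core:
        current.append(f)
        path.append((f, cv_auc(table, labels, current, cv, model_spec)))
    while remaining:
        best_f = None
        best_auc = -np.inf
        for f in remaining:  # sorted -> lexicographic tie-break via strict >
            auc = cv_auc(table, labels, current + [f], cv, model_spec)
            if auc > best_auc:
                best_f, best_auc = f, auc
        assert best_f is not None
        current.append(best_f)
        remaining.remove(best_f)
        path.append((best_f, best_auc))
    aucs = [a for _, a in path]
    best_idx = int(np.argmax(aucs))  # argmax returns first max -> shortest prefix
    features_in_order = [f for f, _ in path]
    return SelectionTrace(
        core_set=core,
        path=tuple(path),
        optimal_set=tuple(features_in_order[: best_idx + 1]),
        optimal_cv_auc=float(aucs[best_idx]),
    )


def select_features(
    table: FeatureTable,
    labels: Mapping[str, int] | pd.Series,
    alpha: float = 0.05,
    auc_margin: float = 0.05,
    exclude: Sequence[str] = (),
    cv: CVConfig | None = None,
    model_spec: ModelSpec | None = None,
) -> tuple[list[ScreenResult], SelectionTrace]:
    """Screen, enumerate the core, hill-climb: the full selection pipeline."""
    screen = screen_features(table, labels, alpha, auc_margin, exclude)
    passed = [r.feature_name for r in screen if r.passed]
    if not passed:
        raise ValueError("no features passed screening; relax alpha or auc_margin")
    core = enumerate_core(table, labels, passed, cv, model_spec)
    trace = hill_climb(
        table, labels, core, [f for f in passed if f not in core], cv, model_spec
    )
    return screen, trace
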