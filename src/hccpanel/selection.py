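"""Feature shortlisting, wrapper reduction and multi-classifier models.

The funnel mirrors a standard biomarker-panel workflow: rank core genes
by single-gene discriminative power, keep the top 10, re-score those by
10-fold cross-validated stump accuracy to keep the top 5, then shrink
5 → 4 → 3 by wrapper-based backward elimination — at each step every
leave-one-out subset is scored by mean 10-fold cross-validated AUROC of
a wrapped classifier and the best-scoring subset survives. Final
diagnosis models are trained per classifier family with a small grid
search scored by AUROC, and evaluated on held-out cohorts with the full
threshold-dependent metric suite plus a stratified-bootstrap AUROC CI.

All cross-validation is stratified with a fixed seed, so a full run is
reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .expression_io import TUMOR, ExpressionDataset
from .stump import MetricSet, confusion_from_predictions, metrics, auroc, stump_cv_metrics

MODEL_FAMILIES = (
    "extra_trees",
    "naive_bayes",
    "knn",
    "random_forest",
    "logistic_regression",
    "svc_rbf",
)

# Small, standard grids; AUROC-scored grid search picks within them.
_GRIDS: dict[str, dict] = {
    "extra_trees": {"n_estimators": [100, 500]},
    "random_forest": {"n_estimators": [100, 500]},
    "knn": {"n_neighbors": [3, 5, 7, 11]},
    "logistic_regression": {"C": [0.01, 0.1, 1, 10]},
    "svc_rbf": {"C": [0.1, 1, 10], "gamma": ["scale", 0.01, 0.1]},
    "naive_bayes": {},
}


def _make_estimator(family: str, seed: int):
    if family == "extra_trees":
        return ExtraTreesClassifier(random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if family == "knn":
        return KNeighborsClassifier()
    if family == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if family == "svc_rbf":
        return SVC(kernel="rbf", random_state=seed)
    if family == "naive_bayes":
        return GaussianNB()
    raise ValueError(f"unknown model family {family!r}; expected one of {MODEL_FAMILIES}")


@dataclass
class FeatureSubsetResult:
    """A feature subset with its cross-validated score and chosen params."""

    features: list[str]
    model_family: str
    cv_auroc_mean: float
    cv_auroc_sd: float
    selected_params: dict = field(default_factory=dict)
    estimator: object | None = None

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("feature subset may not be empty")
        if not 0.0 <= self.cv_auroc_mean <= 1.0:
            raise ValueError("cv_auroc_mean must lie in [0, 1]")


def _design(ds: ExpressionDataset, features: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    missing = [f for f in features if f not in ds.values.index]
    if missing:
        raise KeyError(f"{ds.cohort_id}: features absent from cohort: {missing}")
    X = ds.values.loc[list(features)].to_numpy().T  # samples × features
    y = (ds.labels.to_numpy() == TUMOR).astype(int)
    return X, y


def _cv(seed: int, n_splits: int = 10) -> StratifiedKFold:
    return StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)


def shortlist(
    ranked: pd.DataFrame,
    ds: ExpressionDataset,
    k10: int = 10,
    k5: int = 5,
    seed: int = 0,
    cv_folds: int = 10,
) -> list[str]:
    """Two-stage shortlist: top-k10 by training rank, then top-k5 by CV.

    Stage two re-scores the k10 survivors by mean stratified k-fold
    cross-validated stump accuracy and keeps the k5 best; ties fall back
    to the training-rank order, so the result is deterministic for a
    fixed seed.
    """
    if len(ranked) < k10:
        raise ValueError(f"ranking has {len(ranked)} genes; need at least k10={k10}")
    if k5 > k10:
        raise ValueError("k5 must not exceed k10")
    top10 = list(ranked["gene"].iloc[:k10])
    labels = ds.labels.to_numpy()
    cv_scores = {}
    for g in top10:
        cv = stump_cv_metrics(
            ds.values.loc[g].to_numpy(), labels, n_splits=cv_folds, seed=seed, gene=g
        )
        cv_scores[g] = cv.acc_pct
    train_rank = {g: i for i, g in enumerate(top10)}
    ordered = sorted(top10, key=lambda g: (-cv_scores[g], train_rank[g]))
    return ordered[:k5]


def _score_subset(
    subset: Sequence[str],
    ds: ExpressionDataset,
    family: str,
    seed: int,
    cv_folds: int,
) -> tuple[float, float]:
    X, y = _design(ds, subset)
    est = _make_estimator(family, seed)
    scores = cross_val_score(est, X, y, cv=_cv(seed, cv_folds), scoring="roc_auc")
    return float(scores.mean()), float(scores.std())


def wrapper_reduce(
    features: Sequence[str],
    ds: ExpressionDataset,
    model_family: str = "logistic_regression",
    target_size: int = 3,
    seed: int = 0,
    cv_folds: int = 10,
    audit_log: list | None = None,
) -> FeatureSubsetResult:
    """Greedy backward elimination down to ``target_size`` features.

    At each step every leave-one-out subset of the current feature set is
    scored by mean cross-validated AUROC of the wrapped classifier and
    the best survives (ties: fewer... same size, so alphabetical feature
    tuple). ``audit_log``, if given, collects every (subset, score) pair
    evaluated, which suffices to replay and audit the selection.
    """
    features = list(features)
    if not (len(features) > target_size >= 1):
        if len(features) == target_size:
            mean, sd = _score_subset(features, ds, model_family, seed, cv_folds)
            return FeatureSubsetResult(
                features=features, model_family=model_family,
                cv_auroc_mean=mean, cv_auroc_sd=sd,
            )
        raise ValueError("need |features| > target_size >= 1")
    current = features
    best_result: tuple[float, float, list[str]] | None = None
    while len(current) > target_size:
        candidates = []
        for drop in current:
            subset = [f for f in current if f != drop]
            mean, sd = _score_subset(subset, ds, model_family, seed, cv_folds)
            if audit_log is not None:
                audit_log.append({"subset": tuple(subset), "cv_auroc_mean": mean})
            candidates.append((mean, sd, subset))
        # max CV AUROC; deterministic alphabetical tie-break
        candidates.sort(key=lambda c: (-c[0], tuple(sorted(c[2]))))
        best = candidates[0]
        current = best[2]
        if len(current) == target_size:
            best_result = best
    assert best_result is not None
    mean, sd, subset = best_result
    return FeatureSubsetResult(
        features=subset, model_family=model_family,
        cv_auroc_mean=mean, cv_auroc_sd=sd,
    )


def train_models(
    ds: ExpressionDataset,
    features: Sequence[str],
    families: Sequence[str] = MODEL_FAMILIES,
    seed: int = 0,
    cv_folds: int = 10,
) -> dict[str, FeatureSubsetResult]:
    """Grid-searched, AUROC-scored classifier per family, refit on all data."""
    X, y = _design(ds, features)
    if len(np.unique(y)) < 2:
        raise ValueError("training cohort must contain both classes")
    out: dict[str, FeatureSubsetResult] = {}
    for family in families:
        grid = GridSearchCV(
            _make_estimator(family, seed),
            _GRIDS[family],
            scoring="roc_auc",
            cv=_cv(seed, cv_folds),
            refit=True,
        )
        grid.fit(X, y)
        sd = float(grid.cv_results_["std_test_score"][grid.best_index_])
        out[family] = FeatureSubsetResult(
            features=list(features),
            model_family=family,
            cv_auroc_mean=float(grid.best_score_),
            cv_auroc_sd=sd,
            selected_params=dict(grid.best_params_),
            estimator=grid.best_estimator_,
        )
    return out


def save_model_bundle(result: FeatureSubsetResult, path, seed: int = 0) -> None:
    """Serialize a trained model beside a provenance JSON.

    Writes ``<path>`` (joblib pickle of the estimator) and
    ``<path>.json`` carrying features, family, selected parameters, CV
    score and seed — enough to audit and re-apply the model.
    """
    import json
    from pathlib import Path

    import joblib

    if result.estimator is None:
        raise ValueError("no fitted estimator to save; run train_models first")
    path = Path(path)
    joblib.dump(result.estimator, path)
    provenance = {
        "features": result.features,
        "model_family": result.model_family,
        "selected_params": result.selected_params,
        "cv_auroc_mean": result.cv_auroc_mean,
        "cv_auroc_sd": result.cv_auroc_sd,
        "seed": seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(provenance, indent=1))


def load_model_bundle(path) -> FeatureSubsetResult:
    """Load a model bundle written by :func:`save_model_bundle`."""
    import json
    from pathlib import Path

    import joblib

    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FeatureSubsetResult(
        features=meta["features"],
        model_family=meta["model_family"],
        cv_auroc_mean=meta["cv_auroc_mean"],
        cv_auroc_sd=meta["cv_auroc_sd"],
        selected_params=meta["selected_params"],
        estimator=joblib.load(path),
    )


def _scores_of(estimator, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Continuous scores and the model's native decision threshold.

    Probabilistic models score with P(tumor) and cut at 0.5; margin
    models (SVC) score with the decision function and cut at 0.
    """
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, 1], 0.5
    return estimator.decision_function(X), 0.0


def evaluate_external(
    result: FeatureSubsetResult,
    ds_val: ExpressionDataset,
    threshold: float | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Held-out evaluation: metric suite + AUROC with bootstrap 95% CI.

    Class metrics cut the model's continuous scores at ``threshold``
    (default: the model's native decision threshold); the AUROC comes
    from the continuous scores, with a stratified bootstrap (resampling
    positives and negatives separately) percentile CI.
    """
    if result.estimator is None:
        raise ValueError("result carries no fitted estimator; run train_models first")
    X, y = _design(ds_val, result.features)
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise ValueError(f"{ds_val.cohort_id}: evaluation needs both classes")
    scores, native_threshold = _scores_of(result.estimator, X)
    if threshold is None:
        threshold = native_threshold
    predicted = np.where(scores > threshold, TUMOR, "normal")
    labels = ds_val.labels.to_numpy()
    cm = confusion_from_predictions(predicted, labels)
    m = metrics(cm)
    m.auroc = auroc(scores, labels)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(pos_idx, size=len(pos_idx), replace=True),
                rng.choice(neg_idx, size=len(neg_idx), replace=True),
            ]
        )
        boot[b] = auroc(scores[idx], labels[idx])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return {
        "metrics": m,
        "confusion": cm,
        "auroc_ci": (float(lo), float(hi)),
        "cohort_id": ds_val.cohort_id,
        "model_family": result.model_family,
    }
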