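"""Single-gene threshold classifiers, the confusion-matrix metric suite,
AUROC, and gene ranking.

A *stump* classifies a sample from one gene's expression and a learned
threshold, respecting the gene's regulation direction: for an
up-regulated gene, expression strictly above the threshold predicts
cancer; for a down-regulated gene, expression strictly above the
threshold predicts normal. Samples exactly at the threshold fall on the
normal-for-up / cancer-for-down side, i.e. only strict exceedance counts
as "above".

Fitting is an exhaustive search over the finite set of thresholds that
can change the training predictions: the midpoints of consecutive sorted
unique expression values, plus −∞/+∞ sentinels (predict-all /
predict-none). The objective is training accuracy, with ties broken by
higher Matthews correlation and then by the lower threshold, which makes
the fit deterministic.

Threshold-dependent performance is summarized by sensitivity,
specificity, accuracy (as percentages) and the Matthews correlation
coefficient; the threshold-independent summary is the AUROC, computed
from the direction-oriented raw expression (not the binary stump
output), which equals the Mann–Whitney probability that a positive
outscores a negative (ties counted half).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .expression_io import NORMAL, TUMOR, ExpressionDataset

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class StumpModel:
    """Direction-aware single-gene threshold classifier."""

    gene: str
    threshold: float
    direction: str  # "up": expression > threshold predicts cancer
    degenerate: bool = False  # constant training expression; majority-class rule

    def predict(self, expr: Sequence[float]) -> np.ndarray:
        """Class labels ("tumor"/"normal") for an expression vector."""
        expr = np.asarray(expr, dtype=float)
        above = expr > self.threshold
        cancer = above if self.direction == UP else ~above
        return np.where(cancer, TUMOR, NORMAL)

    def scores(self, expr: Sequence[float]) -> np.ndarray:
        """Direction-oriented continuous scores (higher = more cancer-like)."""
        expr = np.asarray(expr, dtype=float)
        return expr if self.direction == UP else -expr


@dataclass
class MetricSet:
    """Sens/Spec/Acc percentages, MCC, and (optionally) AUROC."""

    sens_pct: float
    spec_pct: float
    acc_pct: float
    mcc: float
    auroc: float | None = None


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Threshold-dependent metric suite from a confusion matrix.

    Sens = TP/(TP+FN)·100, Spec = TN/(TN+FP)·100,
    Acc = (TP+TN)/total·100,
    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN));
    a zero factor in the MCC denominator gives MCC = 0 by convention.
    """
    if cm.n_pos == 0 or cm.n_neg == 0:
        raise ValueError("metrics need at least one positive and one negative")
    sens = 100.0 * cm.tp / cm.n_pos
    spec = 100.0 * cm.tn / cm.n_neg
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    denom_factors = [cm.tp + cm.fp, cm.tp + cm.fn, cm.tn + cm.fp, cm.tn + cm.fn]
    if 0 in denom_factors:
        mcc = 0.0
    else:
        num = float(cm.tp) * cm.tn - float(cm.fp) * cm.fn
        mcc = num / float(np.sqrt(np.prod([float(f) for f in denom_factors])))
    return MetricSet(sens_pct=sens, spec_pct=spec, acc_pct=acc, mcc=mcc)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def reconstruct_confusion(
    sens_pct: float, spec_pct: float, n_pos: int, n_neg: int
) -> ConfusionMatrix:
    """Integer confusion matrix back-computed from printed Sens/Spec.

    TP = round(sens·n_pos/100), TN = round(spec·n_neg/100) with
    round-half-away-from-zero; FN/FP by complement. Lets printed
    performance rows be re-audited exactly.
    """
    if not (0 <= sens_pct <= 100 and 0 <= spec_pct <= 100):
        raise ValueError("percentages must lie in [0, 100]")
    tp = _round_half_away(sens_pct * n_pos / 100.0)
    tn = _round_half_away(spec_pct * n_neg / 100.0)
    return ConfusionMatrix(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


def confusion_from_predictions(
    predicted: Sequence[str], labels: Sequence[str]
) -> ConfusionMatrix:
    predicted = np.asarray(predicted)
    labels = np.asarray(labels)
    pos = labels == TUMOR
    pred_pos = predicted == TUMOR
    return ConfusionMatrix(
        tp=int(np.sum(pos & pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


def _candidate_thresholds(expr: np.ndarray) -> np.ndarray:
    u = np.unique(expr)
    mids = (u[:-1] + u[1:]) / 2.0 if len(u) > 1 else np.empty(0)
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _evaluate_direction(
    expr: np.ndarray, pos: np.ndarray, direction: str
) -> tuple[float, float, float]:
    """Best (acc, mcc, threshold) over the full candidate grid.

    Vectorized over thresholds: for each candidate t, TP/FP follow from
    how many positives/negatives lie strictly above t, obtained from the
    sorted arrays via searchsorted.
    """
    thresholds = _candidate_thresholds(expr)
    pos_sorted = np.sort(expr[pos])
    neg_sorted = np.sort(expr[~pos])
    n_pos, n_neg = len(pos_sorted), len(neg_sorted)
    pos_above = n_pos - np.searchsorted(pos_sorted, thresholds, side="right")
    neg_above = n_neg - np.searchsorted(neg_sorted, thresholds, side="right")
    if direction == UP:
        tp, fp = pos_above, neg_above
    else:
        tp, fp = n_pos - pos_above, n_neg - neg_above
    tn = n_neg - fp
    fn = n_pos - tp
    acc = (tp + tn) / (n_pos + n_neg)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(
            (tp + fp).astype(float) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        mcc = np.where(denom > 0, (tp * tn - fp.astype(float) * fn) / np.where(denom > 0, denom, 1.0), 0.0)
    # lexicographic argmax: accuracy, then MCC, then lower threshold
    best = 0
    for i in range(1, len(thresholds)):
        if (acc[i], mcc[i]) > (acc[best], mcc[best]):
            best = i
    return float(acc[best]), float(mcc[best]), float(thresholds[best])


def fit_stump(
    expr: Sequence[float],
    labels: Sequence[str],
    direction: str = "auto",
    gene: str = "",
) -> StumpModel:
    """Fit the accuracy-maximizing threshold for one gene.

    ``direction="auto"`` tries both orientations and keeps the better
    (ties: higher MCC, then the orientation matching the sign of the
    tumor-minus-normal mean difference). Constant expression yields a
    degenerate majority-class model, flagged as such.
    """
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels)
    pos = labels == TUMOR
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ValueError("fit_stump needs both classes present")
    if len(np.unique(expr)) == 1:
        majority_tumor = pos.sum() >= (~pos).sum()
        # -inf threshold predicts everything cancer under "up"
        return StumpModel(
            gene=gene,
            threshold=-np.inf if majority_tumor else np.inf,
            direction=UP,
            degenerate=True,
        )
    mean_diff = expr[pos].mean() - expr[~pos].mean()
    if direction in (UP, DOWN):
        acc, mcc, thr = _evaluate_direction(expr, pos, direction)
        return StumpModel(gene=gene, threshold=thr, direction=direction)
    res = {d: _evaluate_direction(expr, pos, d) for d in (UP, DOWN)}
    key_up = (res[UP][0], res[UP][1])
    key_down = (res[DOWN][0], res[DOWN][1])
    if key_up > key_down:
        d = UP
    elif key_down > key_up:
        d = DOWN
    else:
        d = UP if mean_diff >= 0 else DOWN
    return StumpModel(gene=gene, threshold=res[d][2], direction=d)


def auroc(
    scores: Sequence[float], labels: Sequence[str], direction: str = UP
) -> float:
    """Area under the ROC curve of continuous scores.

    Equals the Mann–Whitney probability P(score_pos > score_neg) +
    ½·P(tie). For a down-regulated gene the scores are negated first so
    the AUROC reflects the gene's discriminative orientation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels == TUMOR
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValueError("auroc needs both classes present")
    oriented = scores if direction == UP else -scores
    return float(roc_auc_score(y, oriented))


def stump_metrics(
    model: StumpModel, expr: Sequence[float], labels: Sequence[str]
) -> MetricSet:
    """Full MetricSet (incl. AUROC from oriented raw expression)."""
    cm = confusion_from_predictions(model.predict(expr), labels)
    m = metrics(cm)
    m.auroc = auroc(expr, labels, model.direction)
    return m


def stump_cv_metrics(
    expr: Sequence[float],
    labels: Sequence[str],
    n_splits: int = 10,
    seed: int = 0,
    gene: str = "",
) -> MetricSet:
    """Mean stratified k-fold cross-validated stump performance."""
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels)
    y = (labels == TUMOR).astype(int)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accs, sens, specs, mccs, aucs = [], [], [], [], []
    for train, test in skf.split(expr.reshape(-1, 1), y):
        model = fit_stump(expr[train], labels[train], gene=gene)
        cm = confusion_from_predictions(model.predict(expr[test]), labels[test])
        if cm.n_pos == 0 or cm.n_neg == 0:
            continue
        m = metrics(cm)
        accs.append(m.acc_pct)
        sens.append(m.sens_pct)
        specs.append(m.spec_pct)
        mccs.append(m.mcc)
        aucs.append(auroc(expr[test], labels[test], model.direction))
    return MetricSet(
        sens_pct=float(np.mean(sens)),
        spec_pct=float(np.mean(specs)),
        acc_pct=float(np.mean(accs)),
        mcc=float(np.mean(mccs)),
        auroc=float(np.mean(aucs)),
    )


def rank_genes(
    ds: ExpressionDataset,
    genes: Sequence[str],
    cv_folds: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit one stump per gene and rank by discriminative power.

    Ranking order: training accuracy desc, MCC desc, AUROC desc, gene id.
    With ``cv_folds`` set, mean cross-validated metrics are appended as
    ``cv_*`` columns (the ranking stays on the full-data fit).
    """
    labels = ds.labels.to_numpy()
    rows = []
    for g in genes:
        expr = ds.values.loc[g].to_numpy()
        model = fit_stump(expr, labels, gene=g)
        m = stump_metrics(model, expr, labels)
        pos = labels == TUMOR
        row = {
            "gene": g,
            "threshold": model.threshold,
            "direction": model.direction,
            "sens_pct": m.sens_pct,
            "spec_pct": m.spec_pct,
            "acc_pct": m.acc_pct,
            "mcc": m.mcc,
            "auroc": m.auroc,
            "mean_tumor": float(expr[pos].mean()),
            "mean_normal": float(expr[~pos].mean()),
            "mean_diff": float(expr[pos].mean() - expr[~pos].mean()),
            "model": model,
        }
        if cv_folds:
            cv = stump_cv_metrics(expr, labels, n_splits=cv_folds, seed=seed, gene=g)
            row.update(
                cv_acc_pct=cv.acc_pct, cv_mcc=cv.mcc, cv_auroc=cv.auroc,
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["acc_pct", "mcc", "auroc", "gene"],
        ascending=[False, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return table


def ranking_to_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Printable ranking table (drops the model objects)."""
    cols = [
        "gene", "threshold", "sens_pct", "spec_pct", "acc_pct", "mcc",
        "auroc", "mean_tumor", "mean_normal", "mean_diff",
    ]
    extra = [c for c in table.columns if c.startswith("cv_")]
    return table[cols + extra].copy()
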