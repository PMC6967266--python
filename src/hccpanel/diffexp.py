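"""Per-cohort two-group differential expression with Bonferroni control.

Unpaired cohorts use Welch's unequal-variance t-test; paired cohorts use
the Wilcoxon signed-rank test on within-pair differences. All tests are
two-sided. Family-wise error is controlled per cohort by Bonferroni over
the genes actually tested in that cohort, and a gene is called
differentially expressed when its adjusted p falls below ``alpha``
(default 0.01). Direction is the sign of the tumor-minus-normal mean
difference on the log2 scale.

Degenerate genes (zero variance in both groups) get p = 1 and are never
significant, so NaNs cannot propagate downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import NORMAL, TUMOR, ExpressionDataset

UP = "up"
DOWN = "down"

DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression call in one cohort."""

    gene: str
    p_raw: float
    p_adj: float
    mean_tumor: float
    mean_normal: float
    mean_diff: float  # tumor − normal, log2 units
    direction: str  # "up" iff mean_diff > 0
    significant: bool
    test_used: str  # "welch" | "wilcoxon_paired"
    cohort_id: str = ""


def welch_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Degrees of freedom by Welch–Satterthwaite. Both groups constant and
    equal → (0, 1) by convention; both constant but unequal → p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_test needs at least 2 observations per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return np.inf if x.mean() > y.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def wilcoxon_paired_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped first. Exact null distribution for
    n ≤ 25 remaining pairs, normal approximation with continuity
    correction above. All differences zero → (0, 1) by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired test requires equal-length vectors")
    d = x - y
    nz = d[d != 0]
    if len(nz) == 0:
        return 0.0, 1.0
    if len(nz) < 5:
        raise ValueError("need at least 5 nonzero differences for the signed-rank test")
    method = "exact" if len(nz) <= 25 else "approx"
    res = stats.wilcoxon(nz, method=method, correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)


def bonferroni(p: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, p * m)`` elementwise.

    ``m`` defaults to the number of p-values, i.e. the genes tested in
    the cohort at hand.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    return np.minimum(1.0, p * m)


def _vectorized_pvalues(ds: ExpressionDataset, paired: bool) -> tuple[np.ndarray, str]:
    tumor = ds.class_matrix(TUMOR).to_numpy()
    normal_df = ds.class_matrix(NORMAL)
    if paired:
        # align the normal columns to their tumor partners
        order = [ds.pairing[s] for s in ds.samples_of(TUMOR)]
        normal = ds.values[order].to_numpy()
        d = tumor - normal
        n_nz = (d != 0).sum(axis=1)
        p = np.ones(d.shape[0])
        ok = n_nz >= 5
        if ok.any():
            method = "exact" if d.shape[1] <= 25 else "approx"
            res = stats.wilcoxon(
                d[ok], axis=1, method=method, correction=(method == "approx")
            )
            p[ok] = np.atleast_1d(res.pvalue)
        return p, "wilcoxon_paired"
    normal = normal_df.to_numpy()
    var_t = tumor.var(axis=1, ddof=1)
    var_n = normal.var(axis=1, ddof=1)
    degenerate = (var_t == 0) & (var_n == 0)
    p = np.ones(tumor.shape[0])
    ok = ~degenerate
    if ok.any():
        res = stats.ttest_ind(tumor[ok], normal[ok], axis=1, equal_var=False)
        p[ok] = np.atleast_1d(res.pvalue)
    # constant-but-unequal genes: zero-variance convention is p = 1 (never
    # significant) to avoid spurious infinite t statistics
    p[degenerate] = 1.0
    return np.nan_to_num(p, nan=1.0), "welch"


def call_degs(
    ds: ExpressionDataset,
    alpha: float = DEFAULT_ALPHA,
    paired: bool | None = None,
) -> list[DEGRecord]:
    """Differential-expression calls for every gene of one cohort.

    The paired signed-rank test is chosen automatically when pairing
    metadata is present; ``paired`` overrides the choice per cohort.
    Output is ordered by gene id.
    """
    if paired is None:
        paired = ds.is_paired
    if paired and not ds.is_paired:
        raise ValueError(f"{ds.cohort_id}: paired test requested without pairing info")
    n_t = len(ds.samples_of(TUMOR))
    n_n = len(ds.samples_of(NORMAL))
    if n_t < 2 or n_n < 2:
        raise ValueError(
            f"{ds.cohort_id}: need ≥2 samples per class (tumor={n_t}, normal={n_n})"
        )
    p_raw, test_used = _vectorized_pvalues(ds, paired)
    p_adj = bonferroni(p_raw)
    mean_t = ds.class_matrix(TUMOR).mean(axis=1)
    mean_n = ds.class_matrix(NORMAL).mean(axis=1)
    records = []
    for i, gene in enumerate(ds.gene_ids):
        diff = float(mean_t.iloc[i] - mean_n.iloc[i])
        records.append(
            DEGRecord(
                gene=gene,
                p_raw=float(p_raw[i]),
                p_adj=float(p_adj[i]),
                mean_tumor=float(mean_t.iloc[i]),
                mean_normal=float(mean_n.iloc[i]),
                mean_diff=diff,
                direction=UP if diff > 0 else DOWN,
                significant=bool(p_adj[i] < alpha),
                test_used=test_used,
                cohort_id=ds.cohort_id,
            )
        )
    records.sort(key=lambda r: r.gene)
    return records


def degs_to_frame(records: Sequence[DEGRecord]) -> pd.DataFrame:
    """Per-cohort DEG table (gene, p_raw, p_adj, means, direction, flag)."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "mean_tumor": r.mean_tumor,
                "mean_normal": r.mean_normal,
                "mean_diff": r.mean_diff,
                "direction": r.direction,
                "significant": r.significant,
            }
            for r in records
        ]
    )


def write_degs(records: Sequence[DEGRecord], path: str | Path) -> None:
    degs_to_frame(records).to_csv(path, sep="\t", index=False)
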