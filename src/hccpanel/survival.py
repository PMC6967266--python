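"""Prognostic evaluation: dichotomization, Kaplan–Meier / log-rank, Cox.

Patients are split into high/low expression groups at the cohort mean of
a gene (strictly greater than the mean counts as high), the two risk
groups are compared with the log-rank test and visualized as Kaplan–Meier
curves, and hazard ratios come from Cox proportional-hazards fits —
univariate per variable, then a joint multivariate model over the
variables that passed the univariate screen at p < 0.05. Tied event
times are handled with the Efron approximation (lifelines' default, and
the standard of the R survival ecosystem). Missing covariate values are
dropped complete-case per model and the retained count is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

ENDPOINTS = ("OS", "DSS", "DFS", "PFS", "RFS")

ALPHA = 0.05  # significance cut-off used throughout survival analyses


@dataclass
class SurvivalTable:
    """Per-patient time/event for one endpoint plus covariates.

    ``data`` is indexed by patient id and must contain ``time`` (>= 0) and
    ``event`` (0/1); remaining columns are covariates (age, gender, stage,
    gene expression values, dichotomized group labels, ...).
    """

    data: pd.DataFrame
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}; expected one of {ENDPOINTS}")
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"survival table lacks required column {col!r}")
        if (self.data["time"] < 0).any():
            raise ValueError("negative survival times")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event must be coded 0/1")

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())


@dataclass
class SurvivalResult:
    """Hazard ratio with Wald 95% CI and p for one variable."""

    variable: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int = 0
    n_events: int = 0
    n_high: int | None = None
    n_low: int | None = None
    converged: bool = True

    @property
    def significant(self) -> bool:
        return self.converged and self.p < ALPHA


def dichotomize_by_mean(expr: pd.Series | np.ndarray) -> pd.Series:
    """Split patients at the mean: strictly above → ``high``, else ``low``."""
    s = pd.Series(expr) if not isinstance(expr, pd.Series) else expr
    if len(s) < 2:
        raise ValueError("need at least 2 patients to dichotomize")
    if s.nunique() == 1:
        raise ValueError("constant expression cannot be dichotomized")
    groups = pd.Series(np.where(s > s.mean(), "high", "low"), index=s.index)
    if groups.nunique() < 2:
        raise ValueError("dichotomization produced an empty group")
    return groups


def km_logrank(
    groups: pd.Series | Sequence[str],
    times: Sequence[float],
    events: Sequence[int],
) -> tuple[float, float, dict[str, KaplanMeierFitter]]:
    """Two-group log-rank test plus per-group Kaplan–Meier estimates.

    Returns ``(chi2, p, curves)`` where ``curves`` maps group label to a
    fitted :class:`lifelines.KaplanMeierFitter`.
    """
    groups = pd.Series(np.asarray(groups))
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    masks = {g: (groups == g).to_numpy() for g in labels}
    for g, m in masks.items():
        if m.sum() == 0:
            raise ValueError(f"group {g!r} has zero patients")
    if events.sum() == 0:
        raise ValueError("no events observed in either group")
    res = logrank_test(
        times[masks[labels[0]]],
        times[masks[labels[1]]],
        event_observed_A=events[masks[labels[0]]],
        event_observed_B=events[masks[labels[1]]],
    )
    curves = {}
    for g in labels:
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(times[masks[g]], events[masks[g]])
        curves[g] = kmf
    return float(res.test_statistic), float(res.p_value), curves


def _encode(frame: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding for the Cox design matrix (gender M=1/F=0)."""
    out = frame.copy()
    for col in out.columns:
        if out[col].dtype == object:
            uniq = set(out[col].dropna().unique())
            if uniq <= {"M", "F"}:
                out[col] = (out[col] == "M").astype(float)
            elif uniq <= {"high", "low"}:
                out[col] = (out[col] == "high").astype(float)
            else:
                raise ValueError(f"cannot encode non-numeric covariate {col!r}: {uniq}")
    return out.astype(float)


def _fit_cox(df: pd.DataFrame, variables: list[str]) -> tuple[CoxPHFitter | None, pd.DataFrame]:
    """Complete-case Efron-tie Cox fit; returns (fitter or None, used rows)."""
    used = df[["time", "event"] + variables].dropna()
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(used, duration_col="time", event_col="event")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return None, used
    return cph, used


def cox_univariate(
    variable: str,
    table: SurvivalTable,
    min_events: int = 10,
) -> SurvivalResult:
    """Single-covariate proportional-hazards fit.

    HR = exp(coef) per unit of the variable (or for the indicated level of
    a binary variable); Wald 95% CI and p. A monotone-likelihood
    non-convergence is reported as a flagged result with infinite CI
    bounds rather than raised.
    """
    df = _encode(table.data[[variable]]).join(table.data[["time", "event"]])
    if df[variable].nunique(dropna=True) <= 1:
        raise ValueError(f"variable {variable!r} is constant")
    if table.n_events < min_events:
        warnings.warn(
            f"only {table.n_events} events; Cox estimates may be unstable", stacklevel=2
        )
    extra: dict = {}
    if table.data[variable].dtype == object and set(
        table.data[variable].dropna().unique()
    ) <= {"high", "low"}:
        extra["n_high"] = int((table.data[variable] == "high").sum())
        extra["n_low"] = int((table.data[variable] == "low").sum())
    cph, used = _fit_cox(df, [variable])
    if cph is None:
        return SurvivalResult(
            variable=variable, hr=np.inf, ci_low=0.0, ci_high=np.inf, p=np.nan,
            n=len(used), n_events=int(used["event"].sum()), converged=False, **extra,
        )
    s = cph.summary.loc[variable]
    return SurvivalResult(
        variable=variable,
        hr=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        p=float(s["p"]),
        n=len(used),
        n_events=int(used["event"].sum()),
        **extra,
    )


def cox_multivariate(
    variables: Sequence[str],
    table: SurvivalTable,
) -> list[SurvivalResult]:
    """Joint proportional-hazards fit over several variables.

    Collinear inputs are rejected up front with the offending pair named.
    Returns one adjusted :class:`SurvivalResult` per variable.
    """
    variables = list(variables)
    df = _encode(table.data[variables]).join(table.data[["time", "event"]])
    used = df.dropna()
    X = used[variables].to_numpy()
    corr = np.corrcoef(X, rowvar=False) if len(variables) > 1 else np.ones((1, 1))
    for i in range(len(variables)):
        for j in range(i + 1, len(variables)):
            if abs(corr[i, j]) > 1 - 1e-10:
                raise ValueError(
                    f"collinear covariates: {variables[i]!r} and {variables[j]!r}"
                )
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < len(variables):
        raise ValueError(f"covariates {variables} are not jointly full-rank")
    events_per_var = used["event"].sum() / len(variables)
    if events_per_var < 10:
        warnings.warn(
            f"{events_per_var:.1f} events per variable (<10); estimates may be unstable",
            stacklevel=2,
        )
    cph, used = _fit_cox(df, variables)
    results = []
    for v in variables:
        if cph is None:
            results.append(
                SurvivalResult(
                    variable=v, hr=np.inf, ci_low=0.0, ci_high=np.inf, p=np.nan,
                    n=len(used), n_events=int(used["event"].sum()), converged=False,
                )
            )
            continue
        s = cph.summary.loc[v]
        results.append(
            SurvivalResult(
                variable=v,
                hr=float(s["exp(coef)"]),
                ci_low=float(s["exp(coef) lower 95%"]),
                ci_high=float(s["exp(coef) upper 95%"]),
                p=float(s["p"]),
                n=len(used),
                n_events=int(used["event"].sum()),
            )
        )
    return results


def prognostic_analysis(
    table: SurvivalTable,
    genes: Sequence[str],
    clinical: Sequence[str] = ("age", "gender", "stage"),
) -> dict:
    """Full prognostic workflow for one endpoint.

    1. Dichotomize each gene at its cohort mean and run KM + log-rank.
    2. Univariate Cox per dichotomized gene and per clinical covariate.
    3. Multivariate Cox restricted to univariately significant variables
       (p < 0.05); skipped when fewer than two variables qualify.
    """
    df = table.data.copy()
    km_results = {}
    for g in genes:
        groups = dichotomize_by_mean(df[g])
        df[f"{g}_group"] = groups
        chi2, p, curves = km_logrank(groups, df["time"], df["event"])
        km_results[g] = {"chi2": chi2, "p": p, "curves": curves}
    enriched = SurvivalTable(data=df, endpoint=table.endpoint)
    uni: list[SurvivalResult] = []
    for g in genes:
        uni.append(cox_univariate(f"{g}_group", enriched))
    for c in clinical:
        if c in df.columns and df[c].nunique(dropna=True) > 1:
            uni.append(cox_univariate(c, enriched))
    significant = [r.variable for r in uni if r.significant]
    multi = cox_multivariate(significant, enriched) if len(significant) >= 2 else []
    return {
        "endpoint": table.endpoint,
        "km": km_results,
        "univariate": uni,
        "multivariate": multi,
        "multivariate_variables": significant,
    }


def plot_km(
    curves: dict[str, KaplanMeierFitter],
    path,
    title: str = "",
    p_value: float | None = None,
) -> None:
    """Write a Kaplan–Meier plot of the fitted risk-group curves to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, kmf in sorted(curves.items()):
        kmf.plot_survival_function(ax=ax, ci_show=True)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    if p_value is not None:
        ax.text(0.6, 0.9, f"log-rank p = {p_value:.2g}", transform=ax.transAxes)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def results_to_frame(results: Sequence[SurvivalResult]) -> pd.DataFrame:
    """Tabulate SurvivalResults (HR, 95% CI, p) for TSV export."""
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "HR": r.hr,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "n": r.n,
                "n_events": r.n_events,
                "n_high": r.n_high,
                "n_low": r.n_low,
                "converged": r.converged,
            }
            for r in results
        ]
    )
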