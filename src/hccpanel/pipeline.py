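"""End-to-end orchestration: ingest → DEG → consensus → rank → select →
train → evaluate (→ survival), with config, logging and report tables.

A run is described by a :class:`RunConfig`: a cohort manifest assigning
each cohort a role (``discovery`` cohorts vote in the consensus,
exactly one ``training`` cohort drives ranking/selection/model fitting,
``validation`` cohorts are only ever touched in the final evaluation
stage), plus the thresholds of the analysis (alpha, consensus fraction,
shortlist sizes, panel size) and a seed. Every report table is written
as TSV and stamped (in the run metadata) with a hash of the resolved
configuration, so a rerun with the same config and seed reproduces the
tables byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .consensus import build_consensus, consensus_to_frame, select_core_genes
from .diffexp import call_degs, degs_to_frame
from .expression_io import ExpressionDataset, intersect_common_genes, read_dataset
from .selection import (
    MODEL_FAMILIES,
    evaluate_external,
    shortlist,
    train_models,
    wrapper_reduce,
)
from .stump import rank_genes, ranking_to_frame

log = logging.getLogger("hccpanel.pipeline")

ROLES = ("discovery", "training", "validation")


@dataclass
class CohortEntry:
    """Manifest entry for one cohort: where it lives and what it is for."""

    cohort_id: str
    role: str
    matrix: str | None = None
    labels: str | None = None
    pairing: str | None = None
    paired: bool | None = None  # override automatic paired-test choice
    platform_tag: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"{self.cohort_id}: unknown role {self.role!r}")


@dataclass
class RunConfig:
    cohorts: list[CohortEntry]
    alpha: float = 0.01
    min_sig_frac: float = 0.80
    k10: int = 10
    k5: int = 5
    panel_size: int = 3
    model_families: tuple[str, ...] = MODEL_FAMILIES
    wrapper_family: str = "logistic_regression"
    cv_folds: int = 10
    seed: int = 0
    outdir: str | None = None
    # optional prognostic stage: {"clinical": <TSV path>, "endpoint": "OS"}
    # run on the final panel genes after evaluation
    survival: dict | None = None

    def __post_init__(self) -> None:
        roles = [c.role for c in self.cohorts]
        if roles.count("training") != 1:
            raise ValueError(
                f"config must name exactly one training cohort (got {roles.count('training')})"
            )
        if roles.count("discovery") == 0:
            raise ValueError("config must name at least one discovery cohort")
        ids = [c.cohort_id for c in self.cohorts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cohort ids in manifest (roles must be disjoint)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.min_sig_frac <= 1:
            raise ValueError("min_sig_frac must lie in (0, 1]")
        if not (self.k10 >= self.k5 >= self.panel_size >= 1):
            raise ValueError("need k10 >= k5 >= panel_size >= 1")

    def by_role(self, role: str) -> list[CohortEntry]:
        return [c for c in self.cohorts if c.role == role]

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = asdict(self)
        payload.pop("outdir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    cohorts = [CohortEntry(**c) for c in raw.pop("cohorts")]
    if "model_families" in raw:
        raw["model_families"] = tuple(raw["model_families"])
    return RunConfig(cohorts=cohorts, **raw)


def _load(entry: CohortEntry) -> ExpressionDataset:
    if entry.matrix is None or entry.labels is None:
        raise ValueError(f"{entry.cohort_id}: manifest entry lacks matrix/labels paths")
    return read_dataset(
        entry.matrix, entry.labels, cohort_id=entry.cohort_id,
        pairing_path=entry.pairing, platform_tag=entry.platform_tag,
    )


class _Stage:
    """Context manager logging wall-time and bookkeeping per stage."""

    def __init__(self, report: dict, name: str) -> None:
        self.report, self.name = report, name

    def __enter__(self):
        log.info("stage %s: start", self.name)
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        self.report.setdefault("stage_seconds", {})[self.name] = round(dt, 3)
        if exc_type is not None:
            log.error("stage %s: failed (%s)", self.name, exc)
            return False
        log.info("stage %s: done in %.2fs", self.name, dt)
        return False


def run_pipeline(
    cfg: RunConfig,
    datasets: Mapping[str, ExpressionDataset] | None = None,
) -> dict:
    """Execute the full discovery → diagnosis → evaluation chain.

    ``datasets`` may inject in-memory cohorts keyed by cohort id (e.g.
    simulator output); otherwise cohorts are read from the manifest
    paths. Validation cohorts are not loaded or touched before the
    evaluation stage. Raises from the failing stage with the stage name
    and cohort id in the message.
    """
    report: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
    }

    def get(entry: CohortEntry) -> ExpressionDataset:
        if datasets is not None and entry.cohort_id in datasets:
            return datasets[entry.cohort_id]
        return _load(entry)

    with _Stage(report, "ingest"):
        discovery = [get(e) for e in cfg.by_role("discovery")]
        training_entry = cfg.by_role("training")[0]
        training = get(training_entry)
        # validation cohorts stay untouched until the evaluation stage
        report["n_discovery"] = len(discovery)
        report["n_training_samples"] = training.n_samples

    with _Stage(report, "intersect"):
        common = intersect_common_genes(discovery + [training])
        report["n_common_genes"] = len(common)
        discovery = [ds.subset_genes(common) for ds in discovery]
        training = training.subset_genes(common)

    with _Stage(report, "diffexp"):
        records_by_cohort = {}
        for entry, ds in zip(cfg.by_role("discovery"), discovery):
            records_by_cohort[ds.cohort_id] = call_degs(
                ds, alpha=cfg.alpha, paired=entry.paired
            )

    with _Stage(report, "consensus"):
        summaries = build_consensus(records_by_cohort)
        core = select_core_genes(summaries, min_sig_frac=cfg.min_sig_frac)
        report["core_genes"] = core
        if len(core) < cfg.k10:
            raise RuntimeError(
                f"consensus selected only {len(core)} core genes; "
                f"need at least k10={cfg.k10} to rank"
            )

    with _Stage(report, "rank"):
        ranking = rank_genes(training, core, seed=cfg.seed)

    with _Stage(report, "select"):
        top5 = shortlist(
            ranking, training, k10=cfg.k10, k5=cfg.k5,
            seed=cfg.seed, cv_folds=cfg.cv_folds,
        )
        audit: list = []
        panel_result = wrapper_reduce(
            top5, training, model_family=cfg.wrapper_family,
            target_size=cfg.panel_size, seed=cfg.seed,
            cv_folds=cfg.cv_folds, audit_log=audit,
        )
        report["shortlist"] = top5
        report["panel"] = panel_result.features
        report["panel_cv_auroc"] = panel_result.cv_auroc_mean
        report["wrapper_audit"] = audit

    with _Stage(report, "train"):
        models = train_models(
            training, panel_result.features,
            families=cfg.model_families, seed=cfg.seed, cv_folds=cfg.cv_folds,
        )
        report["models"] = {
            fam: {
                "cv_auroc_mean": r.cv_auroc_mean,
                "cv_auroc_sd": r.cv_auroc_sd,
                "params": r.selected_params,
            }
            for fam, r in models.items()
        }

    with _Stage(report, "evaluate"):
        evaluations = []
        for entry in cfg.by_role("validation"):
            ds_val = get(entry).subset_genes(panel_result.features)
            for fam, result in models.items():
                ev = evaluate_external(
                    result, ds_val, seed=cfg.seed, n_boot=500,
                )
                m = ev["metrics"]
                evaluations.append(
                    {
                        "cohort_id": ds_val.cohort_id,
                        "model_family": fam,
                        "sens_pct": m.sens_pct,
                        "spec_pct": m.spec_pct,
                        "acc_pct": m.acc_pct,
                        "mcc": m.mcc,
                        "auroc": m.auroc,
                        "auroc_ci_low": ev["auroc_ci"][0],
                        "auroc_ci_high": ev["auroc_ci"][1],
                    }
                )
        report["evaluations"] = evaluations

    if cfg.survival:
        with _Stage(report, "survival"):
            from .survival import SurvivalTable, prognostic_analysis, results_to_frame

            clin = pd.read_csv(cfg.survival["clinical"], sep="\t", index_col=0)
            table = SurvivalTable(
                data=clin, endpoint=cfg.survival.get("endpoint", "OS")
            )
            panel_in_table = [
                g for g in panel_result.features if g in clin.columns
            ]
            if not panel_in_table:
                raise RuntimeError(
                    "survival stage: no panel gene has an expression column "
                    "in the clinical table"
                )
            prog = prognostic_analysis(table, panel_in_table)
            report["survival"] = {
                "endpoint": prog["endpoint"],
                "km_logrank_p": {g: r["p"] for g, r in prog["km"].items()},
                "univariate": results_to_frame(prog["univariate"]),
                "multivariate": results_to_frame(prog["multivariate"]),
            }

    if cfg.outdir:
        with _Stage(report, "write"):
            outdir = Path(cfg.outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            consensus_to_frame(summaries).to_csv(
                outdir / "consensus.tsv", sep="\t", index=False
            )
            ranking_to_frame(ranking).to_csv(
                outdir / "ranking.tsv", sep="\t", index=False
            )
            for cid, recs in records_by_cohort.items():
                degs_to_frame(recs).to_csv(
                    outdir / f"degs.{cid}.tsv", sep="\t", index=False
                )
            pd.DataFrame(evaluations).to_csv(
                outdir / "evaluation.tsv", sep="\t", index=False
            )
            if "survival" in report:
                report["survival"]["univariate"].to_csv(
                    outdir / "survival_univariate.tsv", sep="\t", index=False
                )
                report["survival"]["multivariate"].to_csv(
                    outdir / "survival_multivariate.tsv", sep="\t", index=False
                )
            meta = {
                "config_hash": report["config_hash"],
                "seed": cfg.seed,
                "n_common_genes": report["n_common_genes"],
                "core_genes": core,
                "shortlist": top5,
                "panel": panel_result.features,
                "models": report["models"],
            }
            (outdir / "run_meta.json").write_text(json.dumps(meta, indent=1))

    report["models_fitted"] = models
    return report
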