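"""Multi-cohort expression and survival simulators with known ground truth.

The generator emulates the situation the discovery pipeline is built for:
many small tumor/normal cohorts profiled on different platforms, each a
log2-intensity matrix with a cohort-specific location shift, a shared set
of genes truly up- or down-regulated in tumors ("planted" genes), and a
background of null genes. A ``consistency`` fraction controls in how many
cohorts a planted gene actually carries its effect, which is what makes
the ≥80%-of-cohorts consensus selection a falsifiable procedure rather
than a tautology.

Survival times are drawn from an exponential proportional-hazards model
whose log-hazard is linear in (centered) expression of chosen genes, with
independent exponential censoring and an administrative follow-up cap.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; there is no hidden global state, and the
ground truth (planted genes, carrier cohorts, baselines) is returned as a
ledger sufficient to score recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_io import NORMAL, TUMOR, ExpressionDataset
from .survival import SurvivalTable

_CLINICAL_COVARIATES = ("age", "gender", "stage")


def default_gene_ids(n_genes: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n_genes)]


@dataclass
class SimulationSpec:
    """Parameters of the multi-cohort expression simulation.

    Defaults describe the reference condition used throughout the test
    suite: 10 cohorts of 30 tumor + 30 normal samples over 1,000 genes,
    with 10 up- and 10 down-regulated planted genes at a log2 effect of
    3, carried in 90% of cohorts, unit noise and unit platform scatter.
    """

    n_cohorts: int = 10
    n_tumor: int = 30
    n_normal: int = 30
    n_genes: int = 1000
    planted_up: tuple[str, ...] = ()
    planted_down: tuple[str, ...] = ()
    effect_size: float = 3.0
    consistency: float = 0.9
    platform_shift_sd: float = 1.0
    noise_sd: float = 1.0
    paired_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.planted_up and not self.planted_down:
            genes = default_gene_ids(self.n_genes)
            self.planted_up = tuple(genes[:10])
            self.planted_down = tuple(genes[10:20])
        self.planted_up = tuple(self.planted_up)
        self.planted_down = tuple(self.planted_down)
        if set(self.planted_up) & set(self.planted_down):
            raise ValueError("planted_up and planted_down must be disjoint")
        if not 0.0 <= self.consistency <= 1.0:
            raise ValueError("consistency must lie in [0, 1]")
        if not 0.0 <= self.paired_fraction <= 1.0:
            raise ValueError("paired_fraction must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.noise_sd < 0 or self.platform_shift_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        gene_set = set(default_gene_ids(self.n_genes))
        missing = (set(self.planted_up) | set(self.planted_down)) - gene_set
        if missing:
            raise ValueError(f"planted genes outside the gene range: {sorted(missing)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return default_gene_ids(self.n_genes)


@dataclass
class GroundTruth:
    """Ledger of the simulation's planted structure, for scoring recovery."""

    planted_up: tuple[str, ...]
    planted_down: tuple[str, ...]
    carrier_cohorts: dict[str, list[int]]  # gene -> cohort indices carrying the effect
    gene_baselines: dict[str, float]
    cohort_shifts: list[float]
    paired_cohorts: list[int]

    @property
    def planted(self) -> set[str]:
        return set(self.planted_up) | set(self.planted_down)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_up": list(self.planted_up),
            "planted_down": list(self.planted_down),
            "carrier_cohorts": self.carrier_cohorts,
            "gene_baselines": self.gene_baselines,
            "cohort_shifts": self.cohort_shifts,
            "paired_cohorts": self.paired_cohorts,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _shared_structure(spec: SimulationSpec) -> GroundTruth:
    """Everything deterministic across cohorts given the base seed.

    Per-gene baselines mu_g ~ Uniform(4, 12) (matching the magnitude of
    log2 intensities seen in real cohorts), the per-gene carrier cohort
    sets (round(consistency * n_cohorts) cohorts each), per-cohort
    platform shifts, and which cohorts are paired designs.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    genes = spec.gene_ids
    baselines = dict(zip(genes, rng.uniform(4.0, 12.0, size=spec.n_genes)))
    n_carry = int(round(spec.consistency * spec.n_cohorts))
    carriers: dict[str, list[int]] = {}
    for g in list(spec.planted_up) + list(spec.planted_down):
        carriers[g] = sorted(
            rng.choice(spec.n_cohorts, size=n_carry, replace=False).tolist()
        )
    shifts = rng.normal(0.0, spec.platform_shift_sd, size=spec.n_cohorts).tolist()
    n_paired = int(round(spec.paired_fraction * spec.n_cohorts))
    paired = sorted(rng.permutation(spec.n_cohorts)[:n_paired].tolist())
    return GroundTruth(
        planted_up=spec.planted_up,
        planted_down=spec.planted_down,
        carrier_cohorts=carriers,
        gene_baselines=baselines,
        cohort_shifts=shifts,
        paired_cohorts=paired,
    )


def simulate_cohort(
    spec: SimulationSpec, cohort_index: int, truth: GroundTruth | None = None
) -> ExpressionDataset:
    """Simulate one cohort's log2 expression matrix.

    Background genes are Normal(mu_g + cohort_shift, noise_sd) in both
    classes; planted up genes add +effect_size to the tumor mean (down
    genes subtract it) in the cohorts that carry the effect. Paired
    cohorts add a per-patient random intercept (sd = noise_sd / 2) shared
    between a patient's tumor and normal sample, which is the structure a
    paired signed-rank test exploits. Fully reproducible from
    (seed, cohort_index).
    """
    if not 0 <= cohort_index < spec.n_cohorts:
        raise ValueError(f"cohort_index {cohort_index} out of range")
    if truth is None:
        truth = _shared_structure(spec)
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed).spawn(2 + cohort_index)[-1]
    )
    genes = spec.gene_ids
    paired = cohort_index in truth.paired_cohorts
    n_t = spec.n_tumor
    n_n = spec.n_tumor if paired else spec.n_normal

    mu = np.array([truth.gene_baselines[g] for g in genes]) + truth.cohort_shifts[
        cohort_index
    ]
    mean_t = np.tile(mu[:, None], (1, n_t))
    mean_n = np.tile(mu[:, None], (1, n_n))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in spec.planted_up:
        if cohort_index in truth.carrier_cohorts[g]:
            mean_t[gene_pos[g], :] += spec.effect_size
    for g in spec.planted_down:
        if cohort_index in truth.carrier_cohorts[g]:
            mean_t[gene_pos[g], :] -= spec.effect_size

    tumor = mean_t + rng.normal(0.0, spec.noise_sd, size=mean_t.shape)
    normal = mean_n + rng.normal(0.0, spec.noise_sd, size=mean_n.shape)

    cid = f"SIM{cohort_index:02d}"
    t_ids = [f"{cid}_T{i:03d}" for i in range(n_t)]
    n_ids = [f"{cid}_N{i:03d}" for i in range(n_n)]
    pairing = None
    if paired:
        intercepts = rng.normal(0.0, spec.noise_sd / 2.0, size=n_t)
        tumor = tumor + intercepts[None, :]
        normal = normal + intercepts[None, :]
        pairing = pd.Series(
            dict(zip(t_ids, n_ids)) | dict(zip(n_ids, t_ids))
        )

    values = pd.DataFrame(
        np.hstack([tumor, normal]), index=pd.Index(genes, name="gene"),
        columns=t_ids + n_ids,
    )
    labels = pd.Series([TUMOR] * n_t + [NORMAL] * n_n, index=t_ids + n_ids)
    return ExpressionDataset(
        cohort_id=cid,
        values=values,
        labels=labels,
        platform_tag=f"synthetic-shift{truth.cohort_shifts[cohort_index]:+.2f}",
        pairing=pairing,
    )


def simulate_cohorts(spec: SimulationSpec) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Simulate all cohorts of the spec plus the ground-truth ledger."""
    truth = _shared_structure(spec)
    datasets = [simulate_cohort(spec, i, truth) for i in range(spec.n_cohorts)]
    return datasets, truth


# ---------------------------------------------------------------------------
# Survival simulation
# ---------------------------------------------------------------------------

@dataclass
class SurvivalSimSpec:
    """Exponential proportional-hazards survival simulation.

    ``log_hr_per_unit`` maps a variable name to its true log hazard ratio
    per unit. Keys are gene ids of the accompanying expression dataset
    (effects act on the gene's centered expression) or one of the clinical
    covariates ``age`` (centered, per year), ``gender`` (M=1, F=0) and
    ``stage`` (ordinal 1–4, centered). ``censor_rate`` sets the rate of an
    independent exponential censoring process relative to the baseline
    hazard so that roughly that fraction of patients is censored before
    their event; ``max_followup`` adds administrative censoring.
    """

    n_patients: int = 500
    baseline_hazard: float = 0.05
    log_hr_per_unit: Mapping[str, float] = field(default_factory=dict)
    censor_rate: float = 0.3
    max_followup: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.max_followup <= 0:
            raise ValueError("max_followup must be positive")


def simulate_survival(
    spec: SurvivalSimSpec, expr: ExpressionDataset, endpoint: str = "OS"
) -> SurvivalTable:
    """Draw per-patient event/censor times from the PH model.

    One patient per expression sample, recycling samples if ``n_patients``
    exceeds the cohort size. Event times are exponential with hazard
    ``baseline × exp(Σ log_hr × covariate_centered)``; censoring is the
    minimum of an independent exponential time and ``max_followup``.
    """
    gene_effects = {
        k: v for k, v in spec.log_hr_per_unit.items() if k not in _CLINICAL_COVARIATES
    }
    missing = [g for g in gene_effects if g not in expr.values.index]
    if missing:
        raise ValueError(f"log_hr_per_unit genes absent from expression data: {missing}")

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    n = spec.n_patients
    sample_ids = (expr.sample_ids * (n // expr.n_samples + 1))[:n]
    patient_ids = [f"P{i:04d}" for i in range(n)]

    covars = pd.DataFrame(index=patient_ids)
    covars["age"] = rng.normal(60.0, 10.0, size=n).round(1)
    covars["gender"] = rng.choice(["M", "F"], size=n)
    covars["stage"] = rng.choice([1, 2, 3, 4], size=n, p=[0.45, 0.25, 0.2, 0.1])
    for g in gene_effects:
        covars[g] = expr.values.loc[g, sample_ids].to_numpy()

    lp = np.zeros(n)
    for name, log_hr in spec.log_hr_per_unit.items():
        if name == "gender":
            x = (covars["gender"] == "M").astype(float).to_numpy()
        else:
            raw = covars[name].to_numpy(dtype=float)
            x = raw - raw.mean()
        lp += log_hr * x

    hazard = spec.baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        censor_hazard = spec.baseline_hazard * spec.censor_rate / (1.0 - spec.censor_rate)
        censor_time = rng.exponential(1.0 / censor_hazard, size=n)
    else:
        censor_time = np.full(n, np.inf)
    censor_time = np.minimum(censor_time, spec.max_followup)

    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    table = covars.copy()
    table.insert(0, "time", time)
    table.insert(1, "event", event)
    return SurvivalTable(data=table.rename_axis("patient_id"), endpoint=endpoint)


# ---------------------------------------------------------------------------
# CLI support: write a full simulated study to disk
# ---------------------------------------------------------------------------

def write_simulation(spec: SimulationSpec, outdir: str | Path) -> GroundTruth:
    """Write per-cohort expression/labels TSVs and the truth ledger JSON."""
    from .expression_io import write_dataset

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    datasets, truth = simulate_cohorts(spec)
    for ds in datasets:
        write_dataset(ds, outdir)
    truth.to_json(outdir / "truth.json")
    return truth
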