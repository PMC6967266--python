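"""Reading, validation and preprocessing of expression matrices.

Expression data are handled as genes × samples matrices on log2 scale.
This module covers the steps that bring heterogeneous cohorts onto a
comparable footing before differential expression: probe-to-gene
aggregation (mean over probes mapping to the same symbol), log2
transformation of linear-scale values (FPKM-like), within-cohort quantile
normalization, and intersection to the genes common to all cohorts.

Conventions
-----------
* Matrices are genes × samples; class labels live beside the matrix,
  never inside it.
* Gene symbols are matched case-sensitively and exactly; no alias
  resolution is attempted.
* Quantile normalization is applied per cohort independently, after
  probe aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

TUMOR = "tumor"
NORMAL = "normal"
UNKNOWN = "unknown"
_VALID_LABELS = {TUMOR, NORMAL, UNKNOWN}


@dataclass
class ExpressionDataset:
    """A single cohort: log2-scale genes × samples matrix plus metadata.

    Parameters
    ----------
    cohort_id : str
        Identifier of the cohort (e.g. an accession or a simulation tag).
    values : pandas.DataFrame
        Genes in rows (index = gene symbols), samples in columns, log2 scale.
    labels : pandas.Series
        Per-sample class, one of ``{"tumor", "normal", "unknown"}``,
        indexed by sample id.
    platform_tag : str
        Free-text description of the profiling platform.
    pairing : pandas.Series, optional
        For paired designs: maps each sample id to its partner sample id.
        Partners must be mutual and carry opposite labels.
    """

    cohort_id: str
    values: pd.DataFrame
    labels: pd.Series
    platform_tag: str = ""
    pairing: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError(f"{self.cohort_id}: duplicate gene ids")
        if v.columns.has_duplicates:
            raise ValueError(f"{self.cohort_id}: duplicate sample ids")
        if not np.all(np.isfinite(v.to_numpy())):
            raise ValueError(f"{self.cohort_id}: non-finite expression values")
        if not set(self.labels.index) == set(v.columns):
            raise ValueError(f"{self.cohort_id}: labels do not cover the sample set")
        bad = set(self.labels.unique()) - _VALID_LABELS
        if bad:
            raise ValueError(f"{self.cohort_id}: invalid labels {sorted(bad)}")
        self.labels = self.labels.reindex(v.columns)
        if self.pairing is not None:
            for s, partner in self.pairing.items():
                if self.pairing.get(partner) != s:
                    raise ValueError(
                        f"{self.cohort_id}: pairing not mutual for {s!r}/{partner!r}"
                    )
                if self.labels[s] == self.labels[partner]:
                    raise ValueError(
                        f"{self.cohort_id}: paired samples {s!r}/{partner!r} share a label"
                    )

    # -- convenience -----------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_of(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def class_matrix(self, label: str) -> pd.DataFrame:
        """Sub-matrix of the samples carrying ``label``."""
        return self.values[self.samples_of(label)]

    @property
    def is_paired(self) -> bool:
        return self.pairing is not None and len(self.pairing) > 0

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"{self.cohort_id}: genes not present: {missing[:5]}")
        return ExpressionDataset(
            cohort_id=self.cohort_id,
            values=self.values.loc[list(genes)],
            labels=self.labels.copy(),
            platform_tag=self.platform_tag,
            pairing=None if self.pairing is None else self.pairing.copy(),
        )


@dataclass
class ProbeMatrix:
    """Probe-level matrix with a (possibly partial) probe → gene symbol map."""

    values: pd.DataFrame  # probes × samples
    probe_to_gene: Mapping[str, str]
    cohort_id: str = ""
    platform_tag: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError(f"{self.cohort_id}: non-finite probe values")

    @property
    def unmapped_probes(self) -> list[str]:
        return [p for p in self.values.index if p not in self.probe_to_gene]


def aggregate_probes(
    pm: ProbeMatrix,
    labels: pd.Series | None = None,
    pairing: pd.Series | None = None,
) -> ExpressionDataset:
    """Collapse a probe-level matrix to gene level by averaging.

    Each output gene row is the arithmetic mean of the probe rows mapped to
    that gene symbol; probes with no mapping are dropped. Gene order in the
    output is lexicographic, hence deterministic and independent of probe
    row order.
    """
    if pm.values.empty:
        raise ValueError(f"{pm.cohort_id}: empty probe matrix")
    mapped = [p for p in pm.values.index if p in pm.probe_to_gene]
    if not mapped:
        raise ValueError(
            f"{pm.cohort_id}: no probe has a gene mapping; cannot aggregate"
        )
    sub = pm.values.loc[mapped]
    genes = pd.Index([pm.probe_to_gene[p] for p in mapped], name="gene")
    agg = sub.groupby(genes, sort=True).mean()
    if labels is None:
        labels = pd.Series(UNKNOWN, index=sub.columns)
    return ExpressionDataset(
        cohort_id=pm.cohort_id,
        values=agg,
        labels=labels,
        platform_tag=pm.platform_tag,
        pairing=pairing,
    )


def log2_transform(values: pd.DataFrame | np.ndarray, pseudocount: float = 1.0):
    """Elementwise ``log2(value + pseudocount)`` for nonnegative input.

    The default pseudocount of 1 maps 0 to 0 and keeps the transform
    zero-safe for FPKM-like linear-scale matrices.
    """
    arr = values.to_numpy() if isinstance(values, pd.DataFrame) else np.asarray(values)
    if np.any(arr < 0):
        raise ValueError("log2_transform requires nonnegative input")
    out = np.log2(arr + pseudocount)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common mean distribution.

    The reference distribution is the row-wise mean of the column-sorted
    matrix; each sample's values are replaced by the reference value at
    their rank. Tied values within a column receive the mean of the
    reference quantiles they span, so the map is well defined and the
    procedure idempotent.

    A single-column matrix is returned unchanged with a warning.
    """
    if values.shape[1] < 2:
        warnings.warn(
            "quantile_normalize: fewer than 2 samples, returning input unchanged",
            stacklevel=2,
        )
        return values.copy()
    arr = values.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        ranks = rankdata(col, method="ordinal") - 1
        assigned = reference[ranks]
        # ties: average the reference values the tied block occupies
        normalized = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
        out[:, j] = normalized
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def intersect_common_genes(datasets: Sequence[ExpressionDataset]) -> list[str]:
    """Sorted intersection of gene ids across all cohorts."""
    if not datasets:
        raise ValueError("no datasets given")
    common = set(datasets[0].gene_ids)
    for ds in datasets[1:]:
        common &= set(ds.gene_ids)
    if not common:
        counts = {ds.cohort_id: ds.n_genes for ds in datasets}
        raise ValueError(f"empty gene intersection; per-cohort gene counts: {counts}")
    return sorted(common)


# ---------------------------------------------------------------------------
# File I/O: TSV/CSV, first column gene (or probe) id, header row of samples.
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes-(or probes-)by-samples matrix; first column is the id."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    return df


def read_labels(path: str | Path) -> pd.Series:
    """Two-column file (sample_id, class) → Series of labels."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def read_pairing(path: str | Path) -> pd.Series:
    """Two-column file (sample_id, partner_id) → Series of partners."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (probe_id, gene_symbol) → dict."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_dataset(
    matrix_path: str | Path,
    labels_path: str | Path,
    cohort_id: str,
    pairing_path: str | Path | None = None,
    platform_tag: str = "",
) -> ExpressionDataset:
    values = read_matrix(matrix_path)
    labels = read_labels(labels_path)
    pairing = read_pairing(pairing_path) if pairing_path else None
    return ExpressionDataset(
        cohort_id=cohort_id,
        values=values,
        labels=labels,
        platform_tag=platform_tag,
        pairing=pairing,
    )


def write_dataset(ds: ExpressionDataset, outdir: str | Path) -> dict[str, Path]:
    """Write matrix + labels (+ pairing) TSVs; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    mpath = outdir / f"{ds.cohort_id}.expr.tsv"
    ds.values.rename_axis("gene").to_csv(mpath, sep="\t")
    paths["matrix"] = mpath
    lpath = outdir / f"{ds.cohort_id}.labels.tsv"
    ds.labels.rename_axis("sample_id").rename("class").to_csv(lpath, sep="\t")
    paths["labels"] = lpath
    if ds.pairing is not None and len(ds.pairing):
        ppath = outdir / f"{ds.cohort_id}.pairing.tsv"
        ds.pairing.rename_axis("sample_id").rename("partner_id").to_csv(ppath, sep="\t")
        paths["pairing"] = ppath
    return paths
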