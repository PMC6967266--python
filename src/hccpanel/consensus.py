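"""Cross-cohort consensus: per-gene tallies and core-gene selection.

Each gene tested in every cohort gets a vote-count summary: in how many
cohorts it is up- vs down-regulated (every cohort contributes a
direction, significant or not), and in how many it is significantly
differentially expressed. "Core" genes are those significant in at least
a fraction ``min_sig_frac`` (default 80%) of cohorts — an inclusive
threshold, so 22 of 27 cohorts (81.48%) qualifies while 21 (77.78%) does
not. Consensus regulation is the majority direction; ties are broken by
the direction among significant cohorts only.

Percentages are reported to two decimals with half-up rounding, matching
how such tallies are conventionally printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .diffexp import DOWN, UP, DEGRecord


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (unlike banker's rounding of ``round``)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConsensusSummary:
    """Vote-count summary of one gene across all cohorts."""

    gene: str
    n_up: int
    n_down: int
    n_sig: int
    n_nonsig: int
    up_pct: float
    down_pct: float
    sig_pct: float
    regulation: str  # consensus direction, "up" | "down"
    direction_conflict: bool = False  # overall majority disagrees with the
    # majority among significant cohorts

    @property
    def n_cohorts(self) -> int:
        return self.n_up + self.n_down


def summarize_gene(records: Sequence[DEGRecord]) -> ConsensusSummary:
    """Tally one gene's direction and significance votes across cohorts."""
    if not records:
        raise ValueError("no records to summarize")
    genes = {r.gene for r in records}
    if len(genes) > 1:
        raise ValueError(f"records mix genes: {sorted(genes)}")
    gene = records[0].gene
    n = len(records)
    n_up = sum(r.direction == UP for r in records)
    n_down = n - n_up
    n_sig = sum(r.significant for r in records)
    sig_up = sum(r.significant and r.direction == UP for r in records)
    sig_down = n_sig - sig_up
    if n_up > n_down:
        regulation = UP
    elif n_down > n_up:
        regulation = DOWN
    else:  # tie: defer to the direction in significant cohorts
        regulation = UP if sig_up >= sig_down else DOWN
    sig_majority = UP if sig_up > sig_down else DOWN if sig_down > sig_up else regulation
    return ConsensusSummary(
        gene=gene,
        n_up=n_up,
        n_down=n_down,
        n_sig=n_sig,
        n_nonsig=n - n_sig,
        up_pct=round_half_up(100.0 * n_up / n),
        down_pct=round_half_up(100.0 * n_down / n),
        sig_pct=round_half_up(100.0 * n_sig / n),
        regulation=regulation,
        direction_conflict=(n_sig > 0 and sig_majority != regulation),
    )


def build_consensus(
    records_by_cohort: Mapping[str, Sequence[DEGRecord]],
) -> list[ConsensusSummary]:
    """Summaries for every gene present in *all* cohorts.

    Genes missing from any cohort are excluded (the common-gene
    intersection is the meaningful voting population); cohort ordering is
    irrelevant to the result.
    """
    cohorts = list(records_by_cohort)
    if not cohorts:
        raise ValueError("no cohorts given")
    per_gene: dict[str, list[DEGRecord]] = {}
    for recs in records_by_cohort.values():
        for r in recs:
            per_gene.setdefault(r.gene, []).append(r)
    n_cohorts = len(cohorts)
    return [
        summarize_gene(recs)
        for gene, recs in sorted(per_gene.items())
        if len(recs) == n_cohorts
    ]


def select_core_genes(
    summaries: Sequence[ConsensusSummary], min_sig_frac: float = 0.80
) -> list[str]:
    """Genes significant in at least ``min_sig_frac`` of cohorts.

    The comparison is on raw counts (``n_sig / n_cohorts``) so printed-
    percentage rounding can never flip a call; the threshold is
    inclusive. Result sorted by sig_pct descending, then gene id.
    """
    eps = 1e-12
    selected = [
        s for s in summaries if s.n_sig / s.n_cohorts >= min_sig_frac - eps
    ]
    selected.sort(key=lambda s: (-s.sig_pct, s.gene))
    return [s.gene for s in selected]


def consensus_to_frame(summaries: Sequence[ConsensusSummary]) -> pd.DataFrame:
    """Tally table with the conventional column set.

    Columns: Gene, #Up, #Down, #Sig, #Non-sig, Up (%), Down (%), Sig (%),
    Regulation — plus a conflict flag for rows whose overall direction
    majority disagrees with the majority among significant cohorts.
    """
    return pd.DataFrame(
        [
            {
                "Gene": s.gene,
                "#Up": s.n_up,
                "#Down": s.n_down,
                "#Sig": s.n_sig,
                "#Non-sig": s.n_nonsig,
                "Up (%)": f"{s.up_pct:.2f}",
                "Down (%)": f"{s.down_pct:.2f}",
                "Sig (%)": f"{s.sig_pct:.2f}",
                "Regulation": s.regulation.capitalize(),
                "DirectionConflict": s.direction_conflict,
            }
            for s in summaries
        ]
    )


def write_consensus(summaries: Sequence[ConsensusSummary], path: str | Path) -> None:
    consensus_to_frame(summaries).to_csv(path, sep="\t", index=False)
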