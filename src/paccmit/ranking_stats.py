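"""Benjamini–Hochberg adjustment and deterministic ranking of predictions.

The family for the BH adjustment is the full set of candidate miRNA–mRNA
pairs evaluated in a run (after site filters, before the alpha threshold),
matching adjusted values computed over a returned table with an analogue
of R's ``p.adjust(x, method = "BH")``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["PredictionRecord", "bh_adjust", "rank_and_filter"]


@dataclass(frozen=True)
class PredictionRecord:
    """One predicted miRNA–transcript interaction."""

    mirna_accession: str
    transcript_id: str
    site_count: int
    positions: tuple[int, ...]
    p_value: float
    gene_name: str | None = None
    p_adjusted: float = math.nan
    rank: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(self.positions))
        if self.site_count < 1:
            raise ValueError("a prediction needs at least one passing site")
        if len(self.positions) != self.site_count:
            raise ValueError("positions length must equal site_count")
        if list(self.positions) != sorted(self.positions):
            raise ValueError("positions must be ascending")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """BH step-up adjusted P-values, in the input order.

    Equivalent to sorting descending, taking the running minimum of
    p*m/rank, capping at 1 and restoring order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adjusted]


def rank_and_filter(
    records: Sequence[PredictionRecord],
    alpha: float = 1.0,
    max_pairs: int | None = None,
) -> list[PredictionRecord]:
    """Keep records with adjusted P <= alpha, sort deterministically, truncate,
    and assign ranks 1..n.

    Sort key: (p_value asc, miRNA accession asc, transcript id asc), so
    output files are byte-reproducible regardless of input order.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if max_pairs is not None and max_pairs < 0:
        raise ValueError("max_pairs must be >= 0")
    kept = [r for r in records if r.p_adjusted <= alpha]
    kept.sort(key=lambda r: (r.p_value, r.mirna_accession, r.transcript_id))
    if max_pairs is not None:
        kept = kept[:max_pairs]
    return [replace(r, rank=i) for i, r in enumerate(kept, start=1)]
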