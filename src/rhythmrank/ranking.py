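"""Combined ranking metrics and tie-aware gene rankings.

Eight metrics rank genes per dataset. Four are per-gene statistics computed
upstream (Per and Reg scores, their empirical p-values, and the JTK
p-value); this module adds the three combinations —

* ``DL``       = p_per * p_reg        (smaller is better)
* ``DL x JTK`` = p_jtk * p_reg        (smaller is better)
* ``PerReg``   = Per(G) * Reg(G)      (larger is better; needs no resampling)

— and turns any metric column into a deterministic :class:`RankedList` whose
tie blocks (maximal runs of equal score) are exported explicitly, because
genes inside a block are scientifically exchangeable: empirical p-values are
discrete, so blocks can be large, and downstream evaluation must not credit
the incidental within-block order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "dl_combined",
    "dl_x_jtk",
    "per_reg",
    "rank_genes",
    "RankedList",
    "METRIC_DIRECTIONS",
    "add_combined_metrics",
    "rankings_long_table",
]

Direction = Literal["ascending", "descending"]

#: ranking direction for every metric column (p-value products ascend:
#: smaller = stronger candidate; naive scores descend)
METRIC_DIRECTIONS: dict[str, Direction] = {
    "per_score": "descending",
    "reg_score": "descending",
    "p_per": "ascending",
    "p_reg": "ascending",
    "p_jtk": "ascending",
    "per_reg": "descending",
    "dl": "ascending",
    "dl_x_jtk": "ascending",
}


def _check_pvalue(p: float, name: str) -> None:
    if not (0.0 < p <= 1.0):
        raise ValueError(f"{name} must lie in (0, 1], got {p}")


def dl_combined(p_per: float, p_reg: float) -> float:
    """Product of the periodicity and regulation empirical p-values."""
    _check_pvalue(p_per, "p_per")
    _check_pvalue(p_reg, "p_reg")
    return p_per * p_reg


def dl_x_jtk(p_jtk: float, p_reg: float) -> float:
    """Product of the JTK rhythmicity p-value and the regulation p-value."""
    _check_pvalue(p_jtk, "p_jtk")
    _check_pvalue(p_reg, "p_reg")
    return p_jtk * p_reg


def per_reg(per_score: float, reg_score: float) -> float:
    """Product of the two naive scores; no resampling involved."""
    if per_score < 0 or reg_score < 0:
        raise ValueError("naive scores must be non-negative")
    return per_score * reg_score


def add_combined_metrics(scores: pd.DataFrame) -> pd.DataFrame:
    """Append per_reg, dl, dl_x_jtk columns to a per-gene score table.

    Expects columns ``per_score``, ``reg_score``, ``p_per``, ``p_reg``,
    ``p_jtk``.
    """
    out = scores.copy()
    out["per_reg"] = out["per_score"] * out["reg_score"]
    out["dl"] = out["p_per"] * out["p_reg"]
    out["dl_x_jtk"] = out["p_jtk"] * out["p_reg"]
    return out


@dataclass(frozen=True)
class RankedList:
    """A deterministic ordering of genes by one metric, with tie structure.

    ``gene_ids`` are stably sorted by score in the metric's direction
    (within equal scores, input order is preserved — a convenience only).
    ``tie_blocks`` partitions positions into maximal runs of equal score;
    evaluation treats each block as unordered.
    """

    metric_name: str
    gene_ids: tuple[str, ...]
    scores: np.ndarray
    direction: Direction
    tie_blocks: tuple[tuple[int, int], ...]  # half-open [start, stop) runs

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        d = np.diff(s)
        if self.direction == "ascending":
            ok = np.all(d >= 0)
        else:
            ok = np.all(d <= 0)
        if not ok:
            raise ValueError("scores are not sorted consistently with direction")

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def min_ranks(self) -> np.ndarray:
        """1-based rank per position, min-rank within each tie block."""
        r = np.empty(self.n, dtype=int)
        for start, stop in self.tie_blocks:
            r[start:stop] = start + 1
        return r


def rank_genes(
    scores: Mapping[str, float] | pd.Series,
    direction: Direction,
    metric_name: str = "score",
) -> RankedList:
    """Stable sort of genes by score, grouping equal scores into tie blocks."""
    if isinstance(scores, pd.Series):
        items = list(scores.items())
    else:
        items = list(scores.items())
    vals = np.array([v for _, v in items], dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = items[int(np.argmax(~np.isfinite(vals)))][0]
        raise ValueError(f"non-finite score for gene {bad!r}")
    if direction not in ("ascending", "descending"):
        raise ValueError(f"unknown direction {direction!r}")
    key = vals if direction == "ascending" else -vals
    order = np.argsort(key, kind="stable")
    sorted_scores = vals[order]
    gene_ids = tuple(items[i][0] for i in order)
    blocks: list[tuple[int, int]] = []
    start = 0
    for i in range(1, len(order) + 1):
        if i == len(order) or sorted_scores[i] != sorted_scores[start]:
            blocks.append((start, i))
            start = i
    return RankedList(
        metric_name=metric_name,
        gene_ids=gene_ids,
        scores=sorted_scores,
        direction=direction,
        tie_blocks=tuple(blocks),
    )


def rankings_long_table(score_table: pd.DataFrame, metrics: Sequence[str] | None = None) -> pd.DataFrame:
    """Long-format ranking table: metric, rank, score, gene_id.

    Rank is 1-based with min-rank inside tie blocks, mirroring how published
    gene-ranking supplements report ties.
    """
    metrics = list(metrics) if metrics is not None else [
        m for m in METRIC_DIRECTIONS if m in score_table.columns
    ]
    rows = []
    for metric in metrics:
        ranked = rank_genes(score_table[metric], METRIC_DIRECTIONS[metric], metric)
        ranks = ranked.min_ranks()
        for pos in range(ranked.n):
            rows.append(
                (metric, int(ranks[pos]), float(ranked.scores[pos]), ranked.gene_ids[pos])
            )
    return pd.DataFrame(rows, columns=["metric", "rank", "score", "gene_id"])
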