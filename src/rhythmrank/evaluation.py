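"""Precision-recall evaluation of gene rankings against label sets.

A ranking is judged by how early its positives (core regulatory genes, or
TFs for the negative-control task) appear: the precision-recall curve, its
summary average precision

    AP = (1/C) * sum over positives of precision at that positive's rank,

the random-classifier baseline C/N, and recall among the top k candidates.

Ties are first-class citizens here. Empirical p-values are discrete, so
rankings contain blocks of genes with identical scores whose internal order
is arbitrary; crediting that order can overstate a metric. Every statistic
therefore takes a tie policy:

* ``expected`` (default) — the exact expectation over uniform random
  orderings within each tie block (closed form, no resampling);
* ``pessimistic`` — all negatives in a block precede its positives (lower
  bound);
* ``optimistic`` — positives first (upper bound).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .expression_data import LabelSet
from .ranking import METRIC_DIRECTIONS, RankedList, rank_genes

__all__ = [
    "PRResult",
    "average_precision",
    "expected_random_ap",
    "pr_curve",
    "recall_at_k",
    "run_task",
    "TASKS",
]

TiePolicy = Literal["expected", "pessimistic", "optimistic"]
Task = Literal["core_in_tfs", "core_in_all", "tf_in_all"]
TASKS: tuple[Task, ...] = ("core_in_tfs", "core_in_all", "tf_in_all")


@dataclass(frozen=True)
class PRResult:
    """Precision-recall summary of one ranking against one label set."""

    recalls: np.ndarray
    precisions: np.ndarray
    average_precision: float
    baseline: float
    n_positives: int
    n_universe: int
    tie_policy: str


def _block_stats(
    ranked: RankedList, labels: LabelSet
) -> list[tuple[int, int, int, int]]:
    """Per tie block: (m, k, b, c) = items before, positives before, size, positives.

    Validates that the ranking and the label universe contain exactly the
    same genes.
    """
    pos = labels.positives
    ranked_set = set(ranked.gene_ids)
    missing = set(labels.universe) - ranked_set
    extra = ranked_set - set(labels.universe)
    if missing or extra:
        raise ValueError(
            "ranking/universe mismatch; "
            f"missing from ranking: {sorted(missing)[:5]}, "
            f"not in universe: {sorted(extra)[:5]}"
        )
    is_pos = np.fromiter((g in pos for g in ranked.gene_ids), dtype=bool)
    out = []
    k = 0
    for start, stop in ranked.tie_blocks:
        c = int(np.sum(is_pos[start:stop]))
        out.append((start, k, stop - start, c))
        k += c
    return out


def _block_ap_contribution(m: int, k: int, b: int, c: int, policy: TiePolicy) -> float:
    """Sum over this block's positives of (expected) precision at their rank."""
    if c == 0:
        return 0.0
    j = np.arange(1, c + 1)
    if policy == "optimistic":
        return float(np.sum((k + j) / (m + j)))
    if policy == "pessimistic":
        return float(np.sum((k + j) / (m + b - c + j)))
    # expected: E[ sum_{r positive} (k + #positives at or before r) / (m + r) ]
    # with the c positives uniformly placed among the b slots:
    #   E[I_r * (k + S_r)] = (k + 1) c/b + (r - 1) c(c-1) / (b(b-1))
    r = np.arange(1, b + 1)
    num = (k + 1) * c / b
    if b > 1:
        num = num + (r - 1) * c * (c - 1) / (b * (b - 1))
    return float(np.sum(num / (m + r)))


def _curve_points(
    m: int, k: int, b: int, c: int, C: int, policy: TiePolicy
) -> tuple[np.ndarray, np.ndarray]:
    """(recall, precision) at each of this block's positives."""
    if c == 0:
        return np.empty(0), np.empty(0)
    j = np.arange(1, c + 1, dtype=float)
    if policy == "optimistic":
        r = j
    elif policy == "pessimistic":
        r = b - c + j
    else:
        # positives evenly interleaved: the j-th positive sits at depth j*b/c,
        # which reproduces the flat precision C/N for a fully tied ranking
        r = j * b / c
    return (k + j) / C, (k + j) / (m + r)


def _evaluate(
    ranked: RankedList, labels: LabelSet, tie_policy: TiePolicy
) -> PRResult:
    if tie_policy not in ("expected", "pessimistic", "optimistic"):
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    C = labels.n_positives
    if C == 0:
        raise ValueError(
            f"label set {labels.name!r} has no positives; AP is undefined"
        )
    blocks = _block_stats(ranked, labels)
    ap = sum(_block_ap_contribution(m, k, b, c, tie_policy) for m, k, b, c in blocks) / C
    rec, prec = [], []
    for m, k, b, c in blocks:
        r_b, p_b = _curve_points(m, k, b, c, C, tie_policy)
        rec.append(r_b)
        prec.append(p_b)
    return PRResult(
        recalls=np.concatenate(rec) if rec else np.empty(0),
        precisions=np.concatenate(prec) if prec else np.empty(0),
        average_precision=float(ap),
        baseline=labels.baseline,
        n_positives=C,
        n_universe=labels.n_universe,
        tie_policy=tie_policy,
    )


def expected_random_ap(n_positives: int, n_universe: int) -> float:
    """Exact mean AP of a uniformly random ranking of C positives among N.

    The commonly quoted random-classifier baseline C/N is the large-C limit;
    the exact expectation of non-interpolated AP is

        E[AP] = H_N / N + (C - 1)(N - H_N) / (N (N - 1)),

    with H_N the N-th harmonic number — strictly above C/N because the
    first few positives of any ranking are evaluated at small denominators.
    At C = 1 this is H_N / N; as C grows at fixed prevalence it approaches
    C/N. Equal, by construction, to the ``expected``-policy AP of a ranking
    consisting of one single tie block.
    """
    C, N = n_positives, n_universe
    if not (1 <= C <= N):
        raise ValueError("need 1 <= C <= N")
    h_n = float(np.sum(1.0 / np.arange(1, N + 1)))
    if N == 1:
        return 1.0
    return h_n / N + (C - 1) * (N - h_n) / (N * (N - 1))


def average_precision(
    ranked: RankedList, labels: LabelSet, tie_policy: TiePolicy = "expected"
) -> PRResult:
    """Average precision of a ranking, tie-aware.

    Non-interpolated AP: the mean, over positives, of precision at each
    positive's rank. A perfect ranking scores exactly 1; a uniformly random
    one scores C/N in expectation.
    """
    return _evaluate(ranked, labels, tie_policy)


def pr_curve(
    ranked: RankedList, labels: LabelSet, tie_policy: TiePolicy = "expected"
) -> PRResult:
    """Precision-recall points, one per positive-containing threshold."""
    return _evaluate(ranked, labels, tie_policy)


def recall_at_k(
    ranked: RankedList,
    labels: LabelSet,
    k: int,
    tie_policy: TiePolicy = "expected",
) -> tuple[float, float]:
    """(fraction of positives in the top k, raw positive count).

    A tie block straddling position k contributes its expected share of
    positives under the ``expected`` policy (hypergeometric mean:
    c * slots_inside / b); the pessimistic/optimistic policies place the
    block's positives last/first. The count is therefore fractional when a
    block straddles k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    C = labels.n_positives
    if C == 0:
        raise ValueError(f"label set {labels.name!r} has no positives")
    count = 0.0
    for m, _, b, c in _block_stats(ranked, labels):
        inside = min(max(k - m, 0), b)
        if inside == 0:
            continue
        if inside == b:
            count += c
        elif tie_policy == "optimistic":
            count += min(c, inside)
        elif tie_policy == "pessimistic":
            count += max(0, inside - (b - c))
        else:
            count += c * inside / b
    return count / C, count


def _resolve_labels(
    scored_genes: Sequence[str],
    positives: Iterable[str],
    name: str,
) -> tuple[LabelSet, list[str]]:
    scored = [g.upper() for g in scored_genes]
    scored_set = set(scored)
    hits, missing = [], []
    for g in {str(p).upper() for p in positives}:
        (hits if g in scored_set else missing).append(g)
    if missing:
        warnings.warn(
            f"{len(missing)} {name} gene(s) absent from the score table "
            f"(e.g. {sorted(missing)[:3]}); excluded from evaluation",
            stacklevel=3,
        )
    return LabelSet(tuple(scored), frozenset(hits), name=name), missing


def _task_setup(
    scores: pd.DataFrame,
    core_ids: Iterable[str],
    tf_ids: Iterable[str],
    task: Task,
) -> tuple[pd.DataFrame, LabelSet]:
    """Resolve a task's candidate universe and positive labels."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    all_genes = [str(g).upper() for g in scores.index]
    core = {str(g).upper() for g in core_ids}
    tfs = {str(g).upper() for g in tf_ids}
    if task == "core_in_tfs":
        if not tfs:
            raise ValueError("core_in_tfs requires a non-empty TF list")
        universe = [g for g in all_genes if g in tfs]
        labels, _ = _resolve_labels(universe, core & tfs, "core")
    elif task == "core_in_all":
        labels, _ = _resolve_labels(all_genes, core, "core")
    else:
        if not tfs:
            raise ValueError("tf_in_all requires a non-empty TF list")
        labels, _ = _resolve_labels(all_genes, tfs, "tf")
    sub = scores.copy()
    sub.index = [str(g).upper() for g in sub.index]
    return sub.loc[list(labels.universe)], labels


def run_task(
    scores: pd.DataFrame,
    core_ids: Iterable[str],
    tf_ids: Iterable[str],
    task: Task,
    *,
    tie_policy: TiePolicy = "expected",
    k: int = 25,
    metrics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Evaluate every metric on one classification task.

    Tasks: ``core_in_tfs`` ranks only the scored TFs and asks how early the
    core genes appear; ``core_in_all`` asks the same over every scored gene;
    ``tf_in_all`` is the negative control — if the dynamic features were
    characteristic of TFs per se rather than of core regulators, this task
    would beat its baseline.

    Returns one row per metric with AP under all three tie policies, the
    C/N baseline, and recall@k.
    """
    metrics = list(metrics) if metrics is not None else [
        m for m in METRIC_DIRECTIONS if m in scores.columns
    ]
    sub, labels = _task_setup(scores, core_ids, tf_ids, task)
    rows = []
    for metric in metrics:
        ranked = rank_genes(sub[metric], METRIC_DIRECTIONS[metric], metric)
        res = {
            pol: _evaluate(ranked, labels, pol)
            for pol in ("expected", "pessimistic", "optimistic")
        }
        rec, cnt = recall_at_k(ranked, labels, k, tie_policy)
        rows.append(
            {
                "task": task,
                "metric": metric,
                "ap": res[tie_policy].average_precision,
                "ap_expected": res["expected"].average_precision,
                "ap_pessimistic": res["pessimistic"].average_precision,
                "ap_optimistic": res["optimistic"].average_precision,
                "baseline": labels.baseline,
                f"recall_at_{k}": rec,
                f"positives_in_top_{k}": cnt,
                "n_positives": labels.n_positives,
                "n_universe": labels.n_universe,
            }
        )
    return pd.DataFrame(rows)


def pr_curves_table(
    scores: pd.DataFrame,
    core_ids: Iterable[str],
    tf_ids: Iterable[str],
    tasks: Sequence[Task] = TASKS,
    *,
    tie_policy: TiePolicy = "expected",
    metrics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format PR curves: one row per (task, metric, recall, precision)."""
    metrics = list(metrics) if metrics is not None else [
        m for m in METRIC_DIRECTIONS if m in scores.columns
    ]
    rows = []
    for task in tasks:
        sub, labels = _task_setup(scores, core_ids, tf_ids, task)
        for metric in metrics:
            ranked = rank_genes(sub[metric], METRIC_DIRECTIONS[metric], metric)
            res = pr_curve(ranked, labels, tie_policy)
            for r, p in zip(res.recalls, res.precisions):
                rows.append((task, metric, float(r), float(p)))
    return pd.DataFrame(rows, columns=["task", "metric", "recall", "precision"])
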