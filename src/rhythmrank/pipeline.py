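"""End-to-end orchestration: preprocess -> score -> rank -> evaluate.

The library-level pipeline behind the command-line interface. Each stage
logs row counts so every filtering decision is auditable (kept + removed
always equals rows in).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import dl_scores, jtk
from .evaluation import TASKS, Task, TiePolicy, recall_at_k, run_task
from .expression_data import (
    ExpressionMatrix,
    FilterReport,
    collapse_duplicate_profiles,
    filter_low_expression,
    log2p1_transform,
)
from .ranking import METRIC_DIRECTIONS, add_combined_metrics, rankings_long_table

logger = logging.getLogger("rhythmrank")

__all__ = ["PreprocessResult", "preprocess", "score_dataset", "evaluate_scores"]


@dataclass
class PreprocessResult:
    matrix: ExpressionMatrix
    reports: list[FilterReport]

    def report_dict(self) -> dict:
        return {
            "steps": [
                {"step": r.step, "rows_in": r.n_in, "rows_out": r.n_out,
                 "rows_removed": r.n_removed}
                for r in self.reports
            ]
        }


def _log_stage(step: str, n_in: int, n_out: int, elapsed: float) -> None:
    logger.info("stage=%s rows_in=%d rows_out=%d elapsed=%.2fs",
                step, n_in, n_out, elapsed)


def preprocess(
    m: ExpressionMatrix,
    *,
    fpkm_floor: float = 1.0,
    fpkm_fraction: float = 0.5,
    drop_first: int = 0,
    collapse: bool = True,
    transform: str = "log2p1",
) -> PreprocessResult:
    """Standard preprocessing chain.

    RNA-seq matrices are filtered for reliably expressed genes and (by
    default) moved to the log2(FPKM + 1) scale; microarray log-ratios are
    used as provided. ``drop_first`` removes leading timepoints confounded
    by synchronization recovery. Duplicate probes are collapsed last.
    """
    from .expression_data import drop_leading_timepoints

    reports: list[FilterReport] = []
    if m.modality == "rnaseq":
        t0 = time.perf_counter()
        m, rep = filter_low_expression(m, fpkm_floor, fpkm_fraction)
        reports.append(rep)
        _log_stage(rep.step, rep.n_in, rep.n_out, time.perf_counter() - t0)
        if transform == "log2p1":
            m = log2p1_transform(m)
        elif transform != "none":
            raise ValueError(f"unknown transform {transform!r}")
    if drop_first:
        n_in = m.n_genes
        m = drop_leading_timepoints(m, drop_first)
        reports.append(FilterReport("drop_leading_timepoints", n_in, m.n_genes))
    if collapse:
        t0 = time.perf_counter()
        m, rep = collapse_duplicate_profiles(m)
        reports.append(rep)
        _log_stage(rep.step, rep.n_in, rep.n_out, time.perf_counter() - t0)
    return PreprocessResult(matrix=m, reports=reports)


def score_dataset(
    m: ExpressionMatrix,
    *,
    n_null: int = 10_000,
    seed: int,
    null_mode: dl_scores.SamplingMode = "pooled",
    phase_step: float | None = None,
    n_exact: int = 25,
) -> pd.DataFrame:
    """All eight per-gene metrics for a preprocessed matrix.

    Columns: per_score, reg_score, p_per, p_reg, p_jtk, best_phase,
    tau_at_best_phase, per_reg, dl, dl_x_jtk; indexed by gene_id.
    """
    t0 = time.perf_counter()
    null = dl_scores.sample_null_profiles(m, n_null=n_null, seed=seed, mode=null_mode)
    scores = dl_scores.score_matrix(m, null)
    _log_stage("dl_scores", m.n_genes, m.n_genes, time.perf_counter() - t0)

    t0 = time.perf_counter()
    templates = jtk.build_templates(m.design, phase_step=phase_step)
    jtk_df = jtk.jtk_pvalues_matrix(m.values, templates, n_exact=n_exact)
    jtk_df.index = scores.index
    _log_stage("jtk", m.n_genes, m.n_genes, time.perf_counter() - t0)

    return add_combined_metrics(pd.concat([scores, jtk_df], axis=1))


def evaluate_scores(
    scores: pd.DataFrame,
    core_ids: Iterable[str],
    tf_ids: Iterable[str],
    tasks: Sequence[Task] = TASKS,
    *,
    tie_policy: TiePolicy = "expected",
    k: int = 25,
) -> pd.DataFrame:
    """AP / baseline / recall@k per task and metric (long format)."""
    frames = [
        run_task(scores, core_ids, tf_ids, task, tie_policy=tie_policy, k=k)
        for task in tasks
    ]
    return pd.concat(frames, ignore_index=True)


def write_outputs(
    outdir: str | Path,
    scores: pd.DataFrame | None = None,
    summary: pd.DataFrame | None = None,
    curves: pd.DataFrame | None = None,
    preprocess_report: dict | None = None,
    sidecar: dict | None = None,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if scores is not None:
        scores.to_csv(outdir / "scores.tsv", sep="\t")
        rankings_long_table(scores).to_csv(outdir / "rankings.tsv", sep="\t", index=False)
    if curves is not None:
        curves.to_csv(outdir / "pr_curves.tsv", sep="\t", index=False)
    if summary is not None:
        summary.to_csv(outdir / "evaluation.tsv", sep="\t", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary.to_dict(orient="records"), fh, indent=2)
    if preprocess_report is not None:
        with open(outdir / "preprocess_report.json", "w") as fh:
            json.dump(preprocess_report, fh, indent=2)
    if sidecar is not None:
        with open(outdir / "run_info.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
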