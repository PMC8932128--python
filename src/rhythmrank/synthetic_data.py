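"""Labeled synthetic periodic transcriptomes.

Generates benchmark datasets embodying the conceptual picture behind
core-gene prioritization: a small **core** of transcriptional regulators
oscillating precisely at the specified period with large amplitude; a layer
of **output** genes driven by the core whose signal degrades with network
distance (geometrically shrinking amplitude, jittered period, exponential
damping); and an aperiodic white-noise **background** majority. The TF label
set is the core plus a random draw of non-core genes, so TF membership per
se carries no dynamic signal — the negative-control task should sit at its
baseline by construction.

An RNA-seq-like mode exponentiates the signal onto a non-negative abundance
scale and plants sub-threshold profiles and duplicate probes so the
preprocessing filters are exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .expression_data import ExpressionMatrix, LabelSet, SamplingDesign

__all__ = ["SimConfig", "SimResult", "simulate_dataset", "simulate_null_dataset"]

#: Default design: a cell-cycle microarray-style grid — 16 min sampling over
#: ~4 h with a specified period of 94 min, i.e. 5.875 timepoints per cycle,
#: deliberately non-integer so phase drift across cycles is the default path.
DEFAULT_DESIGN = SamplingDesign.regular(period=94.0, interval=16.0, duration=254.0, unit="min")


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic transcriptome.

    Amplitudes are on the log-ratio scale (microarray-like). Core amplitudes
    are log-normal with median ``exp(core_log_amplitude_loc)``; output genes
    at network distance d carry amplitude ``A * amplitude_decay**d`` with a
    relative period jitter ``Normal(0, period_jitter_sd)`` and damping
    envelope ``exp(-damping_rate * t)``. Background genes are white noise
    with SD ``background_sd``; measurement noise of SD ``measurement_sd`` is
    added to every gene.
    """

    n_genes: int = 2000
    n_core: int = 15
    n_output: int = 200
    n_tf_extra: int = 150
    design: SamplingDesign = DEFAULT_DESIGN
    core_log_amplitude_loc: float = np.log(2.0)
    core_log_amplitude_scale: float = 0.25
    amplitude_decay: float = 0.6  # gamma per distance step, in (0,1)
    max_distance: int = 3
    period_jitter_sd: float = 0.05  # relative sd of output-gene period
    damping_rate: float = 0.002  # per time unit, >= 0
    background_sd: float = 0.5
    measurement_sd: float = 0.25
    modality: Literal["microarray", "rnaseq"] = "microarray"
    rnaseq_base_fpkm: float = 10.0
    duplicate_probe_fraction: float = 0.0
    low_expression_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_core < 0 or self.n_output < 0 or self.n_tf_extra < 0:
            raise ValueError("gene counts must be non-negative")
        if self.n_core + self.n_output > self.n_genes:
            raise ValueError("n_core + n_output exceeds n_genes")
        if self.n_core + self.n_tf_extra > self.n_genes:
            raise ValueError("TF list larger than the gene set")
        if not (0.0 < self.amplitude_decay < 1.0):
            raise ValueError("amplitude_decay must lie in (0, 1)")
        if self.max_distance < 1:
            raise ValueError("max_distance must be >= 1")
        if min(self.period_jitter_sd, self.damping_rate, self.background_sd,
               self.measurement_sd) < 0:
            raise ValueError("noise and damping parameters must be non-negative")
        if not (0.0 <= self.duplicate_probe_fraction < 1.0):
            raise ValueError("duplicate_probe_fraction must lie in [0, 1)")
        if not (0.0 <= self.low_expression_fraction < 1.0):
            raise ValueError("low_expression_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class SimResult:
    """A synthetic dataset plus its ground truth."""

    matrix: ExpressionMatrix
    core: LabelSet
    tfs: LabelSet
    truth: pd.DataFrame  # gene_id, class, amplitude, period, phase, distance

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.matrix.write_tsv(outdir / "expression.tsv")
        for name, labels in (("core", self.core), ("tf", self.tfs)):
            with open(outdir / f"{name}_genes.txt", "w") as fh:
                fh.write(f"# {name} gene labels (synthetic)\n")
                for g in sorted(labels.positives):
                    fh.write(g + "\n")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1)) if n else 1
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_dataset(config: SimConfig) -> SimResult:
    """Draw one labeled synthetic transcriptome, deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.design.times, dtype=float)
    n_t = t.size
    T = config.design.period
    n_bg = config.n_genes - config.n_core - config.n_output
    names = _gene_names(config.n_genes)

    classes = (["core"] * config.n_core + ["output"] * config.n_output
               + ["background"] * n_bg)
    amplitude = np.zeros(config.n_genes)
    period = np.full(config.n_genes, np.nan)
    phase = np.full(config.n_genes, np.nan)
    distance = np.zeros(config.n_genes, dtype=int)
    values = np.empty((config.n_genes, n_t))

    for i in range(config.n_core):
        A = rng.lognormal(config.core_log_amplitude_loc, config.core_log_amplitude_scale)
        phi = rng.uniform(0.0, T)
        amplitude[i], period[i], phase[i] = A, T, phi
        values[i] = A * np.cos(2.0 * np.pi * (t - phi) / T)

    for i in range(config.n_core, config.n_core + config.n_output):
        d = int(rng.integers(1, config.max_distance + 1))
        A = (rng.lognormal(config.core_log_amplitude_loc, config.core_log_amplitude_scale)
             * config.amplitude_decay ** d)
        Ti = T * (1.0 + rng.normal(0.0, config.period_jitter_sd))
        phi = rng.uniform(0.0, T)
        amplitude[i], period[i], phase[i], distance[i] = A, Ti, phi, d
        values[i] = (A * np.exp(-config.damping_rate * (t - t[0]))
                     * np.cos(2.0 * np.pi * (t - phi) / Ti))

    start_bg = config.n_core + config.n_output
    values[start_bg:] = rng.normal(0.0, config.background_sd, size=(n_bg, n_t))
    values += rng.normal(0.0, config.measurement_sd, size=values.shape)

    # TF labels: all core genes plus a random draw of non-core genes, so TF
    # membership is uninformative about dynamics beyond containing the core.
    non_core = np.arange(config.n_core, config.n_genes)
    extra = rng.choice(non_core, size=config.n_tf_extra, replace=False)
    tf_idx = sorted(set(range(config.n_core)) | set(int(i) for i in extra))

    gene_ids = list(names)
    low_idx = np.empty(0, dtype=int)
    if config.modality == "rnaseq":
        values = config.rnaseq_base_fpkm * np.exp2(values)
        n_low = int(round(config.low_expression_fraction * config.n_genes))
        if n_low:
            if n_low > n_bg:
                raise ValueError("low_expression_fraction exceeds the background pool")
            # overwrite background genes with sub-threshold profiles
            low_idx = rng.choice(np.arange(start_bg, config.n_genes),
                                 size=n_low, replace=False)
            values[low_idx] = rng.uniform(0.0, 0.5, size=(n_low, n_t))
            for i in low_idx:
                classes[i] = "low_expression"
    n_dup = int(round(config.duplicate_probe_fraction * config.n_genes))

    matrix_ids = gene_ids
    matrix_values = values
    if n_dup:
        # duplicate probes never target planted sub-threshold genes, so the
        # FPKM filter and the probe collapse remove disjoint row sets
        pool = np.setdiff1d(np.arange(config.n_genes), low_idx)
        dup_idx = rng.choice(pool, size=n_dup, replace=False)
        dup_rows = (values[dup_idx]
                    + rng.normal(0.0, config.measurement_sd, size=(n_dup, n_t)))
        if config.modality == "rnaseq":
            dup_rows = np.clip(dup_rows, 0.0, None) * 0.5  # lower-abundance probe
        else:
            dup_rows = dup_rows - np.abs(values[dup_idx]).mean()
        matrix_ids = gene_ids + [gene_ids[i] for i in dup_idx]
        matrix_values = np.vstack([values, dup_rows])

    matrix = ExpressionMatrix(
        gene_ids=matrix_ids, values=matrix_values,
        design=config.design, modality=config.modality,
    )
    core = LabelSet(tuple(gene_ids), frozenset(gene_ids[: config.n_core]), "core")
    tfs = LabelSet(tuple(gene_ids), frozenset(gene_ids[i] for i in tf_idx), "tf")
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "class": classes,
            "amplitude": amplitude,
            "period": period,
            "phase": phase,
            "distance": distance,
        }
    )
    return SimResult(matrix=matrix, core=core, tfs=tfs, truth=truth)


def simulate_null_dataset(config: SimConfig) -> ExpressionMatrix:
    """Background-only transcriptome: every gene is white noise.

    The calibration harness: empirical p-values computed on this matrix
    should be uniform, and any label set drawn at random over it should
    evaluate at its C/N baseline.
    """
    null_cfg = replace(
        config,
        n_core=0,
        n_output=0,
        n_tf_extra=0,
        duplicate_probe_fraction=0.0,
        low_expression_fraction=0.0,
    )
    return simulate_dataset(null_cfg).matrix
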