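"""Expression matrices, sampling designs, and preprocessing.

This module holds the three containers the rest of the pipeline works on —
a :class:`SamplingDesign` (the time grid and the specified oscillation
period), an :class:`ExpressionMatrix` (one abundance profile per probe/gene
on that grid), and a :class:`LabelSet` (a candidate universe with binary
positive labels) — together with the preprocessing steps applied to real
time-series transcriptomes before scoring: the FPKM reliability filter for
RNA-seq, removal of leading timepoints confounded by synchronization
recovery, and collapsing of multi-probe genes to their highest-abundance
profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SamplingDesign",
    "ExpressionMatrix",
    "LabelSet",
    "FilterReport",
    "read_expression_table",
    "read_label_list",
    "filter_low_expression",
    "drop_leading_timepoints",
    "collapse_duplicate_profiles",
    "timepoints_per_cycle",
    "log2p1_transform",
]

Modality = Literal["microarray", "rnaseq"]


@dataclass(frozen=True)
class SamplingDesign:
    """Time grid of a time-series expression experiment.

    Parameters
    ----------
    times
        Strictly increasing sample times.
    period
        Specified oscillation period T (cell-cycle or circadian), in the
        same unit as ``times``.
    interval
        Nominal spacing between consecutive samples.
    unit
        Time unit label, recorded for provenance only ("min" or "h").
    """

    times: tuple[float, ...]
    period: float
    interval: float
    unit: str = "min"

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        object.__setattr__(self, "times", times)
        if len(times) < 2:
            raise ValueError("a sampling design needs at least two timepoints")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.interval <= 0:
            raise ValueError("interval must be positive")

    @property
    def n_timepoints(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Last time minus first time."""
        return self.times[-1] - self.times[0]

    @classmethod
    def regular(
        cls, period: float, interval: float, duration: float, *,
        start: float = 0.0, unit: str = "min",
    ) -> "SamplingDesign":
        """Evenly spaced design covering ``[start, start + duration]``."""
        n = int(np.floor(duration / interval + 1e-9)) + 1
        times = tuple(start + interval * k for k in range(n))
        return cls(times=times, period=period, interval=interval, unit=unit)


def timepoints_per_cycle(design: SamplingDesign) -> Fraction:
    """Number of samples per oscillation cycle, ``period / interval``.

    Returned as an exact :class:`fractions.Fraction` (e.g. 94 min sampled
    every 16 min gives 47/8 = 5.875), never rounded: non-integer values mark
    designs whose sample phases drift across cycles, a regime the scoring
    methods must handle on the true time grid.
    """
    return Fraction(design.period).limit_denominator(10**9) / Fraction(
        design.interval
    ).limit_denominator(10**9)


@dataclass
class ExpressionMatrix:
    """Per-gene abundance profiles on a shared time grid.

    ``gene_ids`` may contain duplicates (multi-probe genes) until
    :func:`collapse_duplicate_profiles` is applied. ``values`` is a dense
    ``(n_genes, n_timepoints)`` float array; all entries must be finite.
    """

    gene_ids: list[str]
    values: np.ndarray
    design: SamplingDesign
    modality: Modality = "microarray"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D gene x timepoint array")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError("one row of values per gene id required")
        if self.values.shape[1] != self.design.n_timepoints:
            raise ValueError(
                f"profiles have {self.values.shape[1]} entries but the design "
                f"has {self.design.n_timepoints} timepoints"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        if self.modality not in ("microarray", "rnaseq"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def profile(self, gene_id: str) -> np.ndarray:
        idx = self.gene_ids.index(gene_id)
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=[f"{t:g}" for t in self.design.times],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass(frozen=True)
class LabelSet:
    """A candidate universe of N gene IDs with C positive labels."""

    universe: tuple[str, ...]
    positives: frozenset[str]
    name: str = "core"

    def __post_init__(self) -> None:
        object.__setattr__(self, "universe", tuple(self.universe))
        object.__setattr__(self, "positives", frozenset(self.positives))
        if len(set(self.universe)) != len(self.universe):
            raise ValueError("label universe contains duplicate gene ids")
        stray = self.positives - set(self.universe)
        if stray:
            raise ValueError(
                f"positives not in universe: {sorted(stray)[:5]}"
                + ("..." if len(stray) > 5 else "")
            )

    @property
    def n_universe(self) -> int:
        return len(self.universe)

    @property
    def n_positives(self) -> int:
        return len(self.positives)

    @property
    def baseline(self) -> float:
        """Random-classifier average precision, C/N."""
        return self.n_positives / self.n_universe


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for a preprocessing step: which rows went where."""

    step: str
    n_in: int
    n_out: int
    removed_gene_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out


def read_expression_table(
    path: str | Path,
    design: SamplingDesign,
    *,
    modality: Modality = "microarray",
) -> ExpressionMatrix:
    """Read a delimited gene x timepoint table into an :class:`ExpressionMatrix`.

    The file must be tab- or comma-delimited with one header row of time
    labels and one row per probe/gene, first column the gene ID. Row order is
    preserved and duplicate gene IDs are retained as distinct profiles
    (collapse happens later). Non-numeric or missing cells are an error: the
    scoring methods have no missing-data handling, so problems must surface
    at ingestion.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[1] != design.n_timepoints:
        raise ValueError(
            f"{path.name}: table has {df.shape[1]} value columns but the "
            f"design has {design.n_timepoints} timepoints"
        )
    values = np.empty(df.shape, dtype=float)
    for i, (gene, row) in enumerate(df.iterrows()):
        for j, cell in enumerate(row):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path.name}: non-numeric value {cell!r} for gene "
                    f"{gene!r} in column {df.columns[j]!r}"
                ) from None
    if not np.all(np.isfinite(values)):
        i, j = map(int, np.argwhere(~np.isfinite(values))[0])
        raise ValueError(
            f"{path.name}: non-finite value for gene {df.index[i]!r} "
            f"in column {df.columns[j]!r}"
        )
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        values=values,
        design=design,
        modality=modality,
    )


def read_label_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list: one ID per line, ``#`` comments allowed.

    IDs are upper-cased so that matching against expression tables is
    case-insensitive (gene symbol capitalization conventions differ between
    organisms and databases).
    """
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.append(line.upper())
    return ids


def make_label_set(
    universe: Iterable[str], positives: Iterable[str], name: str = "core"
) -> tuple[LabelSet, list[str]]:
    """Build a :class:`LabelSet`, reporting positives absent from the universe.

    Matching is exact after upper-casing. Returns the label set plus the list
    of unmatched positive IDs — callers must surface these, never drop them
    silently.
    """
    uni = [g.upper() for g in universe]
    uni_set = set(uni)
    pos, missing = [], []
    for g in positives:
        g = g.upper()
        (pos if g in uni_set else missing).append(g)
    return LabelSet(universe=tuple(uni), positives=frozenset(pos), name=name), missing


def filter_low_expression(
    m: ExpressionMatrix, floor: float = 1.0, fraction: float = 0.5
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop RNA-seq profiles that are unreliably low.

    A profile is removed when its abundance is below ``floor`` (default
    1 FPKM) at *strictly more than* ``fraction`` (default half) of the
    timepoints; a profile sitting below the floor at exactly half of them is
    kept. No-op, with a warning, for microarray matrices, whose log-ratio
    values have no comparable floor.
    """
    if m.modality != "rnaseq":
        warnings.warn(
            "low-expression filter applies to RNA-seq abundances only; "
            "matrix left unchanged",
            stacklevel=2,
        )
        return m, FilterReport("filter_low_expression", m.n_genes, m.n_genes)
    n_below = np.sum(m.values < floor, axis=1)
    keep = n_below <= fraction * m.design.n_timepoints
    removed = tuple(g for g, k in zip(m.gene_ids, keep) if not k)
    out = ExpressionMatrix(
        gene_ids=[g for g, k in zip(m.gene_ids, keep) if k],
        values=m.values[keep],
        design=m.design,
        modality=m.modality,
    )
    return out, FilterReport("filter_low_expression", m.n_genes, out.n_genes, removed)


def drop_leading_timepoints(
    m: ExpressionMatrix, k: int = 2
) -> ExpressionMatrix:
    """Remove the first ``k`` timepoints from every profile and the design.

    Used when the start of a time series reflects recovery from the
    synchronization procedure (e.g. centrifugal elutriation) rather than the
    periodic process itself. ``k`` must be smaller than the series length.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return m
    if k >= m.design.n_timepoints:
        raise ValueError(
            f"cannot drop {k} of {m.design.n_timepoints} timepoints"
        )
    design = replace(m.design, times=m.design.times[k:])
    return ExpressionMatrix(
        gene_ids=list(m.gene_ids),
        values=m.values[:, k:],
        design=design,
        modality=m.modality,
    )


def collapse_duplicate_profiles(
    m: ExpressionMatrix,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep one profile per gene: the one with the highest mean abundance.

    Genes measured by multiple probes otherwise contribute several rows to
    the ranking and distort evaluation. Ties in mean abundance keep the
    first profile in input order, so the operation is deterministic and
    order-stable. Row order of first occurrences is preserved.
    """
    means = m.values.mean(axis=1)
    best: dict[str, int] = {}
    for i, g in enumerate(m.gene_ids):
        if g not in best or means[i] > means[best[g]]:
            best[g] = i
    order = sorted(best.values())
    keep = np.zeros(m.n_genes, dtype=bool)
    keep[order] = True
    removed = tuple(g for g, k in zip(m.gene_ids, keep) if not k)
    out = ExpressionMatrix(
        gene_ids=[m.gene_ids[i] for i in order],
        values=m.values[order],
        design=m.design,
        modality=m.modality,
    )
    return out, FilterReport("collapse_duplicate_profiles", m.n_genes, out.n_genes, removed)


def log2p1_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """``log2(x + 1)`` transform for non-negative RNA-seq abundances.

    Variance-based scores on raw FPKM are dominated by the most abundant
    genes; the shifted log puts fold-changes on the scale microarray
    log-ratios already use. Requires non-negative input.
    """
    if np.any(m.values < 0):
        raise ValueError("log2p1 transform requires non-negative abundances")
    return ExpressionMatrix(
        gene_ids=list(m.gene_ids),
        values=np.log2(m.values + 1.0),
        design=m.design,
        modality=m.modality,
    )
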