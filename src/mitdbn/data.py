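"""Time-course expression data model and lag-aware sample alignment.

A :class:`TimeSeriesSet` holds one or more real-valued expression series
(genes in rows, time points in columns) over a common gene set; a
:class:`DiscreteDataset` is the same structure after mapping every value to
one of ``k`` uniform discrete states.  All scoring ultimately runs on an
:class:`AlignedSampleTable`: the child column shifted ``d`` time units
forward together with each lagged parent column, built per series so that no
row ever pairs observations from two different series.

Time is 1-based in the documentation (``x[t]`` regulated by ``x[t - delta]``)
and 0-based internally; the alignment contract is stated purely in terms of
the rows produced, so the convention cannot leak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import EmptyDataError, InvalidInputError, InvalidParameterError

__all__ = [
    "TimeSeriesSet",
    "DiscreteDataset",
    "AlignedSampleTable",
    "quantile_discretize",
    "spline_upsample",
    "average_replicates",
    "effective_observations",
    "align_samples",
    "to_discrete",
]


def _check_series(series: Sequence[np.ndarray], gene_ids: Sequence[str]) -> tuple[np.ndarray, ...]:
    if len(series) == 0:
        raise InvalidInputError("at least one series is required")
    n = len(gene_ids)
    if len(set(gene_ids)) != n:
        raise InvalidInputError("gene_ids must be unique")
    out = []
    for i, s in enumerate(series):
        a = np.asarray(s)
        if a.ndim != 2:
            raise InvalidInputError(f"series {i} is not a 2-D matrix")
        if a.shape[0] != n:
            raise InvalidInputError(
                f"series {i} has {a.shape[0]} genes, expected {n} (genes in rows)"
            )
        if a.shape[1] < 2:
            raise InvalidInputError(f"series {i} has fewer than 2 time points")
        out.append(a)
    return tuple(out)


@dataclass(frozen=True)
class TimeSeriesSet:
    """One or more continuous expression series over the same gene set.

    Attributes
    ----------
    series : tuple of ndarray
        Each matrix is ``n`` genes x ``Ni`` time points (``Ni`` may differ
        between series).
    gene_ids : tuple of str
        Unique identifiers, one per row.
    """

    series: tuple[np.ndarray, ...]
    gene_ids: tuple[str, ...]

    def __init__(self, series: Sequence[np.ndarray], gene_ids: Sequence[str]):
        gene_ids = tuple(str(g) for g in gene_ids)
        mats = _check_series(series, gene_ids)
        mats = tuple(np.asarray(s, dtype=float) for s in mats)
        for i, s in enumerate(mats):
            if not np.all(np.isfinite(s)):
                raise InvalidInputError(f"series {i} contains non-finite values")
        object.__setattr__(self, "series", mats)
        object.__setattr__(self, "gene_ids", gene_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def m(self) -> int:
        """Number of series."""
        return len(self.series)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(s.shape[1] for s in self.series)


@dataclass(frozen=True)
class DiscreteDataset:
    """Expression series mapped to ``k`` uniform discrete states.

    Every entry lies in ``{0, ..., k-1}``; the same ``k`` applies to all
    genes (variable uniformity, required by the global search).
    """

    series: tuple[np.ndarray, ...]
    k: int
    gene_ids: tuple[str, ...]

    def __init__(self, series: Sequence[np.ndarray], k: int, gene_ids: Sequence[str]):
        if int(k) < 2:
            raise InvalidParameterError(f"k must be >= 2, got {k}")
        k = int(k)
        gene_ids = tuple(str(g) for g in gene_ids)
        mats = _check_series(series, gene_ids)
        cast = []
        for i, s in enumerate(mats):
            a = np.asarray(s)
            ai = a.astype(np.int64)
            if not np.array_equal(ai, a):
                raise InvalidInputError(f"series {i} contains non-integer states")
            if ai.min() < 0 or ai.max() >= k:
                raise InvalidInputError(
                    f"series {i} has states outside 0..{k - 1}"
                )
            cast.append(ai)
        object.__setattr__(self, "series", tuple(cast))
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "gene_ids", gene_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def m(self) -> int:
        return len(self.series)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(s.shape[1] for s in self.series)


@dataclass(frozen=True)
class AlignedSampleTable:
    """Child and lagged-parent columns after shifting to a common clock.

    ``ne`` rows total (the effective observation count); column ``j`` of
    ``parent_columns`` corresponds to parent ``j`` at its own lag.  No row
    mixes observations from two different series.
    """

    child_column: np.ndarray
    parent_columns: tuple[np.ndarray, ...]
    ne: int
    d: int

    def __post_init__(self) -> None:
        if self.child_column.shape != (self.ne,):
            raise InvalidInputError("child column length != ne")
        for c in self.parent_columns:
            if c.shape != (self.ne,):
                raise InvalidInputError("parent column length != ne")


def quantile_discretize(tss: TimeSeriesSet, k: int) -> DiscreteDataset:
    """Equal-frequency (quantile) discretization into ``k`` states per gene.

    For each gene, values pooled across all series are split at the
    empirical ``j/k`` quantiles; the (0-based, ascending-value) bin index
    becomes the state and the same thresholds apply to every series of that
    gene.  Values exactly equal to a bin edge go to the lower bin, so
    heavily tied genes may yield unbalanced bins; a gene with fewer than
    ``k`` distinct pooled values triggers a warning.
    """
    if int(k) < 2:
        raise InvalidParameterError(f"k must be >= 2, got {k}")
    k = int(k)
    n = tss.n_genes
    pooled = [np.concatenate([s[g] for s in tss.series]) for g in range(n)]
    for g in range(n):
        if pooled[g].size < k:
            raise InvalidParameterError(
                f"gene {tss.gene_ids[g]!r} has fewer than k={k} pooled observations"
            )
    edges = np.empty((n, k - 1))
    for g in range(n):
        vals = pooled[g]
        if np.unique(vals).size < k:
            warnings.warn(
                f"gene {tss.gene_ids[g]!r} has fewer than {k} distinct values; "
                "discretized bins will be unbalanced",
                stacklevel=2,
            )
        edges[g] = np.quantile(vals, np.arange(1, k) / k)
    out = []
    for s in tss.series:
        disc = np.empty_like(s, dtype=np.int64)
        for g in range(n):
            # side='left': a value equal to an edge is not counted past it,
            # i.e. ties go to the lower bin
            disc[g] = np.searchsorted(edges[g], s[g], side="left")
        out.append(disc)
    return DiscreteDataset(out, k=k, gene_ids=tss.gene_ids)


def spline_upsample(tss: TimeSeriesSet, insert: int) -> TimeSeriesSet:
    """Insert ``insert`` interpolated points between consecutive measurements.

    Each series of length ``Ni`` becomes ``Ni + (Ni - 1) * insert`` points on
    an evenly refined grid; original samples are preserved exactly and
    inserted values lie on a cubic interpolating spline through them (linear
    for series shorter than 4 points, where a cubic is under-determined).
    """
    if int(insert) < 0:
        raise InvalidParameterError(f"insert must be >= 0, got {insert}")
    insert = int(insert)
    if insert == 0:
        return tss
    out = []
    for s in tss.series:
        ni = s.shape[1]
        x = np.arange(ni, dtype=float)
        xf = np.arange((ni - 1) * (insert + 1) + 1, dtype=float) / (insert + 1)
        if ni < 4:
            up = np.vstack([np.interp(xf, x, row) for row in s])
        else:
            up = CubicSpline(x, s, axis=1)(xf)
        # knots are exact up to spline evaluation round-off; pin them
        up[:, :: insert + 1] = s
        out.append(up)
    return TimeSeriesSet(out, gene_ids=tss.gene_ids)


def average_replicates(tss: TimeSeriesSet) -> TimeSeriesSet:
    """Collapse replicate series to their per-gene, per-time arithmetic mean."""
    lens = set(tss.lengths)
    if len(lens) != 1:
        raise InvalidInputError(
            f"replicate averaging requires equal series lengths, got {sorted(lens)}"
        )
    mean = np.mean(np.stack(tss.series), axis=0)
    return TimeSeriesSet([mean], gene_ids=tss.gene_ids)


def _usable_series(dataset: DiscreteDataset | TimeSeriesSet, d: int) -> list[np.ndarray]:
    if int(d) < 1:
        raise InvalidParameterError(f"order d must be >= 1, got {d}")
    usable = []
    for i, s in enumerate(dataset.series):
        if s.shape[1] <= d:
            warnings.warn(
                f"series {i} has length {s.shape[1]} <= d={d}; dropped from alignment",
                stacklevel=3,
            )
        else:
            usable.append(s)
    if not usable:
        raise EmptyDataError(f"no series longer than d={d}; nothing to align")
    return usable


def effective_observations(dataset: DiscreteDataset | TimeSeriesSet, d: int) -> int:
    """Effective sample count ``Ne = sum_i (Ni - d)`` over usable series.

    Series with ``Ni <= d`` contribute nothing and are dropped with a
    warning rather than aborting the run.
    """
    return sum(s.shape[1] - int(d) for s in _usable_series(dataset, d))


def align_samples(
    dataset: DiscreteDataset,
    child: int,
    parents,
    d: int,
) -> AlignedSampleTable:
    """Build the aligned sample table for ``child`` given lagged parents.

    For each series independently, row ``t`` (for ``t = d+1 .. Ni``, 1-based)
    holds ``x_child[t]`` next to ``x_p[t - delta_p]`` for every parent
    ``(p, delta_p)``; rows from all series are concatenated, so no row spans
    a series boundary.

    ``parents`` may be a :class:`~mitdbn.scoring.LaggedParentSet` or any
    iterable of ``(gene_index, lag)`` pairs.
    """
    d = int(d)
    members = getattr(parents, "members", parents)
    members = tuple((int(g), int(lag)) for g, lag in members)
    n = dataset.n_genes
    if not 0 <= int(child) < n:
        raise InvalidParameterError(f"child index {child} out of range")
    for g, lag in members:
        if not 0 <= g < n:
            raise InvalidParameterError(f"parent gene index {g} out of range")
        if not 1 <= lag <= d:
            raise InvalidParameterError(
                f"parent lag {lag} outside 1..{d} (inter-slice edges only)"
            )
    usable = _usable_series(dataset, d)
    child_parts = []
    parent_parts: list[list[np.ndarray]] = [[] for _ in members]
    for s in usable:
        ni = s.shape[1]
        child_parts.append(s[child, d:])
        for j, (g, lag) in enumerate(members):
            parent_parts[j].append(s[g, d - lag : ni - lag])
    child_col = np.concatenate(child_parts)
    parent_cols = tuple(np.concatenate(p) for p in parent_parts)
    return AlignedSampleTable(
        child_column=child_col,
        parent_columns=parent_cols,
        ne=child_col.size,
        d=d,
    )


def to_discrete(tss: TimeSeriesSet, k: int) -> DiscreteDataset:
    """Cast an integer-valued :class:`TimeSeriesSet` (e.g. simulator output)
    to a :class:`DiscreteDataset` with ``k`` states, verifying integrality."""
    return DiscreteDataset(tss.series, k=k, gene_ids=tss.gene_ids)
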