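"""Readers and writers for the package's plain-text formats.

Expression matrices travel as TSV with gene ids in the first column and a
header row of time labels (genes in rows, time in columns; ``transpose``
accommodates the other dialect).  Multiple series are supplied either as
multiple files or as one file plus a list of series lengths.  Discrete
data round-trip through the same dialect with integer entries.

Truth networks are TSV ``regulator<TAB>target<TAB>lag``; learned networks
are written as a TSV edge list with a per-edge ``delta_mi`` column (the
mutual-information gain when that parent is added last, for ranking), as
SIF (``regulator lag<d> target``), or as GraphML.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .benchmarks import LaggedTruthNetwork
from .data import DiscreteDataset, TimeSeriesSet
from .errors import InvalidInputError
from .scoring import time_delayed_mi
from .search import DbnNetwork

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_discrete_tsv",
    "write_discrete_tsv",
    "read_truth_tsv",
    "write_truth_tsv",
    "write_network_tsv",
    "write_network_sif",
    "write_network_graphml",
    "read_network_tsv",
]


def _read_matrix(path, transpose: bool) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    if df.shape[1] < 2:
        raise InvalidInputError(f"{path}: fewer than 2 time points")
    return df.to_numpy(), [str(g) for g in df.index]


def _split_series(mat: np.ndarray, series_lengths: Sequence[int] | None) -> list[np.ndarray]:
    if series_lengths is None:
        return [mat]
    lengths = [int(x) for x in series_lengths]
    if sum(lengths) != mat.shape[1]:
        raise InvalidInputError(
            f"series lengths {lengths} sum to {sum(lengths)}, matrix has "
            f"{mat.shape[1]} columns"
        )
    out, pos = [], 0
    for ln in lengths:
        out.append(mat[:, pos : pos + ln])
        pos += ln
    return out


def read_expression_tsv(
    paths: str | Sequence[str],
    series_lengths: Sequence[int] | None = None,
    transpose: bool = False,
) -> TimeSeriesSet:
    """Read one or more expression TSV files into a :class:`TimeSeriesSet`.

    A single path with ``series_lengths`` splits its columns into multiple
    series; multiple paths contribute one series each (same genes, same
    order, verified).
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    paths = list(paths)
    if len(paths) > 1 and series_lengths is not None:
        raise InvalidInputError("give either multiple files or series lengths, not both")
    mats, ids = [], None
    for p in paths:
        mat, genes = _read_matrix(p, transpose)
        if ids is None:
            ids = genes
        elif genes != ids:
            raise InvalidInputError(f"{p}: gene ids differ from the first file")
        mats.append(mat)
    if len(paths) == 1:
        mats = _split_series(mats[0], series_lengths)
    return TimeSeriesSet(mats, gene_ids=ids)


def write_expression_tsv(path, tss: TimeSeriesSet) -> None:
    """Write all series side by side (columns t1, t2, ...; series
    boundaries recoverable from the series-length list)."""
    mat = np.concatenate(tss.series, axis=1)
    cols = [f"t{i + 1}" for i in range(mat.shape[1])]
    pd.DataFrame(mat, index=list(tss.gene_ids), columns=cols).to_csv(path, sep="\t")


def read_discrete_tsv(
    paths: str | Sequence[str],
    k: int,
    series_lengths: Sequence[int] | None = None,
    transpose: bool = False,
) -> DiscreteDataset:
    tss = read_expression_tsv(paths, series_lengths=series_lengths, transpose=transpose)
    return DiscreteDataset(tss.series, k=k, gene_ids=tss.gene_ids)


def write_discrete_tsv(path, dataset: DiscreteDataset) -> None:
    mat = np.concatenate(dataset.series, axis=1)
    cols = [f"t{i + 1}" for i in range(mat.shape[1])]
    pd.DataFrame(mat, index=list(dataset.gene_ids), columns=cols).to_csv(path, sep="\t")


def read_truth_tsv(path) -> LaggedTruthNetwork:
    df = pd.read_csv(path, sep="\t")
    required = {"regulator", "target", "lag"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"{path}: columns must include {sorted(required)}")
    edges = tuple(
        (str(r), str(t), int(lag))
        for r, t, lag in zip(df["regulator"], df["target"], df["lag"])
    )
    nodes = tuple(sorted({v for r, t, _ in edges for v in (r, t)}))
    return LaggedTruthNetwork(nodes=nodes, edges=edges)


def write_truth_tsv(path, network: LaggedTruthNetwork) -> None:
    pd.DataFrame(
        [{"regulator": r, "target": t, "lag": o} for r, t, o in network.edges]
    ).to_csv(path, sep="\t", index=False)


def _edge_rows(network: DbnNetwork, dataset: DiscreteDataset | None) -> list[dict]:
    rows = []
    for ps in network.parent_sets:
        tgt = network.gene_ids[ps.child]
        for g, lag in ps.members:
            row = {"regulator": network.gene_ids[g], "target": tgt, "lag": lag}
            if dataset is not None:
                full = time_delayed_mi(dataset, ps.child, ps.members, network.d)
                rest = tuple(m for m in ps.members if m != (g, lag))
                row["delta_mi"] = full - time_delayed_mi(
                    dataset, ps.child, rest, network.d
                )
            rows.append(row)
    return rows


def write_network_tsv(path, network: DbnNetwork, dataset: DiscreteDataset | None = None) -> None:
    """TSV edge list ``regulator target lag [delta_mi]``; ``delta_mi`` (the
    Is gain of adding that parent last) is included when data are given."""
    cols = ["regulator", "target", "lag"] + (["delta_mi"] if dataset is not None else [])
    pd.DataFrame(_edge_rows(network, dataset), columns=cols).to_csv(
        path, sep="\t", index=False
    )


def read_network_tsv(path, d: int, gene_ids: Sequence[str]) -> DbnNetwork:
    """Read an edge-list TSV back into a :class:`DbnNetwork` over the given
    gene universe (needed because isolated genes carry no edges)."""
    from .scoring import LaggedParentSet

    df = pd.read_csv(path, sep="\t")
    gene_ids = tuple(str(g) for g in gene_ids)
    index = {g: i for i, g in enumerate(gene_ids)}
    members: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(gene_ids))}
    for r, t, lag in zip(df["regulator"], df["target"], df["lag"]):
        if str(r) not in index or str(t) not in index:
            raise InvalidInputError(f"edge ({r}, {t}) outside the gene universe")
        members[index[str(t)]].append((index[str(r)], int(lag)))
    return DbnNetwork(
        parent_sets=tuple(
            LaggedParentSet(i, tuple(members[i])) for i in range(len(gene_ids))
        ),
        d=int(d),
        gene_ids=gene_ids,
    )


def write_network_sif(path, network: DbnNetwork) -> None:
    """SIF dialect: ``regulator lag<d> target`` per line."""
    with open(path, "w") as fh:
        for r, t, lag in network.edges():
            fh.write(f"{r}\tlag{lag}\t{t}\n")


def write_network_graphml(path, network: DbnNetwork) -> None:
    import networkx as nx

    g = nx.MultiDiGraph()
    g.add_nodes_from(network.gene_ids)
    for r, t, lag in network.edges():
        g.add_edge(r, t, lag=int(lag))
    nx.write_graphml(g, path)
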