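"""Ground-truth networks and seeded simulators for benchmarking.

The centerpiece is a 35-gene, 4-level cascade emulating a hepatic
glucose-homeostasis regulatory module: 52 lagged interactions split into
13 first-, 23 second- and 16 third-order edges, where an edge's order
equals the level gap between regulator and target.  The published wiring
diagram is not machine-readable at print resolution, so the packaged
topology is a documented surrogate (``surrogate=True``) that preserves the
node count, the 4-level cascade structure, the per-order edge counts and
multiple-regulator in-degrees.

Expression data are produced either by static Bayesian-network sampling
followed by level-wise time shifting (each time step is an independent
static sample of the cascade; the profile of a level-L node is then
shifted forward by L-1 time units, turning level gaps into time lags), or
by direct d-th order DBN sampling.  In both generators a child obeys a
deterministic rule of its parents with probability ``q`` (the interaction
strength) and is uniform otherwise.  The rule is the lower median of the
parent states -- a copy for one parent, AND-like for two at k=2 -- chosen
so that every regulator stays informative about the child both jointly
and marginally (a monotone rule, as most transcriptional logic roughly
is; a parity rule would make single regulators look independent of the
target and defeat any pairwise lag selection).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data import TimeSeriesSet
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "LaggedTruthNetwork",
    "SimulationSpec",
    "glucose_fixture",
    "random_cascade_network",
    "simulate_static_then_shift",
    "simulate_dbn",
    "shuffle_control",
]

# fixed construction seed of the packaged glucose surrogate topology
_GLUCOSE_SEED = 20120613
_GLUCOSE_LEVEL_SIZES = (8, 10, 9, 8)


@dataclass(frozen=True)
class LaggedTruthNetwork:
    """A ground-truth lagged edge list, optionally with a node -> level map.

    Edges are ``(regulator, target, order)`` triples with order >= 1.  When
    levels are present, every edge runs from a shallower level to a deeper
    one and its order equals the level gap (the cascade design).
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, int], ...]
    levels: Mapping[str, int] | None = None
    surrogate: bool = False

    def __post_init__(self) -> None:
        nodeset = set(self.nodes)
        if len(nodeset) != len(self.nodes):
            raise InvalidInputError("duplicate node ids")
        if len(set(self.edges)) != len(self.edges):
            raise InvalidInputError("duplicate (regulator, target, order) edge")
        for reg, tgt, order in self.edges:
            if reg not in nodeset or tgt not in nodeset:
                raise InvalidInputError(f"edge ({reg}, {tgt}) references unknown node")
            if order < 1:
                raise InvalidInputError("edge order must be >= 1")
            if self.levels is not None:
                gap = self.levels[tgt] - self.levels[reg]
                if gap < 1 or gap != order:
                    raise InvalidInputError(
                        f"edge ({reg}, {tgt}, {order}) violates the level structure "
                        f"(level gap {gap})"
                    )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edges_by_order(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for _, _, order in self.edges:
            out[order] = out.get(order, 0) + 1
        return out

    def max_order(self) -> int:
        return max((o for _, _, o in self.edges), default=0)

    def parents_of(self, node: str) -> list[tuple[str, int]]:
        return [(r, o) for r, t, o in self.edges if t == node]


@dataclass(frozen=True)
class SimulationSpec:
    """Simulation conditions: interaction strength, series layout, states.

    ``cpt_strength`` (q) is the probability that a child obeys the
    deterministic rule of its parents; otherwise it draws uniformly.
    """

    cpt_strength: float = 0.9
    n_series: int = 10
    length: int = 125
    k: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.cpt_strength <= 1.0:
            raise InvalidParameterError(
                f"cpt_strength must be in (0.5, 1], got {self.cpt_strength}"
            )
        if self.n_series < 1 or self.length < 2:
            raise InvalidParameterError("need n_series >= 1 and length >= 2")
        if self.k < 2:
            raise InvalidParameterError("k must be >= 2")


def random_cascade_network(
    n: int,
    levels: int,
    edges_per_order: Sequence[int],
    seed: int,
    level_sizes: Sequence[int] | None = None,
) -> LaggedTruthNetwork:
    """Seeded random leveled cascade with the requested per-order edge counts.

    Nodes are split (near-evenly unless ``level_sizes`` is given) into
    ``levels`` levels; for order ``o`` the requested number of edges is
    sampled without replacement from all (regulator, target) pairs whose
    level gap is exactly ``o``.
    """
    if levels < 2 or n < levels:
        raise InvalidParameterError("need levels >= 2 and n >= levels")
    if len(edges_per_order) >= levels:
        raise InvalidParameterError(
            f"{len(edges_per_order)} orders impossible with {levels} levels"
        )
    if level_sizes is None:
        base, extra = divmod(n, levels)
        level_sizes = [base + (1 if i < extra else 0) for i in range(levels)]
    if sum(level_sizes) != n or any(s < 1 for s in level_sizes):
        raise InvalidParameterError("level_sizes must be positive and sum to n")
    width = len(str(n))
    nodes = tuple(f"g{i + 1:0{width}d}" for i in range(n))
    level_of: dict[str, int] = {}
    pos = 0
    for lvl, size in enumerate(level_sizes, start=1):
        for node in nodes[pos : pos + size]:
            level_of[node] = lvl
        pos += size
    rng = np.random.default_rng(seed)
    edges: list[tuple[str, str, int]] = []
    for order, count in enumerate(edges_per_order, start=1):
        pairs = [
            (u, v)
            for u in nodes
            for v in nodes
            if level_of[v] - level_of[u] == order
        ]
        if count > len(pairs):
            raise InvalidParameterError(
                f"{count} order-{order} edges requested but only {len(pairs)} "
                "level pairs exist"
            )
        chosen = rng.choice(len(pairs), size=count, replace=False)
        edges.extend((*pairs[i], order) for i in sorted(chosen))
    return LaggedTruthNetwork(
        nodes=nodes, edges=tuple(edges), levels=level_of, surrogate=True
    )


def glucose_fixture() -> LaggedTruthNetwork:
    """The packaged 35-gene glucose-homeostasis benchmark network.

    4 levels (8 master TFs on top), 52 edges: 13 first-, 23 second- and 16
    third-order interactions.  The wiring is a fixed, seeded surrogate
    preserving those counts and the cascade/multi-regulator structure; the
    original diagram is not legible at machine precision, so
    ``surrogate`` is True.
    """
    return random_cascade_network(
        n=35,
        levels=4,
        edges_per_order=(13, 23, 16),
        seed=_GLUCOSE_SEED,
        level_sizes=_GLUCOSE_LEVEL_SIZES,
    )


def _child_rule(parent_states: np.ndarray) -> np.ndarray:
    """Deterministic regulation rule: lower median of the parent states.

    For one parent this is a copy; for two parents at k=2 it is AND-like.
    Monotone in every argument, so each regulator carries marginal signal.
    """
    s = np.sort(parent_states, axis=0)
    return s[(s.shape[0] - 1) // 2]


def simulate_static_then_shift(
    network: LaggedTruthNetwork, spec: SimulationSpec
) -> TimeSeriesSet:
    """Static-BN sampling followed by level-wise time shifting.

    Each time step is an independent static sample of the leveled network
    (roots uniform over ``k`` states, children obeying the lower-median
    rule with probability q); the profile of a level-L node is then shifted
    forward by L-1 time units and all profiles are truncated to the common
    length, so a level gap of g becomes a time lag of g.
    """
    if network.levels is None:
        raise InvalidParameterError("static-then-shift simulation requires levels")
    max_level = max(network.levels.values())
    max_shift = max_level - 1
    if spec.length <= max_shift:
        raise InvalidParameterError(
            f"series length {spec.length} must exceed the maximum shift {max_shift}"
        )
    rng = np.random.default_rng(spec.seed)
    nodes = network.nodes
    index = {v: i for i, v in enumerate(nodes)}
    order = sorted(range(len(nodes)), key=lambda i: network.levels[nodes[i]])
    parents = {i: [index[r] for r, _ in network.parents_of(nodes[i])] for i in range(len(nodes))}
    n, q, k = len(nodes), spec.cpt_strength, spec.k
    raw_len = spec.length + max_shift
    series = []
    for _ in range(spec.n_series):
        x = np.empty((n, raw_len), dtype=np.int64)
        for i in order:
            if not parents[i]:
                x[i] = rng.integers(0, k, size=raw_len)
            else:
                ruled = _child_rule(x[parents[i]])
                noise = rng.integers(0, k, size=raw_len)
                obey = rng.random(raw_len) < q
                x[i] = np.where(obey, ruled, noise)
        shifted = np.empty((n, spec.length), dtype=np.int64)
        for i in range(n):
            lvl = network.levels[nodes[i]]
            start = max_level - lvl  # shift forward by lvl - 1, align window
            shifted[i] = x[i, start : start + spec.length]
        series.append(shifted)
    return TimeSeriesSet(series, gene_ids=nodes)


def simulate_dbn(network: LaggedTruthNetwork, spec: SimulationSpec) -> TimeSeriesSet:
    """Direct d-th order DBN sampling from the lagged truth network.

    The first ``max order`` time slices are uniform; afterwards each gene
    with parents obeys the lower-median rule of its lagged parent values
    with probability q, and draws uniformly otherwise.
    """
    d_max = network.max_order()
    if spec.length <= d_max:
        raise InvalidParameterError(
            f"series length {spec.length} must exceed the maximum lag {d_max}"
        )
    rng = np.random.default_rng(spec.seed)
    nodes = network.nodes
    index = {v: i for i, v in enumerate(nodes)}
    parents = {
        i: [(index[r], o) for r, o in network.parents_of(nodes[i])]
        for i in range(len(nodes))
    }
    n, q, k = len(nodes), spec.cpt_strength, spec.k
    series = []
    for _ in range(spec.n_series):
        x = np.empty((n, spec.length), dtype=np.int64)
        if d_max == 0:
            x[:] = rng.integers(0, k, size=(n, spec.length))
        else:
            x[:, :d_max] = rng.integers(0, k, size=(n, d_max))
            for t in range(d_max, spec.length):
                for i in range(n):
                    if not parents[i]:
                        x[i, t] = rng.integers(0, k)
                    else:
                        vals = np.array([x[g, t - lag] for g, lag in parents[i]])
                        if rng.random() < q:
                            x[i, t] = _child_rule(vals[:, None])[0]
                        else:
                            x[i, t] = rng.integers(0, k)
        series.append(x)
    return TimeSeriesSet(series, gene_ids=nodes)


def shuffle_control(dataset, seed: int):
    """Negative control: independently permute each gene's observations
    within each series, preserving every per-gene value multiset while
    destroying temporal structure.  Works on both continuous and discrete
    datasets and returns the same type.
    """
    rng = np.random.default_rng(seed)
    shuffled = []
    for s in dataset.series:
        out = s.copy()
        for g in range(out.shape[0]):
            out[g] = out[g, rng.permutation(out.shape[1])]
        shuffled.append(out)
    if hasattr(dataset, "k"):
        from .data import DiscreteDataset

        return DiscreteDataset(shuffled, k=dataset.k, gene_ids=dataset.gene_ids)
    return TimeSeriesSet(shuffled, gene_ids=dataset.gene_ids)
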