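"""Globally optimal parent-set search under the MIT score.

Two exact per-node learners are provided for d-th order transition networks
with inter-time-slice edges only (so acyclicity never needs checking and
each node's parents can be learned independently):

* :func:`learn_parents_plus` searches all subsets of the ``n * d`` lagged
  candidates, in increasing cardinality, stopping as soon as the cumulative
  chi-square penalty ``u(p)`` alone reaches the incumbent score -- the rule
  that makes the search polynomial while preserving global optimality.
  This is the search known in the literature as GlobalMIT+.
* :func:`learn_parents_star` first fixes, for every candidate regulator, the
  single lag maximizing its pairwise time-delayed mutual information with
  the child, then runs the same search over those ``n`` candidates
  (GlobalMIT*): a trade-off that keeps the complexity of a first-order
  search while still covering lags up to ``d``.

Both learners share one enumeration engine with deterministic tie-breaking:
candidates are sorted by (gene index, lag), subsets are enumerated
lexicographically, the first minimum at a level wins, and replacement of
the incumbent requires strict improvement -- so ties resolve to the
smallest cardinality, then the lexicographically smallest set.

:func:`exhaustive_oracle` is a deliberately simple brute-force enumerator
(shared tie rule, no early stopping) used to certify global optimality on
small instances.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import chain, combinations

import numpy as np
from scipy.special import xlogy

from .data import DiscreteDataset, align_samples
from .errors import GuardExceededError, InvalidParameterError
from .scoring import (
    LaggedParentSet,
    PenaltyTable,
    _entropy_of_codes,
    parent_set_score,
)

__all__ = [
    "DbnNetwork",
    "SearchTrace",
    "LevelRecord",
    "PStarBound",
    "default_alpha",
    "learn_parents_plus",
    "learn_parents_star",
    "optimal_lag_table",
    "learn_network",
    "pstar_bound",
    "exhaustive_oracle",
]

#: subset-count guard for the brute-force oracle
ORACLE_SUBSET_GUARD = 10**6

# chunking knobs for the vectorized level scorer
_CHUNK_CELLS = 2_000_000
_CHUNK_ROWS_CAP = 16_000
_MAX_BINCOUNT_CELLS = 1 << 16


@dataclass(frozen=True)
class DbnNetwork:
    """A learned transition network: one lagged parent set per gene.

    Lags are in ``[1, d]``; self-edges at lag >= 1 are permitted and
    acyclicity is never checked (edges only run forward in time).
    """

    parent_sets: tuple[LaggedParentSet, ...]
    d: int
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.parent_sets) != len(self.gene_ids):
            raise InvalidParameterError("one parent set per gene required")
        for ps in self.parent_sets:
            for g, lag in ps.members:
                if not 1 <= lag <= self.d:
                    raise InvalidParameterError(
                        f"lag {lag} outside 1..{self.d} in parent set of node {ps.child}"
                    )

    def edges(self) -> list[tuple[str, str, int]]:
        """Edge list as (regulator id, target id, lag) triples."""
        out = []
        for ps in self.parent_sets:
            tgt = self.gene_ids[ps.child]
            for g, lag in ps.members:
                out.append((self.gene_ids[g], tgt, lag))
        return out

    @property
    def n_edges(self) -> int:
        return sum(len(ps) for ps in self.parent_sets)


@dataclass(frozen=True)
class LevelRecord:
    """One enumerated cardinality level of Algorithm 1 for one node."""

    p: int
    n_subsets: int
    u_p: float
    incumbent_before: float
    best_s_level: float


@dataclass
class SearchTrace:
    """Per-node log of the search: levels enumerated, stopping point, bounds."""

    child: int
    n_candidates: int
    ne: int
    hs: float
    levels: list[LevelRecord] = field(default_factory=list)
    stopped_at: int | None = None
    pstar_numeric: int = 0
    pstar_closed_form: int = 0
    trajectory: list[tuple[int, float]] = field(default_factory=list)


@dataclass(frozen=True)
class PStarBound:
    """Cardinality bound of the search: numeric value and the closed-form
    over-estimate derived from chi-square means."""

    numeric: int
    closed_form: int


def default_alpha(ne: int) -> float:
    """Significance-level policy: 0.999 for Ne < 100, else 0.9999."""
    return 0.999 if ne < 100 else 0.9999


def pstar_bound(ne: int, k: int, alpha: float, hs: float | None = None) -> PStarBound:
    """Smallest cardinality p* whose cumulative penalty reaches the v-term
    of the empty parent set, plus the closed-form over-estimate
    ``ceil(log_k(2 Ne log k / (k - 1)) + 1)``.

    ``hs`` switches the threshold from ``2 Ne log k`` to the tighter
    ``2 Ne hs`` (entropy bound).
    """
    if ne < 1:
        raise InvalidParameterError(f"ne must be >= 1, got {ne}")
    threshold = 2.0 * ne * (hs if hs is not None else math.log(k))
    table = PenaltyTable(alpha, k)
    p = 0
    while table.u(p) < threshold:
        p += 1
    closed = math.ceil(math.log(2.0 * ne * math.log(k) / (k - 1), k) + 1)
    return PStarBound(numeric=p, closed_form=closed)


def _candidate_columns(
    dataset: DiscreteDataset, d: int
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Aligned child-time columns: genes x Ne matrix for every lag 1..d.

    Returns (current-slice matrix, {lag: lagged matrix}); column t of the
    lag-delta matrix holds X[t - delta] for the same aligned clock as the
    current slice.
    """
    usable = [s for s in dataset.series if s.shape[1] > d]
    if not usable:
        from .errors import EmptyDataError

        raise EmptyDataError(f"no series longer than d={d}")
    now = np.concatenate([s[:, d:] for s in usable], axis=1)
    lagged = {
        delta: np.concatenate([s[:, d - delta : s.shape[1] - delta] for s in usable], axis=1)
        for delta in range(1, d + 1)
    }
    return now, lagged


def _entropy_pair_terms(
    counts: np.ndarray, ne: int, nlogn: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """H(parents) and H(parents, child) per subset from a (B, q, k) count
    tensor; plug-in, nats.  ``nlogn`` is a precomputed c*log(c) table over
    0..ne (counts are small integers, so a gather beats xlogy here)."""
    log_ne = np.log(ne)
    h_joint = log_ne - nlogn[counts].sum(axis=(1, 2)) / ne
    cpa = counts.sum(axis=2)
    h_pa = log_ne - nlogn[cpa].sum(axis=1) / ne
    return h_pa, h_joint


# precomputed pair tables are only built while they stay below this size
_PAIR_TABLE_BYTES = 64_000_000


class _LevelScorer:
    """Vectorized v-term evaluation for subsets of one node's candidates.

    Joint (parents, child) configurations are mixed-radix codes counted
    with one bincount per chunk; for speed, codes of candidate pairs (and
    pairs with the child folded in as the last digit) are precomputed, so
    a cardinality-p chunk needs about p/2 gathers instead of p.
    """

    def __init__(self, child_col, cand_cols, k, ne, hs, cap):
        self.k = k
        self.ne = ne
        self.hs = hs
        self.cap = cap
        self.child = np.ascontiguousarray(child_col, dtype=np.int32)
        self.cc = np.ascontiguousarray(cand_cols, dtype=np.int32)
        nc = self.cc.shape[0]
        self.nc = nc
        counts_range = np.arange(ne + 1, dtype=float)
        self.nlogn = xlogy(counts_range, counts_range)
        # single candidate with child folded in as least-significant digit
        self.scc = self.cc * k + self.child[None, :]
        if nc * nc * ne * 4 <= _PAIR_TABLE_BYTES:
            pc = (self.cc[:, None, :] * k + self.cc[None, :, :]).reshape(nc * nc, ne)
            self.pc = pc
            self.pcc = pc * k + self.child[None, :]
        else:
            self.pc = self.pcc = None

    def _codes(self, idx: np.ndarray, dtype) -> np.ndarray:
        """Joint (parents..., child) code matrix for a (B, p) index chunk."""
        b, p = idx.shape
        k = self.k
        if self.pc is not None and p >= 2:
            flat = idx[:, 0] * self.nc + idx[:, 1]
            if p == 2:
                return self.pcc[flat].astype(dtype, copy=False)
            codes = self.pc[flat].astype(dtype, copy=False)
            j = 2
            while p - j >= 2:
                codes *= k * k
                codes += self.pc[idx[:, j] * self.nc + idx[:, j + 1]]
                j += 2
            if j < p:  # one candidate left
                codes *= k * k
                codes += self.scc[idx[:, j]]
            else:
                codes *= k
                codes += self.child[None, :]
            return codes
        if p == 1:
            return self.scc[idx[:, 0]].astype(dtype, copy=False)
        codes = self.cc[idx[:, 0]].astype(dtype, copy=False)
        for j in range(1, p):
            codes *= k
            codes += self.cc[idx[:, j]]
        codes *= k
        codes += self.child[None, :]
        return codes

    def score(self, idx: np.ndarray) -> np.ndarray:
        """v-term per subset for a (B, p) chunk of candidate indices."""
        b, p = idx.shape
        k, ne = self.k, self.ne
        if (p + 1) * math.log2(k) >= 62:
            raise GuardExceededError(
                f"joint state space k^{p + 1} overflows 64-bit codes"
            )
        cells = k ** (p + 1)
        if cells <= _MAX_BINCOUNT_CELLS:
            codes = self._codes(idx, np.int32)
            codes += (np.arange(b, dtype=np.int32) * cells)[:, None]
            counts = np.bincount(codes.ravel(), minlength=b * cells).reshape(
                b, k**p, k
            )
            h_pa, h_joint = _entropy_pair_terms(counts, ne, self.nlogn)
        else:
            # joint state space too large for a dense count tensor
            codes = self._codes(idx, np.int64)
            h_pa = np.empty(b)
            h_joint = np.empty(b)
            for i in range(b):
                h_joint[i] = _entropy_of_codes(codes[i])
                h_pa[i] = _entropy_of_codes(codes[i] // k)
        mi = np.maximum(0.0, self.hs + h_pa - h_joint)
        return np.maximum(0.0, 2.0 * ne * (self.cap - mi))


@lru_cache(maxsize=4)
def _combination_table(nc: int, p: int) -> np.ndarray:
    """All C(nc, p) lexicographic combination index rows as one int32 array."""
    total = math.comb(nc, p)
    flat = chain.from_iterable(combinations(range(nc), p))
    return np.fromiter(flat, dtype=np.int32, count=total * p).reshape(total, p)


def _combination_chunks(nc: int, p: int, chunk_rows: int):
    """Yield (B, p) lexicographic index chunks; small tables are cached and
    reused across nodes (all nodes of one search share nc and p)."""
    total = math.comb(nc, p)
    if total * p <= 40_000_000:
        table = _combination_table(nc, p)
        for start in range(0, total, chunk_rows):
            yield table[start : start + chunk_rows]
        return
    flat = chain.from_iterable(combinations(range(nc), p))
    done = 0
    while done < total:
        rows = min(chunk_rows, total - done)
        yield np.fromiter(flat, dtype=np.int32, count=rows * p).reshape(rows, p)
        done += rows


def _algorithm1(
    child_col: np.ndarray,
    cands: list[tuple[int, int]],
    cand_cols: np.ndarray,
    k: int,
    alpha: float,
    bound: str,
    child: int,
) -> tuple[tuple[tuple[int, int], ...], SearchTrace]:
    """Exact minimum-s search with the penalty stopping rule (Algorithm 1).

    Returns the optimal members (as (gene, lag) pairs in candidate order)
    and the search trace.
    """
    ne = child_col.size
    hs = _entropy_of_codes(child_col)
    cap = hs if bound == "entropy" else math.log(k)
    penalty = PenaltyTable(alpha, k)
    nc = len(cands)
    scorer = _LevelScorer(child_col, cand_cols, k, ne, hs, cap)

    best_members: tuple[int, ...] = ()
    best_s = 2.0 * ne * cap  # empty set: v = 2 Ne cap, u = 0

    ps = pstar_bound(ne, k, alpha, hs=hs if bound == "entropy" else None)
    trace = SearchTrace(
        child=child,
        n_candidates=nc,
        ne=ne,
        hs=hs,
        pstar_numeric=ps.numeric,
        pstar_closed_form=ps.closed_form,
    )
    trace.trajectory.append((0, best_s))

    for p in range(1, nc + 1):
        u_p = penalty.u(p)
        if u_p >= best_s:
            trace.stopped_at = p
            break
        level_best = math.inf
        level_best_idx: tuple[int, ...] | None = None
        n_seen = 0
        total = math.comb(nc, p)
        chunk_rows = max(1, min(_CHUNK_ROWS_CAP, _CHUNK_CELLS // max(ne, k ** (p + 1))))
        for idx in _combination_chunks(nc, p, chunk_rows):
            v = scorer.score(idx)
            j = int(np.argmin(v))
            if v[j] < level_best:  # strict: first minimum wins
                level_best = float(v[j])
                level_best_idx = tuple(int(x) for x in idx[j])
            n_seen += idx.shape[0]
        level_s = level_best + u_p
        trace.levels.append(
            LevelRecord(
                p=p,
                n_subsets=n_seen,
                u_p=u_p,
                incumbent_before=best_s,
                best_s_level=level_s,
            )
        )
        if level_s < best_s:
            best_s = level_s
            best_members = level_best_idx
        trace.trajectory.append((p, best_s))
    members = tuple(cands[i] for i in best_members)
    return members, trace


def _plus_candidates(n: int, d: int, child: int, no_self_loops: bool) -> list[tuple[int, int]]:
    return [
        (g, delta)
        for g in range(n)
        for delta in range(1, d + 1)
        if not (no_self_loops and g == child)
    ]


def learn_parents_plus(
    dataset: DiscreteDataset,
    child: int,
    d: int,
    alpha: float | None = None,
    bound: str = "entropy",
    no_self_loops: bool = False,
) -> tuple[LaggedParentSet, SearchTrace]:
    """Globally optimal parent set of ``child`` over all ``n * d`` lagged
    candidates (all genes x lags 1..d, the child's own past included unless
    ``no_self_loops``)."""
    if bound not in ("entropy", "logk"):
        raise InvalidParameterError(f"bound must be 'entropy' or 'logk', got {bound!r}")
    d = int(d)
    now, lagged = _candidate_columns(dataset, d)
    ne = now.shape[1]
    if alpha is None:
        alpha = default_alpha(ne)
    cands = _plus_candidates(dataset.n_genes, d, child, no_self_loops)
    cand_cols = np.stack([lagged[delta][g] for g, delta in cands])
    members, trace = _algorithm1(
        now[child], cands, cand_cols, dataset.k, alpha, bound, child
    )
    return LaggedParentSet(child, members), trace


def optimal_lag_table(dataset: DiscreteDataset, child: int, d: int) -> np.ndarray:
    """Per-gene lag in 1..d maximizing the pairwise time-delayed mutual
    information with ``child``; ties break toward the smallest lag."""
    d = int(d)
    now, lagged = _candidate_columns(dataset, d)
    k = dataset.k
    ne = now.shape[1]
    n = dataset.n_genes
    child_col = now[child]
    hs = _entropy_of_codes(child_col)
    best_mi = np.full(n, -1.0)
    best_lag = np.ones(n, dtype=np.int64)
    cells = k * k
    offsets = (np.arange(n, dtype=np.int64) * cells)[:, None]
    counts_range = np.arange(ne + 1, dtype=float)
    nlogn = xlogy(counts_range, counts_range)
    for delta in range(1, d + 1):
        joint = lagged[delta] * k + child_col[None, :] + offsets
        counts = np.bincount(joint.ravel(), minlength=n * cells).reshape(n, k, k)
        h_pa, h_joint = _entropy_pair_terms(counts, ne, nlogn)
        mi = np.maximum(0.0, hs + h_pa - h_joint)
        better = mi > best_mi  # strict: earlier (smaller) lag wins ties
        best_lag[better] = delta
        best_mi[better] = mi[better]
    return best_lag


def learn_parents_star(
    dataset: DiscreteDataset,
    child: int,
    d: int,
    alpha: float | None = None,
    bound: str = "entropy",
    no_self_loops: bool = False,
) -> tuple[LaggedParentSet, SearchTrace]:
    """Parent-set search restricted to each regulator's single best lag
    (one candidate per gene), exact on that reduced candidate set."""
    if bound not in ("entropy", "logk"):
        raise InvalidParameterError(f"bound must be 'entropy' or 'logk', got {bound!r}")
    d = int(d)
    now, lagged = _candidate_columns(dataset, d)
    ne = now.shape[1]
    if alpha is None:
        alpha = default_alpha(ne)
    lags = optimal_lag_table(dataset, child, d)
    cands = [
        (g, int(lags[g]))
        for g in range(dataset.n_genes)
        if not (no_self_loops and g == child)
    ]
    cand_cols = np.stack([lagged[delta][g] for g, delta in cands])
    members, trace = _algorithm1(
        now[child], cands, cand_cols, dataset.k, alpha, bound, child
    )
    return LaggedParentSet(child, members), trace


def learn_network(
    dataset: DiscreteDataset,
    d: int,
    alpha: float | None = None,
    variant: str = "star",
    threads: int = 1,
    bound: str = "entropy",
    no_self_loops: bool = False,
    return_trace: bool = False,
):
    """Learn the whole transition network by applying the selected per-node
    learner to every gene.

    Nodes are independent (no intra-slice edges), so they may be learned in
    parallel; results are merged by node index and the output is identical
    for any thread count.
    """
    if variant not in ("plus", "star"):
        raise InvalidParameterError(f"variant must be 'plus' or 'star', got {variant!r}")
    learner = learn_parents_plus if variant == "plus" else learn_parents_star

    def one(child: int):
        return learner(
            dataset, child, d, alpha=alpha, bound=bound, no_self_loops=no_self_loops
        )

    genes = range(dataset.n_genes)
    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(one, genes))
    else:
        results = [one(g) for g in genes]
    network = DbnNetwork(
        parent_sets=tuple(r[0] for r in results),
        d=int(d),
        gene_ids=dataset.gene_ids,
    )
    if return_trace:
        return network, [r[1] for r in results]
    return network


def exhaustive_oracle(
    dataset: DiscreteDataset,
    child: int,
    d: int,
    alpha: float | None = None,
    max_card: int = 0,
    bound: str = "entropy",
    no_self_loops: bool = False,
) -> LaggedParentSet:
    """Brute-force minimum-score parent set over all subsets of the lagged
    candidates with cardinality <= ``max_card``.

    Enumerates every subset with no early stopping, using the same
    candidate order and tie rule as the main search; guarded to at most
    ``ORACLE_SUBSET_GUARD`` subsets.
    """
    d = int(d)
    ne = align_samples(dataset, child, (), d).ne
    if alpha is None:
        alpha = default_alpha(ne)
    cands = _plus_candidates(dataset.n_genes, d, child, no_self_loops)
    nc = len(cands)
    max_card = min(int(max_card), nc)
    total = sum(math.comb(nc, p) for p in range(0, max_card + 1))
    if total > ORACLE_SUBSET_GUARD:
        raise GuardExceededError(
            f"{total} subsets exceed the oracle guard of {ORACLE_SUBSET_GUARD}; "
            "reduce max_card or the candidate count"
        )
    penalty = PenaltyTable(alpha, dataset.k)
    best_members: tuple[tuple[int, int], ...] = ()
    best_s = parent_set_score(
        dataset, child, (), d, alpha, bound=bound, penalty=penalty
    ).s
    for p in range(1, max_card + 1):
        for combo in combinations(cands, p):
            s = parent_set_score(
                dataset, child, combo, d, alpha, bound=bound, penalty=penalty
            ).s
            if s < best_s:
                best_s = s
                best_members = combo
    return LaggedParentSet(child, best_members)
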