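"""The MIT scoring metric for d-th order dynamic Bayesian networks.

The score of a candidate parent set Pa_i of child X_i combines a
goodness-of-fit term, 2 Ne I_s(X_i, Pa_i) -- twice the effective sample
count times the time-delayed mutual information between the child and the
joint configuration of its lagged parents -- with a complexity penalty that
charges each added parent the alpha-quantile of a chi-square distribution
whose degrees of freedom grow with the joint state space:

    l_j = (r_i - 1)(r_j - 1) * prod(states of previously charged parents),

parents being charged in decreasing order of state count.  Under variable
uniformity (all variables share k states) this reduces to
``(k-1)^2 k^(j-1)``, so the penalty depends only on the parent-set
cardinality -- the property that makes the global search polynomial.

For minimization the score is written s = v + u with u the penalty and
v = 2 Ne (H_s(X_i) - I_s(X_i, Pa_i)) >= 0 (entropy bound; a looser
``log k`` bound is selectable).  H_s is the plug-in entropy of the child
column after the d-unit shift.

All information quantities are in nats: the chi-square calibration of
2N*I (the G-statistic) holds for natural logarithms.  Probabilities are
plug-in (maximum-likelihood) estimates from raw counts, with 0 log 0 := 0,
so I_s(X, {}) = 0 holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.special import xlogy

from .data import DiscreteDataset, align_samples
from .errors import EmptyDataError, GuardExceededError, InvalidParameterError

__all__ = [
    "LaggedParentSet",
    "PenaltyTable",
    "ScoreParts",
    "NetworkScore",
    "shifted_entropy",
    "time_delayed_mi",
    "penalty_dof",
    "build_penalty_table",
    "parent_set_score",
    "network_score",
    "write_score_report",
]

#: largest chi-square degrees of freedom accepted before refusing outright
MAX_DOF = 10**7


@dataclass(frozen=True)
class LaggedParentSet:
    """A child gene's parents, each a ``(gene index, lag)`` pair.

    Lags are in time units, 1-based: ``(j, delta)`` means X_j[t - delta]
    regulates the child at time t.  May be empty.
    """

    child: int
    members: tuple[tuple[int, int], ...] = ()

    def __init__(self, child: int, members: Iterable[tuple[int, int]] = ()):
        members = tuple((int(g), int(lag)) for g, lag in members)
        if len(set(members)) != len(members):
            raise InvalidParameterError("duplicate (gene, lag) pair in parent set")
        for g, lag in members:
            if lag < 1:
                raise InvalidParameterError(f"lag must be >= 1, got {lag}")
        object.__setattr__(self, "child", int(child))
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


class PenaltyTable:
    """Chi-square penalty quantiles and their cumulative sums for (alpha, k).

    Entry ``j`` (1-based) is the alpha-quantile of chi-square with
    ``(k-1)^2 k^(j-1)`` degrees of freedom; ``u(p)`` returns the cumulative
    sum over the first ``p`` entries, i.e. the total complexity charge of
    any parent set of cardinality ``p`` under variable uniformity.
    The table extends itself on demand and caches per instance.
    """

    def __init__(self, alpha: float, k: int, max_p: int = 0):
        if not 0.0 < alpha < 1.0:
            raise InvalidParameterError(f"alpha must be in (0, 1), got {alpha}")
        if int(k) < 2:
            raise InvalidParameterError(f"k must be >= 2, got {k}")
        self.alpha = float(alpha)
        self.k = int(k)
        self._chi: list[float] = []
        self._cum: list[float] = []
        if max_p:
            self._ensure(int(max_p))

    def _ensure(self, p: int) -> None:
        while len(self._chi) < p:
            j = len(self._chi) + 1
            dof = (self.k - 1) ** 2 * self.k ** (j - 1)
            if dof > MAX_DOF:
                raise GuardExceededError(
                    f"chi-square degrees of freedom {dof} exceed {MAX_DOF} "
                    f"(parent-set cardinality {j})"
                )
            q = float(stats.chi2.ppf(self.alpha, dof))
            self._chi.append(q)
            self._cum.append((self._cum[-1] if self._cum else 0.0) + q)

    def chi(self, j: int) -> float:
        """Quantile charged to the j-th parent (1-based)."""
        if j < 1:
            raise InvalidParameterError("j must be >= 1")
        self._ensure(j)
        return self._chi[j - 1]

    def u(self, p: int) -> float:
        """Cumulative penalty U(p) of a cardinality-p parent set; U(0) = 0."""
        if p < 0:
            raise InvalidParameterError("p must be >= 0")
        if p == 0:
            return 0.0
        self._ensure(p)
        return self._cum[p - 1]

    @property
    def chi_values(self) -> tuple[float, ...]:
        return tuple(self._chi)

    @property
    def cumulative(self) -> tuple[float, ...]:
        return tuple(self._cum)


def build_penalty_table(alpha: float, k: int, max_p: int) -> PenaltyTable:
    """Precompute a :class:`PenaltyTable` up to cardinality ``max_p``."""
    return PenaltyTable(alpha, k, max_p=max_p)


@dataclass(frozen=True)
class ScoreParts:
    """Decomposed per-node score: s = v + u.

    ``v`` is the (bound-dependent) error term, ``u`` the chi-square
    complexity charge, ``mi`` the time-delayed mutual information used and
    ``ne`` the effective observation count.
    """

    v: float
    u: float
    mi: float
    ne: int
    s: float = field(init=False)

    def __post_init__(self) -> None:
        if self.v < 0 or self.u < 0:
            raise InvalidParameterError("score parts must be non-negative")
        object.__setattr__(self, "s", self.v + self.u)


def _entropy_of_codes(codes: np.ndarray) -> float:
    """Plug-in entropy (nats) of an integer code column; 0 log 0 := 0."""
    ne = codes.size
    if ne == 0:
        raise EmptyDataError("cannot estimate entropy from zero observations")
    _, counts = np.unique(codes, return_counts=True)
    return float(np.log(ne) - xlogy(counts, counts).sum() / ne)


def shifted_entropy(dataset: DiscreteDataset, gene: int, d: int) -> float:
    """Entropy H_s (nats) of ``gene`` estimated from its d-unit-shifted
    profile, i.e. the child column of the empty-parent alignment."""
    table = align_samples(dataset, gene, (), d)
    return _entropy_of_codes(table.child_column)


def _joint_codes(columns: Sequence[np.ndarray], k: int) -> np.ndarray:
    """Mixed-radix encoding of the joint configuration of integer columns."""
    if not columns:
        raise InvalidParameterError("need at least one column")
    code = columns[0].astype(np.int64)
    for col in columns[1:]:
        code = code * k + col
    return code


def time_delayed_mi(dataset: DiscreteDataset, child: int, parents, d: int) -> float:
    """Time-delayed mutual information I_s (nats) between the child and the
    joint configuration of its lagged parents.

    Returns exactly 0.0 for an empty parent set (I(X, {}) = 0 by
    convention).  Plug-in estimate on the aligned sample table.
    """
    members = tuple(getattr(parents, "members", parents))
    table = align_samples(dataset, child, members, d)
    if not members:
        return 0.0
    k = dataset.k
    h_child = _entropy_of_codes(table.child_column)
    pa_code = _joint_codes(table.parent_columns, k)
    h_pa = _entropy_of_codes(pa_code)
    h_joint = _entropy_of_codes(pa_code * k + table.child_column)
    return max(0.0, h_child + h_pa - h_joint)


def penalty_dof(
    parents: LaggedParentSet | Sequence[tuple[int, int]],
    state_counts: Sequence[int] | dict[int, int],
    child: int | None = None,
) -> tuple[int, ...]:
    """Degrees of freedom charged to each parent, general (non-uniform) form.

    Parents are sorted by state count descending (the permutation sigma);
    parent ``j`` (1-based, in sorted order) is charged

        (r_child - 1)(r_j - 1) * prod_{k < j} r_k,

    the first parent being charged ``(r_child - 1)(r_1 - 1)``.  Under
    variable uniformity this is ``(k-1)^2 k^(j-1)``.  Returns an empty tuple
    for an empty parent set.
    """
    if isinstance(parents, LaggedParentSet):
        if child is None:
            child = parents.child
        members = parents.members
    else:
        members = tuple(parents)
        if child is None:
            raise InvalidParameterError("child index required for plain parent lists")

    def r_of(gene: int) -> int:
        r = state_counts[gene]
        if r < 2:
            raise InvalidParameterError(f"state count for gene {gene} must be >= 2")
        return int(r)

    r_child = r_of(child)
    parent_rs = sorted((r_of(g) for g, _ in members), reverse=True)
    dofs = []
    running = 1
    for j, r in enumerate(parent_rs, start=1):
        dofs.append((r_child - 1) * (r - 1) * running)
        running *= r
    return tuple(dofs)


def parent_set_score(
    dataset: DiscreteDataset,
    child: int,
    parents,
    d: int,
    alpha: float,
    bound: str = "entropy",
    penalty: PenaltyTable | None = None,
) -> ScoreParts:
    """Score a candidate parent set for minimization: s = v + u.

    ``bound`` selects the constant replacing the intractable
    I_s(X_i, X^d) term: ``"entropy"`` uses H_s(X_i) (tighter, the default),
    ``"logk"`` uses log k.
    """
    if bound not in ("entropy", "logk"):
        raise InvalidParameterError(f"bound must be 'entropy' or 'logk', got {bound!r}")
    members = tuple(getattr(parents, "members", parents))
    table = align_samples(dataset, child, members, d)
    ne = table.ne
    k = dataset.k
    hs = _entropy_of_codes(table.child_column)
    mi = time_delayed_mi(dataset, child, members, d)
    cap = hs if bound == "entropy" else float(np.log(k))
    v = max(0.0, 2.0 * ne * (cap - mi))
    if penalty is None:
        penalty = PenaltyTable(alpha, k)
    u = penalty.u(len(members))
    return ScoreParts(v=v, u=u, mi=mi, ne=ne)


@dataclass(frozen=True)
class NetworkScore:
    """Whole-network MIT score in both orientations.

    ``s_mit`` is the higher-is-better total (sum over nodes with non-empty
    parent sets of 2 Ne I_s minus the penalty); ``total_min`` is the sum of
    per-node minimization parts; maximizing one is equivalent to minimizing
    the other on fixed data.
    """

    s_mit: float
    total_min: float
    per_node: tuple[ScoreParts, ...]


def network_score(
    dataset: DiscreteDataset,
    network,
    d: int,
    alpha: float,
    bound: str = "entropy",
    state_counts: Sequence[int] | None = None,
) -> NetworkScore:
    """Score a whole network (one lagged parent set per gene).

    ``network`` is a :class:`~mitdbn.search.DbnNetwork` or any object with a
    ``parent_sets`` sequence.  Nodes with empty parent sets contribute 0 to
    the maximization score.  ``state_counts`` (per-gene) activates the
    general non-uniform penalty of :func:`penalty_dof` in place of the
    uniform-k table; the global search itself never uses this path.
    """
    parent_sets = list(network.parent_sets)
    if len(parent_sets) != dataset.n_genes:
        raise InvalidParameterError("network and dataset gene counts differ")
    d = int(d)
    for ps in parent_sets:
        for g, lag in ps.members:
            if lag > d:
                raise InvalidParameterError(
                    f"network lag {lag} exceeds scoring order d={d}"
                )
    k = dataset.k
    table = PenaltyTable(alpha, k)
    s_max = 0.0
    parts = []
    for child, ps in enumerate(parent_sets):
        mi = time_delayed_mi(dataset, child, ps, d)
        ne = align_samples(dataset, child, (), d).ne
        hs = shifted_entropy(dataset, child, d)
        if state_counts is None:
            u = table.u(len(ps))
        else:
            dofs = penalty_dof(ps, state_counts, child=child)
            u = float(sum(stats.chi2.ppf(alpha, dof) for dof in dofs))
        cap = hs if bound == "entropy" else float(np.log(k))
        parts.append(ScoreParts(v=max(0.0, 2.0 * ne * (cap - mi)), u=u, mi=mi, ne=ne))
        if len(ps) > 0:
            s_max += 2.0 * ne * mi - u
    return NetworkScore(
        s_mit=s_max,
        total_min=float(sum(p.s for p in parts)),
        per_node=tuple(parts),
    )


def write_score_report(path, dataset: DiscreteDataset, network, d: int, alpha: float,
                       bound: str = "entropy") -> None:
    """Write a per-node TSV audit report: gene, |Pa|, Is, v, u, s."""
    import pandas as pd

    ns = network_score(dataset, network, d, alpha, bound=bound)
    rows = [
        {
            "gene": dataset.gene_ids[i],
            "n_parents": len(network.parent_sets[i]),
            "Is": p.mi,
            "v": p.v,
            "u": p.u,
            "s": p.s,
        }
        for i, p in enumerate(ns.per_node)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
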