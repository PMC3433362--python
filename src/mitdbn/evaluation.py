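"""Inference-quality metrics and degree-distribution analysis.

Edge recovery is scored against a lagged truth network as sensitivity
TP/(TP+FN) and precision TP/(TP+FP).  The default comparison is
lag-agnostic -- an edge counts if the (regulator, target) pair is
recovered at any lag -- because first-order learners evaluated against a
network containing higher-order edges can only be compared coherently
that way; a lag-aware mode requiring the exact lag is also provided.

Scale-free structure is assessed by fitting total node degree (in + out)
to P(x) ~ x^(-gamma) with the approximate discrete maximum-likelihood
estimator gamma_hat = 1 + n / sum(ln(x_i / (xmin - 1/2))).  The sharp
cutoff at xmin biases this estimator downward for small xmin; fitting the
tail (xmin around 4-6) recovers generating exponents accurately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .benchmarks import LaggedTruthNetwork
from .errors import InvalidInputError, InvalidParameterError
from .search import DbnNetwork

__all__ = [
    "EvalReport",
    "DegreeFit",
    "compare_networks",
    "degree_distribution",
    "powerlaw_mle",
]


@dataclass(frozen=True)
class EvalReport:
    """Edge-recovery counts and rates.

    ``sensitivity``/``precision`` are ``None`` (not 0 or 1) when their
    denominator is zero.  ``high_order_tp`` counts recovered truth edges
    whose true order is >= 2.
    """

    tp: int
    fp: int
    fn: int
    mode: str
    high_order_tp: int

    @property
    def sensitivity(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else None

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None


def _inferred_edge_set(network: DbnNetwork | LaggedTruthNetwork) -> set[tuple[str, str, int]]:
    if isinstance(network, LaggedTruthNetwork):
        return set(network.edges)
    return set(network.edges())


def _gene_universe(network: DbnNetwork | LaggedTruthNetwork) -> set[str]:
    if isinstance(network, LaggedTruthNetwork):
        return set(network.nodes)
    return set(network.gene_ids)


def compare_networks(
    inferred: DbnNetwork | LaggedTruthNetwork,
    truth: LaggedTruthNetwork,
    mode: str = "lag-agnostic",
) -> EvalReport:
    """TP/FP/FN edge counts of ``inferred`` against ``truth``.

    ``mode='lag-agnostic'`` (default) projects both edge sets to
    (regulator, target) pairs before counting; ``'lag-aware'`` requires the
    lag to match as well.
    """
    if mode not in ("lag-agnostic", "lag-aware"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    gi, gt = _gene_universe(inferred), _gene_universe(truth)
    if gi != gt:
        offenders = sorted(gi.symmetric_difference(gt))
        raise InvalidInputError(f"gene universes differ: {offenders}")
    inf_edges = _inferred_edge_set(inferred)
    true_edges = set(truth.edges)
    if mode == "lag-agnostic":
        inf_proj = {(r, t) for r, t, _ in inf_edges}
        true_proj = {(r, t) for r, t, _ in true_edges}
        tp_edges = inf_proj & true_proj
        tp, fp, fn = (
            len(tp_edges),
            len(inf_proj - true_proj),
            len(true_proj - tp_edges),
        )
        high = len({(r, t) for r, t, o in true_edges if o >= 2 and (r, t) in tp_edges})
    else:
        tp_edges3 = inf_edges & true_edges
        tp, fp, fn = (
            len(tp_edges3),
            len(inf_edges - true_edges),
            len(true_edges - tp_edges3),
        )
        high = len({e for e in tp_edges3 if e[2] >= 2})
    return EvalReport(tp=tp, fp=fp, fn=fn, mode=mode, high_order_tp=high)


def degree_distribution(network: DbnNetwork | LaggedTruthNetwork) -> dict[str, int]:
    """Total degree (in + out) per node; a self-loop counts once for in
    and once for out, so degrees sum to twice the edge count."""
    nodes = (
        network.nodes if isinstance(network, LaggedTruthNetwork) else network.gene_ids
    )
    deg = {v: 0 for v in nodes}
    edges = (
        network.edges if isinstance(network, LaggedTruthNetwork) else network.edges()
    )
    for r, t, _ in edges:
        deg[r] += 1
        deg[t] += 1
    return deg


@dataclass(frozen=True)
class DegreeFit:
    """Power-law fit of a degree sequence: ML exponent and cutoff used."""

    degrees: tuple[int, ...]
    gamma_hat: float
    xmin: int
    n_tail: int


def powerlaw_mle(degrees: Sequence[int], xmin: int = 1) -> DegreeFit:
    """Approximate discrete ML estimate of the power-law exponent.

        gamma_hat = 1 + n / sum_i ln(x_i / (xmin - 1/2)),  over x_i >= xmin.

    Zeros (and anything below ``xmin``) are excluded.  All-identical tail
    values make the likelihood divergent and raise an error.
    """
    if xmin < 1:
        raise InvalidParameterError(f"xmin must be >= 1, got {xmin}")
    x = np.asarray(degrees, dtype=float)
    tail = x[x >= xmin]
    if tail.size < 2:
        raise InvalidInputError(
            f"need at least 2 observations >= xmin={xmin}, got {tail.size}"
        )
    if np.all(tail == tail[0]):
        raise InvalidInputError(
            "all tail values identical: the ML exponent diverges"
        )
    gamma = 1.0 + tail.size / float(np.sum(np.log(tail / (xmin - 0.5))))
    return DegreeFit(
        degrees=tuple(int(v) for v in np.asarray(degrees).ravel()),
        gamma_hat=gamma,
        xmin=int(xmin),
        n_tail=int(tail.size),
    )
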