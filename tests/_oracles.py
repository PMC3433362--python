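"""Independent brute-force oracles for information quantities and scores.

Deliberately naive: pure-dict contingency counting with explicit loops and
math.log, plus chi-square quantiles through the regularized incomplete
gamma inverse -- separate code paths from the package implementation.
"""

from __future__ import annotations

import math
from collections import Counter

from scipy.special import gammaincinv


def entropy_oracle(column) -> float:
    """Plug-in entropy (nats) by explicit counting."""
    counts = Counter(int(v) for v in column)
    n = sum(counts.values())
    h = 0.0
    for c in counts.values():
        p = c / n
        h -= p * math.log(p)
    return h


def joint_mi_oracle(child, parent_columns) -> float:
    """MI (nats) between a child column and the joint configuration of
    parent columns, by nested-loop contingency counting."""
    if not parent_columns:
        return 0.0
    n = len(child)
    joint: Counter = Counter()
    pa: Counter = Counter()
    ch: Counter = Counter()
    for t in range(n):
        cfg = tuple(int(col[t]) for col in parent_columns)
        c = int(child[t])
        joint[(cfg, c)] += 1
        pa[cfg] += 1
        ch[c] += 1
    mi = 0.0
    for (cfg, c), cnt in joint.items():
        p_joint = cnt / n
        mi += p_joint * math.log(p_joint * n * n / (pa[cfg] * ch[c]))
    return mi


def chi2_quantile_oracle(alpha: float, dof: int) -> float:
    """alpha-quantile of chi-square(dof) via the inverse regularized
    incomplete gamma function: x = 2 * P^{-1}(dof/2, alpha)."""
    return 2.0 * float(gammaincinv(dof / 2.0, alpha))


def score_oracle(dataset, child, members, d, alpha, bound="entropy"):
    """Recompute the minimization score s = v + u from raw counts, using
    only the alignment helper plus the oracles above."""
    from mitdbn.data import align_samples

    table = align_samples(dataset, child, members, d)
    ne = table.ne
    k = dataset.k
    hs = entropy_oracle(table.child_column)
    mi = joint_mi_oracle(table.child_column, table.parent_columns)
    cap = hs if bound == "entropy" else math.log(k)
    v = 2.0 * ne * (cap - mi)
    u = sum(
        chi2_quantile_oracle(alpha, (k - 1) ** 2 * k ** (j - 1))
        for j in range(1, len(tuple(members)) + 1)
    )
    return v + u
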