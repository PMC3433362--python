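# mitdbn

Globally optimal learning of **high-order dynamic Bayesian networks** for
gene-regulatory-network inference from time-course expression data, under
the **MIT (mutual information test) score**.

Genetic interactions are time-delayed — a regulator's protein must be
translated, folded and translocated before its target's transcription
responds — and different regulators of the same gene act with different
lags. `mitdbn` models a gene network as the transition network of a
stationary d-th order Markov DBN whose edges all cross time slices: an
edge X_j --(δ)--> X_i says gene j's state at time t−δ informs gene i's
state at time t, δ ∈ {1..d}. Because edges only run forward in time,
acyclicity is automatic and each gene's parents can be learned
independently — and, unusually for network-structure learning, *exactly*.

## The score and the search

The MIT score balances fit against statistical significance. For child
X_i with lagged parent set Pa_i (s_i parents, all variables discretized
to k states, Ne effective observations after lag alignment):

    S″_MIT  =  Σ_{i: Pa_i≠∅}  [ 2·Ne·I_s(X_i, Pa_i)  −  Σ_{j=1..s_i} χ²_{α, (k−1)² k^(j−1)} ]

where I_s is the time-delayed mutual information (child shifted d units,
each parent shifted to its own lag, never pairing observations across
series boundaries) and each added parent is charged the α-quantile of a
chi-square law whose degrees of freedom grow with the joint state space.

Two exact per-node learners are provided:

* `learn_parents_plus` — searches **all** subsets of the n·d lagged
  candidates in increasing cardinality p, stopping as soon as the
  cumulative penalty U(p) alone reaches the best score found: no larger
  set can win, so the result is the global optimum, reached after at most
  p* ≈ log_k(Ne) levels (the GlobalMIT+ algorithm).
* `learn_parents_star` — first pins each candidate regulator to its
  single MI-maximizing lag, then runs the same exact search over n
  candidates (GlobalMIT*): first-order cost, order-d lag coverage.

A brute-force `exhaustive_oracle` with the identical tie rule certifies
optimality in the test suite, and every search returns a `SearchTrace`
recording the levels enumerated, the stopping point and both p* bounds.

## Worked example

Simulate the packaged 35-gene, 52-edge glucose-homeostasis cascade
(13/23/16 edges of order 1/2/3), learn networks at d=1 and d=3, and
evaluate against the ground truth:

```python
from mitdbn import (glucose_fixture, SimulationSpec, simulate_static_then_shift,
                    to_discrete, learn_network, compare_networks)

truth = glucose_fixture()                      # 35 nodes, 52 lagged edges
spec = SimulationSpec(cpt_strength=0.9, n_series=3, length=25, k=2, seed=7)
data = to_discrete(simulate_static_then_shift(truth, spec), 2)

net_d1 = learn_network(data, d=1, variant="plus")
net_d3 = learn_network(data, d=3, variant="star")
for name, net in [("d=1", net_d1), ("d=3", net_d3)]:
    r = compare_networks(net, truth)           # lag-agnostic by default
    print(f"{name}: Se={r.sensitivity:.3f} Pr={r.precision:.3f} "
          f"high-order TP={r.high_order_tp}")
```

prints

```
d=1: Se=0.115 Pr=0.500 high-order TP=0
d=3: Se=0.519 Pr=0.871 high-order TP=21
```

The first-order learner can only see the 13 lag-1 edges (25% of the
truth), while the third-order learner recovers half of the network —
including 21 of the 39 second/third-order interactions — at high
precision. The same workflow is available from the shell:

```sh
mitdbn simulate --template glucose --series 3 --n-obs 25 --seed 7 \
       --output-data expr.tsv --output-truth truth.tsv
mitdbn learn --input expr.tsv --series-lengths 25,25,25 --discrete --k 2 \
       --order 3 --variant star --output net.tsv
mitdbn evaluate --inferred net.tsv --truth truth.tsv
```

Further subcommands: `discretize` (3-state quantile discretization),
`upsample` (cubic-spline refinement of coarsely sampled series),
`shuffle` (per-gene permutation negative control) and `degree-fit`
(power-law exponent of the degree distribution by approximate discrete
maximum likelihood).

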