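"""MIT score machinery: entropies, time-delayed MI, chi-square penalties."""

import math

import numpy as np
import pytest

from mitdbn import (
    DiscreteDataset,
    LaggedParentSet,
    PenaltyTable,
    build_penalty_table,
    network_score,
    parent_set_score,
    penalty_dof,
    shifted_entropy,
    time_delayed_mi,
)
from mitdbn.errors import GuardExceededError, InvalidParameterError
from mitdbn.scoring import MAX_DOF
from mitdbn.search import DbnNetwork

from ._oracles import chi2_quantile_oracle, entropy_oracle, joint_mi_oracle


def _single(mat, k):
    return DiscreteDataset([np.asarray(mat)], k=k, gene_ids=[f"g{i}" for i in range(len(mat))])


class TestShiftedEntropy:
    def test_balanced_binary_column_is_ln2(self):
        ds = _single([[0] * 5 + [1] * 5, [0, 1] * 5], k=2)
        # child column of gene 1 at d=1 drops the first observation: 1,0,1,...
        h = shifted_entropy(ds, 1, d=1)
        assert h == pytest.approx(entropy_oracle(ds.series[0][1][1:]), abs=1e-15)

    def test_constant_column_is_zero(self):
        ds = _single([[1] * 8, [0, 1] * 4], k=2)
        assert shifted_entropy(ds, 0, d=1) == 0.0

    def test_plug_in_formula_on_three_states(self):
        # column (0,0,1,2): -(1/2 ln 1/2 + 1/4 ln 1/4 + 1/4 ln 1/4)
        ds = _single([[0, 0, 0, 1, 2]], k=3)
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert shifted_entropy(ds, 0, d=1) == pytest.approx(expected, abs=1e-12)


class TestTimeDelayedMI:
    def test_empty_parent_set_is_exactly_zero(self, random_discrete):
        assert time_delayed_mi(random_discrete(), 0, [], d=2) == 0.0

    def test_deterministic_copy_saturates_at_child_entropy(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, size=(2, 60))
        x[1, 1:] = x[0, :-1]
        ds = _single(x, k=2)
        mi = time_delayed_mi(ds, 1, [(0, 1)], d=1)
        assert mi == pytest.approx(shifted_entropy(ds, 1, d=1), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("k,n_parents", [(2, 1), (2, 2), (3, 2), (2, 3)])
    def test_matches_nested_loop_contingency_oracle(self, seed, k, n_parents):
        rng = np.random.default_rng(seed)
        ds = _single(rng.integers(0, k, size=(4, 20)), k=k)
        members = [(g + 1, 1 + g % 2) for g in range(n_parents)]
        got = time_delayed_mi(ds, 0, members, d=2)
        from mitdbn.data import align_samples

        table = align_samples(ds, 0, members, d=2)
        want = joint_mi_oracle(table.child_column, table.parent_columns)
        assert got == pytest.approx(want, abs=1e-12)

    def test_monotone_in_added_parents(self, random_discrete):
        ds = random_discrete(n=5, k=2, lengths=(40,), seed=11)
        base = [(1, 1)]
        mi0 = time_delayed_mi(ds, 0, base, d=2)
        for extra in [(2, 1), (3, 2), (4, 1)]:
            assert time_delayed_mi(ds, 0, base + [extra], d=2) >= mi0 - 1e-12

    def test_bounded_by_child_entropy(self, random_discrete):
        ds = random_discrete(n=4, k=3, lengths=(30,), seed=2)
        hs = shifted_entropy(ds, 0, d=1)
        mi = time_delayed_mi(ds, 0, [(1, 1), (2, 1)], d=1)
        assert 0.0 <= mi <= hs + 1e-12 and hs <= math.log(3) + 1e-12


class TestPenalties:
    def test_uniform_three_state_dofs(self):
        ps = LaggedParentSet(0, [(1, 1), (2, 2)])
        assert penalty_dof(ps, {0: 3, 1: 3, 2: 3}) == (4, 12)

    def test_uniform_binary_dofs(self):
        ps = LaggedParentSet(0, [(1, 1), (2, 1), (3, 1)])
        assert penalty_dof(ps, {i: 2 for i in range(4)}) == (1, 2, 4)

    def test_mixed_state_counts_sorted_descending(self):
        # child r=3, parents r=(2,4): sorted (4,2) -> 6 then 8
        ps = LaggedParentSet(0, [(1, 1), (2, 1)])
        assert penalty_dof(ps, {0: 3, 1: 2, 2: 4}) == (6, 8)

    def test_empty_parent_set_gives_empty_sequence(self):
        assert penalty_dof(LaggedParentSet(0), {0: 2}) == ()

    def test_quantiles_match_incomplete_gamma_oracle(self):
        table = build_penalty_table(alpha=0.999, k=3, max_p=3)
        assert table.chi(1) == pytest.approx(chi2_quantile_oracle(0.999, 4), rel=1e-10)
        assert table.chi(1) == pytest.approx(18.467, abs=5e-4)
        assert table.u(2) == pytest.approx(51.376, abs=5e-4)

    def test_cumulative_strictly_increasing(self):
        for alpha, k in [(0.9, 2), (0.999, 3), (0.5, 4)]:
            t = build_penalty_table(alpha, k, max_p=6)
            diffs = np.diff((0.0,) + t.cumulative)
            assert np.all(diffs > 0)

    def test_alpha_outside_unit_interval_rejected(self):
        with pytest.raises(InvalidParameterError):
            PenaltyTable(alpha=1.0, k=3)

    def test_dof_guard(self):
        t = PenaltyTable(alpha=0.999, k=10)
        with pytest.raises(GuardExceededError):
            t.u(9)  # (10-1)^2 * 10^8 dof
        assert MAX_DOF == 10**7

    def test_penalty_depends_only_on_cardinality(self, random_discrete):
        ds = random_discrete(n=5, k=3, lengths=(30,), seed=8)
        sets = [[(1, 1), (2, 1)], [(3, 2), (4, 1)], [(2, 2), (1, 2)]]
        us = {
            parent_set_score(ds, 0, s, d=2, alpha=0.999).u for s in sets
        }
        assert len(us) == 1


class TestParentSetScore:
    def test_empty_set_score_is_twice_ne_entropy(self, random_discrete):
        ds = random_discrete(n=3, k=2, lengths=(25,), seed=4)
        parts = parent_set_score(ds, 0, [], d=1, alpha=0.999)
        hs = shifted_entropy(ds, 0, d=1)
        assert parts.u == 0.0
        assert parts.s == pytest.approx(2 * 24 * hs, abs=1e-10)

    def test_deterministic_copy_scores_penalty_only(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, size=(2, 80))
        x[1, 1:] = x[0, :-1]
        ds = _single(x, k=2)
        parts = parent_set_score(ds, 1, [(0, 1)], d=1, alpha=0.999)
        assert parts.v == pytest.approx(0.0, abs=1e-9)
        assert parts.s == pytest.approx(chi2_quantile_oracle(0.999, 1), rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_score_oracle(self, seed, random_discrete):
        from ._oracles import score_oracle

        ds = random_discrete(n=4, k=2, lengths=(20, 15), seed=seed)
        members = [(1, 1), (3, 2)]
        got = parent_set_score(ds, 0, members, d=2, alpha=0.999)
        assert got.s == pytest.approx(
            score_oracle(ds, 0, members, 2, 0.999), abs=1e-9
        )

    def test_logk_bound_never_below_entropy_bound(self, random_discrete):
        ds = random_discrete(n=4, k=3, lengths=(30,), seed=6)
        v2 = parent_set_score(ds, 0, [(1, 1)], d=1, alpha=0.999, bound="entropy").v
        v1 = parent_set_score(ds, 0, [(1, 1)], d=1, alpha=0.999, bound="logk").v
        assert v1 >= v2 >= 0.0


class TestNetworkScore:
    def _random_network(self, ds, d, seed):
        rng = np.random.default_rng(seed)
        sets = []
        for child in range(ds.n_genes):
            n_par = int(rng.integers(0, 3))
            members = set()
            while len(members) < n_par:
                members.add((int(rng.integers(0, ds.n_genes)), int(rng.integers(1, d + 1))))
            sets.append(LaggedParentSet(child, tuple(sorted(members))))
        return DbnNetwork(tuple(sets), d=d, gene_ids=ds.gene_ids)

    def test_empty_network_scores_zero(self, random_discrete):
        ds = random_discrete(n=3)
        net = DbnNetwork(
            tuple(LaggedParentSet(i) for i in range(3)), d=1, gene_ids=ds.gene_ids
        )
        assert network_score(ds, net, d=1, alpha=0.999).s_mit == 0.0

    def test_maximization_minimization_equivalence(self, random_discrete):
        ds = random_discrete(n=5, k=2, lengths=(40,), seed=13)
        nets = [self._random_network(ds, 2, s) for s in range(6)]
        scored = [network_score(ds, g, d=2, alpha=0.999) for g in nets]
        order_max = np.argsort([-s.s_mit for s in scored])
        order_min = np.argsort([s.total_min for s in scored])
        assert np.array_equal(order_max, order_min)

    def test_single_edge_network_value(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, size=(2, 80))
        x[1, 1:] = x[0, :-1]
        ds = _single(x, k=2)
        net = DbnNetwork(
            (LaggedParentSet(0), LaggedParentSet(1, ((0, 1),))),
            d=1,
            gene_ids=ds.gene_ids,
        )
        ns = network_score(ds, net, d=1, alpha=0.999)
        hs = shifted_entropy(ds, 1, d=1)
        expected = 2 * 79 * hs - chi2_quantile_oracle(0.999, 1)
        assert ns.s_mit == pytest.approx(expected, rel=1e-9)

    def test_lag_beyond_order_rejected(self, random_discrete):
        ds = random_discrete(n=3)
        net = DbnNetwork(
            (LaggedParentSet(0, ((1, 2),)), LaggedParentSet(1), LaggedParentSet(2)),
            d=2,
            gene_ids=ds.gene_ids,
        )
        with pytest.raises(InvalidParameterError):
            network_score(ds, net, d=1, alpha=0.999)


class TestScoreReport:
    def test_tsv_report_columns_and_totals(self, tmp_path, random_discrete):
        import pandas as pd

        from mitdbn.scoring import write_score_report

        ds = random_discrete(n=4, k=2, lengths=(30,), seed=55)
        net = DbnNetwork(
            tuple(
                LaggedParentSet(i, ((i - 1, 1),) if i else ())
                for i in range(4)
            ),
            d=1,
            gene_ids=ds.gene_ids,
        )
        path = tmp_path / "report.tsv"
        write_score_report(path, ds, net, d=1, alpha=0.999)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["gene", "n_parents", "Is", "v", "u", "s"]
        assert np.allclose(df["s"], df["v"] + df["u"])
        assert df["n_parents"].tolist() == [0, 1, 1, 1]
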