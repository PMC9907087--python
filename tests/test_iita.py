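"""IITA engine: counterexamples, ladder construction, fit measure, selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motispace import (
    BinaryDataset,
    ItemDomain,
    NoiseModel,
    counterexample_counts,
    diff_fit,
    expected_counterexamples,
    gamma_estimate,
    generate_binary_dataset,
    inductive_ladder,
    make_relation,
    select_solution,
    zero_relation,
)
from motispace.errors import DomainError

from conftest import all_quasi_orders, random_quasi_order


def random_dataset(rng, m, n):
    rows = (rng.random((n, m)) < rng.uniform(0.1, 0.9, size=m)).astype(int)
    out = {}
    for r in rows:
        key = "".join(map(str, r))
        out[key] = out.get(key, 0) + 1
    return BinaryDataset(ItemDomain(tuple(f"x{k}" for k in range(m))), out)


class TestCounterexamples:
    def test_toy_counts(self, toy_data):
        cm = counterexample_counts(toy_data)
        x, y = 0, 1
        assert cm.b[x, y] == 2 and cm.b[y, x] == 1

    def test_intrinsic_fixture_spot_check(self):
        from motispace import load_fixture

        data = load_fixture("intrinsic")
        cm = counterexample_counts(data)
        i1, i2 = data.domain.index("i1"), data.domain.index("i2")
        # patterns 10000:3, 10011:1, 10101:1, 10111:4 have i1=1, i2=0
        assert cm.b[i1, i2] == 9

    def test_all_zero_item_has_no_counterexamples(self):
        data = BinaryDataset(ItemDomain(("x", "y")), {"01": 3, "00": 2})
        cm = counterexample_counts(data)
        assert cm.b[0].sum() == 0

    def test_single_item_rejected(self):
        with pytest.raises(DomainError):
            counterexample_counts(BinaryDataset(ItemDomain(("x",)), {"1": 2}))


class TestZeroRelation:
    def test_toy_gives_diagonal(self, toy_data):
        assert zero_relation(counterexample_counts(toy_data)).is_diagonal

    def test_noise_free_chain_recovered(self, external_chain):
        data = generate_binary_dataset(external_chain, 200, noise=NoiseModel(seed=3))
        assert zero_relation(counterexample_counts(data)) == external_chain

    @settings(derandomize=True, max_examples=250)
    @given(st.integers(0, 100_000))
    def test_transitivity_theorem_on_random_data(self, seed):
        """b[i,j]=0 and b[j,k]=0 force b[i,k]=0, so ⊑_0 needs no repair."""
        rng = np.random.default_rng(seed)
        data = random_dataset(rng, int(rng.integers(2, 7)), int(rng.integers(1, 40)))
        zero_relation(counterexample_counts(data))  # validator enforces transitivity


class TestLadder:
    def test_toy_ladder_steps(self, toy_data):
        ladder = inductive_ladder(toy_data)
        assert ladder[0][1].is_diagonal
        assert ladder[1][0] == 1
        # at tolerance 1 the eligible pair is the implication y ⟶ x
        # (1 counterexample), stored in the canonical orientation as x ⊑ y
        assert ladder[1][1].nonreflexive_pairs == {("x", "y")}
        assert ladder[-1][1].is_complete and ladder[-1][0] == 2

    def test_single_pattern_collapses_to_complete(self):
        data = BinaryDataset(ItemDomain(("a", "b", "c")), {"111": 5})
        ladder = inductive_ladder(data)
        assert len(ladder) == 1 and ladder[0][1].is_complete

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 100_000))
    def test_nesting_and_terminality(self, seed):
        rng = np.random.default_rng(seed)
        data = random_dataset(rng, int(rng.integers(2, 6)), int(rng.integers(2, 30)))
        ladder = inductive_ladder(data)
        for (la, ra), (lb, rb) in zip(ladder, ladder[1:]):
            assert la < lb
            assert ra <= rb and ra != rb
        assert ladder[-1][1].is_complete


class TestFitMeasure:
    def test_gamma_empty_set_is_zero(self, toy_data):
        diag = make_relation(toy_data.domain, set())
        assert gamma_estimate(diag, toy_data) == 0.0

    def test_gamma_toy_single_pair(self, toy_data):
        rel = make_relation(toy_data.domain, {("y", "x")})
        assert gamma_estimate(rel, toy_data) == pytest.approx(0.2)

    def test_gamma_zero_on_noise_free_chain(self, external_chain):
        data = generate_binary_dataset(external_chain, 300, noise=NoiseModel(seed=5))
        assert gamma_estimate(external_chain, data) == 0.0

    def test_expected_counts_toy(self, toy_data):
        rel = make_relation(toy_data.domain, {("y", "x")})
        t = expected_counterexamples(rel, toy_data, 0.2)
        x, y = 0, 1
        assert t[x, y] == pytest.approx(2.0)  # case 1: y ⊑ x
        assert t[y, x] == pytest.approx(1.0)  # case 3: x ⊑ y fails, y ⊑ x holds
    def test_case2_zero_when_marginals_one(self):
        data = BinaryDataset(ItemDomain(("x", "y")), {"11": 5})
        diag = make_relation(data.domain, set())
        t = expected_counterexamples(diag, data, 0.0)
        assert t[0, 1] == 0.0 and t[1, 0] == 0.0

    def test_toy_diff_zero_for_true_relation(self, toy_data):
        rel = make_relation(toy_data.domain, {("y", "x")})
        assert diff_fit(rel, toy_data).diff == pytest.approx(0.0)

    def test_diff_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        rows = (rng.random((40, 4)) < 0.5).astype(int)
        data = pattern_rows(rows, ("a", "b", "c", "d"))
        perm = [2, 0, 3, 1]
        data_p = pattern_rows(rows[:, perm], tuple(data.domain.labels[k] for k in perm))
        for rel_pairs in (set(), {("a", "b")}, {("a", "b"), ("b", "c"), ("a", "c")}):
            rel = make_relation(data.domain, rel_pairs, close=True)
            rel_p = make_relation(data_p.domain, rel_pairs, close=True)
            assert diff_fit(rel, data).diff == pytest.approx(diff_fit(rel_p, data_p).diff)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 100_000))
    def test_diff_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        data = random_dataset(rng, int(rng.integers(2, 6)), int(rng.integers(2, 30)))
        rel = random_quasi_order(rng, data.m)
        rel = make_relation(data.domain, {
            (data.domain.labels[int(a)], data.domain.labels[int(b)])
            for a, b in np.argwhere(rel.matrix)
        }, close=True)
        assert diff_fit(rel, data).diff >= 0.0


def pattern_rows(rows, items):
    out = {}
    for r in rows:
        key = "".join(map(str, r))
        out[key] = out.get(key, 0) + 1
    return BinaryDataset(ItemDomain(items), out)


class TestSelection:
    def test_single_candidate_selected(self):
        data = BinaryDataset(ItemDomain(("a", "b")), {"11": 5})
        result = select_solution(data)
        assert len(result.ladder) == 1 and result.selected == 0

    def test_noise_free_chain_selected(self):
        labels = ("a", "b", "c", "d")
        dom = ItemDomain(labels)
        chain = make_relation(
            dom, {(labels[a], labels[b]) for a in range(4) for b in range(a + 1, 4)}
        )
        data = generate_binary_dataset(chain, 100, noise=NoiseModel(seed=9))
        result = select_solution(data)
        assert result.solution == chain
        assert result.record.diff == pytest.approx(0.0)

    def test_selected_attains_minimum(self, toy_data):
        result = select_solution(toy_data)
        assert result.record.diff == min(r.diff for r in result.ladder)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 100_000))
    def test_ladder_minimum_bounded_by_global_optimum(self, seed):
        """The ladder's best diff can never beat exhaustive search over all
        quasi-orders, and matches it on noise-free structured data."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 5))
        data = random_dataset(rng, m, int(rng.integers(3, 15)))
        result = select_solution(data)
        global_min = min(diff_fit(q, data).diff for q in all_quasi_orders(data.domain))
        assert result.record.diff >= global_min - 1e-12

    def test_noise_free_global_optimum_attained(self, external_chain):
        data = generate_binary_dataset(external_chain, 400, noise=NoiseModel(seed=21))
        result = select_solution(data)
        assert result.record.diff == pytest.approx(0.0)
        assert result.solution == external_chain
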