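"""Relation algebra: construction, closure, quotients, restriction, covers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motispace import (
    ItemDomain,
    Poset,
    equivalence_classes,
    hasse_edges,
    make_relation,
    quotient_poset,
    restrict_relation,
    transitive_closure,
)
from motispace.errors import DomainError, TransitivityError

from conftest import closure_oracle, random_quasi_order


def _labels(m):
    return tuple(f"x{k}" for k in range(m))


pair_sets = st.integers(2, 8).flatmap(
    lambda m: st.tuples(
        st.just(m),
        st.sets(
            st.tuples(st.integers(0, m - 1), st.integers(0, m - 1)),
            max_size=m * m,
        ),
    )
)


class TestMakeRelation:
    def test_worked_example_pairs(self, worked_relation):
        assert worked_relation.nonreflexive_pairs == {
            ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")
        }
        assert all(worked_relation.contains(x, x) for x in "abcd")

    def test_empty_pairs_give_diagonal(self):
        rel = make_relation(ItemDomain(("x", "y")), set())
        assert rel.is_diagonal
        assert rel.pairs == {("x", "x"), ("y", "y")}

    def test_close_adds_composite_pair(self):
        rel = make_relation(ItemDomain(("a", "b", "c")), {("a", "b"), ("b", "c")}, close=True)
        assert rel.contains("a", "c")

    def test_unknown_label_rejected(self, abcd_domain):
        with pytest.raises(DomainError):
            make_relation(abcd_domain, {("a", "z")})

    def test_intransitive_without_close_names_triple(self):
        with pytest.raises(TransitivityError) as exc:
            make_relation(ItemDomain(("a", "b", "c")), {("a", "b"), ("b", "c")})
        assert exc.value.triple == ("a", "b", "c")

    @settings(derandomize=True, max_examples=100)
    @given(pair_sets)
    def test_closing_is_idempotent(self, spec):
        m, idx_pairs = spec
        labels = _labels(m)
        dom = ItemDomain(labels)
        pairs = {(labels[a], labels[b]) for a, b in idx_pairs}
        once = make_relation(dom, pairs, close=True)
        twice = make_relation(dom, once.pairs, close=True)
        assert once == twice

    @settings(derandomize=True, max_examples=100)
    @given(pair_sets)
    def test_closure_matches_reachability_oracle(self, spec):
        m, idx_pairs = spec
        labels = _labels(m)
        dom = ItemDomain(labels)
        pairs = {(labels[a], labels[b]) for a, b in idx_pairs}
        assert make_relation(dom, pairs, close=True).pairs == closure_oracle(labels, pairs)


class TestTransitiveClosure:
    def test_chain_cover_fills_all_pairs(self):
        m = 6
        labels = _labels(m)
        chain = {(labels[k], labels[k + 1]) for k in range(m - 1)}
        rel = transitive_closure((ItemDomain(labels), chain))
        assert len(rel.pairs) == m * (m + 1) // 2

    def test_already_transitive_unchanged(self, worked_relation):
        assert transitive_closure(worked_relation) == worked_relation

    def test_two_step_pair_added(self):
        rel = transitive_closure((ItemDomain(("e3", "e4", "e5")), {("e3", "e4"), ("e4", "e5")}))
        assert rel.contains("e3", "e5")


class TestQuotient:
    def test_parallel_items_share_block(self, external_chain):
        blocks = set(equivalence_classes(external_chain).blocks)
        assert blocks == {("e1", "e2"), ("e3",), ("e4",), ("e5",)}

    def test_diagonal_gives_singletons(self):
        rel = make_relation(ItemDomain(_labels(4)), set())
        assert all(len(b) == 1 for b in equivalence_classes(rel).blocks)

    def test_complete_relation_gives_one_block(self):
        labels = _labels(3)
        dom = ItemDomain(labels)
        rel = make_relation(dom, {(p, q) for p in labels for q in labels})
        assert equivalence_classes(rel).blocks == (labels,)

    def test_external_quotient_is_four_chain(self, external_chain):
        poset = quotient_poset(external_chain)
        assert poset.is_chain and len(poset) == 4
        order = sorted(poset.elements, key=lambda blk: poset.leq[:, poset.elements.index(blk)].sum())
        assert order == [("e3",), ("e4",), ("e5",), ("e1", "e2")]

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 10_000))
    def test_quotient_is_antisymmetric_for_random_quasiorders(self, seed):
        rng = np.random.default_rng(seed)
        rel = random_quasi_order(rng, int(rng.integers(1, 8)))
        quotient_poset(rel)  # Poset constructor validates antisymmetry


class TestRestrict:
    def test_singleton_restriction(self, worked_relation):
        rel = restrict_relation(worked_relation, {"c"})
        assert rel.pairs == {("c", "c")}

    def test_chain_restriction_keeps_order(self):
        labels = ("a", "b", "c")
        rel = make_relation(ItemDomain(labels), {("a", "b"), ("b", "c"), ("a", "c")})
        sub = restrict_relation(rel, {"a", "c"})
        assert sub.nonreflexive_pairs == {("a", "c")}

    def test_branch_restriction_is_chain(self, worked_relation):
        sub = restrict_relation(worked_relation, {"b", "c", "d"})
        assert quotient_poset(sub).is_chain

    def test_label_outside_domain_rejected(self, worked_relation):
        with pytest.raises(DomainError):
            restrict_relation(worked_relation, {"a", "zzz"})

    @settings(derandomize=True, max_examples=150)
    @given(st.integers(0, 10_000))
    def test_restriction_is_always_a_quasi_order(self, seed):
        rng = np.random.default_rng(seed)
        rel = random_quasi_order(rng, int(rng.integers(2, 8)))
        labels = list(rel.domain.labels)
        keep = [x for x in labels if rng.random() < 0.6] or labels[:1]
        sub = restrict_relation(rel, keep)
        # re-validate through the constructor
        type(sub)(sub.domain, sub.matrix)


class TestHasse:
    def test_chain_has_length_minus_one_covers(self, external_chain):
        assert len(hasse_edges(quotient_poset(external_chain))) == 3

    def test_antichain_has_no_covers(self):
        rel = make_relation(ItemDomain(_labels(4)), set())
        assert hasse_edges(quotient_poset(rel)) == frozenset()

    def test_diamond_has_four_covers(self):
        dom = ItemDomain(("bot", "l", "r", "top"))
        rel = make_relation(
            dom,
            {("bot", "l"), ("bot", "r"), ("l", "top"), ("r", "top"), ("bot", "top")},
        )
        assert len(hasse_edges(quotient_poset(rel))) == 4

    @settings(derandomize=True, max_examples=150)
    @given(st.integers(0, 10_000))
    def test_cover_closure_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        rel = random_quasi_order(rng, int(rng.integers(1, 8)))
        poset = quotient_poset(rel)
        covers = hasse_edges(poset)
        elems = poset.elements
        idx = {blk: k for k, blk in enumerate(elems)}
        mat = np.eye(len(elems), dtype=bool)
        for low, high in covers:
            mat[idx[low], idx[high]] = True
        closed = mat.copy()
        while True:
            nxt = closed | (closed @ closed)
            if (nxt == closed).all():
                break
            closed = nxt
        assert (closed == poset.leq).all()
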