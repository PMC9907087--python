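"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own algorithms: reachability by
DFS, downsets by power-set scan, width by antichain enumeration, and the
global IITA optimum by scoring every quasi-order on the domain.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from motispace import (
    BinaryDataset,
    ItemDomain,
    QuasiOrder,
    make_relation,
)

# ---------------------------------------------------------------- oracles


def closure_oracle(labels, pairs):
    """Reflexive-transitive closure by DFS reachability."""
    adj = {x: set() for x in labels}
    for p, q in pairs:
        adj[p].add(q)
    out = set()
    for start in labels:
        seen = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        out |= {(start, y) for y in seen}
    return out


def downsets_oracle(rel: QuasiOrder):
    """All relation-compatible subsets by scanning the full power set."""
    labs = rel.domain.labels
    states = []
    for bits in itertools.product([0, 1], repeat=len(labs)):
        members = {x for x, b in zip(labs, bits) if b}
        ok = all(
            p in members
            for p, q in rel.nonreflexive_pairs
            if q in members
        )
        if ok:
            states.append(tuple(x for x in labs if x in members))
    return set(states)


def width_oracle(rel: QuasiOrder):
    """Maximum antichain size of the quotient by subset enumeration."""
    from motispace import quotient_poset

    poset = quotient_poset(rel)
    k = len(poset)
    comp = poset.leq | poset.leq.T
    best = 0
    for size in range(1, k + 1):
        for combo in itertools.combinations(range(k), size):
            if all(not comp[a, b] for a, b in itertools.combinations(combo, 2)):
                best = size
                break
    return best


def all_quasi_orders(domain: ItemDomain):
    """Every quasi-order on the domain (only feasible for m ≤ 4)."""
    m = len(domain)
    off = [(a, b) for a in range(m) for b in range(m) if a != b]
    for bits in itertools.product([False, True], repeat=len(off)):
        mat = np.eye(m, dtype=bool)
        for (a, b), v in zip(off, bits):
            mat[a, b] = v
        if not ((mat @ mat) & ~mat).any():
            yield QuasiOrder(domain, mat)


def random_quasi_order(rng: np.random.Generator, m: int, density: float | None = None) -> QuasiOrder:
    labels = tuple(f"x{k}" for k in range(m))
    dom = ItemDomain(labels)
    density = rng.uniform(0.05, 0.5) if density is None else density
    pairs = {
        (labels[a], labels[b])
        for a in range(m)
        for b in range(m)
        if a != b and rng.random() < density
    }
    return make_relation(dom, pairs, close=True)


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def abcd_domain():
    return ItemDomain(("a", "b", "c", "d"))


@pytest.fixture(scope="session")
def worked_relation(abcd_domain):
    """The four-item example relation: a ⊑ d and b ⊑ c ⊑ d."""
    return make_relation(abcd_domain, {("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")})


@pytest.fixture(scope="session")
def worked_states():
    """Its quasi-ordinal space: {∅, {a}, {b}, {a,b}, {b,c}, {a,b,c}, M}."""
    return {(), ("a",), ("b",), ("a", "b"), ("b", "c"), ("a", "b", "c"), ("a", "b", "c", "d")}


@pytest.fixture(scope="session")
def toy_data():
    """Two-item dataset {11:8, 10:2, 01:1, 00:1} used for hand-checked IITA."""
    return BinaryDataset(ItemDomain(("x", "y")), {"11": 8, "10": 2, "01": 1, "00": 1})


@pytest.fixture(scope="session")
def external_chain():
    """The external-regulation solution: e3 ⊑ e4 ⊑ e5 ⊑ {e1 ≍ e2}."""
    dom = ItemDomain(("e1", "e2", "e3", "e4", "e5"))
    return make_relation(
        dom,
        {("e3", "e4"), ("e4", "e5"), ("e5", "e1"), ("e5", "e2"), ("e1", "e2"), ("e2", "e1")},
        close=True,
    )
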