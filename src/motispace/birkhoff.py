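"""Birkhoff correspondence between quasi-orders and quasi-ordinal state spaces.

A state space (knowledge/motivation structure) is a family of subsets of the
domain containing ∅ and the full domain.  When the family is closed under
union and intersection it is quasi-ordinal and corresponds one-to-one to a
quasi-order on the domain:

    p ⊑ q  ⟺  every state containing q contains p,
    H is a state  ⟺  whenever r ⊑ s and s ∈ H, also r ∈ H.

States are enumerated as downsets of the quotient poset (each equivalence
block expanded back to its items), which keeps the enumeration linear in the
number of states rather than in 2^m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np

from .errors import CapacityError, DomainError
from .relations import ItemDomain, Poset, QuasiOrder, quotient_poset

__all__ = [
    "StateSpace",
    "ClosureReport",
    "states_from_relation",
    "relation_from_states",
    "closure_properties",
    "cover_graph",
]

DEFAULT_STATE_CAP = 1_000_000


@dataclass(frozen=True)
class StateSpace:
    """A family of item subsets containing ∅ and the full domain.

    States are canonicalized as tuples of labels in domain order, with the
    family sorted by (size, positions) for stable equality and serialization.
    """

    domain: ItemDomain
    states: tuple[tuple[str, ...], ...]

    def __post_init__(self):
        canon = set()
        for st in self.states:
            unknown = set(st) - set(self.domain.labels)
            if unknown:
                raise DomainError(f"state {st} uses labels outside the domain: {sorted(unknown)}")
            if len(set(st)) != len(st):
                raise DomainError(f"state {st} repeats an item")
            canon.add(tuple(x for x in self.domain.labels if x in set(st)))
        if () not in canon:
            raise DomainError("state space must contain the empty state")
        if self.domain.labels not in canon:
            raise DomainError("state space must contain the full domain")
        key = lambda st: (len(st), tuple(self.domain.index(x) for x in st))
        object.__setattr__(self, "states", tuple(sorted(canon, key=key)))

    def __len__(self) -> int:
        return len(self.states)

    def __contains__(self, state: Iterable[str]) -> bool:
        state = set(state)
        return tuple(x for x in self.domain.labels if x in state) in set(self.states)


@dataclass(frozen=True)
class ClosureReport:
    union_closed: bool
    intersection_closed: bool

    @property
    def classification(self) -> str:
        if self.union_closed and self.intersection_closed:
            return "quasi-ordinal-space"
        if self.union_closed:
            return "space"
        if self.intersection_closed:
            return "closure-space"
        return "structure"


def states_from_relation(rel: QuasiOrder, cap: int = DEFAULT_STATE_CAP) -> StateSpace:
    """All subsets compatible with ``rel``: H such that s ∈ H and r ⊑ s ⟹ r ∈ H.

    Enumerates downsets of the quotient poset in a topological block order,
    then expands blocks to items.  Raises :class:`CapacityError` if the state
    count would exceed ``cap`` (e.g. near-diagonal relations on many items).
    """
    poset = quotient_poset(rel)
    k = len(poset)
    strict = poset.leq & ~np.eye(k, dtype=bool)
    order = sorted(range(k), key=lambda a: int(strict[:, a].sum()))  # linear extension
    below = [frozenset(map(int, np.flatnonzero(strict[:, a]))) for a in range(k)]

    downsets: list[frozenset[int]] = [frozenset()]
    for a in order:
        new = [ds | {a} for ds in downsets if below[a] <= ds]
        if len(downsets) + len(new) > cap:
            raise CapacityError("state count exceeds cap during downset enumeration", cap)
        downsets.extend(new)

    labs = rel.domain.labels
    states = []
    for ds in downsets:
        members = {x for a in ds for x in poset.elements[a]}
        states.append(tuple(x for x in labs if x in members))
    return StateSpace(rel.domain, tuple(states))


def relation_from_states(space: StateSpace) -> QuasiOrder:
    """p ⊑ q iff every state of ``space`` containing q also contains p.

    The input need not be union/intersection-closed (plain structures are
    accepted); the result is always a quasi-order, but the round trip back
    through :func:`states_from_relation` is the identity only for
    quasi-ordinal spaces.
    """
    dom = space.domain
    m = len(dom)
    member = np.zeros((len(space.states), m), dtype=bool)
    for r, st in enumerate(space.states):
        for x in st:
            member[r, dom.index(x)] = True
    mat = np.ones((m, m), dtype=bool)
    for q in range(m):
        holders = member[member[:, q]]
        if len(holders):
            mat[:, q] = holders.all(axis=0)
        mat[q, q] = True
    return QuasiOrder(dom, mat)


def closure_properties(space: StateSpace) -> ClosureReport:
    """Exhaustive pairwise union/intersection membership test."""
    fam = {frozenset(st) for st in space.states}
    states = list(fam)
    union_closed = all(a | b in fam for a in states for b in states)
    intersection_closed = all(a & b in fam for a in states for b in states)
    return ClosureReport(union_closed, intersection_closed)


def cover_graph(space: StateSpace) -> "nx.DiGraph":
    """Covering ("gain one item at a time") digraph on the states.

    Arc A → B iff A ⊂ B with no state strictly between.  The reverse
    ("loss") arcs are the edge-reversed view and are not stored.
    """
    fam = [frozenset(st) for st in space.states]
    g = nx.DiGraph()
    g.add_nodes_from(space.states)
    for a, A in enumerate(fam):
        for b, B in enumerate(fam):
            if not A < B:
                continue
            if not any(A < C < B for C in fam):
                g.add_edge(space.states[a], space.states[b])
    return g
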