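"""Interpretation of a selected co-occurrence relation.

Combinatorial dimensionality here means the Dilworth width of the quotient
poset: width 1 is a chain (unidimensional); the distance from a chain is
measured by the smallest set of item blocks whose removal leaves a chain,
equivalently a minimum vertex cover of the quotient's incomparability graph.
Also provides the meshing of overlapping subset solutions into one relation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import CapacityError, DomainError
from .relations import (
    ItemDomain,
    Partition,
    Poset,
    QuasiOrder,
    equivalence_classes,
    make_relation,
    quotient_poset,
)

__all__ = [
    "DimensionalityReport",
    "MergeResult",
    "order_width",
    "minimal_chain_pruning",
    "merge_solutions",
    "dimensionality_report",
]

PRUNING_BLOCK_CAP = 22


def order_width(poset: Poset) -> int:
    """Maximum antichain size (Dilworth number); 1 iff ``poset`` is a chain.

    Computed exactly via Dilworth's theorem: width equals the number of
    elements minus a maximum matching in the bipartite split graph of the
    strict order.
    """
    k = len(poset)
    if k == 0:
        return 0
    strict = poset.leq & ~np.eye(k, dtype=bool)
    g = nx.Graph()
    g.add_nodes_from(("u", a) for a in range(k))
    g.add_nodes_from(("v", b) for b in range(k))
    for a, b in np.argwhere(strict):
        g.add_edge(("u", int(a)), ("v", int(b)))
    matching = nx.bipartite.maximum_matching(g, top_nodes=[("u", a) for a in range(k)])
    return k - len(matching) // 2


def _incomparable_pairs(poset: Poset) -> list[tuple[int, int]]:
    k = len(poset)
    comp = poset.leq | poset.leq.T
    return [(a, b) for a in range(k) for b in range(a + 1, k) if not comp[a, b]]


def minimal_chain_pruning(rel: QuasiOrder) -> frozenset[frozenset[str]]:
    """All minimum-cardinality item sets whose removal leaves a chain.

    Works on the quotient: the minimum vertex covers of its incomparability
    graph, each expanded back to the union of the covered blocks' items.
    A chain input yields ``{∅}``.  Exact search, capped at
    ``PRUNING_BLOCK_CAP`` quotient blocks.
    """
    poset = quotient_poset(rel)
    k = len(poset)
    if k > PRUNING_BLOCK_CAP:
        raise CapacityError(f"quotient has {k} blocks; exact pruning search refused", PRUNING_BLOCK_CAP)
    edges = _incomparable_pairs(poset)
    if not edges:
        return frozenset({frozenset()})
    support = sorted({a for e in edges for a in e})
    for size in range(1, len(support) + 1):
        found = [
            frozenset(itertools.chain.from_iterable(poset.elements[a] for a in combo))
            for combo in itertools.combinations(support, size)
            if all(a in combo or b in combo for a, b in edges)
        ]
        if found:
            return frozenset(found)
    raise AssertionError("unreachable: removing all support vertices covers every edge")


def _longest_chain(leq: np.ndarray, alive: set[int]) -> list[int]:
    """Longest chain among ``alive`` elements of a reflexive-transitive leq."""
    order = sorted(alive, key=lambda a: sum(leq[b, a] for b in alive))
    best: dict[int, list[int]] = {}
    for a in order:
        preds = [b for b in order if b != a and leq[b, a]]
        prev = max((best[b] for b in preds if b in best), key=len, default=[])
        best[a] = prev + [a]
    return max(best.values(), key=len, default=[])


@dataclass(frozen=True)
class DimensionalityReport:
    """Summary of how close a quasi-order is to a single chain."""

    blocks: Partition
    quotient_size: int
    width: int
    is_chain: bool
    pruning_sets: frozenset[frozenset[str]]
    chains: tuple[tuple[tuple[str, ...], ...], ...]  # greedy maximal-chain cover

    def __post_init__(self):
        trivial = self.pruning_sets == frozenset({frozenset()})
        if (self.is_chain != (self.width <= 1)) or (self.is_chain != trivial):
            raise DomainError("inconsistent dimensionality report")


def dimensionality_report(rel: QuasiOrder) -> DimensionalityReport:
    """Equivalence blocks, width, pruning sets and a chain cover for ``rel``."""
    part = equivalence_classes(rel)
    poset = quotient_poset(rel)
    width = order_width(poset)
    pruning = minimal_chain_pruning(rel)

    alive = set(range(len(poset)))
    chains: list[tuple[tuple[str, ...], ...]] = []
    while alive:
        chain = _longest_chain(poset.leq, alive)
        chains.append(tuple(poset.elements[a] for a in chain))
        alive -= set(chain)

    return DimensionalityReport(
        blocks=part,
        quotient_size=len(poset),
        width=width,
        is_chain=width <= 1,
        pruning_sets=pruning,
        chains=tuple(chains),
    )


@dataclass(frozen=True)
class MergeResult:
    relation: QuasiOrder
    removed: frozenset[tuple[str, str]]  # base pairs dropped by a replace patch
    induced: frozenset[tuple[str, str]]  # pairs newly created by transitive closure


def merge_solutions(
    base: QuasiOrder,
    patches: list[tuple[QuasiOrder, str]],
) -> MergeResult:
    """Mesh subset solutions into ``base`` over its (master) domain.

    ``append`` unions the patch's pairs into the current relation;
    ``replace`` first drops the current pairs internal to the patch's
    domain, then inserts the patch's pairs.  Either way the transitive
    closure is taken, and the log records base pairs removed and closure
    pairs neither side stated.
    """
    master = base.domain
    pairs: set[tuple[str, str]] = set(base.pairs)
    removed: set[tuple[str, str]] = set()
    for patch, mode in patches:
        unknown = set(patch.domain.labels) - set(master.labels)
        if unknown:
            raise DomainError(f"patch items {sorted(unknown)} outside the master domain")
        if mode not in {"append", "replace"}:
            raise DomainError(f"merge mode must be 'append' or 'replace', got {mode!r}")
        if mode == "replace":
            inside = {
                (p, q)
                for p, q in pairs
                if p != q and p in patch.domain and q in patch.domain
            }
            dropped = inside - patch.pairs
            removed |= dropped
            pairs -= inside
        pairs |= patch.pairs
    merged = make_relation(master, pairs, close=True)
    induced = merged.pairs - frozenset(pairs)
    return MergeResult(merged, frozenset(removed), frozenset(induced))
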