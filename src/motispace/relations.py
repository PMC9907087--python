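"""Binary relations, quasi-orders, and poset utilities on small item domains.

A quasi-order (surmise relation, motivation co-occurrence relation) is a
reflexive and transitive binary relation ⊑ on a finite item domain.  The
stored pair (p, q) is read "p ⊑ q": whoever possesses item q also possesses
item p.  The implication arrow q ⟶ p used in graph renderings is derived
from this, never stored, so there is exactly one canonical orientation
throughout the package.

Relations are held as dense boolean incidence matrices addressed by domain
position; at the domain sizes that occur here (m ≤ 19) the O(m³) boolean
closure is exact and instantaneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import DomainError, TransitivityError

__all__ = [
    "ItemDomain",
    "QuasiOrder",
    "Partition",
    "Poset",
    "make_relation",
    "transitive_closure",
    "equivalence_classes",
    "quotient_poset",
    "restrict_relation",
    "hasse_edges",
]


@dataclass(frozen=True)
class ItemDomain:
    """An ordered set of distinct item labels.

    The label order is significant: it fixes the bit positions of response
    pattern strings and the row/column order of every matrix in the package.
    """

    labels: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        if len(labels) == 0:
            raise DomainError("domain must contain at least one item")
        if len(set(labels)) != len(labels):
            raise DomainError(f"duplicate item labels: {labels}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "_index", {x: k for k, x in enumerate(labels)})

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self._index

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise DomainError(f"unknown item label {label!r}; domain is {self.labels}") from None

    def subdomain(self, subset: Iterable[str]) -> "ItemDomain":
        """Restrict to ``subset``, keeping this domain's label order."""
        subset = set(subset)
        unknown = subset - set(self.labels)
        if unknown:
            raise DomainError(f"labels {sorted(unknown)} not in domain {self.labels}")
        return ItemDomain(tuple(x for x in self.labels if x in subset))


class QuasiOrder:
    """A reflexive, transitive relation on an :class:`ItemDomain`.

    Construct via :func:`make_relation` / :func:`transitive_closure`; the
    constructor validates reflexivity and transitivity of the given matrix.
    """

    __slots__ = ("domain", "matrix")

    def __init__(self, domain: ItemDomain, matrix: np.ndarray, *, _validate: bool = True):
        matrix = np.asarray(matrix, dtype=bool)
        m = len(domain)
        if matrix.shape != (m, m):
            raise DomainError(f"matrix shape {matrix.shape} does not match domain size {m}")
        if _validate:
            if not matrix.diagonal().all():
                missing = domain.labels[int(np.argmin(matrix.diagonal()))]
                raise TransitivityError((missing, missing, missing))
            viol = (matrix @ matrix) & ~matrix
            if viol.any():
                x, z = map(int, np.argwhere(viol)[0])
                y = int(np.flatnonzero(matrix[x] & matrix[:, z])[0])
                raise TransitivityError((domain.labels[x], domain.labels[y], domain.labels[z]))
        self.domain = domain
        self.matrix = matrix
        self.matrix.setflags(write=False)

    # -- queries ---------------------------------------------------------

    def contains(self, p: str, q: str) -> bool:
        """True iff p ⊑ q."""
        return bool(self.matrix[self.domain.index(p), self.domain.index(q)])

    @property
    def pairs(self) -> frozenset[tuple[str, str]]:
        """All stored pairs (p, q) with p ⊑ q, including the diagonal."""
        labs = self.domain.labels
        return frozenset((labs[a], labs[b]) for a, b in np.argwhere(self.matrix))

    @property
    def nonreflexive_pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset((p, q) for p, q in self.pairs if p != q)

    @property
    def is_complete(self) -> bool:
        return bool(self.matrix.all())

    @property
    def is_diagonal(self) -> bool:
        return int(self.matrix.sum()) == len(self.domain)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QuasiOrder):
            return NotImplemented
        return self.domain == other.domain and bool((self.matrix == other.matrix).all())

    def __le__(self, other: "QuasiOrder") -> bool:
        """Subset order on pair sets (domains must match)."""
        if self.domain != other.domain:
            raise DomainError("cannot compare relations over different domains")
        return bool((~self.matrix | other.matrix).all())

    def __hash__(self) -> int:
        return hash((self.domain.labels, self.matrix.tobytes()))

    def __repr__(self) -> str:
        return (
            f"QuasiOrder(m={len(self.domain)}, "
            f"pairs={len(self.nonreflexive_pairs)} non-reflexive)"
        )


@dataclass(frozen=True)
class Partition:
    """Disjoint non-empty blocks covering a domain (equivalence classes)."""

    domain: ItemDomain
    blocks: tuple[tuple[str, ...], ...]

    def __post_init__(self):
        seen: list[str] = [x for blk in self.blocks for x in blk]
        if sorted(seen) != sorted(self.domain.labels):
            raise DomainError("blocks must partition the domain exactly")

    def block_of(self, label: str) -> tuple[str, ...]:
        for blk in self.blocks:
            if label in blk:
                return blk
        raise DomainError(f"label {label!r} not in partition")


@dataclass(frozen=True)
class Poset:
    """An antisymmetric quasi-order whose elements are partition blocks.

    ``leq[a, b]`` means block ``elements[a]`` ≤ block ``elements[b]``.
    """

    elements: tuple[tuple[str, ...], ...]
    leq: np.ndarray

    def __post_init__(self):
        leq = np.asarray(self.leq, dtype=bool)
        k = len(self.elements)
        if leq.shape != (k, k):
            raise DomainError("leq shape does not match element count")
        if not leq.diagonal().all() or ((leq @ leq) & ~leq).any():
            raise TransitivityError(("<poset>",) * 3)
        if (leq & leq.T & ~np.eye(k, dtype=bool)).any():
            raise DomainError("poset relation is not antisymmetric")
        object.__setattr__(self, "leq", leq)
        self.leq.setflags(write=False)

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def is_chain(self) -> bool:
        return bool((self.leq | self.leq.T).all())


# -- construction --------------------------------------------------------


def _pairs_to_matrix(domain: ItemDomain, raw_pairs: Iterable[tuple[str, str]]) -> np.ndarray:
    m = len(domain)
    mat = np.eye(m, dtype=bool)
    for p, q in raw_pairs:
        mat[domain.index(p), domain.index(q)] = True
    return mat


def _warshall(mat: np.ndarray) -> np.ndarray:
    """Boolean transitive closure, iterated squaring until fixpoint."""
    closed = mat.copy()
    while True:
        nxt = closed | (closed @ closed)
        if (nxt == closed).all():
            return closed
        closed = nxt


def make_relation(
    domain: ItemDomain,
    raw_pairs: Iterable[tuple[str, str]],
    close: bool = False,
) -> QuasiOrder:
    """Build a quasi-order from a set of pairs (p, q) meaning p ⊑ q.

    Reflexive pairs are always added.  With ``close=True`` the transitive
    closure is taken; otherwise transitivity is verified and a violating
    triple reported.
    """
    mat = _pairs_to_matrix(domain, raw_pairs)
    if close:
        mat = _warshall(mat)
    return QuasiOrder(domain, mat)


def transitive_closure(rel: QuasiOrder | tuple[ItemDomain, Iterable[tuple[str, str]]]) -> QuasiOrder:
    """Smallest quasi-order containing the input pairs and the diagonal.

    Accepts either an existing :class:`QuasiOrder` (idempotent) or a
    ``(domain, pairs)`` tuple.
    """
    if isinstance(rel, QuasiOrder):
        return rel  # already closed by the class invariant
    domain, pairs = rel
    return QuasiOrder(domain, _warshall(_pairs_to_matrix(domain, pairs)))


# -- quotient machinery --------------------------------------------------


def equivalence_classes(rel: QuasiOrder) -> Partition:
    """Blocks of mutually implying ("parallel", equally informative) items.

    x and y share a block iff x ⊑ y and y ⊑ x: they occur in exactly the
    same states and cannot be separated empirically.
    """
    sym = rel.matrix & rel.matrix.T
    labs = rel.domain.labels
    seen: set[int] = set()
    blocks: list[tuple[str, ...]] = []
    for a in range(len(labs)):
        if a in seen:
            continue
        members = tuple(int(b) for b in np.flatnonzero(sym[a]))
        seen.update(members)
        blocks.append(tuple(labs[b] for b in members))
    return Partition(rel.domain, tuple(blocks))


def quotient_poset(rel: QuasiOrder) -> Poset:
    """Partial order induced on the equivalence blocks of ``rel``."""
    part = equivalence_classes(rel)
    reps = [rel.domain.index(blk[0]) for blk in part.blocks]
    leq = rel.matrix[np.ix_(reps, reps)]
    return Poset(part.blocks, leq)


def restrict_relation(rel: QuasiOrder, subset: Iterable[str]) -> QuasiOrder:
    """Relation induced on ``subset``: pairs of ``rel`` with both ends inside.

    Restriction preserves reflexivity and transitivity, so the result is
    again a quasi-order.
    """
    sub = rel.domain.subdomain(subset)
    idx = [rel.domain.index(x) for x in sub.labels]
    return QuasiOrder(sub, rel.matrix[np.ix_(idx, idx)], _validate=False)


def hasse_edges(poset: Poset) -> frozenset[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Covering pairs (A, B): A < B with no element strictly between."""
    k = len(poset)
    strict = poset.leq & ~np.eye(k, dtype=bool)
    # cover iff strict and no 2-step strict path
    covers = strict & ~(strict @ strict)
    return frozenset(
        (poset.elements[a], poset.elements[b]) for a, b in np.argwhere(covers)
    )
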