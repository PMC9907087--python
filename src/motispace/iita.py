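"""Inductive item tree analysis (IITA), corrected-estimator variant.

From a binary pattern–frequency dataset the algorithm

1. counts, for every ordered item pair, the respondents contradicting the
   implication i ⟶ j (solved i, failed j): the counterexample matrix b;
2. inductively constructs a nested ladder of candidate quasi-orders
   ⊑_0 ⊆ ⊑_1 ⊆ … by raising the tolerated number of counterexamples and
   repairing transitivity at each step;
3. scores every distinct candidate by diff, the mean squared deviation of b
   from its expectation t under a single response-error rate γ estimated
   for that candidate, and selects the minimum-diff candidate.

Pair orientation follows the package convention: the stored pair (j, i),
i.e. j ⊑ i, corresponds to the implication i ⟶ j with observed
counterexample count b[i, j].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dichotomize import BinaryDataset
from .errors import DomainError
from .relations import ItemDomain, QuasiOrder

__all__ = [
    "CounterexampleMatrix",
    "FitRecord",
    "IITAResult",
    "counterexample_counts",
    "zero_relation",
    "inductive_ladder",
    "gamma_estimate",
    "expected_counterexamples",
    "diff_fit",
    "select_solution",
]


@dataclass(frozen=True)
class CounterexampleMatrix:
    """b[i, j] = number of respondents with item i = 1 and item j = 0.

    The diagonal is structurally zero and excluded from all downstream sums.
    """

    domain: ItemDomain
    b: np.ndarray
    N: int

    def __post_init__(self):
        b = np.asarray(self.b, dtype=np.int64)
        object.__setattr__(self, "b", b)
        m = len(self.domain)
        if b.shape != (m, m):
            raise DomainError("counterexample matrix shape does not match domain")
        off = ~np.eye(m, dtype=bool)
        if (b < 0).any() or (b[off] > self.N).any() or ((b + b.T)[off] > self.N).any():
            raise DomainError("counterexample counts out of range for N")
        self.b.setflags(write=False)


@dataclass(frozen=True)
class FitRecord:
    """One candidate of the ladder with its fit diagnostics."""

    L: int
    relation: QuasiOrder
    gamma: float
    t: np.ndarray = field(compare=False)
    diff: float

    @property
    def n_pairs(self) -> int:
        return len(self.relation.nonreflexive_pairs)


@dataclass(frozen=True)
class IITAResult:
    """Deduplicated candidate ladder and the index of the minimum-diff entry."""

    ladder: tuple[FitRecord, ...]
    selected: int

    @property
    def solution(self) -> QuasiOrder:
        return self.ladder[self.selected].relation

    @property
    def record(self) -> FitRecord:
        return self.ladder[self.selected]


def counterexample_counts(data: BinaryDataset) -> CounterexampleMatrix:
    """Observed counterexample counts b for every ordered item pair."""
    if data.m < 2:
        raise DomainError("IITA needs at least two items")
    rows, freq = data.as_arrays()
    weighted = rows * freq[:, None]
    b = weighted.T @ (1 - rows)
    np.fill_diagonal(b, 0)
    return CounterexampleMatrix(data.domain, b, data.N)


def zero_relation(cm: CounterexampleMatrix) -> QuasiOrder:
    """⊑_0: j ⊑ i iff the implication i ⟶ j has zero counterexamples.

    This relation is transitive by construction (no repair needed), which
    the :class:`QuasiOrder` validator re-checks on every call.
    """
    m = len(cm.domain)
    mat = (cm.b.T == 0)
    np.fill_diagonal(mat, True)
    return QuasiOrder(cm.domain, mat)


def _repair(base: np.ndarray, cand: np.ndarray) -> np.ndarray:
    """Delete candidate pairs participating in transitivity violations.

    ``base`` (⊑_L) is immutable; only candidate pairs are ever removed.  A
    candidate pair (x, y) is marked iff in S = base ∪ cand there is a z with
    y ⊑ z but not x ⊑ z, or z ⊑ x but not z ⊑ y.  All marked pairs are
    deleted simultaneously and the scan repeats; the candidate set shrinks
    monotonically, so this terminates, and on exit S is transitive.
    """
    cand = cand.copy()
    while True:
        s = base | cand
        missing = ~s
        viol1 = missing @ s.T  # viol1[x,y]: ∃z with y ⊑ z but not x ⊑ z
        viol2 = s.T @ missing  # viol2[x,y]: ∃z with z ⊑ x but not z ⊑ y
        marked = cand & (viol1.astype(bool) | viol2.astype(bool))
        if not marked.any():
            return cand
        cand &= ~marked


def inductive_ladder(data: BinaryDataset) -> list[tuple[int, QuasiOrder]]:
    """The deduplicated nested candidate sequence ⊑_0 ⊆ ⊑_1 ⊆ … .

    For each tolerance level L+1 = 1 … N the pairs absent from ⊑_L with at
    most L+1 counterexamples are repaired for transitivity and merged.
    Consecutive identical relations are collapsed (keeping the smallest L),
    and construction stops once the complete relation is reached.
    """
    cm = counterexample_counts(data)
    bt = cm.b.T  # bt[j, i] = counterexamples of the implication behind j ⊑ i
    current = zero_relation(cm)
    ladder: list[tuple[int, QuasiOrder]] = [(0, current)]
    for tol in range(1, data.N + 1):
        if current.is_complete:
            break
        base = current.matrix
        cand = (~base) & (bt <= tol)
        cand = _repair(base, cand)
        merged = base | cand
        if (merged != base).any():
            current = QuasiOrder(cm.domain, merged)
            ladder.append((tol, current))
    return ladder


def _gamma_from_b(mat: np.ndarray, b: np.ndarray, p: np.ndarray, N: int) -> float:
    """γ: mean of b[i,j]/(p_i·N) over stored pairs j ⊑ i with i ≠ j, p_i ≠ 0."""
    m = mat.shape[0]
    off = ~np.eye(m, dtype=bool)
    sel = mat.T & off & (p[:, None] != 0)  # sel[i, j] ⟺ j ⊑ i, in b's orientation
    if not sel.any():
        return 0.0
    i_idx, j_idx = np.nonzero(sel)
    return float(np.mean(b[i_idx, j_idx] / (p[i_idx] * N)))


def gamma_estimate(rel: QuasiOrder, data: BinaryDataset) -> float:
    """Estimated single response-error rate under candidate ``rel``."""
    if rel.domain != data.domain:
        raise DomainError("relation and dataset domains differ")
    cm = counterexample_counts(data)
    return _gamma_from_b(rel.matrix, cm.b, data.p, data.N)


def expected_counterexamples(
    rel: QuasiOrder, data: BinaryDataset, gamma: float
) -> np.ndarray:
    """Expected counterexample counts t under ``rel`` at error rate ``gamma``.

    Three cases per ordered pair (i, j), i ≠ j:
      * j ⊑ i (implication holds): t = γ·p_i·N — pure response error;
      * incomparable: items treated as independent, t = (1−p_j)·p_i·N;
      * i ⊑ j only: t = max(0, (p_i − p_j + p_j·γ)·N).
    """
    if not 0 <= gamma <= 1:
        raise DomainError(f"gamma must be in [0, 1], got {gamma}")
    mat = rel.matrix
    p, N, m = data.p, data.N, data.m
    pi = p[:, None]  # p_i varies along rows of t
    pj = p[None, :]
    t = np.where(
        mat.T,  # j ⊑ i
        gamma * pi * N,
        np.where(
            mat,  # i ⊑ j (and not j ⊑ i)
            np.maximum(0.0, (pi - pj + pj * gamma) * N),
            (1.0 - pj) * pi * N,
        ),
    )
    np.fill_diagonal(t, 0.0)
    return t


def diff_fit(rel: QuasiOrder, data: BinaryDataset) -> FitRecord:
    """γ, t and the diff fit statistic for one candidate relation."""
    if data.m < 2:
        raise DomainError("diff needs at least two items")
    cm = counterexample_counts(data)
    gamma = _gamma_from_b(rel.matrix, cm.b, data.p, data.N)
    t = expected_counterexamples(rel, data, gamma)
    off = ~np.eye(data.m, dtype=bool)
    diff = float(((cm.b - t)[off] ** 2).sum() / (data.m * (data.m - 1)))
    return FitRecord(L=-1, relation=rel, gamma=gamma, t=t, diff=diff)


def select_solution(data: BinaryDataset) -> IITAResult:
    """Run the full IITA: ladder construction, diff scoring, minimum choice.

    Ties in diff are broken toward the earlier (sparser) ladder entry; with
    one code path and identical computation order the float comparison is
    exact and the procedure deterministic.
    """
    records = []
    for L, rel in inductive_ladder(data):
        rec = diff_fit(rel, data)
        records.append(FitRecord(L=L, relation=rel, gamma=rec.gamma, t=rec.t, diff=rec.diff))
    best = min(range(len(records)), key=lambda k: (records[k].diff, k))
    return IITAResult(tuple(records), best)
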