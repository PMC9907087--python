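"""Synthetic response data from a known quasi-ordinal structure.

The generator mirrors the error notion the IITA γ estimator targets: each
respondent occupies a latent state of the space induced by a true relation,
and every item response is flipped independently with a configurable
violation rate (a BLIM-style flip model; optionally split into a careless
1→0 rate and a lucky-guess 0→1 rate).  An optional Likert surface layer
re-encodes the binary truth as 1–5 scores with configurable balanced-score
and missingness rates, so the dichotomization stage can be exercised
end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .birkhoff import StateSpace, states_from_relation
from .dichotomize import BinaryDataset, LikertDataset, pattern_table
from .errors import DomainError
from .iita import diff_fit, select_solution
from .relations import QuasiOrder

__all__ = [
    "NoiseModel",
    "generate_binary_dataset",
    "generate_likert_dataset",
    "recovery_experiment",
    "RecoveryReport",
]


@dataclass(frozen=True)
class NoiseModel:
    """Independent per-item response error model.

    ``violation_rate`` is the probability that a *possessed* item is
    nevertheless answered negatively (a careless error) — the mechanism by
    which a true implication is violated in the data, and the quantity the
    IITA γ estimator is consistent for.  A lucky-guess rate (true 0 observed
    1) is off by default and can be switched on via ``guess_rate`` for
    robustness studies; guesses create counterexamples through the premise
    item rather than the conclusion, which biases γ upward, so they are not
    part of the calibrated default.  ``careless_rate`` is an alias that
    overrides ``violation_rate`` when both asymmetric rates are set
    explicitly.  All randomness flows through a generator seeded with
    ``seed``; no global state is touched.
    """

    violation_rate: float = 0.0
    careless_rate: float | None = None
    guess_rate: float | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("violation_rate", "careless_rate", "guess_rate"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must be in [0, 1], got {v}")

    @property
    def rate_10(self) -> float:
        return self.violation_rate if self.careless_rate is None else self.careless_rate

    @property
    def rate_01(self) -> float:
        return 0.0 if self.guess_rate is None else self.guess_rate

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _state_probs(space: StateSpace, dist) -> np.ndarray:
    if isinstance(dist, str):
        if dist != "uniform":
            raise DomainError(f"unknown distribution {dist!r}")
        return np.full(len(space), 1.0 / len(space))
    if isinstance(dist, Mapping):
        keys = {frozenset(st): float(p) for st, p in dist.items()}
        if set(keys) != {frozenset(st) for st in space.states}:
            raise DomainError("distribution keys must be exactly the states of the space")
        probs = np.array([keys[frozenset(st)] for st in space.states])
    else:
        probs = np.asarray(dist, dtype=float)
        if probs.shape != (len(space),):
            raise DomainError("distribution length must equal the state count")
    if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
        raise DomainError("state probabilities must be non-negative and sum to 1")
    return probs / probs.sum()


def _latent_rows(
    rel: QuasiOrder, n: int, dist, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    if n < 1:
        raise DomainError("need at least one respondent")
    space = states_from_relation(rel)
    probs = _state_probs(space, dist)
    member = np.zeros((len(space), len(rel.domain)), dtype=np.int64)
    for r, st in enumerate(space.states):
        for x in st:
            member[r, rel.domain.index(x)] = 1
    draw = rng.choice(len(space), size=n, p=probs)
    rows = member[draw]
    flip = np.where(rows == 1, noise.rate_10, noise.rate_01)
    rows = np.where(rng.random(rows.shape) < flip, 1 - rows, rows)
    return rows


def generate_binary_dataset(
    rel: QuasiOrder,
    n: int,
    dist="uniform",
    noise: NoiseModel = NoiseModel(),
) -> BinaryDataset:
    """Draw ``n`` respondents from the states of ``rel`` and add flip noise."""
    rows = _latent_rows(rel, n, dist, noise, noise.rng())
    return pattern_table(rows, rel.domain.labels)


def generate_likert_dataset(
    rel: QuasiOrder,
    n: int,
    dist="uniform",
    noise: NoiseModel = NoiseModel(),
    mid_rate: float = 0.0,
    miss_rate: float = 0.0,
) -> LikertDataset:
    """Likert surface over the latent binary draw.

    Each cell independently becomes the balanced score 3 with ``mid_rate``,
    missing with ``miss_rate``, and otherwise a uniform draw from {4, 5} for
    a latent 1 or {1, 2} for a latent 0 — so with both rates zero,
    dichotomization at the default thresholds recovers the binary data
    exactly.
    """
    if not (0 <= mid_rate and 0 <= miss_rate and mid_rate + miss_rate <= 1):
        raise DomainError("mid_rate and miss_rate must be non-negative with sum ≤ 1")
    rng = noise.rng()
    rows = _latent_rows(rel, n, dist, noise, rng)
    u = rng.random(rows.shape)
    half = rng.integers(0, 2, size=rows.shape)  # picks within {4,5} / {1,2}
    scores = np.where(rows == 1, 4 + half, 1 + half).astype(float)
    scores[u < mid_rate] = 3.0
    scores[(u >= mid_rate) & (u < mid_rate + miss_rate)] = np.nan
    return LikertDataset(pd.DataFrame(scores, columns=list(rel.domain.labels)))


@dataclass(frozen=True)
class RecoveryReport:
    replicates: int
    exact_fraction: float
    mean_precision: float
    mean_recall: float
    mean_diff_truth: float
    mean_diff_selected: float


def recovery_experiment(
    true_rel: QuasiOrder,
    n: int,
    noise: NoiseModel,
    replicates: int,
    dist="uniform",
) -> RecoveryReport:
    """Simulate, run the full IITA and compare edge-wise against the truth.

    Reports the fraction of replicates where the selected relation equals
    the truth exactly, mean precision/recall on non-reflexive pairs, and
    the mean diff of the true and selected relations.
    """
    if replicates < 1:
        raise DomainError("need at least one replicate")
    seeds = np.random.default_rng(noise.seed).integers(0, 2**31 - 1, size=replicates)
    true_pairs = true_rel.nonreflexive_pairs
    exact = prec = rec = d_true = d_sel = 0.0
    for s in seeds:
        rep_noise = NoiseModel(
            violation_rate=noise.violation_rate,
            careless_rate=noise.careless_rate,
            guess_rate=noise.guess_rate,
            seed=int(s),
        )
        data = generate_binary_dataset(true_rel, n, dist, rep_noise)
        result = select_solution(data)
        got = result.solution.nonreflexive_pairs
        exact += result.solution == true_rel
        hit = len(got & true_pairs)
        prec += hit / len(got) if got else 1.0
        rec += hit / len(true_pairs) if true_pairs else 1.0
        d_true += diff_fit(true_rel, data).diff
        d_sel += result.record.diff
    r = replicates
    return RecoveryReport(r, exact / r, prec / r, rec / r, d_true / r, d_sel / r)
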