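"""Dichotomization of Likert score tables into binary pattern–frequency data.

Scores run 1–5 with 3 the balanced mid-value.  A score ≤ 2 becomes 0 (not
endorsed), ≥ 4 becomes 1 (endorsed); a mid score or missing value makes the
cell indeterminate.  Filtering is listwise *relative to the analyzed item
subset*: a respondent is kept iff every cell within the subset is
determinate.  This is why the same raw table yields different sample sizes
for different subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyDatasetError, ParseError
from .relations import ItemDomain

__all__ = [
    "LikertDataset",
    "BinaryDataset",
    "dichotomize_and_filter",
    "pattern_table",
    "marginals",
]

MISSING_TOKENS = {"", "na", "n/a", "nan", ".", "-"}


@dataclass
class LikertDataset:
    """Respondent-by-item table of integer scores 1–5; NaN marks missing."""

    scores: pd.DataFrame  # float dtype, values in {1..5} or NaN

    def __post_init__(self):
        vals = self.scores.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, [1.0, 2.0, 3.0, 4.0, 5.0]))
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise ParseError(
                f"score {vals[r, c]!r} for item {self.scores.columns[c]!r} "
                f"(row {r}) is not an integer 1-5 or missing"
            )

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(self.scores.columns)

    @property
    def n_respondents(self) -> int:
        return len(self.scores)

    @classmethod
    def from_rows(cls, items: Sequence[str], rows: Iterable[Sequence]) -> "LikertDataset":
        """Build from raw rows; non-numeric / empty tokens are treated as missing."""
        parsed = []
        for row in rows:
            cells = []
            for cell in row:
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    cells.append(np.nan)
                    continue
                tok = str(cell).strip()
                if tok.lower() in MISSING_TOKENS:
                    cells.append(np.nan)
                else:
                    try:
                        cells.append(float(int(float(tok))))
                    except ValueError:
                        cells.append(np.nan)
            parsed.append(cells)
        return cls(pd.DataFrame(parsed, columns=list(items), dtype=float))


@dataclass(frozen=True)
class BinaryDataset:
    """Pattern → frequency table over an item domain.

    Pattern strings are positional: character k refers to ``domain.labels[k]``.
    """

    domain: ItemDomain
    patterns: dict[str, int] = field(hash=False)

    def __post_init__(self):
        m = len(self.domain)
        if not self.patterns:
            raise EmptyDatasetError("pattern table is empty")
        for pat, freq in self.patterns.items():
            if len(pat) != m or set(pat) - {"0", "1"}:
                raise ParseError(f"pattern {pat!r} is not a length-{m} 0/1 string")
            if not (isinstance(freq, (int, np.integer)) and freq >= 1):
                raise ParseError(f"frequency {freq!r} for pattern {pat!r} must be a positive integer")

    @property
    def N(self) -> int:
        return int(sum(self.patterns.values()))

    @property
    def n_unique(self) -> int:
        return len(self.patterns)

    @property
    def m(self) -> int:
        return len(self.domain)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(u × m) 0/1 pattern matrix and length-u frequency vector."""
        pats = sorted(self.patterns)
        rows = np.array([[int(c) for c in p] for p in pats], dtype=np.int64)
        freq = np.array([self.patterns[p] for p in pats], dtype=np.int64)
        return rows, freq

    def expand(self) -> np.ndarray:
        """One row per respondent (N × m), patterns in lexicographic order."""
        rows, freq = self.as_arrays()
        return np.repeat(rows, freq, axis=0)

    @property
    def p(self) -> np.ndarray:
        """Per-item relative frequency of 1s (solving/possessing the item)."""
        rows, freq = self.as_arrays()
        return (rows * freq[:, None]).sum(axis=0) / self.N


def dichotomize_and_filter(
    likert: LikertDataset,
    subset: Iterable[str] | None = None,
    low_max: int = 2,
    high_min: int = 4,
) -> BinaryDataset:
    """Dichotomize ``likert`` on ``subset`` and drop subset-incomplete rows.

    Cells ≤ ``low_max`` become 0, cells ≥ ``high_min`` become 1; anything
    else (the balanced mid score, missing) is indeterminate, and a row with
    any indeterminate cell inside ``subset`` is discarded entirely.
    """
    if low_max >= high_min:
        raise DomainError(f"low_max ({low_max}) must be < high_min ({high_min})")
    items = likert.items if subset is None else tuple(subset)
    if not items:
        raise DomainError("item subset must be non-empty")
    unknown = set(items) - set(likert.items)
    if unknown:
        raise DomainError(f"items {sorted(unknown)} not in the Likert table header")

    vals = likert.scores[list(items)].to_numpy(dtype=float)
    binary = np.where(vals <= low_max, 0, np.where(vals >= high_min, 1, -1))
    binary[np.isnan(vals)] = -1
    keep = (binary >= 0).all(axis=1)
    if not keep.any():
        raise EmptyDatasetError(
            f"no respondent has determinate scores on all of {items}"
        )
    return pattern_table(binary[keep], items)


def pattern_table(rows: np.ndarray | Iterable[Sequence[int]], items: Sequence[str]) -> BinaryDataset:
    """Aggregate 0/1 response rows into a pattern–frequency table."""
    rows = np.asarray(list(rows) if not isinstance(rows, np.ndarray) else rows)
    if rows.size == 0:
        raise EmptyDatasetError("no response rows to aggregate")
    if rows.ndim != 2 or not np.isin(rows, [0, 1]).all():
        raise ParseError("rows must be a rectangular 0/1 array")
    domain = ItemDomain(tuple(items))
    if rows.shape[1] != len(domain):
        raise DomainError(f"rows have {rows.shape[1]} columns for {len(domain)} items")
    patterns: dict[str, int] = {}
    for row in rows:
        key = "".join("1" if v else "0" for v in row)
        patterns[key] = patterns.get(key, 0) + 1
    return BinaryDataset(domain, patterns)


def marginals(data: BinaryDataset) -> pd.DataFrame:
    """Per-item 0/1 counts and relative frequency p_i, indexed by item label."""
    rows, freq = data.as_arrays()
    ones = (rows * freq[:, None]).sum(axis=0)
    out = pd.DataFrame(
        {
            "count0": data.N - ones,
            "count1": ones,
            "p": ones / data.N,
        },
        index=pd.Index(data.domain.labels, name="item"),
    )
    return out
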