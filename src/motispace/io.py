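"""File formats: pattern–frequency tables, Likert CSV, relations, state spaces.

All formats are plain text.  Pattern tables carry their item labels in a
``# items:`` comment so a file is self-describing; relation edge lists store
one non-reflexive pair "p<TAB>q" per line meaning p ⊑ q, with the diagonal
implied.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd

from .birkhoff import StateSpace
from .dichotomize import BinaryDataset, LikertDataset
from .errors import DomainError, EmptyDatasetError, ParseError
from .relations import (
    ItemDomain,
    QuasiOrder,
    equivalence_classes,
    hasse_edges,
    make_relation,
    quotient_poset,
)

__all__ = [
    "read_pattern_table",
    "write_pattern_table",
    "read_likert",
    "read_relation",
    "write_relation",
    "export_relation",
    "read_state_space",
    "write_state_space",
]

EMPTY_STATE_TOKEN = "∅"


# -- pattern-frequency tables -------------------------------------------


def read_pattern_table(path) -> BinaryDataset:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    items: tuple[str, ...] | None = None
    patterns: dict[str, int] = {}
    header_seen = False
    for no, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("items:"):
                items = tuple(x.strip() for x in body[len("items:"):].split(",") if x.strip())
            continue
        parts = line.split("\t")
        if not header_seen:
            if [p.strip().lower() for p in parts] != ["pattern", "frequency"]:
                raise ParseError("expected header 'pattern<TAB>frequency'", no)
            header_seen = True
            continue
        if len(parts) != 2:
            raise ParseError(f"expected two tab-separated fields, got {line!r}", no)
        pat, freq_s = parts[0].strip(), parts[1].strip()
        if set(pat) - {"0", "1"} or not pat:
            raise ParseError(f"pattern {pat!r} is not a 0/1 string", no)
        try:
            freq = int(freq_s)
        except ValueError:
            raise ParseError(f"frequency {freq_s!r} is not an integer", no) from None
        if freq < 1:
            raise ParseError(f"frequency must be positive, got {freq}", no)
        if pat in patterns:
            warnings.warn(f"{path}: duplicate pattern {pat} aggregated", stacklevel=2)
        patterns[pat] = patterns.get(pat, 0) + freq
    if not patterns:
        raise EmptyDatasetError(f"{path}: no pattern rows")
    m = len(next(iter(patterns)))
    if items is None:
        items = tuple(f"x{k + 1}" for k in range(m))
    return BinaryDataset(ItemDomain(items), patterns)


def write_pattern_table(data: BinaryDataset, path) -> None:
    lines = ["# items: " + ",".join(data.domain.labels), "pattern\tfrequency"]
    lines += [f"{pat}\t{data.patterns[pat]}" for pat in sorted(data.patterns)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# -- Likert tables -------------------------------------------------------


def read_likert(path, id_column: str | None = None) -> LikertDataset:
    """Delimited Likert table (separator sniffed), header row of item labels."""
    frame = pd.read_csv(path, sep=None, engine="python")
    if id_column is not None:
        if id_column not in frame.columns:
            raise DomainError(f"id column {id_column!r} not in header {list(frame.columns)}")
        frame = frame.drop(columns=[id_column])
    return LikertDataset.from_rows(tuple(frame.columns), frame.itertuples(index=False))


# -- relations -----------------------------------------------------------


def read_relation(path, domain: ItemDomain | None = None) -> QuasiOrder:
    """Edge list of p<TAB>q lines (p ⊑ q); closure taken, diagonal implied."""
    pairs: list[tuple[str, str]] = []
    items: tuple[str, ...] | None = None
    for no, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("items:"):
                items = tuple(x.strip() for x in body[len("items:"):].split(",") if x.strip())
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) != 2:
            raise ParseError(f"expected 'p<TAB>q', got {line!r}", no)
        pairs.append((parts[0], parts[1]))
    if domain is None:
        if items is not None:
            domain = ItemDomain(items)
        else:
            seen = sorted({x for pr in pairs for x in pr})
            if not seen:
                raise EmptyDatasetError(f"{path}: no pairs and no domain given")
            domain = ItemDomain(tuple(seen))
    return make_relation(domain, pairs, close=True)


def _generating_pairs(rel: QuasiOrder) -> list[tuple[str, str]]:
    """A small pair set whose reflexive-transitive closure is ``rel``.

    Within-block cycles encode the equivalences; one representative pair per
    Hasse cover of the quotient encodes the strict order.
    """
    part = equivalence_classes(rel)
    pairs: list[tuple[str, str]] = []
    for blk in part.blocks:
        for a, b in zip(blk, blk[1:] + blk[:1]):
            if a != b:
                pairs.append((a, b))
    for low, high in hasse_edges(quotient_poset(rel)):
        pairs.append((low[0], high[0]))
    return pairs


def write_relation(rel: QuasiOrder, path) -> None:
    lines = ["# items: " + ",".join(rel.domain.labels)]
    lines += [f"{p}\t{q}" for p, q in sorted(_generating_pairs(rel))]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def export_relation(rel: QuasiOrder, format: str, path) -> None:
    """Write ``rel`` as 'edges' (generating pairs), 'dot', or 'json'."""
    path = Path(path)
    if format == "edges":
        write_relation(rel, path)
    elif format == "dot":
        path.write_text(relation_to_dot(rel), encoding="utf-8")
    elif format == "json":
        part = equivalence_classes(rel)
        payload = {
            "domain": list(rel.domain.labels),
            "pairs": sorted([p, q] for p, q in rel.pairs),
            "blocks": [list(b) for b in part.blocks],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    else:
        raise DomainError(f"unknown export format {format!r}; use edges, dot or json")


def relation_to_dot(rel: QuasiOrder) -> str:
    """DOT digraph: one node per equivalence block, arcs in implication
    direction (q ⟶ p for each covering pair p ⊑ q)."""
    poset = quotient_poset(rel)
    node_id = {blk: f"n{k}" for k, blk in enumerate(poset.elements)}
    lines = ["digraph cooccurrence {", "  rankdir=BT;"]
    for blk, nid in node_id.items():
        lines.append(f'  {nid} [label="{",".join(blk)}"];')
    for low, high in sorted(hasse_edges(poset)):
        lines.append(f"  {node_id[high]} -> {node_id[low]};")
    lines.append("}")
    return "\n".join(lines) + "\n"


# -- state spaces --------------------------------------------------------


def read_state_space(path) -> StateSpace:
    """Text form: '# items:' header, then one state per line as
    comma-separated labels ('∅' for the empty state); or the JSON form."""
    text = Path(path).read_text(encoding="utf-8")
    if text.lstrip().startswith("{"):
        payload = json.loads(text)
        domain = ItemDomain(tuple(payload["domain"]))
        return StateSpace(domain, tuple(tuple(st) for st in payload["states"]))
    items: tuple[str, ...] | None = None
    states: list[tuple[str, ...]] = []
    for no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("items:"):
                items = tuple(x.strip() for x in body[len("items:"):].split(",") if x.strip())
            continue
        if line == EMPTY_STATE_TOKEN:
            states.append(())
        else:
            states.append(tuple(x.strip() for x in line.split(",") if x.strip()))
    if items is None:
        raise ParseError(f"{path}: missing '# items:' header naming the domain order")
    return StateSpace(ItemDomain(items), tuple(states))


def write_state_space(space: StateSpace, path) -> None:
    lines = ["# items: " + ",".join(space.domain.labels)]
    lines += [",".join(st) if st else EMPTY_STATE_TOKEN for st in space.states]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
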