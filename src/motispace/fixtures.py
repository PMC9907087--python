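"""Packaged datasets of the learning-motivation study.

The ten pattern–frequency tables are one-to-one transcriptions of the
printed appendix data (no deposited machine-readable version exists) and
validate against their printed sample size N and unique-pattern count u on
every load.  Column orders follow the printed tables; note the joint tables
list introjected items before identified/external ones.

``final_relation`` is different in kind: it is the meshed overall
co-occurrence relation, transcribed from a published *figure* rather than a
data table, so it is suitable for structural property checks but is not a
numeric target.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .dichotomize import BinaryDataset
from .errors import FixtureLookupError, ParseError
from .io import read_pattern_table, read_relation
from .relations import QuasiOrder

__all__ = ["FIXTURES", "load_fixture", "load_final_relation", "fixture_names"]


@dataclass(frozen=True)
class FixtureInfo:
    filename: str
    N: int
    u: int
    items: tuple[str, ...]


def _ids(prefix: str, nums) -> tuple[str, ...]:
    return tuple(f"{prefix}{k}" for k in nums)


I5 = _ids("i", range(1, 6))
E5 = _ids("e", range(1, 6))
D5 = _ids("d", range(1, 6))
J4 = _ids("j", range(1, 5))

FIXTURES: dict[str, FixtureInfo] = {
    "intrinsic": FixtureInfo("intrinsic.tsv", 948, 25, I5),
    "external": FixtureInfo("external.tsv", 1028, 30, E5),
    "identified": FixtureInfo("identified.tsv", 1073, 29, D5),
    "introjected": FixtureInfo("introjected.tsv", 1168, 16, J4),
    "autonomous": FixtureInfo("autonomous.tsv", 482, 59, I5 + D5),
    "controlled": FixtureInfo("controlled.tsv", 550, 134, J4 + E5),
    "all": FixtureInfo("all.tsv", 180, 109, I5 + J4 + D5 + E5),
    "subset_A": FixtureInfo(
        "subset_A.tsv", 342, 130,
        ("i1", "i3", "i4", "i5") + J4 + ("d5", "e3", "e4", "e5"),
    ),
    "subset_B": FixtureInfo("subset_B.tsv", 577, 52, I5 + D5[:4]),
    "subset_C": FixtureInfo("subset_C.tsv", 706, 114, J4 + ("d5", "e1", "e2", "e5")),
}

FINAL_RELATION_FILE = "final_relation.tsv"


def fixture_names() -> tuple[str, ...]:
    return tuple(FIXTURES) + ("final_relation",)


def _data_path(filename: str):
    return resources.files("motispace").joinpath("data", filename)


def load_fixture(name: str) -> BinaryDataset:
    """Load a packaged dataset, validating its printed N and u."""
    if name == "final_relation":
        raise FixtureLookupError(
            "'final_relation' is a relation, not a dataset; use load_final_relation()"
        )
    try:
        info = FIXTURES[name]
    except KeyError:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; valid names: {', '.join(fixture_names())}"
        ) from None
    with resources.as_file(_data_path(info.filename)) as path:
        data = read_pattern_table(path)
    if data.N != info.N or data.n_unique != info.u:
        raise ParseError(
            f"fixture {name}: got N={data.N}, u={data.n_unique}; "
            f"expected N={info.N}, u={info.u}"
        )
    if data.domain.labels != info.items:
        raise ParseError(f"fixture {name}: unexpected item order {data.domain.labels}")
    return data


def load_final_relation() -> QuasiOrder:
    """The meshed overall co-occurrence relation (figure-derived fixture)."""
    with resources.as_file(_data_path(FINAL_RELATION_FILE)) as path:
        return read_relation(path)
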