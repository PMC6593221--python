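"""96-well plate geometry, well addressing, and experiment layouts.

Wells are addressed by zero-based ``(row, col)`` coordinates: row A = 0
through H = 7, column 1 = 0 through 12 = 11.  Distances between wells are
Euclidean ("Pythagorean") in well units, matching how contamination
distance-decay is usually plotted.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .errors import AddressingError, LayoutError

N_ROWS = 8
N_COLS = 12
ROW_LETTERS = "ABCDEFGH"

_WELL_RE = re.compile(r"^([A-H])([1-9]|1[0-2])$")


class Role(str, Enum):
    """What a well holds: a high-biomass source isolate, a low-biomass sink
    isolate, a no-template blank (NTC), or nothing at all."""

    SOURCE = "SOURCE"
    SINK = "SINK"
    BLANK = "BLANK"
    UNUSED = "UNUSED"


@dataclass(frozen=True, order=True)
class WellAddress:
    """A position on an 8x12 plate, zero-based."""

    row: int
    col: int

    def __post_init__(self) -> None:
        if not (0 <= self.row < N_ROWS and 0 <= self.col < N_COLS):
            raise AddressingError(
                f"well coordinates out of range: ({self.row}, {self.col})"
            )

    @property
    def label(self) -> str:
        """Canonical label like ``'E5'`` (no zero padding)."""
        return f"{ROW_LETTERS[self.row]}{self.col + 1}"

    @classmethod
    def from_label(cls, label: str) -> "WellAddress":
        return parse_well_id(label)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def parse_well_id(label: str) -> WellAddress:
    """Parse a well identifier like ``'E5'`` into a :class:`WellAddress`.

    Raises :class:`AddressingError` naming the offending string for anything
    that is not a row letter A-H followed by a column number 1-12.
    """
    if not isinstance(label, str):
        raise AddressingError(f"well id must be a string, got {label!r}")
    m = _WELL_RE.match(label.strip())
    if m is None:
        raise AddressingError(f"malformed well id: {label!r}")
    return WellAddress(row=ROW_LETTERS.index(m.group(1)), col=int(m.group(2)) - 1)


def format_well_id(address: WellAddress) -> str:
    return address.label


def well_distance(a: WellAddress, b: WellAddress) -> float:
    """Euclidean distance between two wells, in well units."""
    return math.hypot(a.row - b.row, a.col - b.col)


@dataclass(frozen=True)
class WellSpec:
    """A single well's role in the experiment.

    ``source_label`` is required iff the role is SOURCE; ``nominal_cells``
    is the intended input biomass in cells.
    """

    address: WellAddress
    role: Role
    source_label: str | None = None
    nominal_cells: float = 0.0

    def __post_init__(self) -> None:
        if self.nominal_cells < 0:
            raise LayoutError(
                f"nominal_cells must be >= 0 in well {self.address.label}"
            )
        if self.role is Role.SOURCE and not self.source_label:
            raise LayoutError(
                f"SOURCE well {self.address.label} is missing a source_label"
            )
        if self.role is not Role.SOURCE and self.source_label is not None:
            raise LayoutError(
                f"non-SOURCE well {self.address.label} carries a source_label"
            )


@dataclass
class PlateLayout:
    """A complete 96-well layout: one :class:`WellSpec` per well."""

    plate_id: str
    wells: list[WellSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.wells) != N_ROWS * N_COLS:
            raise LayoutError(
                f"layout {self.plate_id!r} has {len(self.wells)} wells, expected 96"
            )
        addresses = [w.address for w in self.wells]
        if len(set(addresses)) != len(addresses):
            raise LayoutError(f"layout {self.plate_id!r} has duplicate well addresses")
        self._by_address = {w.address: w for w in self.wells}

    def __getitem__(self, address: WellAddress | str) -> WellSpec:
        if isinstance(address, str):
            address = parse_well_id(address)
        return self._by_address[address]

    def wells_with_role(self, role: Role) -> list[WellSpec]:
        return [w for w in self.wells if w.role is role]

    def role_counts(self) -> dict[Role, int]:
        counts = {r: 0 for r in Role}
        for w in self.wells:
            counts[w.role] += 1
        return counts

    @property
    def source_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.wells:
            if w.role is Role.SOURCE:
                seen.setdefault(w.source_label, None)
        return list(seen)

    def origin_wells(self, label: str, sink_label: str | None = None) -> set[WellAddress]:
        """Wells where ``label`` legitimately belongs.

        Source labels map to their SOURCE wells; if ``sink_label`` is given
        and matches, all SINK wells are origins.
        """
        origins = {
            w.address
            for w in self.wells
            if w.role is Role.SOURCE and w.source_label == label
        }
        if sink_label is not None and label == sink_label:
            origins |= {w.address for w in self.wells if w.role is Role.SINK}
        if not origins:
            raise LayoutError(
                f"label {label!r} has no origin well in layout {self.plate_id!r}"
            )
        return origins

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["well", "role", "source_label", "nominal_cells"])
            for w in sorted(self.wells, key=lambda w: (w.address.row, w.address.col)):
                writer.writerow(
                    [w.address.label, w.role.value, w.source_label or "", w.nominal_cells]
                )

    @classmethod
    def from_csv(cls, path: str | Path, plate_id: str | None = None) -> "PlateLayout":
        wells: list[WellSpec] = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                role = Role(row["role"].strip().upper())
                label = row.get("source_label", "").strip() or None
                wells.append(
                    WellSpec(
                        address=parse_well_id(row["well"]),
                        role=role,
                        source_label=label,
                        nominal_cells=float(row.get("nominal_cells") or 0.0),
                    )
                )
        return cls(plate_id=plate_id or Path(path).stem, wells=wells)


def build_checkerboard_layout(
    n_sources: int = 16,
    sink_count: int = 24,
    blank_count: int = 48,
    *,
    n_source_wells: int | None = None,
    source_cells: float = 1e7,
    sink_cells: float = 1e5,
    plate_id: str = "checkerboard",
    seed: int | None = None,
) -> PlateLayout:
    """Build the default checkerboard experiment layout.

    Sources and sinks alternate on one parity class of the grid (so no two
    occupied high-biomass wells are orthogonally adjacent to each other);
    blanks fill the opposite parity.  With the defaults this yields 24
    SOURCE wells drawn round-robin from ``n_sources`` labels, 24 SINK and
    48 BLANK wells.  ``seed`` shuffles positions within each parity class;
    ``None`` gives the canonical deterministic layout.
    """
    if n_source_wells is None:
        n_source_wells = N_ROWS * N_COLS - sink_count - blank_count
    if n_source_wells < n_sources:
        raise LayoutError(
            f"{n_source_wells} source wells cannot host {n_sources} distinct labels"
        )
    total = n_source_wells + sink_count + blank_count
    if total > N_ROWS * N_COLS:
        raise LayoutError(f"requested {total} occupied wells on a 96-well plate")
    if n_sources < 1:
        raise LayoutError("need at least one source label")

    all_addresses = [
        WellAddress(r, c) for r in range(N_ROWS) for c in range(N_COLS)
    ]
    even = [a for a in all_addresses if (a.row + a.col) % 2 == 0]
    odd = [a for a in all_addresses if (a.row + a.col) % 2 == 1]
    if seed is not None:
        rng = np.random.default_rng(seed)
        even = [even[i] for i in rng.permutation(len(even))]
        odd = [odd[i] for i in rng.permutation(len(odd))]

    labels = [f"source_{i + 1:02d}" for i in range(n_sources)]
    wells: dict[WellAddress, WellSpec] = {}

    # sources and sinks interleave on the even parity; overflow spills to odd
    occupied_order = even + odd
    hot: list[tuple[Role, str | None, float]] = []
    for i in range(n_source_wells):
        hot.append((Role.SOURCE, labels[i % n_sources], source_cells))
    for _ in range(sink_count):
        hot.append((Role.SINK, None, sink_cells))
    # interleave source/sink so same-label sources sit far apart
    interleaved: list[tuple[Role, str | None, float]] = []
    sources = [h for h in hot if h[0] is Role.SOURCE]
    sinks = [h for h in hot if h[0] is Role.SINK]
    while sources or sinks:
        if sources:
            interleaved.append(sources.pop(0))
        if sinks:
            interleaved.append(sinks.pop(0))
    for spec, addr in zip(interleaved, occupied_order):
        wells[addr] = WellSpec(addr, spec[0], spec[1], spec[2])

    remaining = [a for a in odd + even if a not in wells]
    for addr in remaining[:blank_count]:
        wells[addr] = WellSpec(addr, Role.BLANK, None, 0.0)
    for addr in remaining[blank_count:]:
        wells[addr] = WellSpec(addr, Role.UNUSED, None, 0.0)

    return PlateLayout(plate_id=plate_id, wells=list(wells.values()))
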