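"""Locate contamination events on the plate and fit the distance decay.

A *contamination event* is a (foreign isolate label, well) pair with at
least one read: isolate k observed in a well where k was never placed.
Each event carries the read count and the Euclidean distance (in well
units) to the nearest well where k legitimately belongs.  Event counts
binned by distance give the decay histogram; a log-linear regression of
background-normalized read rates against distance estimates the decay
length of an exponential transfer kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .classify import Category, SotuClassification
from .errors import LayoutError, ParameterError
from .plate import N_COLS, N_ROWS, PlateLayout, Role, WellAddress, well_distance
from .quantify import ContaminationPartition, SampleRecord
from .table import FeatureTable


@dataclass(frozen=True)
class ContaminationEvent:
    """Isolate ``label`` observed with >=1 read in a well it was never placed in."""

    label: str
    origin_wells: frozenset[WellAddress]
    observed_well: WellAddress
    sample_id: str
    reads: int
    distance: float  # min over origin wells

    def __post_init__(self) -> None:
        if self.observed_well in self.origin_wells:
            raise LayoutError("event observed in one of its own origin wells")
        if self.reads < 1:
            raise ParameterError("events require >= 1 read")


def _label_origins(
    cls: SotuClassification, layout: PlateLayout
) -> dict[str, set[WellAddress]]:
    """Map every on-plate panel label to the wells where it belongs."""
    origins: dict[str, set[WellAddress]] = {}
    sink_wells = {w.address for w in layout.wells_with_role(Role.SINK)}
    for call in cls.calls.values():
        if call.category is Category.SOURCE and call.label not in origins:
            wells = {
                w.address
                for w in layout.wells_with_role(Role.SOURCE)
                if w.source_label == call.label
            }
            if not wells:
                raise LayoutError(
                    f"source label {call.label!r} has no well in layout "
                    f"{layout.plate_id!r}"
                )
            origins[call.label] = wells
        elif call.category is Category.SINK and call.label not in origins:
            if not sink_wells:
                raise LayoutError(
                    f"sink label {call.label!r} but layout {layout.plate_id!r} "
                    "has no SINK wells"
                )
            origins[call.label] = sink_wells
    return origins


def find_events(
    table: FeatureTable,
    cls: SotuClassification,
    layout: PlateLayout,
    records: Iterable[SampleRecord],
) -> list[ContaminationEvent]:
    """One event per (foreign label, well) pair with at least one read.

    CONTROL-category labels are skipped: they were never on the plate, so
    their reads are index leakage, not spatial transfer.
    """
    origins = _label_origins(cls, layout)
    # per-sample reads per label
    by_label: dict[str, list[str]] = {}
    for sotu, call in cls.calls.items():
        if call.category in (Category.SOURCE, Category.SINK):
            by_label.setdefault(call.label, []).append(sotu)

    events: list[ContaminationEvent] = []
    for rec in records:
        if rec.sample_id not in table.counts.index:
            continue
        counts = table.counts.loc[rec.sample_id]
        for label, sotus in by_label.items():
            present = [s for s in sotus if s in counts.index]
            reads = int(counts[present].sum()) if present else 0
            if reads < 1:
                continue
            origin = origins[label]
            if rec.well in origin:
                continue
            events.append(
                ContaminationEvent(
                    label=label,
                    origin_wells=frozenset(origin),
                    observed_well=rec.well,
                    sample_id=rec.sample_id,
                    reads=reads,
                    distance=min(well_distance(rec.well, o) for o in origin),
                )
            )
    return events


@dataclass
class DecayHistogram:
    """Events and reads binned by distance: bins ``[k*w, (k+1)*w)``."""

    label: str
    bin_width: float
    bin_edges: np.ndarray  # len nbins + 1
    event_counts: np.ndarray
    read_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.label,
                "distance_lo": self.bin_edges[:-1],
                "distance_hi": self.bin_edges[1:],
                "event_count": self.event_counts,
                "read_count": self.read_counts,
            }
        )


def decay_histogram(
    events: Iterable[ContaminationEvent],
    bin_width: float = 1.0,
    label: str = "all",
) -> DecayHistogram:
    """Bin contamination events (and their reads) by distance."""
    if bin_width <= 0:
        raise ParameterError(f"bin_width must be > 0, got {bin_width}")
    events = list(events)
    max_d = max((e.distance for e in events), default=0.0)
    n_bins = max(1, int(np.floor(max_d / bin_width)) + 1)
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    ev = np.zeros(n_bins, dtype=np.int64)
    rd = np.zeros(n_bins, dtype=np.int64)
    for e in events:
        k = min(int(e.distance // bin_width), n_bins - 1)
        ev[k] += 1
        rd[k] += e.reads
    return DecayHistogram(label, bin_width, edges, ev, rd)


def decay_histograms_by_label(
    events: Iterable[ContaminationEvent], bin_width: float = 1.0
) -> dict[str, DecayHistogram]:
    events = list(events)
    out = {"all": decay_histogram(events, bin_width, "all")}
    for label in sorted({e.label for e in events}):
        out[label] = decay_histogram(
            [e for e in events if e.label == label], bin_width, label
        )
    return out


def plate_matrix(
    table: FeatureTable,
    cls: SotuClassification,
    label: str,
    records: Iterable[SampleRecord],
) -> np.ndarray:
    """8x12 matrix of reads of one isolate label across the plate.

    Entry (r, c) is the label's read count in the sample occupying that
    well (summed if several samples share the well; 0 if unsampled).
    Ready for heatmap rendering.
    """
    sotus = [
        s
        for s, call in cls.calls.items()
        if call.label == label and call.category is not Category.BACKGROUND
    ]
    if not sotus:
        raise LayoutError(f"label {label!r} not present in the classification")
    mat = np.zeros((N_ROWS, N_COLS), dtype=np.int64)
    for rec in records:
        if rec.sample_id not in table.counts.index:
            continue
        counts = table.counts.loc[rec.sample_id]
        present = [s for s in sotus if s in counts.index]
        if present:
            mat[rec.well.row, rec.well.col] += int(counts[present].sum())
    return mat


def fit_decay_length(
    events: Iterable[ContaminationEvent],
    partitions: Iterable[ContaminationPartition] | Mapping[str, ContaminationPartition],
    min_background_reads: int = 10,
) -> float:
    """Estimate the exponential decay length of the transfer kernel.

    For a recipient well, the read count of a transferred isolate scales
    with the kernel mass it received *divided by the well's total template*
    — sequencing depth normalizes everything to fractions.  Dividing each
    event's reads by the same sample's background reads cancels that
    normalization (the background load is shared across wells), leaving a
    quantity proportional to exp(-d / l).  A read-weighted least-squares
    fit of log(reads / background_reads) against distance then returns
    ``l = -1 / slope``.
    """
    if not isinstance(partitions, Mapping):
        partitions = {p.sample_id: p for p in partitions}
    xs, ys, ws = [], [], []
    for e in events:
        p = partitions.get(e.sample_id)
        if p is None or p.reads_background < min_background_reads:
            continue
        xs.append(e.distance)
        ys.append(np.log(e.reads / p.reads_background))
        ws.append(float(e.reads))
    if len(xs) < 3 or len(set(xs)) < 2:
        raise ParameterError(
            "too few usable events to fit a decay length "
            f"({len(xs)} events with background >= {min_background_reads})"
        )
    x = np.asarray(xs)
    y = np.asarray(ys)
    w = np.asarray(ws)
    slope = np.polyfit(x, y, 1, w=np.sqrt(w))[0]
    if slope >= 0:
        raise ParameterError("no decay detected (non-negative slope)")
    return -1.0 / slope
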