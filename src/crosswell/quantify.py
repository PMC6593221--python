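"""Partition each sample's reads into expected / well-to-well / background.

A sample "expects" reads only from the isolate placed in its well: a
source well expects its own source label, a sink well expects the sink
label, and a no-template control expects nothing.  Reads carrying any
*other* panel label are well-to-well (W2W) contamination — physical
transfer between wells during processing — and reads matching no panel
isolate at all are background (reagent/consumable) contamination.

The partition conserves reads exactly:
``reads_expected + reads_w2w + reads_background = reads_total``.
Reads of a separately-plated CONTROL isolate are tallied under background
here (they were never on the plate, so they are not well-to-well transfer);
they are counted in the dedicated barcode-leakage analysis instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .classify import Category, SotuClassification
from .errors import AccountingError, ConfigError, MetadataError, SummaryError
from .plate import WellAddress, parse_well_id
from .table import FeatureTable

SAMPLE_TYPES = ("NTC", "sink", "source")


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata needed for read accounting."""

    sample_id: str
    well: WellAddress
    extraction_plate: str = ""
    extraction_method: str = ""
    pcr_rep: str = ""
    site: str = ""
    sample_type: str = "NTC"
    expected_label: str | None = None
    est_input_cells: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise MetadataError(
                f"sample {self.sample_id!r}: unknown sample_type "
                f"{self.sample_type!r} (expected one of {SAMPLE_TYPES})"
            )
        if self.sample_type == "source" and not self.expected_label:
            raise MetadataError(
                f"source sample {self.sample_id!r} is missing expected_label"
            )
        if self.sample_type != "source" and self.expected_label:
            raise MetadataError(
                f"non-source sample {self.sample_id!r} carries expected_label"
            )


@dataclass(frozen=True)
class ContaminationPartition:
    """A sample's reads split into expected / well-to-well / background."""

    sample_id: str
    reads_expected: int
    reads_w2w: int
    reads_background: int
    reads_control: int  # subset of reads_background from the off-plate control
    richness: int
    n_w2w_sotus: int
    sample_type: str
    empty: bool

    @property
    def reads_total(self) -> int:
        return self.reads_expected + self.reads_w2w + self.reads_background

    @property
    def fraction_w2w(self) -> float:
        return self.reads_w2w / self.reads_total if self.reads_total else 0.0

    @property
    def fraction_background(self) -> float:
        return self.reads_background / self.reads_total if self.reads_total else 0.0

    @property
    def w2w_richness_share(self) -> float:
        return self.n_w2w_sotus / self.richness if self.richness else 0.0


def records_from_metadata(metadata: pd.DataFrame) -> list[SampleRecord]:
    """Build :class:`SampleRecord` objects from a metadata frame.

    Expects columns well_ID, sample_type, and optionally extraction_plate,
    extraction_method, pcr_rep, site, expected_label, est_input_cells.
    """
    required = {"well_ID", "sample_type"}
    missing = required - set(metadata.columns)
    if missing:
        raise MetadataError(f"metadata is missing columns: {sorted(missing)}")

    def get(row: pd.Series, col: str, default: str = "") -> str:
        v = row.get(col, default)
        return default if pd.isna(v) else str(v)

    records = []
    for sample_id, row in metadata.iterrows():
        expected = get(row, "expected_label") or None
        records.append(
            SampleRecord(
                sample_id=str(sample_id),
                well=parse_well_id(get(row, "well_ID")),
                extraction_plate=get(row, "extraction_plate"),
                extraction_method=get(row, "extraction_method"),
                pcr_rep=get(row, "pcr_rep"),
                site=get(row, "site"),
                sample_type=get(row, "sample_type"),
                expected_label=expected,
                est_input_cells=float(get(row, "est_input_cells", "0") or 0),
            )
        )
    return records


def partition_sample(
    counts: Mapping[str, int] | pd.Series,
    cls: SotuClassification,
    rec: SampleRecord,
) -> ContaminationPartition:
    """Partition one sample's per-sOTU counts by contamination class."""
    if isinstance(counts, pd.Series):
        items = [(str(k), int(v)) for k, v in counts.items()]
    else:
        items = [(str(k), int(v)) for k, v in counts.items()]

    expected = w2w = background = control = 0
    richness = 0
    n_w2w = 0
    for sotu, n in items:
        if n < 0:
            raise AccountingError(f"negative count for sOTU in {rec.sample_id!r}")
        if n == 0:
            continue
        if sotu not in cls:
            raise AccountingError(
                f"sample {rec.sample_id!r}: sOTU {sotu[:30]!r}... is unclassified"
            )
        call = cls[sotu]
        richness += 1
        if call.category is Category.BACKGROUND:
            background += n
        elif call.category is Category.CONTROL:
            # off-plate control isolate: not well-to-well transfer
            background += n
            control += n
        elif rec.sample_type == "source":
            if call.category is Category.SOURCE and call.label == rec.expected_label:
                expected += n
            else:
                w2w += n
                n_w2w += 1
        elif rec.sample_type == "sink":
            if call.category is Category.SINK:
                expected += n
            else:
                w2w += n
                n_w2w += 1
        else:  # NTC: nothing is expected
            w2w += n
            n_w2w += 1

    total = expected + w2w + background
    return ContaminationPartition(
        sample_id=rec.sample_id,
        reads_expected=expected,
        reads_w2w=w2w,
        reads_background=background,
        reads_control=control,
        richness=richness,
        n_w2w_sotus=n_w2w,
        sample_type=rec.sample_type,
        empty=total == 0,
    )


def partition_table(
    table: FeatureTable,
    cls: SotuClassification,
    records: Iterable[SampleRecord],
) -> list[ContaminationPartition]:
    """Partition every sample in ``table`` that has a metadata record."""
    by_id = {r.sample_id: r for r in records}
    missing = [s for s in table.sample_ids if s not in by_id]
    if missing:
        raise MetadataError(
            f"{len(missing)} sample(s) missing metadata records: {missing[:5]}"
        )
    return [
        partition_sample(table.sample_counts(s), cls, by_id[s])
        for s in table.sample_ids
    ]


def partitions_frame(
    partitions: Iterable[ContaminationPartition],
    records: Iterable[SampleRecord] | None = None,
) -> pd.DataFrame:
    """Flatten partitions (optionally joined to metadata) into a DataFrame."""
    rows = []
    for p in partitions:
        rows.append(
            {
                "sample_id": p.sample_id,
                "sample_type": p.sample_type,
                "reads_expected": p.reads_expected,
                "reads_w2w": p.reads_w2w,
                "reads_background": p.reads_background,
                "reads_control": p.reads_control,
                "reads_total": p.reads_total,
                "fraction_w2w": p.fraction_w2w,
                "fraction_background": p.fraction_background,
                "richness": p.richness,
                "n_w2w_sotus": p.n_w2w_sotus,
                "w2w_richness_share": p.w2w_richness_share,
                "empty": p.empty,
            }
        )
    df = pd.DataFrame(rows).set_index("sample_id")
    if records is not None:
        md = pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in records],
                "well_ID": [r.well.label for r in records],
                "extraction_plate": [r.extraction_plate for r in records],
                "extraction_method": [r.extraction_method for r in records],
                "pcr_rep": [r.pcr_rep for r in records],
                "site": [r.site for r in records],
            }
        ).set_index("sample_id")
        df = df.join(md, how="left")
    return df


#: Column order mirrors the published-style summary table: prevalence,
#: richness block, W2W composition block, background composition block.
SUMMARY_COLUMNS = [
    "n_samples",
    "prevalence_pct",
    "mean_richness",
    "w2w_pct_of_richness",
    "w2w_mean_pct",
    "w2w_median_pct",
    "w2w_max_pct",
    "background_mean_pct",
    "background_median_pct",
    "background_max_pct",
]


def summarize_groups(
    partitions: pd.DataFrame | Iterable[ContaminationPartition],
    group_keys: list[str] | None = None,
    min_reads: int = 1,
) -> pd.DataFrame:
    """Summarize contamination per group of samples.

    Prevalence is the percentage of samples with *any* well-to-well
    contamination (>= 1 W2W read, no floor).  Composition statistics are
    the mean/median/max of per-sample W2W (and background) read fractions,
    in percent; medians use the midpoint convention for even n.  Samples
    with fewer than ``min_reads`` total reads are excluded.
    """
    df = partitions if isinstance(partitions, pd.DataFrame) else partitions_frame(partitions)
    if group_keys is None:
        group_keys = ["sample_type"]
    missing = [k for k in group_keys if k not in df.columns]
    if missing:
        raise SummaryError(f"grouping columns not present: {missing}")
    df = df[df["reads_total"] >= min_reads]
    if df.empty:
        raise SummaryError("no samples meet the minimum-read threshold")

    rows = []
    for keys, sub in df.groupby(group_keys, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        frac = sub["fraction_w2w"].to_numpy(dtype=float)
        bg = sub["fraction_background"].to_numpy(dtype=float)
        rows.append(
            dict(zip(group_keys, keys))
            | {
                "n_samples": len(sub),
                "prevalence_pct": 100.0 * float((sub["reads_w2w"] >= 1).mean()),
                "mean_richness": float(sub["richness"].mean()),
                "w2w_pct_of_richness": 100.0
                * float(sub["w2w_richness_share"].mean()),
                "w2w_mean_pct": 100.0 * float(np.mean(frac)),
                "w2w_median_pct": 100.0 * float(np.median(frac)),
                "w2w_max_pct": 100.0 * float(np.max(frac)),
                "background_mean_pct": 100.0 * float(np.mean(bg)),
                "background_median_pct": 100.0 * float(np.median(bg)),
                "background_max_pct": 100.0 * float(np.max(bg)),
            }
        )
    return pd.DataFrame(rows).set_index(group_keys)[SUMMARY_COLUMNS]


def barcode_leakage(
    experiment_table: FeatureTable,
    control_table: FeatureTable,
    cls: SotuClassification,
) -> dict:
    """Count reads that crossed between co-sequenced library plates.

    The control isolate was extracted and amplified on a physically
    separate plate, so any of its reads appearing in experiment samples —
    or any experiment-isolate reads appearing in control samples — must
    come from index misassignment, not physical well-to-well transfer.
    When zero crossover reads are seen, an upper rate bound of
    ``1 / total_reads`` is reported instead of zero.
    """
    control_sotus = set(cls.sotus_in_category(Category.CONTROL))
    if not control_sotus:
        raise ConfigError("no CONTROL label in the classification/panel")
    experiment_sotus = set(cls.sotus_in_category(Category.SOURCE)) | set(
        cls.sotus_in_category(Category.SINK)
    )

    def reads_of(table: FeatureTable, sotus: set[str]) -> int:
        cols = [s for s in table.sotu_ids if s in sotus]
        return int(table.counts[cols].to_numpy().sum()) if cols else 0

    leaked = reads_of(experiment_table, control_sotus) + reads_of(
        control_table, experiment_sotus
    )
    total = experiment_table.total_reads() + control_table.total_reads()
    if total == 0:
        raise ConfigError("no reads in either table; leakage rate undefined")
    if leaked == 0:
        rate_bound = 1.0 / total
    else:
        rate_bound = leaked / total
    return {
        "leaked_reads": leaked,
        "total_reads": total,
        "rate_bound": rate_bound,
        "is_upper_bound": leaked == 0,
    }
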