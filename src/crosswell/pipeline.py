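"""Configuration and the end-to-end analysis driver.

``run_pipeline`` ties the stages together: singleton filter -> exact-match
classification -> per-sample read partitioning -> group summaries ->
spatial events/decay -> replicate beta-diversity -> optional barcode
leakage.  Every output TSV starts with a comment line carrying the config
hash and seed so reruns are attributable and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify as _classify
from . import diversity as _diversity
from . import quantify as _quantify
from . import spatial as _spatial
from .errors import ConfigError, CrosswellError, PairingError
from .plate import PlateLayout
from .table import FeatureTable, read_feature_table, read_metadata

log = logging.getLogger("crosswell")


@dataclass
class PipelineConfig:
    table: str = ""
    metadata: str = ""
    refs: str = ""
    layout: str = ""
    control_table: str = ""
    out_dir: str = "crosswell_out"
    trim_length: int = 150
    min_reads: int = 1
    bin_width: float = 1.0
    metrics: list[str] = field(default_factory=lambda: ["bray_curtis", "jaccard"])
    pairings: list[str] = field(
        default_factory=lambda: ["pcr_replicates", "extraction_replicates"]
    )
    group_keys: list[str] = field(
        default_factory=lambda: ["sample_type", "site", "extraction_method"]
    )
    column_map: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        # out_dir and log level do not affect the analysis
        fields = {
            k: v
            for k, v in asdict(self).items()
            if k not in ("out_dir", "log_level")
        }
        blob = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate_paths(self) -> None:
        for name in ("table", "metadata", "refs", "layout"):
            value = getattr(self, name)
            if not value:
                raise ConfigError(f"config is missing required path: {name}")
            if not Path(value).exists():
                raise ConfigError(f"{name} path does not exist: {value}")
        if self.control_table and not Path(self.control_table).exists():
            raise ConfigError(
                f"control_table path does not exist: {self.control_table}"
            )


def _write_tsv(df: pd.DataFrame, path: Path, header: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the in-memory report bundle."""
    logging.basicConfig(level=config.log_level)
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"crosswell config={config.config_hash()} seed={config.seed}"
    bundle: dict = {"config": config}

    def stage(name: str):
        log.info("stage: %s", name)
        return name

    try:
        stage("load")
        metadata = read_metadata(config.metadata, column_map=config.column_map or None)
        table = read_feature_table(config.table, metadata=metadata)
        panel = _classify.ReferencePanel.from_fasta(
            config.refs, trim_length=config.trim_length
        )
        layout = PlateLayout.from_csv(config.layout)
    except CrosswellError as err:
        raise type(err)(f"[load] {err}") from err

    try:
        stage("filter+classify")
        table = _classify.remove_singletons(table)
        cls = _classify.classify_sotus(table, panel)
        _write_tsv(cls.to_frame(), out / "classification.tsv", header)
    except CrosswellError as err:
        raise type(err)(f"[classify] {err}") from err

    try:
        stage("quantify")
        records = _quantify.records_from_metadata(
            metadata.loc[[s for s in metadata.index if s in table.counts.index]]
        )
        partitions = _quantify.partition_table(table, cls, records)
        pframe = _quantify.partitions_frame(partitions, records)
        _write_tsv(pframe, out / "partitions.tsv", header)
        group_keys = [k for k in config.group_keys if k in pframe.columns]
        summary = _quantify.summarize_groups(
            pframe, group_keys, min_reads=config.min_reads
        )
        _write_tsv(summary, out / "group_summary.tsv", header)
        bundle.update(partitions=partitions, partitions_frame=pframe, summary=summary)
    except CrosswellError as err:
        raise type(err)(f"[quantify] {err}") from err

    try:
        stage("spatial")
        events = _spatial.find_events(table, cls, layout, records)
        eframe = pd.DataFrame(
            {
                "label": [e.label for e in events],
                "observed_well": [e.observed_well.label for e in events],
                "sample_id": [e.sample_id for e in events],
                "reads": [e.reads for e in events],
                "distance": [e.distance for e in events],
            }
        )
        _write_tsv(eframe, out / "events.tsv", header, index=False)
        hist = _spatial.decay_histogram(events, bin_width=config.bin_width)
        _write_tsv(hist.to_frame(), out / "decay_histogram.tsv", header, index=False)
        bundle.update(events=events, histogram=hist)
    except CrosswellError as err:
        raise type(err)(f"[spatial] {err}") from err

    try:
        stage("diversity")
        tests = []
        for pairing in config.pairings:
            for metric in config.metrics:
                try:
                    grouped, skipped = _diversity.replicate_distances(
                        table, metadata, pairing_kind=pairing, metric=metric
                    )
                except PairingError as err:
                    log.info("skipping %s/%s: %s", pairing, metric, err)
                    continue
                for stype, dists in sorted(grouped.items()):
                    tests.append(
                        {
                            "pairing": pairing,
                            "metric": metric,
                            "sample_type": stype,
                            "n_pairs": len(dists),
                            "median_distance": float(pd.Series(dists).median()),
                            "n_skipped": len(skipped),
                        }
                    )
        if tests:
            _write_tsv(
                pd.DataFrame(tests), out / "replicate_distances.tsv", header,
                index=False,
            )
        rinfl = _diversity.richness_inflation(partitions)
        _write_tsv(rinfl, out / "richness_inflation.tsv", header)
        bundle.update(replicate_distances=tests, richness_inflation=rinfl)
    except CrosswellError as err:
        raise type(err)(f"[diversity] {err}") from err

    if config.control_table:
        try:
            stage("leakage")
            control = read_feature_table(config.control_table)
            control_cls = _classify.classify_sotus(
                _classify.remove_singletons(control), panel
            )
            merged_calls = dict(cls.calls)
            merged_calls.update(control_cls.calls)
            leak = _quantify.barcode_leakage(
                table, control, _classify.SotuClassification(merged_calls)
            )
            with open(out / "leakage.txt", "w") as fh:
                fh.write(f"# {header}\n")
                for k, v in leak.items():
                    fh.write(f"{k}\t{v}\n")
            bundle["leakage"] = leak
        except CrosswellError as err:
            raise type(err)(f"[leakage] {err}") from err

    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"# {header}\n")
        fh.write(f"samples\t{table.n_samples}\nsotus\t{table.n_sotus}\n")
        fh.write(f"total_reads\t{table.total_reads()}\n")
    log.info("wrote report to %s", out)
    return bundle
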