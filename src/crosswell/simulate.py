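"""Simulate a plate contamination experiment with known ground truth.

The generative model mirrors the checkerboard validation experiment:

1.  A 96-well plate holds high-biomass source wells (~1e7 cells, one
    isolate each), low-biomass sink wells (~1e5 cells, one shared
    isolate), and no-template blanks.
2.  During extraction, each occupied well sheds a fixed fraction of its
    cells (``transfer_mass``); the shed mass lands in the other wells with
    probability proportional to a distance-decay kernel, exponential by
    default: K(d) = exp(-d / decay_length).  Realized transferred cell
    counts are Poisson.
3.  Every well additionally receives a shared reagent "contaminome": a
    seeded heavy-tailed pool of background tags at a fixed cell-equivalent
    load, with Poisson per-well realization.
4.  PCR + sequencing turn the realized cell composition into reads: a
    per-tag lognormal amplification factor (``pcr_noise_cv``) followed by
    a multinomial draw at the sample's depth.  PCR replicates redraw this
    step from the *same* extraction composition, so replicate pairs share
    extraction-stage contamination but differ stochastically.

Every read is tracked by class (expected / well-to-well / background), so
the quantifier can be validated against exact ground truth.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import Category, ReferencePanel, ReferenceSequence
from .errors import ParameterError
from .plate import PlateLayout, Role, WellSpec, build_checkerboard_layout, well_distance
from .table import FeatureTable

SINK_LABEL = "sink_aliivibrio"
CONTROL_LABEL = "control_clostridium"
CLASSES = ("expected", "w2w", "background")
_BASES = np.array(list("ACGT"))


def derive_seed(seed: int, *tokens: object) -> int:
    """Stable sub-seed (< 2^31) from a master seed and string tokens."""
    h = hashlib.sha256(("|".join([str(seed), *map(str, tokens)])).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def _kernel(name: str, decay_length: float, power_exponent: float):
    if name == "exponential":
        return lambda d: math.exp(-d / decay_length)
    if name == "power_law":
        return lambda d: (1.0 + d) ** (-power_exponent)
    if name == "nearest":
        return lambda d: 1.0 if d <= 1.5 else 0.0  # orthogonal + diagonal ring
    raise ParameterError(f"unknown kernel {name!r}")


@dataclass
class SimParams:
    """Study-design and noise parameters for the simulator.

    Defaults follow the validation experiment's stated conditions: source
    wells ~1e7 cells, sinks ~1e5, blanks 0, a 16-label / 24-source-well /
    24-sink / 48-blank checkerboard, 150-bp tags, 30k reads/sample.
    Transfer magnitude and background load are the package's calibration:
    they place plate-extraction NTC median W2W read fractions in the high
    range reported for robot plate extractions.
    """

    layout: PlateLayout | None = None
    cells_source: float = 1e7
    cells_sink: float = 1e5
    cells_blank: float = 0.0
    transfer_mass: float = 1e-3
    decay_length: float = 0.7
    kernel: str = "exponential"
    power_exponent: float = 3.0
    pcr_transfer_mass: float = 0.0
    background_pool_size: int = 200
    background_load: float = 500.0
    background_sigma: float = 2.0
    depth: int = 30_000
    depth_cv: float = 0.3
    pcr_noise_cv: float = 0.3
    trim_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = {
            "cells_source": self.cells_source,
            "cells_sink": self.cells_sink,
            "cells_blank": self.cells_blank,
            "transfer_mass": self.transfer_mass,
            "decay_length": self.decay_length,
            "pcr_transfer_mass": self.pcr_transfer_mass,
            "background_load": self.background_load,
            "background_sigma": self.background_sigma,
            "depth_cv": self.depth_cv,
            "pcr_noise_cv": self.pcr_noise_cv,
        }
        for name, v in numeric.items():
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {v}")
        if self.decay_length <= 0:
            raise ParameterError("decay_length must be > 0")
        if self.depth < 0 or self.background_pool_size < 0:
            raise ParameterError("depth and background_pool_size must be >= 0")

    def resolved_layout(self) -> PlateLayout:
        if self.layout is not None:
            return self.layout
        return build_checkerboard_layout(
            source_cells=self.cells_source, sink_cells=self.cells_sink
        )


def _random_tags(rng: np.random.Generator, n: int, length: int) -> list[str]:
    tags: set[str] = set()
    while len(tags) < n:
        tags.add("".join(rng.choice(_BASES, size=length)))
    return sorted(tags)


def make_reference_panel(
    source_labels: list[str],
    trim_length: int = 150,
    seed: int = 0,
    operon_every: int = 5,
) -> ReferencePanel:
    """Random but reproducible isolate references.

    Every ``operon_every``-th source label gets a second rRNA operon
    variant (5 substitutions off its first), exercising multi-sequence
    labels.  A sink isolate and an off-plate control isolate are included.
    """
    rng = np.random.default_rng(derive_seed(seed, "panel"))
    n_labels = len(source_labels) + 2
    tags = _random_tags(rng, n_labels, trim_length)
    entries: list[ReferenceSequence] = []
    for i, label in enumerate(source_labels):
        entries.append(ReferenceSequence(label, Category.SOURCE, tags[i]))
        if operon_every and (i + 1) % operon_every == 0:
            seq = list(tags[i])
            pos = rng.choice(trim_length, size=5, replace=False)
            for p in pos:
                seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
            entries.append(ReferenceSequence(label, Category.SOURCE, "".join(seq)))
    entries.append(
        ReferenceSequence(SINK_LABEL, Category.SINK, tags[len(source_labels)])
    )
    entries.append(
        ReferenceSequence(CONTROL_LABEL, Category.CONTROL, tags[len(source_labels) + 1])
    )
    return ReferencePanel(entries=entries, trim_length=trim_length)


def make_background_pool(params: SimParams) -> tuple[list[str], np.ndarray]:
    """Shared contaminome: tags plus heavy-tailed relative abundances."""
    rng = np.random.default_rng(derive_seed(params.seed, "background"))
    tags = _random_tags(rng, params.background_pool_size, params.trim_length)
    profile = rng.lognormal(mean=0.0, sigma=params.background_sigma,
                            size=params.background_pool_size)
    profile /= profile.sum()
    return tags, profile


@dataclass
class SimTruth:
    """Ground-truth read tallies per sample and per (sample, label)."""

    per_sample: pd.DataFrame  # index sample_id; reads_expected/w2w/background
    per_label: pd.DataFrame  # sample_id, label, read_class, reads

    def w2w_reads(self, sample_id: str) -> int:
        return int(self.per_sample.loc[sample_id, "reads_w2w"])


@dataclass
class ExtractionSim:
    """One simulated extraction plate plus everything needed to re-PCR it."""

    table: FeatureTable
    metadata: pd.DataFrame
    panel: ReferencePanel
    truth: SimTruth
    params: SimParams
    extraction_id: str
    pcr_rep: str
    # cell composition: wells x sotus x class, fixed at extraction time
    composition: np.ndarray = field(repr=False)
    sotu_index: list[str] = field(repr=False)
    sotu_labels: list[str] = field(repr=False)
    sampled_wells: list[WellSpec] = field(repr=False)


def _sample_type(role: Role) -> str:
    return {"BLANK": "NTC", "SINK": "sink", "SOURCE": "source"}[role.value]


def _operon_weights(n: int) -> np.ndarray:
    if n == 1:
        return np.array([1.0])
    w = np.array([0.8] + [0.2 / (n - 1)] * (n - 1))
    return w / w.sum()


def _build_composition(
    params: SimParams, layout: PlateLayout, panel: ReferencePanel,
    bg_tags: list[str], bg_profile: np.ndarray, extraction_id: str,
) -> tuple[np.ndarray, list[str], list[str], list[WellSpec]]:
    """Realize the post-extraction cell composition of every sampled well."""
    rng = np.random.default_rng(
        derive_seed(params.seed, "extraction", extraction_id)
    )
    wells = [w for w in layout.wells if w.role is not Role.UNUSED]
    label_seqs: dict[str, list[str]] = {}
    for e in panel.entries:
        if e.role in (Category.SOURCE, Category.SINK):
            label_seqs.setdefault(e.label, []).append(e.sequence)

    sotus = [s for seqs in label_seqs.values() for s in seqs] + list(bg_tags)
    sotu_of_label = {lab: [sotus.index(s) for s in seqs] for lab, seqs in label_seqs.items()}
    labels_of_sotu = ["background"] * len(sotus)
    for lab, idxs in sotu_of_label.items():
        for i in idxs:
            labels_of_sotu[i] = lab

    n_wells, n_sotus = len(wells), len(sotus)
    comp = np.zeros((n_wells, n_sotus, len(CLASSES)))
    kern = _kernel(params.kernel, params.decay_length, params.power_exponent)

    def own_label(w: WellSpec) -> str | None:
        if w.role is Role.SOURCE:
            return w.source_label
        if w.role is Role.SINK:
            return SINK_LABEL
        return None

    # genuine cells
    for i, w in enumerate(wells):
        lab = own_label(w)
        if lab is None or w.nominal_cells <= 0:
            continue
        idxs = sotu_of_label[lab]
        for j, frac in zip(idxs, _operon_weights(len(idxs))):
            comp[i, j, 0] += w.nominal_cells * frac

    # well-to-well transfer (Poisson around kernel-distributed mass)
    if params.transfer_mass > 0:
        for j_well, donor in enumerate(wells):
            lab = own_label(donor)
            if lab is None or donor.nominal_cells <= 0:
                continue
            mass = params.transfer_mass * donor.nominal_cells
            weights = np.array(
                [
                    0.0 if i == j_well else kern(
                        well_distance(donor.address, w.address)
                    )
                    for i, w in enumerate(wells)
                ]
            )
            z = weights.sum()
            if z == 0:
                continue
            means = mass * weights / z
            realized = rng.poisson(means)
            idxs = sotu_of_label[lab]
            ws = _operon_weights(len(idxs))
            for i_well, cells in enumerate(realized):
                if cells == 0:
                    continue
                # transfer into a well that legitimately holds the same
                # label is indistinguishable from its own signal
                cls = 0 if own_label(wells[i_well]) == lab else 1
                split = rng.multinomial(cells, ws)
                for j, c in zip(idxs, split):
                    comp[i_well, j, cls] += c

    # shared background contaminome
    if params.background_load > 0 and len(bg_tags):
        offset = n_sotus - len(bg_tags)
        means = params.background_load * bg_profile
        for i in range(n_wells):
            comp[i, offset:, 2] += rng.poisson(means)

    return comp, sotus, labels_of_sotu, wells


def _draw_reads(
    comp: np.ndarray,
    params: SimParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """PCR + sequencing: lognormal per-tag amplification, multinomial depth."""
    n_wells, n_sotus, n_cls = comp.shape
    reads = np.zeros_like(comp, dtype=np.int64)
    sigma = math.sqrt(math.log(1.0 + params.pcr_noise_cv**2))
    dsig = math.sqrt(math.log(1.0 + params.depth_cv**2)) if params.depth_cv > 0 else 0.0
    for i in range(n_wells):
        weights = comp[i].copy()
        if weights.sum() == 0 or params.depth == 0:
            continue
        if sigma > 0:
            factors = rng.lognormal(-sigma**2 / 2, sigma, size=n_sotus)
            weights *= factors[:, None]  # same factor for every class of a tag
        depth = params.depth
        if dsig > 0:
            depth = int(round(params.depth * rng.lognormal(-dsig**2 / 2, dsig)))
        if depth <= 0:
            continue
        p = weights.ravel() / weights.sum()
        reads[i] = rng.multinomial(depth, p).reshape(n_sotus, n_cls)
    return reads


def _emit(
    reads: np.ndarray,
    wells: list[WellSpec],
    sotus: list[str],
    labels_of_sotu: list[str],
    panel: ReferencePanel,
    params: SimParams,
    extraction_id: str,
    pcr_rep: str,
    site: str,
    extraction_method: str,
) -> tuple[FeatureTable, pd.DataFrame, SimTruth]:
    sample_ids = [f"{extraction_id}.{pcr_rep}.{w.address.label}" for w in wells]
    counts = pd.DataFrame(
        reads.sum(axis=2), index=sample_ids, columns=sotus
    )
    counts = counts.loc[:, counts.sum(axis=0) > 0]  # only observed tags

    md = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "well_ID": [w.address.label for w in wells],
            "extraction_plate": extraction_id,
            "extraction_method": extraction_method,
            "pcr_rep": pcr_rep,
            "site": site,
            "sample_type": [_sample_type(w.role) for w in wells],
            "expected_label": [
                w.source_label if w.role is Role.SOURCE else "" for w in wells
            ],
            "est_input_cells": [w.nominal_cells for w in wells],
        }
    ).set_index("sample_id")

    per_sample = pd.DataFrame(
        reads.sum(axis=1),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[f"reads_{c}" for c in CLASSES],
    )
    rows = []
    labels_arr = np.asarray(labels_of_sotu)
    for li, label in enumerate(sorted(set(labels_of_sotu))):
        mask = labels_arr == label
        per_class = reads[:, mask, :].sum(axis=1)  # wells x class
        for s, row in zip(sample_ids, per_class):
            for ci, cname in enumerate(CLASSES):
                if row[ci]:
                    rows.append(
                        {"sample_id": s, "label": label,
                         "read_class": cname, "reads": int(row[ci])}
                    )
    per_label = pd.DataFrame(
        rows, columns=["sample_id", "label", "read_class", "reads"]
    )
    truth = SimTruth(per_sample=per_sample, per_label=per_label)
    return FeatureTable(counts, metadata=md), md, truth


def simulate_extraction_plate(
    params: SimParams,
    extraction_id: str = "plate1",
    pcr_rep: str = "A",
    site: str = "SIM",
    extraction_method: str = "robot",
) -> ExtractionSim:
    """Simulate one extraction plate and its first PCR plate.

    Reproducible: the reference panel and background pool depend only on
    ``params.seed``; the extraction realization additionally depends on
    ``extraction_id``; the read draw depends on ``pcr_rep`` too.  Two
    extraction plates simulated from the same params therefore share the
    panel and contaminome but not the transfer realization.
    """
    layout = params.resolved_layout()
    panel = make_reference_panel(
        layout.source_labels, trim_length=params.trim_length, seed=params.seed
    )
    bg_tags, bg_profile = make_background_pool(params)
    comp, sotus, labels_of_sotu, wells = _build_composition(
        params, layout, panel, bg_tags, bg_profile, extraction_id
    )
    rng = np.random.default_rng(
        derive_seed(params.seed, "pcr", extraction_id, pcr_rep)
    )
    reads = _draw_reads(comp, params, rng)
    table, md, truth = _emit(
        reads, wells, sotus, labels_of_sotu, panel, params,
        extraction_id, pcr_rep, site, extraction_method,
    )
    return ExtractionSim(
        table=table, metadata=md, panel=panel, truth=truth, params=params,
        extraction_id=extraction_id, pcr_rep=pcr_rep, composition=comp,
        sotu_index=sotus, sotu_labels=labels_of_sotu, sampled_wells=wells,
    )


def simulate_pcr_replicate(sim: ExtractionSim, pcr_rep: str = "B") -> ExtractionSim:
    """Re-draw reads from an existing extraction's cell composition.

    Replicates share every extraction-stage contamination event and differ
    only through PCR amplification noise and the sequencing draw.
    """
    rng = np.random.default_rng(
        derive_seed(sim.params.seed, "pcr", sim.extraction_id, pcr_rep)
    )
    reads = _draw_reads(sim.composition, sim.params, rng)
    md_method = sim.metadata["extraction_method"].iloc[0] if len(sim.metadata) else ""
    site = sim.metadata["site"].iloc[0] if len(sim.metadata) else "SIM"
    table, md, truth = _emit(
        reads, sim.sampled_wells, sim.sotu_index, sim.sotu_labels, sim.panel,
        sim.params, sim.extraction_id, pcr_rep, site, md_method,
    )
    return replace(
        sim, table=table, metadata=md, truth=truth, pcr_rep=pcr_rep
    )


def simulate_control_plate(
    params: SimParams,
    leakage_rate: float = 0.0,
    experiment: FeatureTable | None = None,
    n_control_wells: int = 16,
    control_cells: float = 1e7,
) -> tuple[FeatureTable, pd.DataFrame, FeatureTable | None]:
    """Simulate the separately-plated control isolate and optional leakage.

    The control plate holds ``n_control_wells`` replicate wells of a single
    isolate (plus the shared background contaminome).  If ``experiment`` is
    given, each of its reads independently leaks with probability
    ``leakage_rate``, adding control-tag reads to experiment samples —
    the count-level model of index misassignment between co-sequenced
    plates.  Returns (control table, control metadata, leaked experiment
    table or None).
    """
    if not 0.0 <= leakage_rate < 1.0:
        raise ParameterError(f"leakage_rate must be in [0, 1), got {leakage_rate}")
    layout = params.resolved_layout()
    panel = make_reference_panel(
        layout.source_labels, trim_length=params.trim_length, seed=params.seed
    )
    control_seq = next(
        e.sequence for e in panel.entries if e.role is Category.CONTROL
    )
    bg_tags, bg_profile = make_background_pool(params)
    rng = np.random.default_rng(derive_seed(params.seed, "control_plate"))

    all_addr = [w.address for w in layout.wells]
    wells = sorted(all_addr, key=lambda a: (a.row, a.col))[:n_control_wells]
    sotus = [control_seq] + list(bg_tags)
    sample_ids = [f"control.{a.label}" for a in wells]
    counts = np.zeros((len(wells), len(sotus)), dtype=np.int64)
    sigma = math.sqrt(math.log(1.0 + params.pcr_noise_cv**2))
    for i in range(len(wells)):
        cells = np.concatenate(
            [[control_cells], rng.poisson(params.background_load * bg_profile)]
        ).astype(float)
        if sigma > 0:
            cells *= rng.lognormal(-sigma**2 / 2, sigma, size=len(cells))
        if cells.sum() == 0 or params.depth == 0:
            continue
        counts[i] = rng.multinomial(params.depth, cells / cells.sum())
    control_counts = pd.DataFrame(counts, index=sample_ids, columns=sotus)
    control_counts = control_counts.loc[:, control_counts.sum(axis=0) > 0]
    control_md = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "well_ID": [a.label for a in wells],
            "extraction_plate": "control",
            "extraction_method": "m_tube",
            "pcr_rep": "A",
            "site": "SIM",
            "sample_type": "NTC",
            "expected_label": "",
            "est_input_cells": control_cells,
        }
    ).set_index("sample_id")
    control_table = FeatureTable(control_counts, metadata=control_md)

    leaked = None
    if experiment is not None:
        counts = experiment.counts.copy()
        depths = counts.sum(axis=1).to_numpy()
        extra = rng.binomial(depths, leakage_rate)
        if control_seq not in counts.columns:
            counts[control_seq] = 0
        counts[control_seq] += extra
        leaked = FeatureTable(
            counts.loc[:, counts.sum(axis=0) > 0], metadata=experiment.metadata
        )
    return control_table, control_md, leaked


def simulate_study(
    params: SimParams,
    n_extractions: int = 1,
    pcr_reps: tuple[str, ...] = ("A", "B"),
    extraction_method: str = "robot",
) -> tuple[FeatureTable, pd.DataFrame, ReferencePanel, SimTruth, list[ExtractionSim]]:
    """Simulate several extraction plates x PCR replicates and concatenate."""
    sims: list[ExtractionSim] = []
    for e in range(1, n_extractions + 1):
        base = simulate_extraction_plate(
            params, extraction_id=f"plate{e}", pcr_rep=pcr_reps[0],
            extraction_method=extraction_method,
        )
        sims.append(base)
        for rep in pcr_reps[1:]:
            sims.append(simulate_pcr_replicate(base, pcr_rep=rep))
    counts = pd.concat([s.table.counts for s in sims]).fillna(0).astype(np.int64)
    md = pd.concat([s.metadata for s in sims])
    truth = SimTruth(
        per_sample=pd.concat([s.truth.per_sample for s in sims]),
        per_label=pd.concat(
            [s.truth.per_label for s in sims], ignore_index=True
        ),
    )
    table = FeatureTable(counts, metadata=md)
    return table, md, sims[0].panel, truth, sims
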