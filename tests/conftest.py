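import numpy as np
import pandas as pd
import pytest

from crosswell.classify import Category, ReferencePanel, ReferenceSequence
from crosswell.plate import WellAddress, parse_well_id
from crosswell.quantify import SampleRecord
from crosswell.simulate import SimParams, simulate_extraction_plate
from crosswell.table import FeatureTable


def _tag(rng: np.random.Generator, length: int = 150) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def tiny_panel():
    """Three-label panel: two sources (one with two operons), a sink, a control."""
    rng = np.random.default_rng(42)
    s1 = _tag(rng)
    s1b = list(s1)
    s1b[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s1b[10]]
    entries = [
        ReferenceSequence("source_01", Category.SOURCE, s1),
        ReferenceSequence("source_01", Category.SOURCE, "".join(s1b)),
        ReferenceSequence("source_02", Category.SOURCE, _tag(rng)),
        ReferenceSequence("sink_iso", Category.SINK, _tag(rng)),
        ReferenceSequence("control_iso", Category.CONTROL, _tag(rng)),
    ]
    return ReferencePanel(entries=entries, trim_length=150)


@pytest.fixture(scope="session")
def tiny_table(tiny_panel):
    """Hand-built 3-sample table over the tiny panel plus one background tag."""
    rng = np.random.default_rng(7)
    bg = _tag(rng)
    seqs = {
        "s1": tiny_panel.entries[0].sequence,
        "s1_op2": tiny_panel.entries[1].sequence,
        "s2": tiny_panel.entries[2].sequence,
        "sink": tiny_panel.entries[3].sequence,
        "bg": bg,
    }
    counts = pd.DataFrame(
        {
            seqs["s1"]: [100, 5, 0],
            seqs["s1_op2"]: [20, 0, 0],
            seqs["s2"]: [0, 200, 3],
            seqs["sink"]: [0, 10, 900],
            seqs["bg"]: [4, 4, 40],
        },
        index=["samp_source1", "samp_source2", "samp_sink"],
    )
    return FeatureTable(counts), seqs


@pytest.fixture(scope="session")
def tiny_records():
    return [
        SampleRecord("samp_source1", parse_well_id("A1"), sample_type="source",
                     expected_label="source_01", site="X", extraction_method="m_tube"),
        SampleRecord("samp_source2", parse_well_id("C3"), sample_type="source",
                     expected_label="source_02", site="X", extraction_method="m_tube"),
        SampleRecord("samp_sink", parse_well_id("B2"), sample_type="sink",
                     site="X", extraction_method="m_tube"),
    ]


@pytest.fixture(scope="session")
def default_sim():
    """One simulated extraction plate under default study conditions."""
    return simulate_extraction_plate(SimParams(seed=1))


@pytest.fixture(scope="session")
def fast_params():
    """Smaller depth for tests that iterate over several simulations."""
    return SimParams(seed=1, depth=10_000)
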