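import numpy as np
import pandas as pd
import pytest

from crosswell.classify import Category, SotuCall, SotuClassification, classify_sotus
from crosswell.errors import (
    AccountingError,
    ConfigError,
    MetadataError,
    SummaryError,
)
from crosswell.plate import parse_well_id
from crosswell.quantify import (
    ContaminationPartition,
    SampleRecord,
    barcode_leakage,
    partition_sample,
    partition_table,
    partitions_frame,
    records_from_metadata,
    summarize_groups,
)
from crosswell.table import FeatureTable


def _cls(**calls):
    return SotuClassification(
        {
            k: SotuCall(Category[cat], label)
            for k, (cat, label) in calls.items()
        }
    )


CLS = _cls(
    src_k=("SOURCE", "k"),
    src_j=("SOURCE", "j"),
    sink=("SINK", "sink_iso"),
    bg=("BACKGROUND", None),
    ctrl=("CONTROL", "ctrl_iso"),
)


def _rec(sample_type, expected_label=None, sample_id="s", well="A1", **kw):
    return SampleRecord(
        sample_id, parse_well_id(well), sample_type=sample_type,
        expected_label=expected_label, **kw,
    )


class TestPartitionSample:
    def test_ntc_fractions(self):
        p = partition_sample({"bg": 90, "src_k": 10}, CLS, _rec("NTC"))
        assert p.fraction_w2w == pytest.approx(0.10)
        assert p.fraction_background == pytest.approx(0.90)
        assert p.reads_expected == 0

    def test_source_with_only_own_reads(self):
        p = partition_sample({"src_k": 500}, CLS, _rec("source", "k"))
        assert p.fraction_w2w == 0.0
        assert p.w2w_richness_share == 0.0
        assert p.reads_expected == 500

    def test_sink_one_percent(self):
        p = partition_sample({"sink": 99000, "src_j": 1000}, CLS, _rec("sink"))
        assert p.fraction_w2w == pytest.approx(0.01)

    def test_read_conservation(self):
        p = partition_sample(
            {"sink": 10, "src_j": 3, "src_k": 2, "bg": 5}, CLS, _rec("source", "k")
        )
        assert p.reads_expected + p.reads_w2w + p.reads_background == p.reads_total
        assert (p.reads_expected, p.reads_w2w, p.reads_background) == (2, 13, 5)

    def test_foreign_sink_reads_in_source_well_are_w2w(self):
        p = partition_sample({"src_k": 10, "sink": 4}, CLS, _rec("source", "k"))
        assert p.reads_w2w == 4

    def test_control_reads_count_as_background_not_w2w(self):
        p = partition_sample({"src_k": 10, "ctrl": 7}, CLS, _rec("source", "k"))
        assert p.reads_w2w == 0
        assert p.reads_background == 7
        assert p.reads_control == 7

    def test_zero_total_flagged_empty(self):
        p = partition_sample({"bg": 0}, CLS, _rec("NTC"))
        assert p.empty
        assert p.fraction_w2w == 0.0

    def test_unclassified_sotu_rejected(self):
        with pytest.raises(AccountingError):
            partition_sample({"mystery": 3}, CLS, _rec("NTC"))

    def test_unknown_sample_type_rejected(self):
        with pytest.raises(MetadataError):
            _rec("plasma")

    def test_richness_counts_only_present_sotus(self):
        p = partition_sample({"src_k": 1, "src_j": 0, "bg": 2}, CLS, _rec("NTC"))
        assert p.richness == 2
        assert p.n_w2w_sotus == 1


def test_exact_truth_agreement_on_simulation(default_sim):
    """Quantifier read classes equal simulator ground truth for every sample."""
    cls = classify_sotus(default_sim.table, default_sim.panel)
    records = records_from_metadata(default_sim.metadata)
    parts = partition_table(default_sim.table, cls, records)
    pf = partitions_frame(parts)
    truth = default_sim.truth.per_sample
    assert (pf["reads_w2w"] == truth["reads_w2w"]).all()
    assert (pf["reads_background"] == truth["reads_background"]).all()
    assert (pf["reads_expected"] == truth["reads_expected"]).all()
    # conservation against the emitted table
    assert (
        pf["reads_total"].to_numpy()
        == default_sim.table.counts.sum(axis=1).to_numpy()
    ).all()


class TestSummarizeGroups:
    def _toy_frame(self):
        parts = [
            ContaminationPartition("a", 90, 10, 0, 0, 3, 1, "NTC", False),
            ContaminationPartition("b", 100, 0, 0, 0, 1, 0, "NTC", False),
            ContaminationPartition("c", 80, 20, 0, 0, 4, 2, "NTC", False),
            ContaminationPartition("d", 100, 0, 0, 0, 2, 0, "NTC", False),
        ]
        return partitions_frame(parts)

    def test_prevalence_counting(self):
        out = summarize_groups(self._toy_frame(), ["sample_type"])
        assert out.loc["NTC", "prevalence_pct"] == pytest.approx(50.0)
        assert out.loc["NTC", "n_samples"] == 4

    def test_even_n_median_midpoint(self):
        out = summarize_groups(self._toy_frame(), ["sample_type"])
        # fractions are 0.1, 0, 0.2, 0 -> median (0 + 0.1)/2 = 0.05 -> 5%
        assert out.loc["NTC", "w2w_median_pct"] == pytest.approx(5.0)
        assert out.loc["NTC", "w2w_max_pct"] == pytest.approx(20.0)

    def test_all_zero_group(self):
        parts = [
            ContaminationPartition(s, 10, 0, 0, 0, 1, 0, "sink", False)
            for s in "abc"
        ]
        out = summarize_groups(partitions_frame(parts), ["sample_type"])
        row = out.loc["sink"]
        assert row["w2w_mean_pct"] == row["w2w_median_pct"] == row["w2w_max_pct"] == 0

    def test_w2w_pct_of_richness_is_mean_of_shares(self):
        out = summarize_groups(self._toy_frame(), ["sample_type"])
        shares = [1 / 3, 0, 2 / 4, 0]
        assert out.loc["NTC", "w2w_pct_of_richness"] == pytest.approx(
            100 * np.mean(shares)
        )

    def test_min_reads_excludes_empty_samples(self):
        parts = [
            ContaminationPartition("a", 0, 0, 0, 0, 0, 0, "NTC", True),
            ContaminationPartition("b", 5, 5, 0, 0, 2, 1, "NTC", False),
        ]
        out = summarize_groups(partitions_frame(parts), ["sample_type"])
        assert out.loc["NTC", "n_samples"] == 1

    def test_empty_group_set_rejected(self):
        parts = [ContaminationPartition("a", 0, 0, 0, 0, 0, 0, "NTC", True)]
        with pytest.raises(SummaryError):
            summarize_groups(partitions_frame(parts), ["sample_type"])
        with pytest.raises(SummaryError):
            summarize_groups(self._toy_frame(), ["no_such_column"])


class TestBarcodeLeakage:
    def _tables(self, crossover=0):
        exp = FeatureTable(
            pd.DataFrame(
                {"src_k": [1000, 0], "sink": [0, 500], "ctrl": [crossover, 0]},
                index=["e1", "e2"],
            )
        )
        ctl = FeatureTable(pd.DataFrame({"ctrl": [2000]}, index=["c1"]))
        return exp, ctl

    def test_synthetic_injection_rate(self):
        exp, ctl = self._tables(crossover=5)
        out = barcode_leakage(exp, ctl, CLS)
        assert out["leaked_reads"] == 5
        assert out["rate_bound"] == pytest.approx(5 / out["total_reads"])
        assert not out["is_upper_bound"]

    def test_zero_crossover_gives_upper_bound(self):
        exp, ctl = self._tables(crossover=0)
        out = barcode_leakage(exp, ctl, CLS)
        assert out["leaked_reads"] == 0
        assert out["is_upper_bound"]
        assert out["rate_bound"] == pytest.approx(1 / out["total_reads"])

    def test_experiment_labels_in_control_plate_count(self):
        exp = FeatureTable(pd.DataFrame({"src_k": [1000]}, index=["e1"]))
        ctl = FeatureTable(pd.DataFrame({"ctrl": [900], "src_j": [4]}, index=["c1"]))
        out = barcode_leakage(exp, ctl, CLS)
        assert out["leaked_reads"] == 4

    def test_missing_control_label_rejected(self):
        exp, ctl = self._tables()
        no_ctrl = _cls(src_k=("SOURCE", "k"), sink=("SINK", "s"))
        with pytest.raises(ConfigError):
            barcode_leakage(exp, ctl, no_ctrl)


def test_records_from_metadata_roundtrip():
    md = pd.DataFrame(
        {
            "well_ID": ["A1", "B2"],
            "sample_type": ["source", "NTC"],
            "expected_label": ["k", ""],
            "extraction_method": ["robot", "robot"],
            "site": ["UCSD", "UCSD"],
        },
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )
    recs = records_from_metadata(md)
    assert recs[0].expected_label == "k"
    assert recs[1].expected_label is None
    assert recs[1].well == parse_well_id("B2")
    with pytest.raises(MetadataError):
        records_from_metadata(md.drop(columns=["well_ID"]))
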