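import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial import distance as sp_distance

from crosswell.diversity import (
    bray_curtis,
    distance_matrix,
    jaccard_binary,
    rank_test,
    replicate_distances,
    richness_inflation,
)
from crosswell.errors import PairingError, StatTestError, UndefinedDistanceError
from crosswell.quantify import ContaminationPartition
from crosswell.table import FeatureTable


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ((5, 3, 1), (5, 3, 1), 0.0),
        ((1, 0, 0), (0, 0, 9), 1.0),
        ((1, 1, 0), (0, 1, 1), 0.5),
    ],
)
def test_bray_curtis_examples(x, y, expected):
    assert bray_curtis(x, y) == pytest.approx(expected)


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ((5, 3, 1), (1, 1, 1), 0.0),
        ((1, 0, 0), (0, 0, 9), 1.0),
        ((1, 1, 0), (0, 1, 1), 2 / 3),
    ],
)
def test_jaccard_examples(x, y, expected):
    assert jaccard_binary(x, y) == pytest.approx(expected)


@pytest.mark.parametrize("fn", [bray_curtis, jaccard_binary])
def test_both_empty_undefined(fn):
    with pytest.raises(UndefinedDistanceError):
        fn([0, 0], [0, 0])
    with pytest.raises(UndefinedDistanceError):
        fn([1, 2], [1, 2, 3])


def test_metric_properties_1000_random_draws():
    """d(x,x)=0, symmetry, and [0,1] range on random count vectors."""
    rng = np.random.default_rng(0)
    for _ in range(1000):
        n = rng.integers(1, 30)
        x = rng.poisson(2.0, size=n).astype(float)
        y = rng.poisson(2.0, size=n).astype(float)
        if x.sum() == 0 and y.sum() == 0:
            continue
        for fn in (bray_curtis, jaccard_binary):
            assert fn(x, y) == pytest.approx(fn(y, x))
            assert 0.0 <= fn(x, y) <= 1.0
            if x.sum() > 0:
                assert fn(x, x) == 0.0


@settings(max_examples=100, deadline=None)
@given(
    arrays(np.int64, st.integers(2, 20), elements=st.integers(0, 1000)),
    st.randoms(use_true_random=False),
)
def test_matches_scipy_reference(x, rnd):
    """Cross-check against scipy's distance implementations."""
    y = np.array([rnd.randint(0, 1000) for _ in x], dtype=np.int64)
    if x.sum() == 0 or y.sum() == 0:
        return
    assert bray_curtis(x, y) == pytest.approx(
        sp_distance.braycurtis(x.astype(float), y.astype(float))
    )
    assert jaccard_binary(x, y) == pytest.approx(
        sp_distance.jaccard(x > 0, y > 0)
    )


def test_one_read_spike_hits_jaccard_harder_than_bray_curtis():
    """A single foreign read barely moves Bray-Curtis but visibly moves
    Jaccard once total depth is large."""
    rng = np.random.default_rng(5)
    base = rng.multinomial(5000, np.full(10, 0.1)).astype(float)
    spiked = np.append(base, 1.0)
    padded = np.append(base, 0.0)
    d_bc = bray_curtis(padded, spiked)
    d_j = jaccard_binary(padded, spiked)
    assert d_j > d_bc
    assert d_j >= 1 / 11
    assert d_bc < 1e-3


class TestRankTest:
    def test_identical_groups_null_center(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = rank_test([g, list(g)], "mann_whitney")
        assert out["p_value"] > 0.9
        out = rank_test([g, list(g), list(g)], "kruskal_wallis")
        assert out["p_value"] > 0.9

    def test_unit_shift_detected(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 50)
        assert rank_test([a, b], "mann_whitney")["p_value"] < 1e-3
        assert rank_test([a, b], "kruskal_wallis")["p_value"] < 1e-3

    def test_exact_small_sample_matches_enumeration(self):
        """Brute-force permutation null for small tie-free samples."""
        x = [1.3, 2.7, 5.1, 8.2]
        y = [0.4, 3.3, 4.0, 6.6, 9.9]
        out = rank_test([x, y], "mann_whitney")
        pooled = sorted(x + y)
        n, m = len(x), len(y)

        def u_stat(xs):
            return sum(1 for a in xs for b in set(pooled) - set(xs) if a > b)

        observed = u_stat(x)
        us = [u_stat(c) for c in itertools.combinations(pooled, n)]
        p_exact = np.mean(
            [min(u, n * m - u) <= min(observed, n * m - observed) for u in us]
        )
        assert out["p_value"] == pytest.approx(p_exact)

    def test_group_structure_errors(self):
        with pytest.raises(StatTestError):
            rank_test([[1, 2]], "mann_whitney")
        with pytest.raises(StatTestError):
            rank_test([[1, 2], [3, 4], [5, 6]], "mann_whitney")
        with pytest.raises(StatTestError):
            rank_test([[1], [2, 3]], "kruskal_wallis")
        with pytest.raises(StatTestError):
            rank_test([[1, 2], [3, 4]], "t_test")


class TestReplicateDistances:
    def _table_md(self, jitter=False):
        rng = np.random.default_rng(2)
        base = rng.multinomial(1000, np.full(5, 0.2), size=4).astype(int)
        rows = {}
        md_rows = []
        for plate in ("p1", "p2"):
            for rep in ("A", "B"):
                for i, well in enumerate(["A1", "A2", "B1", "B2"]):
                    sid = f"{plate}.{rep}.{well}"
                    vec = base[i].copy()
                    if jitter and plate == "p2":
                        vec = vec + rng.poisson(5, size=5)
                    rows[sid] = vec
                    md_rows.append(
                        {
                            "sample_id": sid,
                            "well_ID": well,
                            "extraction_plate": plate,
                            "pcr_rep": rep,
                            "sample_type": "sink",
                        }
                    )
        counts = pd.DataFrame(rows).T
        counts.columns = [f"t{i}" for i in range(5)]
        md = pd.DataFrame(md_rows).set_index("sample_id")
        return FeatureTable(counts), md

    def test_identical_replicates_give_zero_distances(self):
        table, md = self._table_md()
        for metric in ("bray_curtis", "jaccard"):
            grouped, skipped = replicate_distances(
                table, md, "pcr_replicates", metric
            )
            assert all(d == 0 for d in grouped["sink"])
            assert len(grouped["sink"]) == 8  # 2 plates x 4 wells

    def test_extraction_pairing_crosses_plates(self):
        table, md = self._table_md(jitter=True)
        grouped, _ = replicate_distances(
            table, md, "extraction_replicates", "jaccard"
        )
        assert len(grouped["sink"]) == 8  # 2 pcr reps x 4 wells

    def test_single_pair(self):
        table, md = self._table_md()
        sub = md[(md["extraction_plate"] == "p1") & (md["well_ID"] == "A1")]
        grouped, _ = replicate_distances(table, sub, "pcr_replicates", "bray_curtis")
        assert len(grouped["sink"]) == 1

    def test_zero_pairs_rejected(self):
        table, md = self._table_md()
        only_a = md[md["pcr_rep"] == "A"]
        with pytest.raises(PairingError):
            replicate_distances(table, only_a, "pcr_replicates", "bray_curtis")

    def test_unknown_pairing_rejected(self):
        table, md = self._table_md()
        with pytest.raises(PairingError):
            replicate_distances(table, md, "technical", "bray_curtis")


def test_distance_matrix_symmetric_zero_diagonal():
    counts = pd.DataFrame(
        {"a": [3, 0, 1], "b": [1, 2, 1], "c": [0, 5, 1]},
        index=["s1", "s2", "s3"],
    )
    dm = distance_matrix(FeatureTable(counts), "bray_curtis")
    assert np.allclose(dm, dm.T)
    assert np.all(np.diag(dm) == 0)


class TestRichnessInflation:
    def test_own_sotu_only_no_excess(self):
        p = ContaminationPartition("a", 100, 0, 0, 0, 1, 0, "sink", False)
        out = richness_inflation([p])
        assert out.loc["a", "excess"] == 0
        assert out.loc["a", "w2w_richness_share"] == 0.0

    def test_w2w_share_of_richness(self):
        p = ContaminationPartition("a", 50, 10, 40, 0, 5, 2, "sink", False)
        out = richness_inflation([p])
        assert out.loc["a", "w2w_richness_share"] == pytest.approx(0.4)
        assert out.loc["a", "excess"] == 4
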