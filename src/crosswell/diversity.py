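"""Alpha/beta-diversity impact of contamination, and rank-based group tests.

Contamination inflates observed richness (every control well should hold a
single isolate) and perturbs between-replicate dissimilarities.  Binary
metrics (Jaccard) weight rare foreign tags as heavily as the dominant
genuine one, so they are more sensitive to low-level contamination than
abundance-weighted metrics (Bray-Curtis).  Distances are computed on
unrarefied counts.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PairingError, StatTestError, UndefinedDistanceError
from .quantify import ContaminationPartition
from .table import FeatureTable


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    denom = float((x + y).sum())
    if denom == 0:
        raise UndefinedDistanceError("Bray-Curtis undefined for two empty vectors")
    return float(np.abs(x - y).sum()) / denom


def jaccard_binary(x: Sequence[float], y: Sequence[float]) -> float:
    """Binary Jaccard dissimilarity: 1 - |A n B| / |A u B| on presence sets."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    a = x > 0
    b = y > 0
    union = int((a | b).sum())
    if union == 0:
        raise UndefinedDistanceError("Jaccard undefined for two empty vectors")
    return 1.0 - int((a & b).sum()) / union


_METRICS = {"bray_curtis": bray_curtis, "jaccard": jaccard_binary}


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise UndefinedDistanceError(
            f"vectors have different lengths: {x.shape} vs {y.shape}"
        )
    if (x < 0).any() or (y < 0).any():
        raise UndefinedDistanceError("count vectors must be nonnegative")


def distance_matrix(table: FeatureTable, metric: str = "bray_curtis") -> pd.DataFrame:
    """Square labeled dissimilarity matrix over all samples."""
    fn = _METRICS[metric]
    ids = table.sample_ids
    arr = table.counts.to_numpy(dtype=float)
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fn(arr[i], arr[j])
    return pd.DataFrame(out, index=ids, columns=ids)


def replicate_distances(
    table: FeatureTable,
    metadata: pd.DataFrame,
    pairing_kind: str = "pcr_replicates",
    metric: str = "bray_curtis",
) -> tuple[dict[str, list[float]], list[tuple[str, ...]]]:
    """Per-pair dissimilarities between replicates sharing a well_ID.

    ``pcr_replicates`` pairs samples from the same extraction plate that
    differ only in PCR replicate; ``extraction_replicates`` pairs samples
    from different extraction plates sharing well_ID and PCR replicate.
    Returns distances grouped by sample_type plus the skipped (unpairable
    or empty) pair keys.
    """
    if pairing_kind == "pcr_replicates":
        group_cols, axis_col = ["extraction_plate", "well_ID"], "pcr_rep"
    elif pairing_kind == "extraction_replicates":
        group_cols, axis_col = ["pcr_rep", "well_ID"], "extraction_plate"
    else:
        raise PairingError(f"unknown pairing_kind {pairing_kind!r}")
    needed = set(group_cols + [axis_col, "sample_type"])
    missing = needed - set(metadata.columns)
    if missing:
        raise PairingError(f"metadata missing columns: {sorted(missing)}")

    fn = _METRICS[metric]
    md = metadata.loc[[s for s in metadata.index if s in table.counts.index]]
    grouped: dict[str, list[float]] = {}
    skipped: list[tuple[str, ...]] = []
    for keys, sub in md.groupby(group_cols, sort=True):
        if len(sub) < 2 or sub[axis_col].nunique() < 2:
            skipped.append(tuple(map(str, keys if isinstance(keys, tuple) else (keys,))))
            continue
        # one member per replicate level, deterministic order
        sub = sub.sort_values(axis_col)
        ids = [g.index[0] for _, g in sub.groupby(axis_col, sort=True)]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                x = table.counts.loc[ids[i]].to_numpy(dtype=float)
                y = table.counts.loc[ids[j]].to_numpy(dtype=float)
                if x.sum() == 0 and y.sum() == 0:
                    skipped.append((ids[i], ids[j]))
                    continue
                stype = str(sub["sample_type"].iloc[0])
                grouped.setdefault(stype, []).append(fn(x, y))
    if not grouped:
        raise PairingError(f"pairing {pairing_kind!r} yielded zero usable pairs")
    return grouped, skipped


def rank_test(groups: Sequence[Sequence[float]], test_name: str) -> dict:
    """Two-sided nonparametric comparison of >= 2 groups.

    ``kruskal_wallis`` accepts any number of groups; ``mann_whitney``
    requires exactly two (exact null distribution for small tie-free
    samples, normal approximation with tie correction otherwise).  Ties
    are handled by midranks.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise StatTestError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise StatTestError("every group needs at least two observations")
    if test_name == "kruskal_wallis":
        res = stats.kruskal(*groups)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test_name == "mann_whitney":
        if len(groups) != 2:
            raise StatTestError("mann_whitney requires exactly two groups")
        x, y = groups
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (len(x) <= 20 and len(y) <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise StatTestError(f"unknown test {test_name!r}")
    return {
        "test_name": test_name,
        "statistic": stat,
        "p_value": min(p, 1.0),
        "group_sizes": [len(g) for g in groups],
    }


def richness_inflation(
    partitions: Iterable[ContaminationPartition],
    expected_richness: int = 1,
) -> pd.DataFrame:
    """Per-sample richness inflation over the expected single-isolate sOTU.

    Control wells hold one isolate, so any richness beyond
    ``expected_richness`` is contamination (well-to-well or background) or
    extra rRNA operons.  ``w2w_richness_share`` is the fraction of observed
    sOTUs that are well-to-well contaminants.
    """
    rows = []
    for p in partitions:
        rows.append(
            {
                "sample_id": p.sample_id,
                "sample_type": p.sample_type,
                "richness": p.richness,
                "excess": max(p.richness - expected_richness, 0),
                "n_w2w_sotus": p.n_w2w_sotus,
                "w2w_richness_share": p.w2w_richness_share,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "sample_type",
            "richness",
            "excess",
            "n_w2w_sotus",
            "w2w_richness_share",
        ],
    ).set_index("sample_id")
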