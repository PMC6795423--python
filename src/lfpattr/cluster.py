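"""Hierarchical clustering of trials and the baseline/treatment overlap statistic.

Whole trials are treated as points in R^N under the Euclidean metric and
merged agglomeratively into a dendrogram.  For a concatenated
baseline-plus-treatment ensemble cut into k clusters, the mixing of the
two conditions inside each cluster is scored as

    overlap% = 100 * min(n_baseline, n_treatment) / n_cluster,

which is 0 for a pure cluster and at most 50 for a perfectly mixed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .dataio import TrialSet, concat_matrix

__all__ = [
    "DendrogramResult",
    "OverlapReport",
    "TwoConditionOverlap",
    "linkage_euclidean",
    "cut",
    "overlap_percentage",
    "overlap_at_ks",
]

_LINKAGES = ("single", "complete", "average", "ward")


@dataclass
class DendrogramResult:
    """Agglomerative merge tree in SciPy linkage form.

    ``merge_tree`` rows are ``(cluster_a, cluster_b, height, size)``;
    heights are non-decreasing for the monotone linkages used here.
    """

    merge_tree: np.ndarray
    n_leaves: int
    linkage_name: str


def _observations(data) -> np.ndarray:
    if isinstance(data, TrialSet):
        return data.as_matrix()
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a TrialSet or a 2-D observation matrix")
    return arr


def linkage_euclidean(data, method: str = "single") -> DendrogramResult:
    """Merge tree on the Euclidean distances between whole observations.

    ``data`` may be a TrialSet (rows = trials; align first for the
    distances to reflect waveform shape rather than stimulus phase) or
    any 2-D matrix of observations, e.g. scattered 2-D points.
    """
    if method not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    obs = _observations(data)
    if obs.shape[0] < 2:
        raise ValueError("clustering needs at least two observations")
    z = linkage(pdist(obs), method=method)
    return DendrogramResult(merge_tree=z, n_leaves=obs.shape[0], linkage_name=method)


def cut(tree: DendrogramResult, k: int) -> np.ndarray:
    """Partition the leaves into exactly ``k`` clusters (labels 1..k).

    Cutting at k and at k' > k yields nested partitions.
    """
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k={k} outside 1..{tree.n_leaves}")
    return fcluster(tree.merge_tree, t=k, criterion="maxclust")


@dataclass
class OverlapReport:
    """Per-cluster condition mixing at one cluster count.

    ``per_cluster`` rows are ``(n_total, n_baseline, n_other,
    overlap_percent)``; overlap is bounded in [0, 50] by construction.
    """

    k: int
    per_cluster: list[tuple[int, int, int, float]]
    mean: float
    sd: float


def overlap_percentage(labels: np.ndarray, is_baseline: np.ndarray) -> OverlapReport:
    """Score baseline/treatment mixing of a flat clustering.

    ``is_baseline`` marks, per trial, membership of the baseline block of
    the concatenated ensemble.  The summary is the plain (unweighted)
    mean and sd of the per-cluster overlap percentages.
    """
    labels = np.asarray(labels)
    is_baseline = np.asarray(is_baseline, dtype=bool)
    if labels.shape != is_baseline.shape:
        raise ValueError("labels and membership must have the same length")
    rows = []
    for lab in np.unique(labels):
        in_cluster = labels == lab
        n_total = int(in_cluster.sum())
        n_base = int((in_cluster & is_baseline).sum())
        n_other = n_total - n_base
        pct = 100.0 * min(n_base, n_other) / n_total
        rows.append((n_total, n_base, n_other, pct))
    pcts = np.array([r[3] for r in rows])
    report = OverlapReport(
        k=len(rows), per_cluster=rows, mean=float(pcts.mean()), sd=float(pcts.std())
    )
    for r in rows:
        assert 0.0 <= r[3] <= 50.0  # consequence of the min/total form
    return report


@dataclass
class TwoConditionOverlap:
    """Overlap reports at several cluster counts plus their mean difference."""

    reports: dict[int, OverlapReport]
    mean_difference: float | None


def overlap_at_ks(
    set_a: TrialSet,
    set_b: TrialSet,
    ks: tuple[int, ...] = (6, 12),
    method: str = "single",
) -> TwoConditionOverlap:
    """Concatenate baseline (set_a) and treatment (set_b), cut at each k.

    Returns one OverlapReport per requested cluster count and, when at
    least two counts are given, the difference of the first two mean
    overlaps (the coarse-vs-fine consistency check).
    """
    mat, is_baseline = concat_matrix(set_a, set_b)
    tree = linkage_euclidean(mat, method=method)
    reports = {k: overlap_percentage(cut(tree, k), is_baseline) for k in ks}
    mean_diff = None
    if len(ks) >= 2:
        mean_diff = reports[ks[0]].mean - reports[ks[1]].mean
    return TwoConditionOverlap(reports=reports, mean_difference=mean_diff)
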