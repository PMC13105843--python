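"""Sample ordering and representative selection for stacked barplots.

Meaningful sample order is what makes group differences readable in a
stacked barplot.  Three arrangements are provided:

* input-row order (lets the user encode time, treatment, or any predefined
  factor in the file itself);
* hierarchical-clustering order — complete linkage on Euclidean distance by
  default, the classic recipe for placing compositionally similar samples
  next to each other — taking the dendrogram's leaf order;
* grouped order: groups laid out contiguously, clustered independently
  within each group (e.g. all control samples left, all treatment right).

For large studies, :func:`select_representatives` shows one sample per
cluster: either the member nearest the cluster centroid (Euclidean) or the
Bray–Curtis medoid, after cutting a complete-linkage dendrogram into ``k``
clusters.

All operations are deterministic: clustering is scipy's agglomerative
implementation (itself deterministic for a fixed input), and remaining ties
(centroid/medoid equidistance) are broken by smallest original sample index.
Bray–Curtis, BC(x, y) = Σ|x_k − y_k| / Σ(x_k + y_k), is bounded in [0, 1]
for non-negative data and is not a metric (the triangle inequality can
fail); it is undefined for a pair of all-zero samples, which raises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .tables import AbundanceTable

__all__ = [
    "Arrangement",
    "DissimilarityMatrix",
    "ArrangementError",
    "bray_curtis",
    "euclidean",
    "order_by_rows",
    "order_by_clustering",
    "order_grouped",
    "select_representatives",
]

METRICS = ("euclidean", "bray-curtis")


class ArrangementError(ValueError):
    pass


@dataclass
class Arrangement:
    """An ordered (possibly subset) sample sequence for the bar panel."""

    ordered_samples: list[str]
    groups: dict[str, str] | None = None
    representatives: dict[int, str] | None = None


@dataclass
class DissimilarityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal
    metric: str

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def _check_metric(metric: str) -> None:
    if metric not in METRICS:
        raise ArrangementError(f"unknown metric {metric!r}; expected one of {METRICS}")


def bray_curtis(a: AbundanceTable) -> DissimilarityMatrix:
    """Pairwise Bray–Curtis dissimilarities between samples.

    Requires non-negative values and no pair of all-zero samples (for such a
    pair the quotient is 0/0).
    """
    x = a.values
    if np.any(x < 0):
        raise ArrangementError("Bray-Curtis requires non-negative abundances")
    zero_rows = [sid for sid, tot in zip(a.sample_ids, x.sum(axis=1)) if tot == 0]
    if len(zero_rows) >= 2:
        raise ArrangementError(
            f"Bray-Curtis undefined for all-zero sample pairs: {zero_rows}"
        )
    d = squareform(pdist(x, metric="braycurtis"), checks=False)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(ids=a.sample_ids, values=d, metric="bray-curtis")


def euclidean(a: AbundanceTable) -> DissimilarityMatrix:
    d = squareform(pdist(a.values, metric="euclidean"), checks=False)
    return DissimilarityMatrix(ids=a.sample_ids, values=d, metric="euclidean")


def _dissimilarity(a: AbundanceTable, metric: str) -> DissimilarityMatrix:
    _check_metric(metric)
    return bray_curtis(a) if metric == "bray-curtis" else euclidean(a)


def order_by_rows(a: AbundanceTable) -> Arrangement:
    """Input order, verbatim: the user's file order is the display order."""
    return Arrangement(ordered_samples=a.sample_ids)


def order_by_clustering(
    a: AbundanceTable, metric: str = "euclidean", linkage: str = "complete"
) -> Arrangement:
    """Dendrogram leaf order of agglomerative clustering over samples.

    Defaults (complete linkage, Euclidean distance) follow the standard
    community-composition recipe; both are options.  Fewer than two samples
    returns the input order with a warning.
    """
    if a.n_samples < 2:
        warnings.warn("fewer than 2 samples: returning input order", stacklevel=2)
        return Arrangement(ordered_samples=a.sample_ids)
    dm = _dissimilarity(a, metric)
    Z = sch.linkage(dm.condensed(), method=linkage)
    order = sch.leaves_list(Z)
    ids = a.sample_ids
    return Arrangement(ordered_samples=[ids[i] for i in order])


def _group_order(a: AbundanceTable, groups: dict[str, str]) -> list[str]:
    seen: list[str] = []
    for sid in a.sample_ids:
        g = groups[sid]
        if g not in seen:
            seen.append(g)
    return seen


def order_grouped(
    a: AbundanceTable,
    groups: dict[str, str],
    metric: str = "euclidean",
    linkage: str = "complete",
    group_order: list[str] | None = None,
) -> Arrangement:
    """Contiguous groups, clustered independently within each group.

    ``group_order`` defaults to first appearance over the sample ids; an
    explicit order (e.g. control before treatment) overrides it.
    """
    missing = [sid for sid in a.sample_ids if sid not in groups]
    if missing:
        raise ArrangementError(f"samples without a group label: {missing}")
    order = group_order if group_order is not None else _group_order(a, groups)
    known = set(order)
    stray = sorted({groups[sid] for sid in a.sample_ids} - known)
    if stray:
        raise ArrangementError(f"groups missing from group_order: {stray}")
    ordered: list[str] = []
    for g in order:
        members = [sid for sid in a.sample_ids if groups[sid] == g]
        if not members:
            continue
        sub = a.subset_samples(members)
        if len(members) < 2:
            ordered.extend(members)
        else:
            ordered.extend(order_by_clustering(sub, metric=metric, linkage=linkage).ordered_samples)
    return Arrangement(
        ordered_samples=ordered,
        groups={sid: groups[sid] for sid in ordered},
    )


def select_representatives(
    a: AbundanceTable, k: int, method: str = "centroid"
) -> Arrangement:
    """One representative sample per cluster after cutting the dendrogram at ``k``.

    ``"centroid"`` clusters on Euclidean distance (complete linkage) and picks
    the member nearest its cluster mean; ``"bc-medoid"`` clusters on
    Bray–Curtis and picks the member minimizing summed dissimilarity to its
    cluster.  Clusters are reported in dendrogram-leaf-order of first
    appearance; ties are broken by smallest original sample index.
    """
    n = a.n_samples
    if not (1 <= k <= n):
        raise ArrangementError(f"k={k} outside [1, {n}]")
    if method not in ("centroid", "bc-medoid"):
        raise ArrangementError(f"unknown method {method!r}")
    metric = "euclidean" if method == "centroid" else "bray-curtis"
    ids = a.sample_ids
    if n == 1:
        return Arrangement(ordered_samples=list(ids), representatives={0: ids[0]})
    dm = _dissimilarity(a, metric)
    Z = sch.linkage(dm.condensed(), method="complete")
    labels = sch.fcluster(Z, t=k, criterion="maxclust")
    leaf_seq = sch.leaves_list(Z)
    cluster_order: list[int] = []
    for i in leaf_seq:
        if labels[i] not in cluster_order:
            cluster_order.append(labels[i])
    x = a.values
    reps: dict[int, str] = {}
    ordered: list[str] = []
    for pos, cl in enumerate(cluster_order):
        members = [i for i in range(n) if labels[i] == cl]  # ascending index
        if method == "centroid":
            center = x[members].mean(axis=0)
            cost = np.linalg.norm(x[members] - center, axis=1)
        else:
            sub = dm.values[np.ix_(members, members)]
            cost = sub.sum(axis=1)
        best = members[int(np.argmin(cost))]  # argmin -> smallest index on ties
        reps[pos] = ids[best]
        ordered.append(ids[best])
    return Arrangement(ordered_samples=ordered, representatives=reps)
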