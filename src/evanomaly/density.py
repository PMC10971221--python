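"""Density filtering of pooled donor-space points with OPTICS.

Points from all conditions are pooled and ordered by OPTICS (Euclidean
metric). Clusters are then extracted at a fixed reachability radius eps —
the DBSCAN-equivalent extraction, matching the reading of the reachability
parameter as an extraction radius — and only the primary cluster is kept
for downstream analysis. The primary cluster is, by default, the most
populous cluster whose members have strictly positive raw peak areas in
every donor: the dominant, consistently quantified protein population.
Separating distinct point clouds is this stage's job; flagging extreme
points *within* the retained cloud belongs to the isolation-forest stage.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import OPTICS, cluster_optics_dbscan
from sklearn.neighbors import NearestNeighbors

from .preprocess import DonorPoint, LogAbundanceTable

__all__ = [
    "NOISE",
    "OpticsParams",
    "ClusterAssignment",
    "optics_order",
    "extract_clusters",
    "select_primary_cluster",
    "filter_to_cluster",
    "suggest_eps",
]

logger = logging.getLogger(__name__)

#: Label of points not assigned to any cluster.
NOISE = -1


@dataclasses.dataclass(frozen=True)
class OpticsParams:
    """OPTICS parameters: core-point neighborhood size and extraction radius.

    Defaults are the values used on the motivating three-donor dataset
    (min_pts=50, eps=0.05); eps is in log-abundance units, so it is only
    meaningful at a given data scale — use :func:`suggest_eps` to adapt it.
    """

    min_pts: int = 50
    eps: float = 0.05

    def __post_init__(self) -> None:
        if self.min_pts < 2:
            raise ValueError("min_pts must be >= 2")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")


@dataclasses.dataclass
class ClusterAssignment:
    """OPTICS ordering plus (after extraction) per-point cluster labels.

    All arrays are indexed by the input point order. ``labels`` is None
    until :func:`extract_clusters` runs; ``selected_cluster_id`` is None
    until :func:`select_primary_cluster` runs.
    """

    points: list[DonorPoint]
    params: OpticsParams
    ordering: np.ndarray
    reachability: np.ndarray
    core_distances: np.ndarray
    labels: np.ndarray | None = None
    selected_cluster_id: int | None = None

    def label_of(self, accession: str, condition: str) -> int:
        if self.labels is None:
            raise RuntimeError("extract_clusters has not been run")
        for point, label in zip(self.points, self.labels):
            if point.accession == accession and point.condition == condition:
                return int(label)
        raise KeyError((accession, condition))

    def cluster_sizes(self) -> dict[int, int]:
        if self.labels is None:
            raise RuntimeError("extract_clusters has not been run")
        ids, counts = np.unique(self.labels[self.labels != NOISE],
                                return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


def optics_order(points: Sequence[DonorPoint],
                 params: OpticsParams) -> ClusterAssignment:
    """Compute the OPTICS processing order with core/reachability distances.

    The core distance of a point is its distance to the min_pts-th nearest
    neighbor; the reachability distance of Q from P is max(core(P), d(P, Q)).
    Deterministic for a fixed input order.
    """
    points = list(points)
    if len(points) < params.min_pts:
        raise ValueError(
            f"{len(points)} points < min_pts={params.min_pts}; "
            "use a smaller min_pts")
    X = np.vstack([p.coords for p in points])
    model = OPTICS(min_samples=params.min_pts, metric="euclidean",
                   max_eps=np.inf, cluster_method="dbscan", eps=params.eps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on all-noise extraction
        model.fit(X)
    return ClusterAssignment(
        points=points,
        params=params,
        ordering=model.ordering_.copy(),
        reachability=model.reachability_.copy(),
        core_distances=model.core_distances_.copy(),
    )


def extract_clusters(assignment: ClusterAssignment,
                     eps: float | None = None) -> ClusterAssignment:
    """DBSCAN-equivalent cluster extraction at radius eps over the ordering.

    A consecutive run of points in the ordering with reachability <= eps,
    seeded at a core point, forms a cluster; all other points are NOISE.
    """
    if eps is None:
        eps = assignment.params.eps
    labels = cluster_optics_dbscan(
        reachability=assignment.reachability,
        core_distances=assignment.core_distances,
        ordering=assignment.ordering,
        eps=eps,
    )
    assignment.labels = np.asarray(labels, dtype=int)
    assignment.selected_cluster_id = None
    return assignment


def _all_positive(raw_table, accession: str, conditions: Iterable[str]) -> bool:
    for cond in conditions:
        vals = raw_table.values(accession, cond)
        if not np.all(np.isfinite(vals)) or not np.all(vals > 0):
            return False
    return True


def select_primary_cluster(assignment: ClusterAssignment,
                           logtable: LogAbundanceTable,
                           rule: str = "largest_all_positive") -> ClusterAssignment:
    """Choose the cluster carried into the distance analysis.

    ``largest_all_positive`` (default): the most populous cluster all of
    whose member proteins have strictly positive raw peak areas in every
    donor, in the member point's own condition; falls back to ``largest``
    with a warning when no cluster qualifies.
    """
    if rule not in {"largest_all_positive", "largest"}:
        raise ValueError(f"unknown selection rule {rule!r}")
    if assignment.labels is None:
        raise RuntimeError("extract_clusters must run before selection")
    sizes = assignment.cluster_sizes()
    if not sizes:
        raise ValueError("no clusters found (all points are noise); "
                         "try a larger eps")
    # Sort by (size desc, id asc) for a deterministic choice.
    by_size = sorted(sizes, key=lambda cid: (-sizes[cid], cid))

    chosen = None
    if rule == "largest_all_positive":
        raw = logtable.raw
        for cid in by_size:
            members = [p for p, lab in zip(assignment.points, assignment.labels)
                       if lab == cid]
            if all(_all_positive(raw, p.accession, [p.condition])
                   for p in members):
                chosen = cid
                break
        if chosen is None:
            logger.warning(
                "no cluster has all-positive raw peak areas; "
                "falling back to the largest cluster")
    if chosen is None:
        chosen = by_size[0]
    assignment.selected_cluster_id = int(chosen)
    return assignment


def filter_to_cluster(assignment: ClusterAssignment, comparison,
                      membership_rule: str = "both") -> set[str]:
    """Accessions whose points lie in the selected cluster for a comparison.

    ``both`` (default): the protein's points in *both* conditions of the
    comparison must be members — a distance between an in-cluster point and
    an unfiltered one would mix populations. ``either`` relaxes this to at
    least one condition.
    """
    if membership_rule not in {"both", "either"}:
        raise ValueError(f"unknown membership rule {membership_rule!r}")
    if assignment.selected_cluster_id is None:
        raise RuntimeError("select_primary_cluster must run before filtering")
    sel = assignment.selected_cluster_id
    member: dict[str, set[str]] = {}
    for point, label in zip(assignment.points, assignment.labels):
        if label == sel:
            member.setdefault(point.accession, set()).add(point.condition)
    wanted = {comparison.reference, comparison.treatment}
    if membership_rule == "both":
        return {a for a, conds in member.items() if wanted <= conds}
    return {a for a, conds in member.items() if conds & wanted}


def suggest_eps(points: Sequence[DonorPoint], min_pts: int,
                quantile: float = 0.98, inflation: float = 2.0) -> float:
    """Data-scale-adapted extraction radius from the k-distance profile.

    Returns ``inflation * quantile(d_k)`` where ``d_k`` is each point's
    distance to its min_pts-th nearest neighbor. The high quantile plus
    inflation keep eps above nearly all within-cloud k-distances, so only
    order-of-magnitude density gaps (distinct point clouds) split; cluster
    peripheries are retained for the outlier stage to judge.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    X = np.vstack([p.coords for p in points])
    if len(X) <= min_pts:
        raise ValueError(f"need more than min_pts={min_pts} points")
    nn = NearestNeighbors(n_neighbors=min_pts + 1).fit(X)
    dist, _ = nn.kneighbors(X)
    return float(inflation * np.quantile(dist[:, -1], quantile))
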