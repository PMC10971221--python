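"""Cross-condition Euclidean displacement and the empirical anomaly threshold.

For every eligible protein the displacement between its two donor-space
points (reference vs treatment condition) is the straight-line Euclidean
distance; the same-donor pairing means donor-level offsets cancel and the
distance measures how much the protein's expression profile moved. The
whole set of distances is thresholded at mean + k standard deviations
(k = 1 by default); proteins strictly above the threshold are the
"extremely changing" anomalies.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .preprocess import DonorPoint, LogAbundanceTable

__all__ = [
    "ComparisonSpec",
    "DistanceRecord",
    "AnomalySet",
    "euclidean_distance",
    "comparison_distances",
    "cross_condition_distance_matrix",
    "anomaly_threshold",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ComparisonSpec:
    """A reference-vs-treatment condition pair, optionally per biomaterial."""

    reference: str
    treatment: str
    experiment: str = ""

    def __post_init__(self) -> None:
        if self.reference == self.treatment:
            raise ValueError("reference and treatment must differ")

    @property
    def label(self) -> str:
        core = f"{self.reference}_vs_{self.treatment}"
        return f"{self.experiment}_{core}" if self.experiment else core


@dataclasses.dataclass(frozen=True)
class DistanceRecord:
    """Per-protein displacement d (log units, >= 0) and log fold change."""

    accession: str
    d: float
    logFC: float


@dataclasses.dataclass
class AnomalySet:
    """Distances, the mean + k*SD threshold, and the flagged accessions."""

    comparison: ComparisonSpec
    records: list[DistanceRecord]   # sorted by descending d
    tau: float
    k: float
    flagged: set[str]


def euclidean_distance(p: DonorPoint, q: DonorPoint) -> float:
    """Straight-line distance between two donor-space points."""
    if p.coords.shape != q.coords.shape:
        raise ValueError(
            f"dimension mismatch: {p.coords.shape} vs {q.coords.shape}")
    return float(np.sqrt(np.sum((p.coords - q.coords) ** 2)))


def comparison_distances(logtable: LogAbundanceTable, eligible: set[str],
                         comparison: ComparisonSpec) -> list[DistanceRecord]:
    """One distance record per eligible accession, in table order.

    d is the displacement of the protein between the two conditions (the
    diagonal of the cross-condition distance matrix); logFC is the mean
    treatment log abundance minus the mean reference log abundance.
    Proteins with missing values in either condition are skipped with a log
    message.
    """
    if not eligible:
        logger.warning("empty eligible set for %s: no distances "
                       "(threshold undefined downstream)", comparison.label)
        return []
    records = []
    for acc in logtable.accessions:
        if acc not in eligible:
            continue
        ref = logtable.values(acc, comparison.reference)
        trt = logtable.values(acc, comparison.treatment)
        if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(trt))):
            logger.info("skipping %s in %s: missing values", acc,
                        comparison.label)
            continue
        d = float(np.sqrt(np.sum((trt - ref) ** 2)))
        records.append(DistanceRecord(acc, d, float(trt.mean() - ref.mean())))
    return records


def cross_condition_distance_matrix(logtable: LogAbundanceTable,
                                    accessions: list[str],
                                    comparison: ComparisonSpec) -> np.ndarray:
    """All pairwise distances, reference points (rows) vs treatment (cols).

    The per-protein displacements of :func:`comparison_distances` are this
    matrix's diagonal.
    """
    ref = np.vstack([logtable.values(a, comparison.reference)
                     for a in accessions])
    trt = np.vstack([logtable.values(a, comparison.treatment)
                     for a in accessions])
    diff = ref[:, None, :] - trt[None, :, :]
    return np.sqrt(np.sum(diff ** 2, axis=-1))


def anomaly_threshold(records: list[DistanceRecord], k: float = 1.0,
                      comparison: ComparisonSpec | None = None,
                      sd_ddof: int = 1) -> AnomalySet:
    """Threshold the distance set at tau = mean + k * SD (sample SD).

    Proteins strictly above tau are flagged; ties at tau are not. Records
    are returned sorted by descending distance. Raises on fewer than two
    records (the SD, hence the threshold, is undefined).
    """
    if len(records) < 2:
        raise ValueError("need >= 2 distance records to form a threshold")
    d = np.array([r.d for r in records], dtype=float)
    tau = float(d.mean() + k * d.std(ddof=sd_ddof))
    flagged = {r.accession for r in records if r.d > tau}
    ordered = sorted(records, key=lambda r: (-r.d, r.accession))
    if comparison is None:
        comparison = ComparisonSpec("reference", "treatment")
    return AnomalySet(comparison=comparison, records=ordered, tau=tau, k=k,
                      flagged=flagged)
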