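"""Per-condition outlier scoring with an Isolation Forest.

Each condition's donor-space points are scored by an ensemble of random
isolation trees (random feature, uniform split between that feature's min
and max). Points isolated after few splits are atypical; the anomaly score
is

    s(x) = 2 ** (-E[h(x)] / c(n))

where E[h(x)] is the average path length over trees (with the standard
unsuccessful-search correction at truncated leaves) and c(n) the expected
path length of an unsuccessful binary-search-tree search on n points.
s > 0.5 means shorter-than-average isolation paths, i.e. more anomalous.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import IsolationForest

from .preprocess import DonorPoint

__all__ = [
    "ForestParams",
    "OutlierLabeling",
    "average_path_length",
    "fit_isolation_forest",
    "outlier_union",
]

_EULER_GAMMA = 0.5772156649015328606
_EXACT_HARMONIC_LIMIT = 10_000


def average_path_length(n: int) -> float:
    """c(n) = 2 H(n-1) - 2 (n-1)/n, the score normalizer.

    H(i) is the i-th harmonic number, summed exactly for moderate n and
    approximated by ln(i) + Euler-Mascheroni gamma above that.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return 0.0
    if n - 1 <= _EXACT_HARMONIC_LIMIT:
        harmonic = float(np.sum(1.0 / np.arange(1, n)))
    else:
        harmonic = math.log(n - 1) + _EULER_GAMMA
    return 2.0 * harmonic - 2.0 * (n - 1) / n


@dataclasses.dataclass(frozen=True)
class ForestParams:
    """Isolation-forest hyperparameters.

    ``subsample_size`` of None means min(256, n). ``contamination`` is the
    fraction of points flagged as outliers, or "auto" to flag s > 0.5.
    """

    n_trees: int = 500
    subsample_size: int | None = None
    contamination: float | str = 0.10
    seed: int = 1337

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.contamination != "auto" and not 0 < self.contamination <= 0.5:
            raise ValueError("contamination must be in (0, 0.5] or 'auto'")


@dataclasses.dataclass
class OutlierLabeling:
    """Scores and inlier/outlier flags for one condition's points."""

    condition: str
    scores: dict[str, float]      # accession -> s in (0, 1)
    flags: dict[str, bool]        # accession -> True if outlier

    @property
    def outliers(self) -> set[str]:
        return {a for a, f in self.flags.items() if f}


def fit_isolation_forest(points: Sequence[DonorPoint],
                         params: ForestParams = ForestParams()) -> OutlierLabeling:
    """Score one condition's points and flag the most anomalous.

    With a numeric contamination q, the ceil(q * n) points with the highest
    scores are flagged (ties broken by input order); with "auto", points
    with s > 0.5 are flagged.
    """
    points = list(points)
    if len(points) < 2:
        raise ValueError("need at least 2 points to fit the forest")
    conditions = {p.condition for p in points}
    if len(conditions) != 1:
        raise ValueError(f"points span multiple conditions: {sorted(conditions)}")
    X = np.vstack([p.coords for p in points])
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite coordinates")

    n = len(points)
    subsample = params.subsample_size
    if subsample is None:
        subsample = min(256, n)
    elif subsample > n:
        import warnings
        warnings.warn(f"subsample_size {subsample} > {n} points; clamping")
        subsample = n

    model = IsolationForest(n_estimators=params.n_trees,
                            max_samples=subsample,
                            contamination="auto",
                            random_state=params.seed)
    model.fit(X)
    # score_samples returns the negated anomaly score: s = -score_samples.
    scores = -model.score_samples(X)

    flags = np.zeros(n, dtype=bool)
    if params.contamination == "auto":
        flags = scores > 0.5
    else:
        k = int(math.ceil(params.contamination * n))
        # Stable ranking: highest score first, input order breaks ties.
        order = np.lexsort((np.arange(n), -scores))
        flags[order[:k]] = True

    condition = points[0].condition
    return OutlierLabeling(
        condition=condition,
        scores={p.accession: float(s) for p, s in zip(points, scores)},
        flags={p.accession: bool(f) for p, f in zip(points, flags)},
    )


def outlier_union(labelings: Mapping[str, OutlierLabeling], comparison,
                  rule: str = "union") -> set[str]:
    """Combine the two conditions' outlier flags for a comparison.

    ``union`` (default): flagged in at least one condition — a protein
    extreme in either condition can produce a large cross-condition
    displacement. ``intersection``: flagged in both. ``either_condition_only``:
    flagged in exactly one.
    """
    try:
        ref = labelings[comparison.reference]
        trt = labelings[comparison.treatment]
    except KeyError as exc:
        raise ValueError(f"no outlier labeling for condition {exc}") from None
    a, b = ref.outliers, trt.outliers
    if rule == "union":
        return a | b
    if rule == "intersection":
        return a & b
    if rule == "either_condition_only":
        return a ^ b
    raise ValueError(f"unknown pairing rule {rule!r}")
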