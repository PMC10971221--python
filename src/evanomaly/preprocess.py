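"""Log transformation and donor-space point construction.

Mass-spectral peak areas span a wide dynamic range; the log transform
compresses it so that distances between proteins are dominated by relative
(fold) changes rather than absolute intensity. Each retained protein then
becomes, per condition, a single point whose coordinates are its log
abundances in the D donors ("donor space", D = 3 in the motivating design).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AbundanceTable, ProteinId

__all__ = ["LogAbundanceTable", "DonorPoint", "log_transform", "donor_points"]

_BASES = {2: math.log(2), 10: math.log(10), "e": 1.0}


@dataclasses.dataclass(frozen=True)
class DonorPoint:
    """One protein's log-abundance vector across donors in one condition."""

    accession: str
    condition: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"non-finite coordinates for {self.accession}")


class LogAbundanceTable:
    """An abundance table after log transformation.

    Same shape as the source :class:`~evanomaly.io.AbundanceTable`; values in
    log units of the recorded base. ``dropped_proteins`` lists (accession,
    reason) pairs removed by the non-positive-value policy. ``raw`` keeps a
    reference to the source table (needed by the all-positive cluster
    selection rule).
    """

    def __init__(self, proteins: Sequence[ProteinId], donors: Sequence[str],
                 conditions: Sequence[str], data: pd.DataFrame,
                 log_base, dropped_proteins: list[tuple[str, str]],
                 raw: AbundanceTable):
        self.proteins = list(proteins)
        self.donors = list(donors)
        self.conditions = list(conditions)
        self.data = data
        self.log_base = log_base
        self.dropped_proteins = list(dropped_proteins)
        self.raw = raw

    @property
    def accessions(self) -> list[str]:
        return [p.accession for p in self.proteins]

    def values(self, accession: str, condition: str) -> np.ndarray:
        row = self.data.loc[accession]
        return np.array([row[(d, condition)] for d in self.donors], dtype=float)

    def __repr__(self) -> str:
        return (f"LogAbundanceTable({len(self.proteins)} proteins, "
                f"base={self.log_base}, dropped={len(self.dropped_proteins)})")


def log_transform(table: AbundanceTable, base=2,
                  nonpositive_policy: str = "drop_protein",
                  epsilon: float | None = None) -> LogAbundanceTable:
    """Log-transform all peak areas.

    Parameters
    ----------
    base
        2 (default: log fold changes read as doublings), 10, or "e".
    nonpositive_policy
        How to treat values <= 0, which are not log-transformable:
        ``drop_protein`` (default) removes the protein from the analysis,
        ``drop_cell`` blanks only the offending cell (it becomes missing),
        ``epsilon_floor`` replaces it by log(epsilon).
    epsilon
        Floor value for ``epsilon_floor``; must be > 0.
    """
    if base not in _BASES:
        raise ValueError(f"base must be one of 2, 10, 'e'; got {base!r}")
    if nonpositive_policy not in {"drop_protein", "drop_cell", "epsilon_floor"}:
        raise ValueError(f"unknown nonpositive_policy {nonpositive_policy!r}")
    if nonpositive_policy == "epsilon_floor":
        if epsilon is None or epsilon <= 0:
            raise ValueError("epsilon_floor requires epsilon > 0")

    denom = _BASES[base]
    values = table.data.to_numpy(dtype=float, copy=True)
    nonpos = np.isfinite(values) & (values <= 0)

    dropped: list[tuple[str, str]] = []
    keep = np.ones(len(table.proteins), dtype=bool)
    if nonpositive_policy == "drop_protein":
        bad_rows = nonpos.any(axis=1)
        for i in np.flatnonzero(bad_rows):
            acc = table.proteins[i].accession
            dropped.append((acc, "nonpositive peak area in at least one sample"))
        keep = ~bad_rows
        values = values[keep]
    elif nonpositive_policy == "drop_cell":
        values[nonpos] = np.nan
    else:  # epsilon_floor
        values[nonpos] = epsilon

    with np.errstate(divide="ignore", invalid="ignore"):
        logged = np.log(values) / denom
    proteins = [p for p, k in zip(table.proteins, keep) if k]
    data = pd.DataFrame(logged, index=[p.accession for p in proteins],
                        columns=table.data.columns)
    return LogAbundanceTable(proteins, table.donors, table.conditions, data,
                             base, dropped, table)


def donor_points(logtable: LogAbundanceTable, condition: str) -> list[DonorPoint]:
    """One donor-space point per retained protein for one condition.

    Proteins with any missing (NaN) value in the condition emit no point.
    Output order follows the table's protein order (deterministic).
    """
    if condition not in logtable.conditions:
        raise ValueError(
            f"unknown condition {condition!r}; available: {logtable.conditions}")
    points = []
    for p in logtable.proteins:
        coords = logtable.values(p.accession, condition)
        if np.all(np.isfinite(coords)):
            points.append(DonorPoint(p.accession, condition, coords))
    return points
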