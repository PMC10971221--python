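"""Reading and writing abundance tables and result tables.

The tool starts from a quantified, already-normalized peak-area matrix:
one row per protein, one column per (donor, condition) pair. Two on-disk
dialects are supported:

* **wide** (TSV or CSV): metadata columns ``accession``, ``gene``, ``name``
  followed by one column per sample named ``<donor>:<condition>``.
* **long** (TSV): columns ``accession``, ``gene``, ``name``, ``donor``,
  ``condition``, ``abundance``; one row per measured cell.

Missing measurements are encoded as empty cells or ``NA`` and kept as NaN
internally — they are never silently dropped. Parsing is locale-independent
("." decimal separator only).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProteinId",
    "AbundanceTable",
    "read_abundance_table",
    "write_abundance_table",
    "write_results_table",
    "read_results_table",
    "RESULT_COLUMNS",
]

_META_COLS = ("accession", "gene", "name")

#: Fixed column order of every per-comparison results table.
RESULT_COLUMNS = (
    "accession",
    "gene",
    "name",
    "distance",
    "threshold_flag",
    "p_value",
    "tier",
    "logFC",
    "var_ref",
    "var_trt",
    "abs_var_diff",
)

_NA_STRINGS = {"", "NA", "NaN", "nan"}


@dataclasses.dataclass(frozen=True)
class ProteinId:
    """A protein identity: UniProt-style accession plus optional labels.

    Isoform accessions (e.g. ``P24821-4``) are distinct identities from
    their parent accession.
    """

    accession: str
    gene: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")


class AbundanceTable:
    """Proteins x (donor, condition) matrix of normalized peak areas.

    ``data`` is a DataFrame indexed by accession (input row order preserved)
    with a (donor, condition) column MultiIndex; missing cells are NaN.
    Donors are identical across conditions — the same-donor pairing is what
    makes the donor-space geometry meaningful.
    """

    def __init__(self, proteins: Sequence[ProteinId], donors: Sequence[str],
                 conditions: Sequence[str], data: pd.DataFrame):
        accs = [p.accession for p in proteins]
        dupes = pd.Index(accs)[pd.Index(accs).duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate accession: {dupes[0]!r}")
        expected = pd.MultiIndex.from_product(
            [list(donors), list(conditions)], names=["donor", "condition"])
        missing_cols = set(expected) - set(data.columns)
        if missing_cols:
            raise ValueError(
                f"ragged donor/condition grid: missing columns {sorted(missing_cols)}")
        self.proteins = list(proteins)
        self.donors = list(donors)
        self.conditions = list(conditions)
        self.data = data.loc[accs, expected].astype(float)

    @property
    def accessions(self) -> list[str]:
        return [p.accession for p in self.proteins]

    def protein(self, accession: str) -> ProteinId:
        for p in self.proteins:
            if p.accession == accession:
                return p
        raise KeyError(accession)

    def values(self, accession: str, condition: str) -> np.ndarray:
        """Peak areas of one protein in one condition, in donor order."""
        row = self.data.loc[accession]
        return np.array([row[(d, condition)] for d in self.donors], dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (self.proteins == other.proteins
                and self.donors == other.donors
                and self.conditions == other.conditions
                and np.array_equal(self.data.to_numpy(), other.data.to_numpy(),
                                   equal_nan=True))

    def __repr__(self) -> str:
        return (f"AbundanceTable({len(self.proteins)} proteins, "
                f"donors={self.donors}, conditions={self.conditions})")


def _parse_cell(raw: str, row: int, col: str) -> float:
    s = raw.strip() if isinstance(raw, str) else raw
    if s is None or (isinstance(s, float) and math.isnan(s)) or s in _NA_STRINGS:
        return math.nan
    try:
        return float(s)
    except (TypeError, ValueError):
        raise ValueError(
            f"non-numeric abundance value {raw!r} at row {row}, column {col!r}"
        ) from None


def _from_wide(df: pd.DataFrame) -> AbundanceTable:
    sample_cols = [c for c in df.columns if c not in _META_COLS]
    pairs = []
    for c in sample_cols:
        if ":" not in c:
            raise ValueError(
                f"sample column {c!r} is not in '<donor>:<condition>' form")
        donor, _, cond = c.partition(":")
        pairs.append((donor, cond))
    donors = list(dict.fromkeys(d for d, _ in pairs))
    conditions = list(dict.fromkeys(c for _, c in pairs))
    if set(pairs) != {(d, c) for d in donors for c in conditions}:
        raise ValueError("ragged donor set: every donor must appear in every condition")

    proteins = [ProteinId(str(r["accession"]),
                          str(r.get("gene", "") or ""),
                          str(r.get("name", "") or ""))
                for _, r in df.iterrows()]
    seen: set[str] = set()
    for p in proteins:
        if p.accession in seen:
            raise ValueError(f"duplicate accession: {p.accession!r}")
        seen.add(p.accession)

    values = {}
    for (donor, cond), col in zip(pairs, sample_cols):
        values[(donor, cond)] = [
            _parse_cell(v, i, col) for i, v in enumerate(df[col])
        ]
    data = pd.DataFrame(values, index=[p.accession for p in proteins])
    data.columns = pd.MultiIndex.from_tuples(data.columns,
                                             names=["donor", "condition"])
    return AbundanceTable(proteins, donors, conditions, data)


def _from_long(df: pd.DataFrame) -> AbundanceTable:
    required = {"accession", "donor", "condition", "abundance"}
    if not required.issubset(df.columns):
        raise ValueError(f"long dialect requires columns {sorted(required)}")
    donors = list(dict.fromkeys(df["donor"].astype(str)))
    conditions = list(dict.fromkeys(df["condition"].astype(str)))
    order = list(dict.fromkeys(df["accession"].astype(str)))

    meta: dict[str, ProteinId] = {}
    grid: dict[str, dict[tuple[str, str], float]] = {a: {} for a in order}
    for i, r in df.iterrows():
        acc = str(r["accession"])
        pid = ProteinId(acc, str(r.get("gene", "") or ""), str(r.get("name", "") or ""))
        if acc in meta and meta[acc] != pid:
            raise ValueError(f"inconsistent gene/name metadata for {acc!r}")
        meta[acc] = pid
        key = (str(r["donor"]), str(r["condition"]))
        if key in grid[acc]:
            raise ValueError(
                f"duplicate accession: {acc!r} measured twice for {key}")
        grid[acc][key] = _parse_cell(r["abundance"], int(i), "abundance")

    full = [(d, c) for d in donors for c in conditions]
    for acc in order:
        missing = set(full) - set(grid[acc])
        if missing:
            raise ValueError(
                f"ragged donor set: {acc!r} lacks cells {sorted(missing)}")
    data = pd.DataFrame(
        {key: [grid[acc][key] for acc in order] for key in full}, index=order)
    data.columns = pd.MultiIndex.from_tuples(data.columns,
                                             names=["donor", "condition"])
    return AbundanceTable([meta[a] for a in order], donors, conditions, data)


def read_abundance_table(path: str | Path,
                         dialect: str = "wide_tsv") -> AbundanceTable:
    """Read an abundance table; dialect is one of wide_tsv, wide_csv, long_tsv.

    Raises :class:`ValueError` on duplicate accessions, ragged
    donor/condition grids, or non-numeric cells (with coordinates).
    """
    path = Path(path)
    if dialect not in {"wide_tsv", "wide_csv", "long_tsv"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "wide_csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if dialect == "long_tsv":
        return _from_long(df)
    return _from_wide(df)


def write_abundance_table(table: AbundanceTable, path: str | Path,
                          dialect: str = "wide_tsv") -> None:
    """Write a table in the wide dialect (round-trip partner of the reader)."""
    if dialect not in {"wide_tsv", "wide_csv"}:
        raise ValueError(f"unsupported write dialect {dialect!r}")
    sep = "," if dialect == "wide_csv" else "\t"
    out = pd.DataFrame({
        "accession": [p.accession for p in table.proteins],
        "gene": [p.gene for p in table.proteins],
        "name": [p.name for p in table.proteins],
    })
    for d in table.donors:
        for c in table.conditions:
            out[f"{d}:{c}"] = table.data[(d, c)].to_numpy()
    out.to_csv(path, sep=sep, index=False, na_rep="NA", float_format="%.17g")


def _fmt(value: float | None, ndec: int) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return f"{value:.{ndec}f}"


def write_results_table(records: Iterable[dict], path: str | Path) -> None:
    """Write per-protein comparison results as TSV in fixed column order.

    Each record is a mapping with (a subset of) the :data:`RESULT_COLUMNS`
    keys; absent or NaN numeric fields render as ``NA``. p-values are
    rendered with 5 decimals, variances with 2, distances and log fold
    changes with 5.
    """
    rows = []
    for rec in records:
        rows.append({
            "accession": rec["accession"],
            "gene": rec.get("gene", ""),
            "name": rec.get("name", ""),
            "distance": _fmt(rec.get("distance"), 5),
            "threshold_flag": str(int(bool(rec.get("threshold_flag", False)))),
            "p_value": _fmt(rec.get("p_value"), 5),
            "tier": rec.get("tier", "NA"),
            "logFC": _fmt(rec.get("logFC"), 5),
            "var_ref": _fmt(rec.get("var_ref"), 2),
            "var_trt": _fmt(rec.get("var_trt"), 2),
            "abs_var_diff": _fmt(rec.get("abs_var_diff"), 2),
        })
    df = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV with numeric columns parsed (NA -> NaN)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("distance", "p_value", "logFC", "var_ref", "var_trt", "abs_var_diff"):
        df[col] = pd.to_numeric(df[col].replace("NA", np.nan))
    df["threshold_flag"] = df["threshold_flag"].astype(int).astype(bool)
    return df
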