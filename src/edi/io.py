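"""Cell-level spatial tables, cohort tables and copy-number matrices.

The method starts from classified cell positions: one row per cell, with
coordinates in micrometres and a cell class drawn from a fixed three-class
vocabulary (cancer, lymphocyte, stromal).  Upstream image segmentation and
classification are outside this package; the CSV contract defined here is
the canonical interchange format.

Coordinates follow image conventions: origin at the top-left, y increasing
downward.  Only relative positions matter for tiling, so any consistent
frame works.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The fixed cell-class vocabulary (m = 3 types).
CELL_TYPES: tuple[str, ...] = ("cancer", "lymphocyte", "stromal")

#: Administrative censoring horizon for disease-specific survival, months.
FOLLOW_UP_CAP_MONTHS: float = 120.0

#: Canonical cell-table column names.
CELL_COLUMNS = ("x_um", "y_um", "cell_type")


class CellTableError(ValueError):
    """Base class for cell-table validation failures."""


class SchemaError(CellTableError):
    """A required column is missing or unmappable."""


class CoordinateError(CellTableError):
    """A coordinate is non-numeric, non-finite, or negative."""


class CellTypeError(CellTableError):
    """A cell-class label is outside the three-class vocabulary."""


class CohortValidationError(ValueError):
    """A clinical table failed validation."""


@dataclass
class CellMap:
    """Classified cells with spatial coordinates for one tumor.

    Parameters
    ----------
    cells : pandas.DataFrame
        Columns ``x_um``, ``y_um`` (micrometres, finite, non-negative) and
        ``cell_type`` (one of :data:`CELL_TYPES`); optional ``section_id``
        identifying the physical section each cell came from.
    tumor_id : str
        Identifier for the tumor the cells belong to.
    """

    cells: pd.DataFrame
    tumor_id: str = "tumor"

    def __post_init__(self) -> None:
        df = self.cells.copy()
        missing = [c for c in CELL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"cell table missing column(s): {missing}")
        for col in ("x_um", "y_um"):
            vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
            bad = np.flatnonzero(~np.isfinite(vals) | (vals < 0))
            if bad.size:
                raise CoordinateError(
                    f"column {col!r}: non-finite or negative coordinate "
                    f"at row {int(bad[0])}"
                )
            df[col] = vals
        unknown = set(df["cell_type"].unique()) - set(CELL_TYPES)
        if unknown:
            raise CellTypeError(
                f"unknown cell type label(s) {sorted(map(str, unknown))}; "
                f"expected one of {list(CELL_TYPES)}"
            )
        self.cells = df.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def has_sections(self) -> bool:
        return "section_id" in self.cells.columns

    def type_counts(self) -> pd.Series:
        """Total cell count per class, in vocabulary order."""
        counts = self.cells["cell_type"].value_counts()
        return counts.reindex(CELL_TYPES, fill_value=0).astype(int)

    def equals(self, other: "CellMap") -> bool:
        if self.tumor_id != other.tumor_id:
            return False
        a, b = self.cells, other.cells
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        return all(
            np.array_equal(a[c].to_numpy(), b[c].to_numpy()) for c in a.columns
        )


def read_cell_table(
    path, schema: dict[str, str] | None = None, tumor_id: str | None = None
) -> CellMap:
    """Read a cell table CSV into a validated :class:`CellMap`.

    Parameters
    ----------
    path : str or path-like
        CSV with columns mappable to ``x_um``, ``y_um``, ``cell_type`` and
        an optional ``section_id``.
    schema : dict, optional
        Mapping from file column names to the canonical names, for files
        using different headers (e.g. ``{"X": "x_um"}``).
    tumor_id : str, optional
        Defaults to the file stem.

    Notes
    -----
    Row order is preserved.  A header-only file yields a valid empty map.
    """
    # the correctly-rounded parser makes write/read an exact round trip
    df = pd.read_csv(path, float_precision="round_trip")
    if schema:
        df = df.rename(columns=schema)
    keep = [c for c in (*CELL_COLUMNS, "section_id") if c in df.columns]
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if tumor_id is None:
        import os

        tumor_id = os.path.splitext(os.path.basename(str(path)))[0]
    return CellMap(cells=df[keep], tumor_id=tumor_id)


def write_cell_table(cellmap: CellMap, path) -> None:
    """Write a :class:`CellMap` to CSV; re-reading it round-trips exactly."""
    # %.17g preserves float64 coordinates bit-exactly across the round trip
    cellmap.cells.to_csv(path, index=False, float_format="%.17g")


COHORT_CATEGORICALS = {
    "event": {0, 1},
    "grade": {1, 2, 3},
    "size_cat": {1, 2, 3},
    "node": {0, 1},
    "er": {0, 1},
    "tp53": {"WT", "MUT"},
}


def validate_cohort(table: pd.DataFrame, cap: float = FOLLOW_UP_CAP_MONTHS) -> pd.DataFrame:
    """Validate a clinical table and apply administrative censoring.

    Survival beyond the 10-year disease-specific endpoint is capped:
    times > ``cap`` months are set to ``cap`` with ``event = 0``.
    Idempotent: re-validating a validated table is a no-op.

    Raises
    ------
    CohortValidationError
        On non-positive survival times or out-of-vocabulary categorical
        levels.
    """
    df = table.copy()
    if "survival_months" not in df.columns or "event" not in df.columns:
        raise CohortValidationError(
            "cohort table requires 'survival_months' and 'event' columns"
        )
    t = pd.to_numeric(df["survival_months"], errors="coerce")
    if t.isna().any() or (t <= 0).any():
        bad = int(np.flatnonzero(t.isna() | (t <= 0))[0])
        raise CohortValidationError(
            f"non-positive or non-numeric survival time at row {bad}"
        )
    over = t > cap
    df.loc[over, "survival_months"] = cap
    df.loc[over, "event"] = 0
    for col, levels in COHORT_CATEGORICALS.items():
        if col in df.columns:
            observed = set(df[col].dropna().unique())
            if not observed <= levels:
                raise CohortValidationError(
                    f"column {col!r}: unexpected level(s) {observed - levels}"
                )
    return df


def read_cohort_table(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (one row per tumor)."""
    return validate_cohort(pd.read_csv(path))


#: Valid copy-number call levels: -2 deletion, -1 loss, 0 neutral, 1 gain,
#: 2 amplification.
CNA_CALLS = frozenset({-2, -1, 0, 1, 2})


def read_cna_matrix(path) -> pd.DataFrame:
    """Read a genes x samples copy-number call matrix.

    First column is the gene identifier (index); remaining columns are one
    per sample with integer calls in {-2, -1, 0, 1, 2}.
    """
    df = pd.read_csv(path, index_col=0)
    return validate_cna_matrix(df)


def validate_cna_matrix(df: pd.DataFrame) -> pd.DataFrame:
    vals = df.to_numpy()
    observed = set(np.unique(vals[~pd.isna(vals)]).astype(int).tolist())
    if not observed <= set(CNA_CALLS):
        raise ValueError(
            f"copy-number calls outside {{-2..2}}: {sorted(observed - set(CNA_CALLS))}"
        )
    return df.astype(int)
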