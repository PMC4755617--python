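"""Quadrat tiling and regional diversity scores.

A tumor section is divided into square regions (quadrats) of side ``r``
micrometres, and each region is scored with the Shannon diversity index of
its cell-type proportions,

    d_j = -sum_i p_i ln p_i,

with ``0 ln 0 := 0``.  With m = 3 cell classes, ``0 <= d_j <= ln 3``: zero
for a region dominated by a single class, ln 3 for exact equal thirds.  The
vector D = d_1..d_n over a tumor's regions is the input to the mixture
clustering that yields the ecosystem diversity index.

The natural logarithm is used throughout; the base only rescales scores
monotonically but a fixed convention is required for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CELL_TYPES, CellMap

COUNT_COLUMNS = tuple(f"n_{t}" for t in CELL_TYPES)


class EmptyInputError(ValueError):
    """An operation requiring cells received an empty map or profile."""


def _check_proportions(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1 (got {p.sum()!r})")
    return p


def shannon_index(proportions) -> float:
    """Shannon diversity (entropy, nats) of a proportion vector.

    ``0 * ln 0`` is taken as 0, so single-type regions score exactly 0.
    The maximum over m types is ln m, attained at equal proportions.
    """
    p = _check_proportions(proportions)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def simpson_index(proportions) -> float:
    """Simpson diversity ``1 - sum p_i^2``.

    Comparison metric only: more dominated by common types than Shannon,
    which also accounts for rare ones.
    """
    p = _check_proportions(proportions)
    return float(1.0 - (p**2).sum())


@dataclass
class RegionGrid:
    """Square tiling of one or more sections with per-tile class counts.

    ``counts`` has one row per non-empty tile: ``section_id``, ``row``,
    ``col`` and one count column per cell class.  Tiles are half-open
    ``[x0 + c*r, x0 + (c+1)*r)`` so every cell lands in exactly one tile.
    """

    region_size: float
    origins: dict = field(default_factory=dict)  # section_id -> (x0, y0)
    counts: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_regions(self) -> int:
        return len(self.counts)

    def total_counts(self) -> np.ndarray:
        return self.counts[list(COUNT_COLUMNS)].to_numpy().sum(axis=0)


def tile_regions(
    cellmap: CellMap, region_size: float, origin: tuple[float, float] | None = None
) -> RegionGrid:
    """Assign every cell to a square region and count classes per region.

    Cell (x, y) goes to tile ``(floor((y - y0)/r), floor((x - x0)/r))``.
    The default origin is the bounding-box minimum of each section's cells,
    making the tiling invariant to translation of the whole section; pass
    ``origin`` to pin the grid instead.  Sections (``section_id`` column)
    are tiled independently.
    """
    if region_size <= 0:
        raise ValueError(f"region_size must be positive (got {region_size})")
    if cellmap.n_cells == 0:
        raise EmptyInputError("cannot tile an empty cell map")

    df = cellmap.cells
    sections = (
        df.groupby("section_id", sort=True) if cellmap.has_sections else [(0, df)]
    )
    origins: dict = {}
    parts = []
    for sid, sdf in sections:
        x = sdf["x_um"].to_numpy()
        y = sdf["y_um"].to_numpy()
        x0, y0 = origin if origin is not None else (x.min(), y.min())
        origins[sid] = (float(x0), float(y0))
        col = np.floor((x - x0) / region_size).astype(int)
        row = np.floor((y - y0) / region_size).astype(int)
        tab = pd.crosstab([row, col], sdf["cell_type"].to_numpy())
        tab = tab.reindex(columns=list(CELL_TYPES), fill_value=0)
        tab.columns = list(COUNT_COLUMNS)
        tab.index.names = ["row", "col"]
        tab = tab.reset_index()
        tab.insert(0, "section_id", sid)
        parts.append(tab)
    counts = pd.concat(parts, ignore_index=True)
    return RegionGrid(region_size=float(region_size), origins=origins, counts=counts)


@dataclass
class DiversityProfile:
    """Regional Shannon scores D = d_1..d_n for one tumor.

    ``d`` holds one score per retained region (nats, in [0, ln 3]);
    ``regions`` carries the per-region counts and identifiers so cluster
    labels can be mapped back to space; ``excluded_regions`` counts tiles
    dropped by the minimum-cell filter.
    """

    d: np.ndarray
    regions: pd.DataFrame
    excluded_regions: int = 0
    m: int = len(CELL_TYPES)

    @property
    def n(self) -> int:
        return len(self.d)

    def proportions(self) -> np.ndarray:
        c = self.regions[list(COUNT_COLUMNS)].to_numpy(dtype=float)
        return c / c.sum(axis=1, keepdims=True)


def regional_diversity(grid: RegionGrid, min_cells: int = 10) -> DiversityProfile:
    """Score each retained region with the Shannon index.

    Regions with fewer than ``min_cells`` cells in total are excluded (and
    counted): proportions from a handful of cells make d_j unstable.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    counts = grid.counts
    c = counts[list(COUNT_COLUMNS)].to_numpy(dtype=float)
    totals = c.sum(axis=1)
    keep = totals >= min_cells
    if not keep.any():
        raise EmptyInputError(
            f"all {len(counts)} regions fall below min_cells={min_cells}"
        )
    ck = c[keep]
    p = ck / ck.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    d = -terms.sum(axis=1)
    regions = counts.loc[keep].reset_index(drop=True).copy()
    regions["d"] = d
    return DiversityProfile(
        d=d, regions=regions, excluded_regions=int((~keep).sum())
    )


def whole_tumor_shannon(cellmap: CellMap) -> float:
    """Shannon index of the pooled cell-type proportions of a whole tumor.

    Measures composition only; unlike the regional profile it carries no
    spatial information.
    """
    if cellmap.n_cells == 0:
        raise EmptyInputError("empty cell map")
    counts = cellmap.type_counts().to_numpy(dtype=float)
    return shannon_index(counts / counts.sum())
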