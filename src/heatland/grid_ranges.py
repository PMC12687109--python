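"""Equal-area analysis grid and rasterized species ranges.

The analysis runs on a square equal-area lattice (the study design uses a
24.125 km cell edge, i.e. 582.02 km² per cell, in a Behrmann projection).
Synthetic grids here are abstract lattices: the pipeline consumes per-cell
polygon-overlap fractions directly, so no CRS machinery is involved.

Rasterization follows two rules:

* species whose polygonal range is smaller than one grid cell keep *every*
  cell their polygon touches;
* larger-ranged species drop cells whose overlap with the polygon is below a
  minimum fraction (default 10%, with overlap exactly equal to the threshold
  kept — the exclusion is strict "< 10%").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

#: Taxonomic groups covered by the analysis.
TAXA = ("amphibian", "bird", "mammal", "reptile")

#: IUCN Red List categories used as species labels.
REDLIST_CATEGORIES = ("LC", "NT", "VU", "EN", "CR", "DD")

#: Cell edge of the study design's equal-area grid, km.
DEFAULT_CELL_EDGE_KM = 24.125

#: The five shared habitat / land-use classes (see :mod:`heatland.landuse`).
FIVE_CLASSES = ("forest", "non_forest", "agriculture", "managed", "urban")


class EmptyRangeError(ValueError):
    """Raised when a species has no overlap with the grid at all."""


@dataclass(frozen=True)
class Grid:
    """A rectangular equal-area cell lattice.

    Cells are identified by integer ids in row-major order
    (``cell_id = row * n_cols + col``).
    """

    n_rows: int
    n_cols: int
    cell_edge_km: float = DEFAULT_CELL_EDGE_KM

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if not self.cell_edge_km > 0:
            raise ValueError("cell_edge_km must be positive")

    @property
    def cell_area_km2(self) -> float:
        return self.cell_edge_km ** 2

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells, dtype=np.int64)

    def row_col(self, cell_id: int) -> tuple[int, int]:
        return divmod(int(cell_id), self.n_cols)

    def cell_id(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"({row}, {col}) outside grid")
        return row * self.n_cols + col

    def neighbors(self, cell_id: int) -> list[int]:
        """4-connected neighbours (used for blob-shaped synthetic ranges)."""
        r, c = self.row_col(cell_id)
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < self.n_rows and 0 <= cc < self.n_cols:
                out.append(rr * self.n_cols + cc)
        return out


def build_grid(n_rows: int, n_cols: int,
               cell_edge_km: float = DEFAULT_CELL_EDGE_KM) -> Grid:
    """Construct an equal-area lattice of ``n_rows`` × ``n_cols`` cells."""
    return Grid(n_rows=n_rows, n_cols=n_cols, cell_edge_km=cell_edge_km)


@dataclass
class RangeOverlap:
    """Fractional overlap of one species' range polygon with grid cells."""

    species_id: str
    cell_overlaps: dict[int, float]
    polygon_area_km2: float

    def __post_init__(self) -> None:
        if self.polygon_area_km2 < 0:
            raise ValueError("polygon_area_km2 must be >= 0")
        for cell, frac in self.cell_overlaps.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"overlap fraction {frac} for cell {cell} outside [0, 1]")


@dataclass(frozen=True)
class SpeciesRecord:
    """A species with its rasterized range and habitat preferences."""

    species_id: str
    taxon: str
    redlist: str
    range_cells: frozenset[int]
    habitat_classes: frozenset[str]

    def __post_init__(self) -> None:
        if self.taxon not in TAXA:
            raise ValueError(f"unknown taxon {self.taxon!r}")
        if self.redlist not in REDLIST_CATEGORIES:
            raise ValueError(f"unknown Red List category {self.redlist!r}")
        if not self.range_cells:
            raise ValueError("range_cells must be non-empty")
        if not self.habitat_classes:
            raise ValueError("habitat_classes must be non-empty")
        unknown = set(self.habitat_classes) - set(FIVE_CLASSES)
        if unknown:
            raise ValueError(f"unknown habitat classes {sorted(unknown)}")


def rasterize_range(overlap: RangeOverlap, grid: Grid,
                    min_overlap: float = 0.1) -> set[int]:
    """Turn a fractional overlap map into the set of range cells.

    Small-range species (polygon smaller than one grid cell) keep every
    touched cell regardless of ``min_overlap``. Larger species keep cells
    with overlap >= ``min_overlap``. A large-range species whose every
    overlap falls below the threshold keeps its single best cell (with a
    warning) so that no analysed species ends up rangeless.
    """
    if not 0.0 <= min_overlap <= 1.0:
        raise ValueError("min_overlap must be in [0, 1]")
    touched = {c: f for c, f in overlap.cell_overlaps.items() if f > 0}
    if not touched:
        raise EmptyRangeError(
            f"species {overlap.species_id!r} has no positive overlap")

    if overlap.polygon_area_km2 < grid.cell_area_km2:
        return set(touched)

    kept = {c for c, f in touched.items() if f >= min_overlap}
    if not kept:
        best = max(touched, key=lambda c: (touched[c], -c))
        logger.warning(
            "species %s: all overlaps below %.0f%% threshold; "
            "keeping max-overlap cell %d",
            overlap.species_id, 100 * min_overlap, best)
        kept = {best}
    return kept
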