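"""Suitable-area trajectories, exposure indices and driver attribution.

A species' Suitable Area (SA) in a year is the cell-area-weighted sum, over
its range cells, of the fraction of each cell covered by its preferred
habitat classes, masked by the binary climate-suitability flag of that
cell-year. The 2015 baseline SA_2015 assumes a suitable climate everywhere.
Three driver modes are distinguished:

* ``combined``      — climate flag × current-year habitat fraction;
* ``climate_only``  — climate flag × habitat fraction frozen at 2015;
* ``landuse_only``  — current-year habitat fraction, climate ignored.

An absorbing extinction rule applies: once SA reaches zero it stays zero,
even if conditions later become suitable. Before that, any range cell is
instantly recolonised as soon as its land use turns suitable again.

Percent change from SA_2015 is signed: gains use 1 − SA_2015/SA_y (bounded
below 100), losses use SA_y/SA_2015 − 1 (bounded at −100). Shifting by +100
gives the 0–200 change index (0 = total loss, 100 = no change). The
exposure fraction is the loss side as a 0–1 share of SA_2015.

Species whose combined exposure reaches a threshold are attributed to a
driver by re-running the two single-driver counterfactuals: ``heat`` if
only climate_only reaches the threshold, ``landuse`` if only landuse_only
does, ``both`` if each does alone, ``combined_only`` if neither does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid_ranges import Grid, SpeciesRecord
from .landuse import FiveClassLayer, habitat_fraction

logger = logging.getLogger(__name__)

SCENARIOS = ("SSP1-RCP2.6", "SSP2-RCP4.5", "SSP3-RCP7.0", "SSP5-RCP8.5")
DRIVER_MODES = ("combined", "climate_only", "landuse_only")


@dataclass(frozen=True)
class ScenarioConfig:
    """Years and driver mode for one SSP-RCP scenario run."""

    name: str
    first_year: int = 2015
    last_year: int = 2100
    base_year: int = 2015
    climate_start: int = 2020
    driver_mode: str = "combined"

    def __post_init__(self) -> None:
        if not (self.base_year <= self.climate_start <= self.last_year):
            raise ValueError("need base_year <= climate_start <= last_year")
        if self.driver_mode not in DRIVER_MODES:
            raise ValueError(f"unknown driver mode {self.driver_mode!r}")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)


@dataclass
class SATrajectory:
    """Annual suitable area (km²) for one species / scenario / driver mode."""

    species_id: str
    scenario: str
    driver_mode: str
    years: np.ndarray
    sa: np.ndarray
    sa_2015: float
    extinct_year: int | None = None


@dataclass(frozen=True)
class ExposureRecord:
    species_id: str
    scenario: str
    year: int
    pct_change: float
    index_0_200: float
    exposure_fraction: float


@dataclass(frozen=True)
class AttributionRecord:
    species_id: str
    scenario: str
    threshold: float
    cls: str  # heat | landuse | both | combined_only


class NoInitialHabitatError(ValueError):
    """SA_2015 is zero: species excluded from percent-change statistics."""


# ---------------------------------------------------------------------------
# suitable area

def sa_2015(species: SpeciesRecord, layer_2015: FiveClassLayer,
            grid: Grid) -> float:
    """Baseline suitable area, km²: suitable land use, climate assumed OK."""
    total = sum(habitat_fraction(species, layer_2015, c)
                for c in species.range_cells)
    return total * grid.cell_area_km2


def suitable_area_year(
    species: SpeciesRecord,
    layers: Mapping[int, FiveClassLayer],
    climate_ok: Mapping[int, Mapping[int, bool]] | None,
    year: int,
    grid: Grid,
    driver_mode: str = "combined",
    base_year: int = 2015,
    climate_start: int = 2020,
) -> float:
    """Suitable area for one species-year under a driver mode.

    ``climate_ok[year][cell]`` is the ensemble climate-suitability flag;
    years before ``climate_start`` (and ``landuse_only`` mode) treat every
    cell as climatically suitable.
    """
    if driver_mode not in DRIVER_MODES:
        raise ValueError(f"unknown driver mode {driver_mode!r}")
    hab_year = base_year if driver_mode == "climate_only" else year
    if hab_year not in layers:
        raise KeyError(f"no land-use layer for year {hab_year}")
    layer = layers[hab_year]
    use_climate = driver_mode != "landuse_only" and year >= climate_start
    total = 0.0
    for cell in species.range_cells:
        if use_climate:
            if climate_ok is None or year not in climate_ok:
                raise KeyError(f"no climate flags for year {year}")
            if not climate_ok[year].get(cell, True):
                continue
        total += habitat_fraction(species, layer, cell)
    return total * grid.cell_area_km2


def suitable_area_series(
    habitat_frac: np.ndarray,
    climate_ok: np.ndarray,
    cell_area_km2: float,
    driver_mode: str = "combined",
    base_index: int = 0,
) -> np.ndarray:
    """Vectorised SA over years for one species.

    habitat_frac
        (n_years, n_range_cells) preferred-habitat fraction per cell-year.
    climate_ok
        (n_years, n_range_cells) boolean ensemble suitability (True =
        suitable); pre-climate-start years must already be all-True.
    """
    hf = np.asarray(habitat_frac, dtype=float)
    ok = np.asarray(climate_ok, dtype=bool)
    if hf.shape != ok.shape:
        raise ValueError("habitat_frac and climate_ok shapes differ")
    if driver_mode == "climate_only":
        hf = np.broadcast_to(hf[base_index], hf.shape)
    elif driver_mode == "landuse_only":
        ok = np.ones_like(ok)
    elif driver_mode != "combined":
        raise ValueError(f"unknown driver mode {driver_mode!r}")
    return (hf * ok).sum(axis=1) * cell_area_km2


# ---------------------------------------------------------------------------
# extinction rule and percent change

def apply_extinction_rule(
    sa: np.ndarray, years: np.ndarray | None = None,
) -> tuple[np.ndarray, int | None]:
    """Force SA to zero from its first zero year onwards (absorbing).

    Returns the modified copy and the extinction year (or index when
    ``years`` is omitted; None if SA never reaches zero). Idempotent.
    """
    sa = np.asarray(sa, dtype=float).copy()
    zeros = np.flatnonzero(sa == 0)
    if zeros.size == 0:
        return sa, None
    first = int(zeros[0])
    sa[first:] = 0.0
    extinct = first if years is None else int(np.asarray(years)[first])
    return sa, extinct


def percent_change(sa_y: float, sa_base: float) -> tuple[float, float]:
    """Signed percent change from SA_2015 and the shifted 0–200 index.

    Gains: (1 − SA_2015/SA_y)·100 ∈ (0, 100); losses:
    (SA_y/SA_2015 − 1)·100 ∈ [−100, 0); equality → 0. Index = pct + 100.
    """
    if sa_base <= 0:
        raise NoInitialHabitatError("SA_2015 must be positive")
    if sa_y < 0:
        raise ValueError("suitable area must be >= 0")
    if sa_y > sa_base:
        pct = (1.0 - sa_base / sa_y) * 100.0
    elif sa_y < sa_base:
        pct = (sa_y / sa_base - 1.0) * 100.0
    else:
        pct = 0.0
    return pct, pct + 100.0


def exposure_fraction(pct_change_value: float) -> float:
    """Share of SA_2015 rendered unsuitable: the loss side of the index."""
    return max(0.0, -pct_change_value) / 100.0


def build_trajectory(
    species_id: str,
    scenario: str,
    driver_mode: str,
    years: np.ndarray,
    habitat_frac: np.ndarray,
    climate_ok: np.ndarray,
    cell_area_km2: float,
    base_index: int = 0,
) -> SATrajectory:
    """SA series for one species with the absorbing extinction rule applied."""
    sa = suitable_area_series(habitat_frac, climate_ok, cell_area_km2,
                              driver_mode, base_index)
    # same reduction path as the trajectory so that a no-change world gives
    # bitwise-identical SA_2015 and SA_y (pct_change exactly 0)
    sa_base = float(suitable_area_series(
        habitat_frac, np.ones_like(climate_ok, dtype=bool), cell_area_km2,
        "landuse_only", base_index)[base_index])
    sa, extinct = apply_extinction_rule(sa, years)
    return SATrajectory(species_id=species_id, scenario=scenario,
                        driver_mode=driver_mode, years=np.asarray(years),
                        sa=sa, sa_2015=sa_base, extinct_year=extinct)


def exposure_at(traj: SATrajectory, year: int) -> ExposureRecord:
    """Exposure record for one trajectory at an evaluation year."""
    idx = int(np.flatnonzero(traj.years == year)[0])
    pct, index = percent_change(float(traj.sa[idx]), traj.sa_2015)
    return ExposureRecord(species_id=traj.species_id, scenario=traj.scenario,
                          year=year, pct_change=pct, index_0_200=index,
                          exposure_fraction=exposure_fraction(pct))


# ---------------------------------------------------------------------------
# attribution and threshold counts

def attribute_driver(
    species_id: str,
    scenario: str,
    combined_fraction: float,
    climate_only_fraction: float,
    landuse_only_fraction: float,
    threshold: float = 0.5,
) -> AttributionRecord:
    """Classify which driver pushes a species over an exposure threshold.

    Only defined for species whose combined exposure reaches the threshold.
    """
    if combined_fraction < threshold:
        raise ValueError(
            "attribution undefined: combined exposure below threshold")
    heat = climate_only_fraction >= threshold
    land = landuse_only_fraction >= threshold
    if heat and land:
        cls = "both"
    elif heat:
        cls = "heat"
    elif land:
        cls = "landuse"
    else:
        cls = "combined_only"
    return AttributionRecord(species_id=species_id, scenario=scenario,
                             threshold=threshold, cls=cls)


def threshold_counts(
    exposures: pd.DataFrame,
    thresholds: Sequence[float] = (0.5, 1.0),
    group_by: str | None = None,
) -> pd.DataFrame:
    """Counts and within-group percentages of species over each threshold.

    ``exposures`` needs one row per species with an ``exposure_fraction``
    column (plus the grouping column when ``group_by`` is given). Empty
    groups report pct 0 with ``undefined_pct=True``.
    """
    rows = []
    groups = ([(None, exposures)] if group_by is None
              else list(exposures.groupby(group_by, observed=True)))
    for key, sub in groups:
        n = len(sub)
        for thr in thresholds:
            count = int((sub["exposure_fraction"] >= thr).sum())
            rows.append({
                "group": "all" if key is None else key,
                "threshold": thr,
                "n_total": n,
                "n_exposed": count,
                "pct_exposed": (100.0 * count / n) if n else 0.0,
                "undefined_pct": n == 0,
            })
    return pd.DataFrame(rows)
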