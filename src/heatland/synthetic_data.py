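"""Synthetic worlds with known ground truth for the exposure pipeline.

The generator emulates the three global data sources the analysis design
consumes, at desk scale and with explicit seeding:

* **Land use** — LUH2-style fractional compositions per cell in the 12
  state categories, summing to ≤ 1 (water/ice remainder), with
  scenario-dependent annual conversion trends: strongest natural-habitat
  loss under the SSP3-like scenario, partial recovery (cropland →
  secondary vegetation) under the SSP1-like one.
* **Daily climate** — NEX-GDDP-style per-cell daily maximum temperature,
  1950–2100 on a 365-day no-leap calendar: a latitudinal base-temperature
  gradient + a sinusoidal seasonal cycle + a slow shared historical trend +
  a scenario warming trend from 2015 + AR(1) noise per pseudo-GCM. The
  noise and historical part are scenario-independent, so the 1950–2005
  baseline is identical across scenarios, as it must be.
* **Species** — blob-shaped contiguous ranges with log-normal sizes
  (smaller on average for amphibians and reptiles), fractional cell
  overlaps, habitat-class preferences and Red List labels whose threat
  level is tilted towards smaller-ranged species.

Series are generated lazily per (scenario, gcm, cell) to bound memory; a
fixed seed makes every output byte-identical across runs. Designed worlds
(:func:`make_half_loss_world`, :func:`make_null_world`) carry analytically
known expectations in the ground-truth sidecar.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .grid_ranges import (Grid, RangeOverlap, SpeciesRecord, TAXA,
                          build_grid, rasterize_range)
from .landuse import (LUH2_STATES, LandUseLayer, FiveClassLayer,
                      reclassify_luh2)
from .exposure import SCENARIOS

DAYS_PER_YEAR = 365

#: Species counts of the global study the generator emulates (amphibians,
#: birds, mammals, reptiles; they sum to the 29,657 analysed tetrapods).
#: Used as the default taxonomic mix of synthetic worlds.
STUDY_SPECIES_COUNTS: dict[str, int] = {
    "amphibian": 6407,
    "bird": 9472,
    "mammal": 5161,
    "reptile": 8617,
}

_DEFAULT_WARMING = {          # °C per decade from 2015, by scenario
    "SSP1-RCP2.6": 0.15,
    "SSP2-RCP4.5": 0.30,
    "SSP3-RCP7.0": 0.45,
    "SSP5-RCP8.5": 0.60,
}
_DEFAULT_LU_TREND = {         # annual conversion rate; <0 = recovery
    "SSP1-RCP2.6": -0.002,
    "SSP2-RCP4.5": 0.0015,
    "SSP3-RCP7.0": 0.004,
    "SSP5-RCP8.5": 0.002,
}
#: Dirichlet weights of the initial 12-state composition (matches
#: LUH2_STATES order): mostly primary/secondary vegetation, some cropland
#: and pasture, little urban.
_COMPOSITION_ALPHA = np.array(
    [4.0, 2.0, 1.5, 1.0, 0.15, 0.8, 0.4, 0.2, 0.2, 0.2, 1.0, 1.0])

_NATURAL = [LUH2_STATES.index(s) for s in ("primf", "primn", "secdf", "secdn")]
_CROPS = [LUH2_STATES.index(s)
          for s in ("c3ann", "c4ann", "c3per", "c4per", "c3nfx")]
_SECONDARY = [LUH2_STATES.index(s) for s in ("secdf", "secdn")]
_C3ANN = LUH2_STATES.index("c3ann")


class InvalidWorldConfigError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclass(frozen=True)
class WorldConfig:
    """Full specification of a synthetic world (seed mandatory)."""

    seed: int
    n_rows: int = 30
    n_cols: int = 30
    cell_edge_km: float = 24.125
    n_species: int = 200
    scenarios: tuple[str, ...] = SCENARIOS
    start_year: int = 1950
    baseline_end: int = 2005
    base_year: int = 2015
    climate_start: int = 2020
    end_year: int = 2100
    n_gcms: int = 3                      # 5 for full runs
    gcm_noise_sd: float = 2.0            # stationary AR(1) sd, °C
    noise_ar: float = 0.6                # day-to-day autocorrelation
    seasonal_amplitude: float = 8.0      # °C
    lat_range_c: tuple[float, float] = (32.0, 12.0)  # row 0 -> last row base
    historic_warming: float = 0.1        # °C/decade, shared by scenarios
    warming_rate: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_WARMING))
    landuse_trend: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LU_TREND))
    range_size_median: Mapping[str, float] = field(
        default_factory=lambda: {"amphibian": 5.0, "reptile": 6.0,
                                 "bird": 14.0, "mammal": 12.0})
    range_size_sigma: float = 0.7        # log-scale sd of range size
    hot_rows: int | None = None          # warming confined to top rows
    uniform_landuse: Mapping[str, float] | None = None
    record_thermal_truth: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InvalidWorldConfigError("seed is mandatory")
        if not (self.start_year <= self.baseline_end < self.base_year
                <= self.climate_start <= self.end_year):
            raise InvalidWorldConfigError("inconsistent year spans")
        for sc in self.scenarios:
            if sc not in self.warming_rate or sc not in self.landuse_trend:
                raise InvalidWorldConfigError(
                    f"scenario {sc!r} lacks warming/land-use rates")
        max_median = max(self.range_size_median.values())
        if max_median > self.n_rows * self.n_cols:
            raise InvalidWorldConfigError("median range exceeds grid size")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def n_days(self) -> int:
        return self.n_years * DAYS_PER_YEAR

    @property
    def baseline_days(self) -> int:
        return (self.baseline_end - self.start_year + 1) * DAYS_PER_YEAR

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for key in ("warming_rate", "landuse_trend", "range_size_median",
                    "uniform_landuse"):
            if d[key] is not None:
                d[key] = dict(d[key])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "WorldConfig":
        d = json.loads(text)
        for key in ("scenarios", "lat_range_c"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


class ClimateGenerator:
    """Lazy deterministic daily-Tmax factory per (scenario, gcm, cell)."""

    def __init__(self, config: WorldConfig, grid: Grid):
        self.config = config
        self.grid = grid
        rows = np.arange(grid.n_rows)
        t0, t1 = config.lat_range_c
        frac = rows / max(1, grid.n_rows - 1)
        self._base_by_row = t0 + (t1 - t0) * frac
        if config.hot_rows is None:
            self._hot_scale = np.ones(grid.n_cells)
        else:
            scale = np.zeros(grid.n_cells)
            for cell in range(grid.n_cells):
                r, _ = grid.row_col(cell)
                scale[cell] = 1.0 if r < config.hot_rows else 0.0
            self._hot_scale = scale
        t = np.arange(config.n_days)
        doy = t % DAYS_PER_YEAR
        self._season = config.seasonal_amplitude * np.sin(
            2 * np.pi * doy / DAYS_PER_YEAR - np.pi / 2)
        self._year_frac = t / DAYS_PER_YEAR          # years since start
        self._future_years = np.maximum(
            0.0, self._year_frac - (config.base_year - config.start_year))

    def _noise(self, gcm: int, cell: int) -> np.ndarray:
        cfg = self.config
        if cfg.gcm_noise_sd == 0:
            return np.zeros(cfg.n_days)
        ss = np.random.SeedSequence([cfg.seed, 101, gcm, cell])
        rng = np.random.default_rng(ss)
        innov_sd = cfg.gcm_noise_sd * math.sqrt(1 - cfg.noise_ar ** 2)
        e = rng.standard_normal(cfg.n_days) * innov_sd
        return lfilter([1.0], [1.0, -cfg.noise_ar], e)

    def daily_series(self, scenario: str, gcm: int, cell: int) -> np.ndarray:
        """Daily Tmax (°C) for the full 1950–2100 span of one cell.

        The pre-2015 part is scenario-independent by construction.
        """
        cfg = self.config
        row, _ = self.grid.row_col(cell)
        base = self._base_by_row[row]
        warming = (cfg.historic_warming / 10.0 * self._year_frac
                   + cfg.warming_rate[scenario] / 10.0 * self._future_years
                   * self._hot_scale[cell])
        return base + self._season + warming + self._noise(gcm, cell)

    def baseline_series(self, gcm: int, cell: int) -> np.ndarray:
        """The scenario-independent 1950–baseline_end slice."""
        return self.daily_series(self.config.scenarios[0], gcm,
                                 cell)[: self.config.baseline_days]


@dataclass
class World:
    """A complete synthetic study system consumed by the pipeline."""

    config: WorldConfig
    grid: Grid
    species: list[SpeciesRecord]
    overlaps: dict[str, RangeOverlap]
    species_table: pd.DataFrame
    landuse_raw: dict[str, dict[int, LandUseLayer]]
    landuse: dict[str, dict[int, FiveClassLayer]]
    climate: ClimateGenerator
    ground_truth: dict


# ---------------------------------------------------------------------------
# land use

def _initial_composition(config: WorldConfig, grid: Grid,
                         rng: np.random.Generator) -> np.ndarray:
    if config.uniform_landuse is not None:
        frac = np.zeros(len(LUH2_STATES))
        for state, val in config.uniform_landuse.items():
            frac[LUH2_STATES.index(state)] = val
        if frac.sum() > 1 + 1e-9:
            raise InvalidWorldConfigError("uniform_landuse sums above 1")
        return np.tile(frac, (grid.n_cells, 1))
    land_total = rng.uniform(0.85, 1.0, size=grid.n_cells)
    comp = rng.dirichlet(_COMPOSITION_ALPHA, size=grid.n_cells)
    return comp * land_total[:, None]


def _generate_landuse(config: WorldConfig, grid: Grid,
                      rng: np.random.Generator
                      ) -> dict[str, dict[int, LandUseLayer]]:
    initial = _initial_composition(config, grid, rng)
    years = range(config.base_year, config.end_year + 1)
    out: dict[str, dict[int, LandUseLayer]] = {}
    for scenario in config.scenarios:
        rate = config.landuse_trend[scenario]
        frac = initial.copy()
        layers = {}
        for year in years:
            layers[year] = LandUseLayer(year=year, fractions=frac.copy())
            if rate > 0:        # natural -> annual cropland
                moved = frac[:, _NATURAL] * rate
                frac[:, _NATURAL] -= moved
                frac[:, _C3ANN] += moved.sum(axis=1)
            elif rate < 0:      # cropland abandonment -> secondary vegetation
                moved = frac[:, _CROPS] * (-rate)
                frac[:, _CROPS] -= moved
                recovered = moved.sum(axis=1) / len(_SECONDARY)
                for idx in _SECONDARY:
                    frac[:, idx] += recovered
        out[scenario] = layers
    return out


# ---------------------------------------------------------------------------
# species

_HABITAT_WEIGHTS = {"forest": 0.45, "non_forest": 0.35, "agriculture": 0.10,
                    "managed": 0.07, "urban": 0.03}
_THREAT_CATEGORIES = ("NT", "VU", "EN", "CR")
_THREAT_WEIGHTS = (0.30, 0.30, 0.25, 0.15)


def _grow_blob(grid: Grid, size: int, rng: np.random.Generator) -> list[int]:
    start = int(rng.integers(grid.n_cells))
    blob = {start}
    frontier = set(grid.neighbors(start))
    while len(blob) < size and frontier:
        nxt = sorted(frontier)
        cell = int(nxt[rng.integers(len(nxt))])
        frontier.discard(cell)
        blob.add(cell)
        frontier.update(c for c in grid.neighbors(cell) if c not in blob)
    return sorted(blob)


def _draw_habitats(rng: np.random.Generator) -> frozenset[str]:
    classes = list(_HABITAT_WEIGHTS)
    w = np.array(list(_HABITAT_WEIGHTS.values()))
    n_classes = 1 + rng.binomial(2, 0.4)
    picked = rng.choice(classes, size=n_classes, replace=False, p=w / w.sum())
    return frozenset(picked.tolist())


def _draw_redlist(size: int, median_size: float,
                  rng: np.random.Generator) -> str:
    if rng.uniform() < 0.07:
        return "DD"
    # smaller-ranged species are more likely to be threatened
    p_threat = 1 / (1 + math.exp(-0.8 * (math.log(median_size)
                                         - math.log(size))))
    if rng.uniform() < 0.20 + 0.55 * p_threat:
        return str(rng.choice(_THREAT_CATEGORIES, p=_THREAT_WEIGHTS))
    return "LC"


def _taxon_sequence(n_species: int) -> list[str]:
    total = sum(STUDY_SPECIES_COUNTS.values())
    counts = {t: max(1, round(n_species * c / total))
              for t, c in STUDY_SPECIES_COUNTS.items()}
    while sum(counts.values()) > n_species:
        counts[max(counts, key=counts.get)] -= 1
    while sum(counts.values()) < n_species:
        counts[min(counts, key=counts.get)] += 1
    seq = []
    for t in TAXA:
        seq.extend([t] * counts[t])
    return seq[:n_species]


def _generate_species(config: WorldConfig, grid: Grid,
                      rng: np.random.Generator
                      ) -> tuple[list[SpeciesRecord], dict[str, RangeOverlap]]:
    species: list[SpeciesRecord] = []
    overlaps: dict[str, RangeOverlap] = {}
    taxa = _taxon_sequence(config.n_species)
    median_all = float(np.mean(list(config.range_size_median.values())))
    max_size = max(2, grid.n_cells // 3)
    for i, taxon in enumerate(taxa):
        sid = f"sp{i:04d}_{taxon[:3]}"
        median = config.range_size_median[taxon]
        size = int(round(float(rng.lognormal(math.log(median),
                                             config.range_size_sigma))))
        size = int(np.clip(size, 1, max_size))
        if size == 1:
            # below one grid cell: all touched pixels kept
            seed_cell = int(rng.integers(grid.n_cells))
            cell_ov = {seed_cell: float(rng.uniform(0.2, 0.8))}
            for nb in grid.neighbors(seed_cell):
                if rng.uniform() < 0.5:
                    cell_ov[nb] = float(rng.uniform(0.02, 0.15))
            polygon_area = grid.cell_area_km2 * float(rng.uniform(0.15, 0.85))
        else:
            blob = _grow_blob(grid, size, rng)
            cell_ov = {c: float(rng.uniform(0.3, 1.0)) for c in blob}
            fringe = {nb for c in blob for nb in grid.neighbors(c)} - set(blob)
            for nb in sorted(fringe):
                if rng.uniform() < 0.4:
                    cell_ov[nb] = float(rng.uniform(0.01, 0.08))
            polygon_area = (len(blob) * grid.cell_area_km2
                            * float(rng.uniform(0.8, 1.1)))
        ov = RangeOverlap(species_id=sid, cell_overlaps=cell_ov,
                          polygon_area_km2=polygon_area)
        cells = rasterize_range(ov, grid, min_overlap=0.1)
        rec = SpeciesRecord(species_id=sid, taxon=taxon,
                            redlist=_draw_redlist(size, median_all, rng),
                            range_cells=frozenset(cells),
                            habitat_classes=_draw_habitats(rng))
        species.append(rec)
        overlaps[sid] = ov
    return species, overlaps


def _species_table(species: list[SpeciesRecord],
                   overlaps: dict[str, RangeOverlap]) -> pd.DataFrame:
    rows = [{
        "species_id": sp.species_id,
        "taxon": sp.taxon,
        "redlist": sp.redlist,
        "habitat_classes": "|".join(sorted(sp.habitat_classes)),
        "polygon_area_km2": overlaps[sp.species_id].polygon_area_km2,
        "n_range_cells": len(sp.range_cells),
    } for sp in species]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# worlds

def generate_world(config: WorldConfig) -> World:
    """Build a complete deterministic synthetic world from a config."""
    grid = build_grid(config.n_rows, config.n_cols, config.cell_edge_km)
    lu_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    sp_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 22]))
    landuse_raw = _generate_landuse(config, grid, lu_rng)
    landuse = {sc: {yr: reclassify_luh2(layer)
                    for yr, layer in layers.items()}
               for sc, layers in landuse_raw.items()}
    species, overlaps = _generate_species(config, grid, sp_rng)
    climate = ClimateGenerator(config, grid)

    ground_truth: dict = {
        "species": {sp.species_id: {
            "taxon": sp.taxon, "redlist": sp.redlist,
            "n_range_cells": len(sp.range_cells),
            "habitat_classes": sorted(sp.habitat_classes),
        } for sp in species},
        "designed": {},
    }
    if config.record_thermal_truth and species:
        cache: dict[tuple[int, int], float] = {}
        limits: dict[str, dict[str, float]] = {}
        for sp in species:
            limits[sp.species_id] = {}
            for gcm in range(config.n_gcms):
                p99 = []
                for cell in sp.range_cells:
                    key = (gcm, cell)
                    if key not in cache:
                        cache[key] = float(np.quantile(
                            climate.baseline_series(gcm, cell), 0.99))
                    p99.append(cache[key])
                limits[sp.species_id][f"gcm{gcm}"] = max(p99)
        ground_truth["thermal_limits"] = limits

    return World(config=config, grid=grid, species=species,
                 overlaps=overlaps,
                 species_table=_species_table(species, overlaps),
                 landuse_raw=landuse_raw, landuse=landuse,
                 climate=climate, ground_truth=ground_truth)


def make_null_world(config: WorldConfig) -> World:
    """World with zero trends and zero noise: nothing ever changes.

    The null condition is a deterministic, stationary climate (the seasonal
    cycle repeats identically every year) and static land use, so every
    species keeps exactly its 2015 suitable area through 2100.
    """
    null_cfg = dataclasses.replace(
        config,
        gcm_noise_sd=0.0,
        historic_warming=0.0,
        warming_rate={sc: 0.0 for sc in config.scenarios},
        landuse_trend={sc: 0.0 for sc in config.scenarios},
    )
    return generate_world(null_cfg)


def make_half_loss_world(seed: int = 0, n_rows: int = 4,
                         n_cols: int = 4) -> World:
    """Designed world: one species loses exactly half its range to heat.

    A single species occupies every cell of a flat-temperature grid with a
    spatially uniform, static habitat fraction. Strong warming is confined
    to the top half of the rows; the other half repeats the baseline
    seasonal cycle forever. By 2100 exactly half the range cells are
    climatically unsuitable, so the pipeline must return an exposure
    fraction of exactly 0.5 (recorded in the ground-truth sidecar).
    """
    if n_rows % 2:
        raise InvalidWorldConfigError("n_rows must be even for a half split")
    scenario = "SSP5-RCP8.5"
    cfg = WorldConfig(
        seed=seed, n_rows=n_rows, n_cols=n_cols, n_species=0,
        scenarios=(scenario,), n_gcms=1,
        gcm_noise_sd=0.0, historic_warming=0.0,
        seasonal_amplitude=6.0, lat_range_c=(30.0, 30.0),
        warming_rate={scenario: 1.0},
        landuse_trend={scenario: 0.0},
        hot_rows=n_rows // 2,
        # dyadic fractions keep every suitable-area sum exact in binary,
        # so the recovered exposure is 0.5 to the last bit
        uniform_landuse={"primf": 0.5, "pastr": 0.25},
        record_thermal_truth=False,
    )
    grid = build_grid(cfg.n_rows, cfg.n_cols, cfg.cell_edge_km)
    lu_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    landuse_raw = _generate_landuse(cfg, grid, lu_rng)
    landuse = {sc: {yr: reclassify_luh2(layer) for yr, layer in layers.items()}
               for sc, layers in landuse_raw.items()}
    sid = "designed_half_loss"
    all_cells = frozenset(int(c) for c in grid.cell_ids)
    sp = SpeciesRecord(species_id=sid, taxon="reptile", redlist="LC",
                       range_cells=all_cells,
                       habitat_classes=frozenset({"forest"}))
    ov = RangeOverlap(species_id=sid,
                      cell_overlaps={int(c): 1.0 for c in grid.cell_ids},
                      polygon_area_km2=grid.n_cells * grid.cell_area_km2)
    ground_truth = {
        "species": {sid: {"taxon": sp.taxon, "redlist": sp.redlist,
                          "n_range_cells": grid.n_cells,
                          "habitat_classes": ["forest"]}},
        "designed": {sid: {"expected_exposure_2100": 0.5,
                           "scenario": scenario}},
    }
    return World(config=cfg, grid=grid, species=[sp], overlaps={sid: ov},
                 species_table=_species_table([sp], {sid: ov}),
                 landuse_raw=landuse_raw, landuse=landuse,
                 climate=ClimateGenerator(cfg, grid),
                 ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# persistence (CSV/JSON only; daily climate is stored as its generator
# config and regenerated on load)

def world_to_dir(world: World, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(world.config.to_json())
    world.species_table.to_csv(outdir / "species.csv", index=False)
    rows = []
    for sid, ov in world.overlaps.items():
        for cell, frac in sorted(ov.cell_overlaps.items()):
            rows.append({"species_id": sid, "cell_id": cell,
                         "overlap_fraction": frac,
                         "polygon_area_km2": ov.polygon_area_km2})
    pd.DataFrame(rows).to_csv(outdir / "range_overlaps.csv", index=False)
    for sc, layers in world.landuse_raw.items():
        recs = []
        for yr, layer in layers.items():
            df = pd.DataFrame(layer.fractions, columns=list(LUH2_STATES))
            df.insert(0, "cell_id", np.arange(len(df)))
            df.insert(0, "year", yr)
            recs.append(df)
        pd.concat(recs).to_csv(outdir / f"landuse_{sc}.csv", index=False)
    (outdir / "ground_truth.json").write_text(
        json.dumps(world.ground_truth, indent=2, sort_keys=True))


def world_from_dir(indir: str | Path) -> World:
    """Rebuild a world from :func:`world_to_dir` output.

    The config is authoritative: the generator is deterministic, so
    regenerating from config.json reproduces the saved tables exactly.
    """
    cfg = WorldConfig.from_json((Path(indir) / "config.json").read_text())
    return generate_world(cfg)
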