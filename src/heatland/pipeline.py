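"""End-to-end orchestration: synthetic world -> exposure report bundle.

Stages, in order: per-cell baseline temperature percentiles -> species
realised thermal limits (per pseudo-GCM) -> baseline event maxima ->
per-cell-year suitability flags (ensemble median across GCMs) ->
suitable-area trajectories in the three driver modes -> exposure records at
the evaluation year -> driver attribution -> species counts over exposure
thresholds (by taxon and Red List category) -> per-cell summaries and
bivariate classes -> ZOIB regression of exposure on range size and threat
category. Everything is deterministic given the world's seed; the manifest
records the configuration hash and per-stage checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .grid_ranges import Grid, SpeciesRecord
from .landuse import class_fractions
from .heat_events import (HeatEventConfig, DEFAULT_CONFIG, BaselineMaxima,
                          annual_metrics, combine_gcms, suitable_years)
from .exposure import (DRIVER_MODES, build_trajectory, exposure_at,
                       attribute_driver, threshold_counts)
from .cell_summaries import (DEFAULT_CLIMATE_EDGES, DEFAULT_LANDUSE_EDGES,
                             DEFAULT_WINDOW, summarize_cells)
from .zoib import ZOIBData, build_design, fit_zoib
from .synthetic_data import World

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineSettings:
    """Run-level knobs (scenario subset, thresholds, window, ensemble)."""

    scenarios: tuple[str, ...] | None = None
    thresholds: tuple[float, ...] = (0.5, 1.0)
    eval_year: int = 2100
    window: tuple[int, int] = DEFAULT_WINDOW
    window_rule: str = "any"            # or "majority" of window years
    gcm_rule: str = "median"
    heat: HeatEventConfig = DEFAULT_CONFIG
    landuse_edges: tuple[float, float] = DEFAULT_LANDUSE_EDGES
    climate_edges: tuple[float, float] = DEFAULT_CLIMATE_EDGES
    fit_zoib_model: bool = True

    def __post_init__(self) -> None:
        for thr in self.thresholds:
            if not 0 < thr <= 1:
                raise ValueError("thresholds must lie in (0, 1]")
        if self.window_rule not in ("any", "majority"):
            raise ValueError("window_rule must be 'any' or 'majority'")


@dataclass
class PipelineResult:
    manifest: dict
    thermal_limits: pd.DataFrame
    baseline: pd.DataFrame
    trajectories: pd.DataFrame
    exposure: pd.DataFrame
    attribution: pd.DataFrame
    counts: pd.DataFrame
    cell_summaries: pd.DataFrame
    zoib_fits: dict
    flags: dict            # scenario -> species -> {cells, years, unsuitable}
    excluded: list[str]    # species with no initial habitat


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(world: World, settings: PipelineSettings | None = None
                 ) -> PipelineResult:
    settings = settings or PipelineSettings()
    cfg = world.config
    grid = world.grid
    species = world.species
    scenarios = settings.scenarios or cfg.scenarios
    heat_cfg = settings.heat

    years_lu = np.arange(cfg.base_year, cfg.end_year + 1)
    n_years = len(years_lu)
    climate_start_idx = cfg.climate_start - cfg.base_year
    base_day0 = (cfg.base_year - cfg.start_year) * 365

    species_by_cell: dict[int, list[SpeciesRecord]] = {}
    for sp in species:
        for cell in sp.range_cells:
            species_by_cell.setdefault(cell, []).append(sp)
    cells_used = sorted(species_by_cell)
    cell_index = {sp.species_id: {c: i for i, c in
                                  enumerate(sorted(sp.range_cells))}
                  for sp in species}
    sp_cells = {sp.species_id: np.array(sorted(sp.range_cells))
                for sp in species}

    # --- stage 1: per-cell baseline percentile, species thermal limits ----
    logger.info("stage thermal-limits: %d cells, %d gcms",
                len(cells_used), cfg.n_gcms)
    p99: dict[tuple[int, int], float] = {}
    for gcm in range(cfg.n_gcms):
        for cell in cells_used:
            p99[(gcm, cell)] = float(np.quantile(
                world.climate.baseline_series(gcm, cell),
                heat_cfg.quantile, method=heat_cfg.quantile_method))
    t_star = {(sp.species_id, gcm): max(p99[(gcm, c)]
                                        for c in sp.range_cells)
              for sp in species for gcm in range(cfg.n_gcms)}
    thermal_df = pd.DataFrame(
        [{"species_id": sid, "gcm": f"gcm{g}", "t_star": t}
         for (sid, g), t in sorted(t_star.items())])

    # --- stage 2: baseline event maxima (scenario-independent) ------------
    logger.info("stage baseline-maxima")
    base_max = {(sp.species_id, g): np.zeros(3)
                for sp in species for g in range(cfg.n_gcms)}
    for gcm in range(cfg.n_gcms):
        for cell in cells_used:
            series = world.climate.baseline_series(gcm, cell)
            for sp in species_by_cell[cell]:
                m = annual_metrics(series, t_star[(sp.species_id, gcm)],
                                   heat_cfg)
                np.maximum(base_max[(sp.species_id, gcm)], m.max(axis=0),
                           out=base_max[(sp.species_id, gcm)])
    baselines = {key: BaselineMaxima(*map(float, v))
                 for key, v in base_max.items()}
    baseline_df = pd.DataFrame(
        [{"species_id": sid, "gcm": f"gcm{g}",
          "max_frequency": b.max_frequency, "max_duration": b.max_duration,
          "max_intensity": b.max_intensity}
         for (sid, g), b in sorted(baselines.items())])

    # --- per-scenario stages ----------------------------------------------
    prefs_cache: dict[tuple[str, tuple[str, ...]], np.ndarray] = {}

    def habitat_matrix(scenario: str, prefs: tuple[str, ...]) -> np.ndarray:
        key = (scenario, prefs)
        if key not in prefs_cache:
            layers = world.landuse[scenario]
            prefs_cache[key] = np.stack(
                [class_fractions(prefs, layers[y]) for y in years_lu])
        return prefs_cache[key]

    traj_rows, exp_rows, attr_rows, count_frames, cell_frames = \
        [], [], [], [], []
    zoib_fits: dict[str, dict] = {}
    flags_out: dict[str, dict[str, dict]] = {}
    excluded: list[str] = []

    win_lo, win_hi = settings.window
    win_idx = np.flatnonzero((years_lu >= win_lo) & (years_lu <= win_hi))

    for scenario in scenarios:
        logger.info("stage suitability-flags: scenario %s", scenario)
        unsuit = {sp.species_id: np.zeros(
            (cfg.n_gcms, len(sp.range_cells), n_years), dtype=bool)
            for sp in species}
        for gcm in range(cfg.n_gcms):
            for cell in cells_used:
                series = world.climate.daily_series(scenario, gcm, cell)
                fut = series[base_day0:]
                for sp in species_by_cell[cell]:
                    sid = sp.species_id
                    m = annual_metrics(fut, t_star[(sid, gcm)], heat_cfg)
                    bad = ~suitable_years(m, baselines[(sid, gcm)])
                    bad[:climate_start_idx] = False
                    unsuit[sid][gcm, cell_index[sid][cell]] = bad

        ensemble: dict[str, np.ndarray] = {}
        for sp in species:
            ens = combine_gcms(unsuit[sp.species_id], rule=settings.gcm_rule)
            ens[:, :climate_start_idx] = False
            ensemble[sp.species_id] = ens          # (n_cells_sp, n_years)
        flags_out[scenario] = {
            sid: {"cells": sp_cells[sid], "years": years_lu,
                  "unsuitable": ens}
            for sid, ens in ensemble.items()}

        logger.info("stage trajectories/exposure: scenario %s", scenario)
        extinct_combined: dict[str, int | None] = {}
        frac_by_mode: dict[str, dict[str, float]] = {m: {}
                                                     for m in DRIVER_MODES}
        scenario_exp_rows = []
        for sp in species:
            sid = sp.species_id
            prefs = tuple(sorted(sp.habitat_classes))
            hf = habitat_matrix(scenario, prefs)[:, sp_cells[sid]]
            if hf[0].sum() <= 0:
                if sid not in excluded:
                    logger.warning("species %s has no initial habitat; "
                                   "excluded from percent-change stats", sid)
                    excluded.append(sid)
                continue
            climate_ok = ~ensemble[sid].T           # (n_years, n_cells_sp)
            row = {"species_id": sid, "scenario": scenario,
                   "taxon": sp.taxon, "redlist": sp.redlist}
            for mode in DRIVER_MODES:
                traj = build_trajectory(sid, scenario, mode, years_lu, hf,
                                        climate_ok, grid.cell_area_km2)
                rec = exposure_at(traj, settings.eval_year)
                row[f"sa_2015_km2"] = traj.sa_2015
                row[f"pct_change_{mode}"] = rec.pct_change
                row[f"index_0_200_{mode}"] = rec.index_0_200
                row[f"exposure_{mode}"] = rec.exposure_fraction
                frac_by_mode[mode][sid] = rec.exposure_fraction
                if mode == "combined":
                    extinct_combined[sid] = traj.extinct_year
                    row["extinct_year"] = traj.extinct_year
                for yr, sa in zip(traj.years, traj.sa):
                    traj_rows.append({"species_id": sid, "scenario": scenario,
                                      "driver_mode": mode, "year": int(yr),
                                      "sa_km2": float(sa)})
            scenario_exp_rows.append(row)

        # driver attribution at the first threshold
        thr = settings.thresholds[0]
        for row in scenario_exp_rows:
            sid = row["species_id"]
            if frac_by_mode["combined"][sid] >= thr:
                rec = attribute_driver(
                    sid, scenario, frac_by_mode["combined"][sid],
                    frac_by_mode["climate_only"][sid],
                    frac_by_mode["landuse_only"][sid], thr)
                row["attribution"] = rec.cls
                attr_rows.append(dataclasses.asdict(rec))
            else:
                row["attribution"] = None
        exp_rows.extend(scenario_exp_rows)

        exp_df = pd.DataFrame(scenario_exp_rows)
        if not exp_df.empty:
            counted = exp_df.rename(
                columns={"exposure_combined": "exposure_fraction"})
            for group_var in (None, "taxon", "redlist"):
                tbl = threshold_counts(counted, settings.thresholds,
                                       group_by=group_var)
                tbl.insert(0, "group_var", group_var or "all")
                tbl.insert(0, "scenario", scenario)
                count_frames.append(tbl)

        # per-cell summaries over the end-of-century window
        logger.info("stage cell-summaries: scenario %s", scenario)
        need = (1 if settings.window_rule == "any"
                else (len(win_idx) // 2 + 1))
        window_flags = {
            sid: {int(c): bool(ens[i, win_idx].sum() >= need)
                  for c, i in cell_index[sid].items()}
            for sid, ens in ensemble.items()}
        extinct_early = [sid for sid, yr in extinct_combined.items()
                         if yr is not None and yr < win_lo]
        cs = summarize_cells(
            grid, species, world.landuse[scenario], window_flags, scenario,
            window=settings.window, base_year=cfg.base_year,
            extinct_before_window=extinct_early,
            landuse_edges=settings.landuse_edges,
            climate_edges=settings.climate_edges)
        cell_frames.append(cs)

        # ZOIB regression of exposure on range size and threat category.
        # All analysed species enter: unexposed species supply the zero
        # mass, extinct species the one mass.
        if settings.fit_zoib_model and not exp_df.empty:
            zoib_fits[scenario] = _fit_scenario_zoib(exp_df)

    exposure_df = pd.DataFrame(exp_rows)
    result = PipelineResult(
        manifest={},
        thermal_limits=thermal_df,
        baseline=baseline_df,
        trajectories=pd.DataFrame(traj_rows),
        exposure=exposure_df,
        attribution=pd.DataFrame(
            attr_rows, columns=["species_id", "scenario", "threshold", "cls"]),
        counts=(pd.concat(count_frames, ignore_index=True)
                if count_frames else pd.DataFrame()),
        cell_summaries=(pd.concat(cell_frames, ignore_index=True)
                        if cell_frames else pd.DataFrame()),
        zoib_fits=zoib_fits,
        flags=flags_out,
        excluded=excluded,
    )
    result.manifest = _build_manifest(world, settings, result)
    return result


def _fit_scenario_zoib(exp_df: pd.DataFrame) -> dict:
    """Fit exposure ~ log10 range size (+ Red List terms when n allows)."""
    n = len(exp_df)
    if n == 0:
        return {"skipped": "no analysable species"}
    log_range = np.log10(exp_df["sa_2015_km2"].to_numpy())
    y = exp_df["exposure_combined"].to_numpy()
    X_full, names_full = build_design(log_range, exp_df["redlist"].tolist())
    if n >= 5 * (3 * X_full.shape[1] + 1):
        X, names = X_full, names_full
    else:
        X, names = X_full[:, :2], names_full[:2]
    if n < 5 * (3 * X.shape[1] + 1):
        return {"skipped": f"n={n} too small for ZOIB fit"}
    fit = fit_zoib(ZOIBData(y=y, X=X, names=names))
    return fit.summary()


def _build_manifest(world: World, settings: PipelineSettings,
                    result: PipelineResult) -> dict:
    settings_json = json.dumps(dataclasses.asdict(settings), sort_keys=True,
                               default=str)
    return {
        "package_version": __version__,
        "seed": world.config.seed,
        "config_hash": _sha256(world.config.to_json()),
        "settings_hash": _sha256(settings_json),
        "n_species": len(world.species),
        "n_cells": world.grid.n_cells,
        "scenarios": list(settings.scenarios or world.config.scenarios),
        "excluded_species": list(result.excluded),
        "stage_checksums": {
            "thermal_limits": _sha256(result.thermal_limits.to_csv(index=False)),
            "baseline": _sha256(result.baseline.to_csv(index=False)),
            "exposure": _sha256(result.exposure.to_csv(index=False)),
            "counts": _sha256(result.counts.to_csv(index=False)),
            "cell_summaries": _sha256(result.cell_summaries.to_csv(index=False)),
        },
    }


def write_result(result: PipelineResult, outdir: str | Path) -> None:
    """Write the report bundle as CSV/JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.thermal_limits.to_csv(outdir / "thermal_limits.csv", index=False)
    result.baseline.to_csv(outdir / "baseline_maxima.csv", index=False)
    result.trajectories.to_csv(outdir / "trajectories.csv", index=False)
    result.exposure.to_csv(outdir / "exposure.csv", index=False)
    result.attribution.to_csv(outdir / "attribution.csv", index=False)
    result.counts.to_csv(outdir / "threshold_counts.csv", index=False)
    result.cell_summaries.to_csv(outdir / "cell_summaries.csv", index=False)
    (outdir / "zoib_fits.json").write_text(
        json.dumps(result.zoib_fits, indent=2, default=float))
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2))
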