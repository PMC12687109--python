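"""Extreme heat events against species-specific realised thermal limits.

A species' realised thermal limit (t*) is the spatial maximum, over its
range cells, of the 99th percentile of daily maximum air temperature during
a historical baseline (1950–2005). An extreme heat event in a cell is a run
of *more than five* consecutive days with Tmax strictly above t* (so the
minimum qualifying run is six days). Each cell-year is summarised by

* frequency — number of events,
* duration  — length of the longest event, days (configurable: total event
  days),
* intensity — maximum °C exceedance above t* over event days (configurable:
  mean exceedance).

A future cell-year is climatically *unsuitable* when any of the three
metrics strictly exceeds the species-wide maximum of that metric recorded
anywhere in the range during the baseline; equality stays suitable. Flags
from an odd ensemble of climate models are combined by majority (the median
of binary flags).

All series use a 365-day no-leap calendar. Runs are evaluated within
calendar years; a run crossing December 31 is split at the boundary (the
per-cell-year bookkeeping makes this the simplest consistent choice).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class HeatEventConfig:
    """Tunables for event detection and metric definitions.

    min_run
        Minimum qualifying run length in days; the default 6 encodes the
        "more than five consecutive days" rule.
    quantile / quantile_method
        Percentile and numpy interpolation method for the thermal limit.
    duration_metric
        "longest" (longest single event, default) or "total" (sum of event
        days in the year).
    intensity_metric
        "max" (default) or "mean" exceedance over event days.
    """

    min_run: int = 6
    quantile: float = 0.99
    quantile_method: str = "linear"
    duration_metric: str = "longest"
    intensity_metric: str = "max"

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be in (0, 1)")
        if self.duration_metric not in ("longest", "total"):
            raise ValueError("duration_metric must be 'longest' or 'total'")
        if self.intensity_metric not in ("max", "mean"):
            raise ValueError("intensity_metric must be 'max' or 'mean'")


DEFAULT_CONFIG = HeatEventConfig()


@dataclass(frozen=True)
class ThermalLimit:
    species_id: str
    gcm_id: str
    t_star: float


@dataclass(frozen=True)
class HeatEvent:
    """One maximal qualifying run of exceedance days."""

    start_day: int
    length: int
    max_exceedance: float
    mean_exceedance: float = float("nan")


@dataclass(frozen=True)
class EventMetrics:
    frequency: int
    duration: int
    intensity: float
    species_id: str | None = None
    gcm_id: str | None = None
    cell_id: int | None = None
    year: int | None = None


@dataclass(frozen=True)
class BaselineMaxima:
    """Species-wide per-metric maxima over range cells × baseline years."""

    max_frequency: float
    max_duration: float
    max_intensity: float
    species_id: str | None = None
    gcm_id: str | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.max_frequency, self.max_duration,
                         self.max_intensity])


class MissingSeriesError(KeyError):
    """A range cell lacks a daily temperature series."""


def thermal_limit(
    series_by_cell: Mapping[int, np.ndarray],
    range_cells: Iterable[int] | None = None,
    config: HeatEventConfig = DEFAULT_CONFIG,
) -> float:
    """Spatial maximum over range cells of each cell's Tmax percentile.

    ``series_by_cell`` maps cell id -> daily baseline values. When
    ``range_cells`` is given, every listed cell must have a series.
    """
    cells = list(series_by_cell) if range_cells is None else list(range_cells)
    if not cells:
        raise MissingSeriesError("no range cells supplied")
    per_cell = []
    for cell in cells:
        if cell not in series_by_cell:
            raise MissingSeriesError(f"no daily series for range cell {cell}")
        per_cell.append(np.quantile(np.asarray(series_by_cell[cell], float),
                                    config.quantile,
                                    method=config.quantile_method))
    return float(max(per_cell))


def detect_events(values: np.ndarray, t_star: float,
                  min_run: int = DEFAULT_CONFIG.min_run) -> list[HeatEvent]:
    """Maximal runs of consecutive days strictly above ``t_star``.

    Runs shorter than ``min_run`` days are not events.
    """
    values = np.asarray(values, dtype=float)
    mask = values > t_star
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    events = []
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            exc = values[s:e] - t_star
            events.append(HeatEvent(start_day=int(s), length=int(e - s),
                                    max_exceedance=float(exc.max()),
                                    mean_exceedance=float(exc.mean())))
    return events


def event_metrics(events: Sequence[HeatEvent],
                  config: HeatEventConfig = DEFAULT_CONFIG,
                  **ids) -> EventMetrics:
    """Frequency / duration / intensity for one cell-year's events."""
    if not events:
        return EventMetrics(frequency=0, duration=0, intensity=0.0, **ids)
    lengths = [ev.length for ev in events]
    duration = (max(lengths) if config.duration_metric == "longest"
                else sum(lengths))
    if config.intensity_metric == "max":
        intensity = max(ev.max_exceedance for ev in events)
    else:
        total_days = sum(lengths)
        intensity = sum(ev.mean_exceedance * ev.length
                        for ev in events) / total_days
    return EventMetrics(frequency=len(events), duration=int(duration),
                        intensity=float(intensity), **ids)


def annual_metrics(values: np.ndarray, t_star: float,
                   config: HeatEventConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Per-year (frequency, duration, intensity) for a multi-year series.

    ``values`` length must be a multiple of 365 (no-leap calendar). Returns
    an array of shape (n_years, 3). Runs are confined to calendar years: a
    run spanning a year boundary counts separately in each year.

    Vectorised: years are padded with one sentinel day so a single run scan
    over the flattened array never crosses a year boundary.
    """
    values = np.asarray(values, dtype=float)
    if values.size % DAYS_PER_YEAR:
        raise ValueError("series length must be a multiple of 365")
    n_years = values.size // DAYS_PER_YEAR
    out = np.zeros((n_years, 3))
    yearly = values.reshape(n_years, DAYS_PER_YEAR)
    # pad each year with a -inf sentinel, then scan runs once
    pad = np.full((n_years, 1), -np.inf)
    flat = np.concatenate([yearly, pad], axis=1).ravel()
    mask = flat > t_star
    if not mask.any():
        return out
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    lengths = ends - starts
    keep = lengths >= config.min_run
    if not keep.any():
        return out
    starts, ends, lengths = starts[keep], ends[keep], lengths[keep]
    years = starts // (DAYS_PER_YEAR + 1)
    out[:, 0] = np.bincount(years, minlength=n_years)
    for s, e, ln, yr in zip(starts, ends, lengths, years):
        exc = flat[s:e] - t_star
        if config.duration_metric == "longest":
            out[yr, 1] = max(out[yr, 1], ln)
        else:
            out[yr, 1] += ln
        if config.intensity_metric == "max":
            out[yr, 2] = max(out[yr, 2], exc.max())
        else:
            out[yr, 2] += exc.sum()  # normalised below
    if config.intensity_metric == "mean":
        total_days = np.bincount(years, weights=lengths, minlength=n_years)
        nz = total_days > 0
        out[nz, 2] /= total_days[nz]
    return out


def baseline_maxima(metrics: np.ndarray, **ids) -> BaselineMaxima:
    """Per-metric maxima over a (…, 3) table of cell-year metrics."""
    metrics = np.asarray(metrics, dtype=float)
    if metrics.size == 0:
        return BaselineMaxima(0.0, 0.0, 0.0, **ids)
    flat = metrics.reshape(-1, 3)
    mx = flat.max(axis=0)
    return BaselineMaxima(max_frequency=float(mx[0]),
                          max_duration=float(mx[1]),
                          max_intensity=float(mx[2]), **ids)


def climate_suitable(metrics: EventMetrics | Sequence[float],
                     baseline: BaselineMaxima) -> bool:
    """True when no metric strictly exceeds its baseline maximum."""
    if isinstance(metrics, EventMetrics):
        f, d, i = metrics.frequency, metrics.duration, metrics.intensity
    else:
        f, d, i = metrics
    return not (f > baseline.max_frequency
                or d > baseline.max_duration
                or i > baseline.max_intensity)


def suitable_years(metrics: np.ndarray, baseline: BaselineMaxima) -> np.ndarray:
    """Vectorised :func:`climate_suitable` over a (n_years, 3) table."""
    metrics = np.asarray(metrics, dtype=float)
    return ~np.any(metrics > baseline.as_array()[None, :], axis=1)


def combine_gcms(unsuitable_flags: np.ndarray, rule: str = "median") -> np.ndarray:
    """Combine per-model *unsuitable* flags by the median (strict majority).

    ``unsuitable_flags`` has models on axis 0 (True = unsuitable). The model
    count must be odd so the median of binary flags is itself binary.
    Returns the ensemble unsuitable flag(s), same shape minus axis 0.
    """
    if rule != "median":
        raise ValueError(f"unknown ensemble rule {rule!r}")
    flags = np.asarray(unsuitable_flags, dtype=bool)
    n = flags.shape[0]
    if n % 2 == 0:
        raise ValueError("median ensemble rule requires an odd model count")
    return flags.sum(axis=0) * 2 > n
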