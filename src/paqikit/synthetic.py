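"""Synthetic co-registered rasters with a known ground-truth PM surface.

Emulates the study's input stack — satellite aerosol retrievals (AOT,
SSA), reanalysis meteorology (wind speed, relative humidity, skin
temperature, boundary-layer height), gridded population density, and
province-like zone labels — as spatially correlated random fields on one
regular grid, so every downstream stage (screening, network training,
index calculation, exposure statistics) is testable end to end without any
external download.

The ground-truth PM2.5 surface is a fixed smooth nonlinear function of the
predictors: saturating in aerosol optical thickness, linearly increasing
in relative humidity, exponentially decreasing in boundary-layer height
(vertical dilution) and wind speed (ventilation), with mild skin
temperature, single-scattering-albedo and latitude terms.  PM10 adds a
non-negative coarse-mode component, so PM10 >= PM2.5 holds everywhere.
Station observations are truth plus independent Gaussian noise.

One integer seed drives every sub-generator through
``numpy.random.SeedSequence`` spawning, in a fixed documented order
(fields, population, zones, stations), so a config reproduces its full
fixture set bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .rasters import GridField, GridTransform, StationTable, ZoneMask, align_check

__all__ = [
    "SimConfig",
    "DEFAULT_TRUTH_SPEC",
    "PREDICTOR_NAMES",
    "simulate_fields",
    "simulate_population",
    "simulate_zones",
    "sample_stations",
    "truth_pm",
]

#: The eight screened predictors, in canonical order.
PREDICTOR_NAMES = ("lat", "lon", "WS", "RH", "SKT", "HPBL", "AOT", "SSA")

#: Coefficients of the ground-truth PM function (units give µg/m³ output).
DEFAULT_TRUTH_SPEC: dict[str, float] = {
    "base": 15.0,         # background fine PM, µg/m³
    "aot_amp": 130.0,     # amplitude of the saturating AOT response
    "aot_half": 0.6,      # AOT at half saturation
    "rh_coef": 0.30,      # µg/m³ per % relative humidity (hygroscopic growth)
    "hpbl_amp": 45.0,     # dilution term amplitude
    "hpbl_scale": 1200.0, # e-folding boundary-layer height, m
    "ws_amp": 18.0,       # ventilation term amplitude
    "ws_scale": 4.0,      # e-folding wind speed, m/s
    "skt_coef": 0.08,     # µg/m³ per K above 285 K
    "ssa_amp": 12.0,      # absorbing-aerosol term: scales with (1 - SSA)
    "lat_coef": 0.4,      # weak meridional gradient, µg/m³ per degree
    "coarse_base": 20.0,      # PM10 coarse-mode floor
    "coarse_aot_amp": 60.0,   # dust loading term
    "coarse_rh_scale": 150.0, # humidity suppression of resuspension
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic study domain.

    smoothness is the spatial correlation length in cells (Gaussian kernel
    sigma); noise_sd is the station observation noise in µg/m³.
    """

    shape: tuple[int, int] = (40, 40)
    cell_size: float = 0.1
    origin: tuple[float, float] = (100.0, 45.0)  # (lon, lat) of upper-left corner
    seed: int = 0
    smoothness: float = 4.0
    noise_sd: float = 5.0
    n_stations: int = 300
    n_zones: int = 5
    truth_spec: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUTH_SPEC))

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows < 4 or cols < 4:
            raise ValueError("grid must be at least 4x4")
        if self.n_zones < 1:
            raise ValueError("n_zones must be >= 1")
        if self.n_zones > rows * cols:
            raise ValueError("n_zones exceeds cell count")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def transform(self) -> GridTransform:
        return GridTransform(self.origin[0], self.origin[1], self.cell_size, -self.cell_size)

    def _seeds(self) -> dict[str, np.random.SeedSequence]:
        # Fixed spawning order: changing it would change every fixture.
        children = np.random.SeedSequence(self.seed).spawn(4)
        return dict(zip(("fields", "population", "zones", "stations"), children))


def _correlated_field(rng: np.random.Generator, shape: tuple[int, int], smoothness: float) -> np.ndarray:
    """Standardized Gaussian random field: smoothed white noise."""
    white = rng.standard_normal(shape)
    if smoothness > 0:
        smooth = ndimage.gaussian_filter(white, sigma=smoothness, mode="reflect")
    else:
        smooth = white
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def truth_pm(
    fields: Mapping[str, np.ndarray], spec: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the ground-truth (PM2.5, PM10) surfaces from predictor arrays."""
    aot, rh = fields["AOT"], fields["RH"]
    pm25 = (
        spec["base"]
        + spec["aot_amp"] * aot / (spec["aot_half"] + aot)
        + spec["rh_coef"] * rh
        + spec["hpbl_amp"] * np.exp(-fields["HPBL"] / spec["hpbl_scale"])
        + spec["ws_amp"] * np.exp(-fields["WS"] / spec["ws_scale"])
        + spec["skt_coef"] * (fields["SKT"] - 285.0)
        + spec["ssa_amp"] * (1.0 - fields["SSA"])
        + spec["lat_coef"] * (fields["lat"] - np.mean(fields["lat"]))
    )
    coarse = (
        spec["coarse_base"]
        + spec["coarse_aot_amp"]
        * aot / (spec["aot_half"] + aot)
        * np.exp(-rh / spec["coarse_rh_scale"])
    )
    return pm25, pm25 + coarse


def simulate_fields(config: SimConfig) -> dict[str, GridField]:
    """Generate the eight predictor rasters plus PM25_true and PM10_true.

    Predictors are spatially correlated and clipped to physical ranges
    (RH in [0, 100] %, SSA in (0, 1], AOT >= 0, HPBL > 0 m, WS >= 0 m/s).
    """
    rng = np.random.default_rng(config._seeds()["fields"])
    shape = config.shape
    t = config.transform
    ys, xs = t.cell_centers(shape)
    lat = np.broadcast_to(ys[:, None], shape).copy()
    lon = np.broadcast_to(xs[None, :], shape).copy()

    def g() -> np.ndarray:
        return _correlated_field(rng, shape, config.smoothness)

    raw = {
        "lat": lat,
        "lon": lon,
        "WS": np.clip(3.0 + 2.0 * g(), 0.0, None),
        "RH": np.clip(55.0 + 18.0 * g(), 0.0, 100.0),
        "SKT": 288.0 + 8.0 * g(),
        "HPBL": np.clip(800.0 + 350.0 * g(), 50.0, None),
        "AOT": np.clip(0.5 + 0.3 * g(), 0.0, None),
        "SSA": np.clip(0.90 + 0.04 * g(), 0.5, 1.0),
    }
    pm25, pm10 = truth_pm(raw, config.truth_spec)
    raw["PM25_true"] = pm25
    raw["PM10_true"] = pm10
    mask = np.ones(shape, bool)
    return {
        name: GridField(values=v, mask=mask.copy(), transform=t, name=name)
        for name, v in raw.items()
    }


def simulate_population(config: SimConfig) -> GridField:
    """Population surface: log-normal background plus dense urban clusters.

    Values are persons per cell.  ``meta['total_population']`` records the
    domain total; ``meta['cluster_cells']`` the (row, col) cluster centers.
    """
    rng = np.random.default_rng(config._seeds()["population"])
    shape = config.shape
    log_bg = _correlated_field(rng, shape, config.smoothness)
    background = np.exp(3.0 + 1.0 * log_bg)  # log-normal rural background

    n_clusters = config.n_zones
    rows = rng.integers(0, shape[0], size=n_clusters)
    cols = rng.integers(0, shape[1], size=n_clusters)
    amps = np.exp(rng.normal(np.log(200.0), 0.3, size=n_clusters)) * background.max()
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    pop = background.copy()
    for r0, c0, a in zip(rows, cols, amps):
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        pop += a * np.exp(-d2 / (2 * 1.5**2))
    fieldobj = GridField(
        values=pop,
        mask=np.ones(shape, bool),
        transform=config.transform,
        name="population",
    )
    fieldobj.meta["total_population"] = float(pop.sum())
    fieldobj.meta["cluster_cells"] = [(int(r), int(c)) for r, c in zip(rows, cols)]
    fieldobj.meta["background_p99"] = float(np.percentile(background, 99))
    return fieldobj


def simulate_zones(config: SimConfig) -> ZoneMask:
    """Voronoi partition of the grid into n_zones contiguous labeled regions."""
    rng = np.random.default_rng(config._seeds()["zones"])
    rows, cols = config.shape
    n = config.n_zones
    flat = rng.choice(rows * cols, size=n, replace=False)
    centers = np.column_stack(np.unravel_index(flat, (rows, cols)))
    rr, cc = np.mgrid[0:rows, 0:cols]
    d2 = (rr[..., None] - centers[:, 0]) ** 2 + (cc[..., None] - centers[:, 1]) ** 2
    labels = np.argmin(d2, axis=-1) + 1
    names = {i: f"zone_{i:02d}" for i in range(1, n + 1)}
    return ZoneMask(labels=labels, zone_names=names, transform=config.transform)


def sample_stations(
    fields: Mapping[str, GridField],
    config: SimConfig,
    pollutant: str = "PM2.5",
) -> StationTable:
    """Draw station records at distinct valid cells of the simulated domain.

    observed_pm is the truth value at the cell plus N(0, noise_sd) noise,
    floored at zero; predictor values are copied from the cell.
    """
    truth_key = {"PM2.5": "PM25_true", "PM10": "PM10_true"}.get(pollutant)
    if truth_key is None:
        raise ValueError(f"unknown pollutant {pollutant!r}")
    align_check(dict(fields))
    truth = fields[truth_key]
    valid = np.flatnonzero(truth.mask)
    if config.n_stations > valid.size:
        raise ValueError(
            f"requested {config.n_stations} stations but only {valid.size} valid cells"
        )
    rng = np.random.default_rng(config._seeds()["stations"])
    chosen = rng.choice(valid, size=config.n_stations, replace=False)
    rows, cols = np.unravel_index(chosen, truth.shape)
    noise = rng.normal(0.0, config.noise_sd, size=config.n_stations)
    observed = np.clip(truth.values[rows, cols] + noise, 0.0, None)
    data = {
        "id": [f"S{i:04d}" for i in range(config.n_stations)],
        "lat": fields["lat"].values[rows, cols],
        "lon": fields["lon"].values[rows, cols],
        "pollutant": pollutant,
        "observed_pm": observed,
    }
    for name in PREDICTOR_NAMES:
        if name not in ("lat", "lon"):
            data[name] = fields[name].values[rows, cols]
    frame = pd.DataFrame(data)
    return StationTable(frame, list(PREDICTOR_NAMES))
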