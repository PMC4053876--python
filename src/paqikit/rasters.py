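"""Gridded data model and I/O.

A :class:`GridField` is a single-variable 2-D raster on a regular
geographic grid: row 0 is the northernmost row, the affine transform is
origin-at-upper-left with a positive x step and a negative y step, and a
boolean mask marks valid cells.  All downstream statistics ignore masked
cells.  Grids are exchanged as single-band GeoTIFF (via tifffile, with
standard georeference tags) or NetCDF (via xarray); station records as CSV.

No resampling is performed anywhere: inputs must share one grid, and
:func:`align_check` enforces that before any multi-field computation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridTransform",
    "GridField",
    "ZoneMask",
    "StationTable",
    "AlignmentError",
    "read_grid",
    "write_grid",
    "read_zones",
    "write_zones",
    "align_check",
    "read_stations",
]

# GeoTIFF tag ids: pixel scale, tie point, GDAL nodata.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_NODATA = 42113

#: Columns every station CSV must provide besides predictor columns.
STATION_MANDATORY = ("id", "lat", "lon", "pollutant", "observed_pm")


class AlignmentError(ValueError):
    """Two grids that should share a grid do not."""


@dataclass(frozen=True)
class GridTransform:
    """Affine georeference of a north-up regular grid.

    ``x0, y0`` locate the outer corner of the upper-left cell; ``dx > 0``
    and ``dy < 0`` are the cell steps in the x and y directions.
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if not (self.dx > 0):
            raise ValueError(f"x cell size must be positive, got {self.dx}")
        if not (self.dy < 0):
            raise ValueError(f"y cell size must be negative (north-up), got {self.dy}")

    def cell_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (y_centers, x_centers) 1-D coordinate arrays for *shape*."""
        rows, cols = shape
        xs = self.x0 + self.dx * (np.arange(cols) + 0.5)
        ys = self.y0 + self.dy * (np.arange(rows) + 0.5)
        return ys, xs

    def close_to(self, other: "GridTransform", tol: float = 1e-9) -> bool:
        a = (self.x0, self.y0, self.dx, self.dy)
        b = (other.x0, other.y0, other.dx, other.dy)
        return all(abs(u - v) <= tol * max(1.0, abs(u), abs(v)) for u, v in zip(a, b))


@dataclass
class GridField:
    """One georeferenced raster variable with a validity mask.

    ``values`` holds the cell values (units depend on the variable);
    ``mask`` is True where the cell is valid.  Masked cells are excluded
    from every statistic computed downstream.
    """

    values: np.ndarray
    mask: np.ndarray
    transform: GridTransform
    crs_label: str = "EPSG:4326"
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError(f"grid values must be 2-D, got {self.values.ndim}-D")
        if self.values.size == 0:
            raise ValueError("grid must contain at least one cell")
        if self.values.shape != self.mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.mask.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        """1-D array of valid cell values."""
        return self.values[self.mask]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "GridField":
        """New field on the same grid with different values (mask kept)."""
        return replace(
            self, values=np.asarray(values, float), mask=self.mask.copy(),
            name=self.name if name is None else name, meta={},
        )


@dataclass
class ZoneMask:
    """Integer zone labels on a grid; 0 means outside every zone."""

    labels: np.ndarray
    zone_names: dict[int, str]
    transform: GridTransform
    crs_label: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("zone labels must be 2-D")
        if self.labels.min() < 0:
            raise ValueError("zone labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.zone_names)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from zone_names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def zone_ids(self) -> list[int]:
        return sorted(set(np.unique(self.labels)) - {0})


class StationTable:
    """Ground-observation records used to train and validate the estimator.

    Wraps a DataFrame with columns id, lat, lon, pollutant, observed_pm and
    one numeric column per predictor.  lat and lon double as predictors.
    """

    def __init__(self, frame: pd.DataFrame, predictor_names: Sequence[str]):
        for col in STATION_MANDATORY:
            if col not in frame.columns:
                raise ValueError(f"station table missing mandatory column {col!r}")
        names = list(predictor_names)
        if len(names) != len(set(names)):
            raise ValueError("duplicate predictor names")
        for name in names:
            if name not in frame.columns:
                raise ValueError(f"predictor column {name!r} missing from table")
        if (frame["observed_pm"] < 0).any():
            raise ValueError("observed_pm must be non-negative")
        self.frame = frame.reset_index(drop=True)
        self.predictor_names = names

    def __len__(self) -> int:
        return len(self.frame)

    def X(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Predictor matrix (n, p) in the given (or stored) column order."""
        cols = self.predictor_names if names is None else list(names)
        return self.frame[cols].to_numpy(dtype=float)

    def y(self) -> np.ndarray:
        return self.frame["observed_pm"].to_numpy(dtype=float)

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# grid I/O


def _format_of(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    if suffix in (".nc", ".nc4", ".cdf"):
        return "netcdf"
    raise ValueError(f"unsupported raster format {suffix!r} for {path}")


def read_grid(path: str | Path, variable: str | None = None) -> GridField:
    """Read one 2-D variable from a GeoTIFF or NetCDF file.

    The mask is derived from the format's no-data convention (NaN / nodata
    tag / _FillValue).  For NetCDF, *variable* selects the dataset variable;
    for single-band GeoTIFF it is optional.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    fmt = _format_of(path)
    if fmt == "geotiff":
        return _read_geotiff(path, variable)
    return _read_netcdf(path, variable)


def _read_geotiff(path: Path, variable: str | None) -> GridField:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray()
            tags = page.tags
            desc = {}
            if page.description:
                try:
                    desc = json.loads(page.description)
                except (ValueError, TypeError):
                    desc = {}
            if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
                raise ValueError(f"{path} lacks georeference tags")
            sx, sy, _ = tags[_TAG_PIXEL_SCALE].value
            tie = tags[_TAG_TIEPOINT].value
            x0, y0 = float(tie[3]), float(tie[4])
            nodata = None
            if _TAG_NODATA in tags:
                nodata = float(tags[_TAG_NODATA].value)
    except tifffile.TiffFileError as exc:
        raise ValueError(f"{path} is not a readable GeoTIFF: {exc}") from exc
    if values.ndim != 2:
        raise ValueError(f"{path} holds a {values.ndim}-D band, expected 2-D")
    values = np.asarray(values, float)
    if nodata is None or np.isnan(nodata):
        mask = ~np.isnan(values)
    else:
        mask = (values != nodata) & ~np.isnan(values)
    name = variable or desc.get("variable", "")
    if variable and desc.get("variable") and desc["variable"] != variable:
        raise KeyError(f"variable {variable!r} not in {path} (holds {desc['variable']!r})")
    return GridField(
        values=values,
        mask=mask,
        transform=GridTransform(x0, y0, float(sx), -abs(float(sy))),
        crs_label=desc.get("crs", "EPSG:4326"),
        name=name,
    )


def _read_netcdf(path: Path, variable: str | None) -> GridField:
    import xarray as xr

    with xr.open_dataset(path, engine="scipy", mask_and_scale=True) as ds:
        data_vars = list(ds.data_vars)
        if variable is None:
            if len(data_vars) != 1:
                raise ValueError(
                    f"{path} holds variables {data_vars}; specify one explicitly"
                )
            variable = data_vars[0]
        if variable not in ds:
            raise KeyError(f"variable {variable!r} not found in {path} ({data_vars})")
        da = ds[variable]
        if da.ndim != 2:
            raise ValueError(f"variable {variable!r} is {da.ndim}-D, expected 2-D")
        values = da.to_numpy().astype(float)
        ys = ds["y"].to_numpy()
        xs = ds["x"].to_numpy()
        crs = str(ds.attrs.get("crs", "EPSG:4326"))
    dx = float(xs[1] - xs[0]) if len(xs) > 1 else 1.0
    dy = float(ys[1] - ys[0]) if len(ys) > 1 else -1.0
    transform = GridTransform(float(xs[0]) - dx / 2, float(ys[0]) - dy / 2, dx, dy)
    return GridField(
        values=values, mask=~np.isnan(values), transform=transform,
        crs_label=crs, name=variable,
    )


def write_grid(field: GridField, path: str | Path) -> None:
    """Write a GridField to GeoTIFF or NetCDF (chosen by extension).

    Masked cells are encoded as NaN (NetCDF ``_FillValue`` convention /
    GeoTIFF nodata tag), so a round-trip through :func:`read_grid`
    reproduces values, mask, and transform.
    """
    path = Path(path)
    fmt = _format_of(path)
    values = np.where(field.mask, field.values, np.nan)
    if fmt == "geotiff":
        import tifffile

        t = field.transform
        desc = json.dumps({"crs": field.crs_label, "variable": field.name})
        tifffile.imwrite(
            path,
            values,
            description=desc,
            metadata=None,
            extratags=[
                (_TAG_PIXEL_SCALE, "d", 3, (t.dx, abs(t.dy), 0.0)),
                (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x0, t.y0, 0.0)),
                (_TAG_NODATA, "s", 0, "nan"),
            ],
        )
    else:
        import xarray as xr

        ys, xs = field.transform.cell_centers(field.shape)
        name = field.name or "variable"
        ds = xr.Dataset(
            {name: (("y", "x"), values)},
            coords={"y": ys, "x": xs},
            attrs={"crs": field.crs_label},
        )
        ds.to_netcdf(path, engine="scipy")


def write_zones(zones: ZoneMask, path: str | Path) -> None:
    """Write zone labels as integer GeoTIFF plus a JSON {id: name} sidecar."""
    path = Path(path)
    import tifffile

    t = zones.transform
    tifffile.imwrite(
        path,
        zones.labels.astype(np.int32),
        description=json.dumps({"crs": zones.crs_label, "variable": "zones"}),
        metadata=None,
        extratags=[
            (_TAG_PIXEL_SCALE, "d", 3, (t.dx, abs(t.dy), 0.0)),
            (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x0, t.y0, 0.0)),
        ],
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({str(k): v for k, v in sorted(zones.zone_names.items())}, indent=0)
    )


def read_zones(path: str | Path) -> ZoneMask:
    path = Path(path)
    grid = _read_geotiff(path, None)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"zone-name sidecar not found: {sidecar}")
    names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return ZoneMask(
        labels=grid.values.astype(int),
        zone_names=names,
        transform=grid.transform,
        crs_label=grid.crs_label,
    )


def align_check(
    fields: Sequence[GridField] | Mapping[str, GridField],
    zones: ZoneMask | None = None,
    tol: float = 1e-9,
) -> None:
    """Raise :class:`AlignmentError` unless all grids share shape and transform.

    Passes silently on success.  The first mismatching pair is named in the
    error.  *zones*, when given, must align with the fields too.
    """
    if isinstance(fields, Mapping):
        items: list[tuple[str, GridField | ZoneMask]] = list(fields.items())
    else:
        items = [(f.name or f"field[{i}]", f) for i, f in enumerate(fields)]
    if not items:
        raise ValueError("align_check requires at least one field")
    if zones is not None:
        items.append(("zones", zones))
    ref_name, ref = items[0]
    for name, other in items[1:]:
        if other.shape != ref.shape:
            raise AlignmentError(
                f"shape mismatch: {ref_name} {ref.shape} vs {name} {other.shape}"
            )
        if not ref.transform.close_to(other.transform, tol=tol):
            raise AlignmentError(
                f"transform mismatch: {ref_name} {ref.transform} vs {name} {other.transform}"
            )


def read_stations(path: str | Path) -> StationTable:
    """Read a station CSV into a typed :class:`StationTable`.

    Columns beyond the mandatory five are treated as predictors, with lat
    and lon also included as predictors.  Rows whose observed_pm or any
    predictor is non-numeric/blank are dropped, with row numbers reported
    in a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"station file not found: {path}")
    frame = pd.read_csv(path)
    for col in STATION_MANDATORY:
        if col not in frame.columns:
            raise ValueError(f"station CSV {path} missing mandatory column {col!r}")
    predictor_names = ["lat", "lon"] + [
        c for c in frame.columns if c not in STATION_MANDATORY
    ]
    numeric_cols = ["observed_pm"] + predictor_names
    coerced = frame[numeric_cols].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    if bad.any():
        rows = [int(i) + 2 for i in frame.index[bad]]  # +2: header + 1-based
        warnings.warn(
            f"dropped {bad.sum()} station row(s) with non-numeric values "
            f"(CSV line numbers {rows})",
            stacklevel=2,
        )
    frame = frame.loc[~bad].copy()
    frame[numeric_cols] = coerced.loc[~bad]
    return StationTable(frame, predictor_names)
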