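"""Raster plumbing: regular lat-lon grids, NetCDF IO, co-registration and masks.

All mapped fields ride on :class:`Grid`, a 2-D array on a regular,
cell-centered latitude-longitude lattice. Latitude is normalized to
ascending order on construction; missing data is NaN for float fields.

Salinity enters the model as an eight-class ordinal field; the class bins
and the terrigenous / bathymetric mask logic live here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import xarray as xr

logger = logging.getLogger("carbfact")

#: factory identifiers, in the fixed tie-break order used throughout
FACTORIES = ("biochemical", "photozoan_T", "photo_C", "heterozoan_C")

#: integer codes for categorical factory maps (and their serialized form)
FACTORY_CODES: dict[str, int] = {
    "none": 0,
    "biochemical": 1,
    "photozoan_T": 2,
    "photo_C": 3,
    "heterozoan_C": 4,
    "masked": -1,
}
CODE_TO_FACTORY = {v: k for k, v in FACTORY_CODES.items()}

#: terrigenous shelf-deposit categories
TERR_NONE, TERR_LOW, TERR_HIGH, TERR_ARCTIC = 0, 1, 2, 3
TERR_LABELS = {TERR_NONE: "none", TERR_LOW: "low", TERR_HIGH: "high", TERR_ARCTIC: "arctic"}

#: left edges of salinity classes 2..8; class 1 is everything below 31.5 psu
_SSS_EDGES = np.array([31.5, 33.0, 34.0, 35.0, 35.5, 36.5, 37.5])

_AXIS_TOL = 1e-9


@dataclass
class Grid:
    """A single field on a regular cell-centered lat-lon lattice.

    Parameters
    ----------
    values
        2-D array, shape ``(len(lat), len(lon))``. Float arrays use NaN
        as the missing-data sentinel; integer arrays are categorical.
    lat, lon
        Cell-center coordinates in degrees, strictly monotonic with
        uniform spacing. Descending latitude is accepted and flipped to
        ascending (values flipped with it).
    """

    values: np.ndarray
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (self.lat.size, self.lon.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match axes "
                f"({self.lat.size}, {self.lon.size})"
            )
        if self.lat.size > 1 and self.lat[0] > self.lat[-1]:  # normalize to ascending
            self.lat = self.lat[::-1].copy()
            self.values = self.values[::-1].copy()
        for name, ax in (("lat", self.lat), ("lon", self.lon)):
            if ax.size > 1:
                d = np.diff(ax)
                if not np.all(d > 0):
                    raise ValueError(f"{name} axis is not strictly monotonic")
                if np.ptp(d) > _AXIS_TOL:
                    raise ValueError(f"{name} axis spacing is not uniform within {_AXIS_TOL}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def resolution(self) -> float:
        """Cell size in degrees (latitude spacing; axes share it on our lattices)."""
        if self.lat.size > 1:
            return float(self.lat[1] - self.lat[0])
        if self.lon.size > 1:
            return float(self.lon[1] - self.lon[0])
        return float("nan")

    def like(self, values: np.ndarray) -> "Grid":
        """A new grid with the same lattice and the given values."""
        return Grid(np.asarray(values), self.lat.copy(), self.lon.copy())

    def copy(self) -> "Grid":
        return self.like(self.values.copy())

    def same_lattice(self, other: "Grid", tol: float = _AXIS_TOL) -> bool:
        return (
            self.lat.size == other.lat.size
            and self.lon.size == other.lon.size
            and bool(np.all(np.abs(self.lat - other.lat) <= tol))
            and bool(np.all(np.abs(self.lon - other.lon) <= tol))
        )

    def to_dataarray(self, name: str = "value") -> xr.DataArray:
        return xr.DataArray(
            self.values, coords={"lat": self.lat, "lon": self.lon}, dims=("lat", "lon"), name=name
        )

    @classmethod
    def from_dataarray(cls, da: xr.DataArray) -> "Grid":
        lat_name = next((n for n in ("lat", "latitude", "y") if n in da.dims), None)
        lon_name = next((n for n in ("lon", "longitude", "x") if n in da.dims), None)
        if lat_name is None or lon_name is None:
            raise ValueError(f"cannot identify lat/lon dimensions in {da.dims}")
        da = da.transpose(lat_name, lon_name)
        return cls(da.values, da[lat_name].values, da[lon_name].values)


@dataclass
class EnvStack:
    """Co-registered seasonal environmental grids.

    Seasons are local warm ("summer") and cool ("winter") composites, so a
    single pair of fields covers both hemispheres. Bathymetry is water
    depth in metres, positive down; land is negative or NaN. Salinity is
    the eight-class ordinal field, productivity the absorption due to
    phytoplankton (m^-1, a primary-productivity proxy).
    """

    sst_summer: Grid
    sst_winter: Grid
    sss_class_summer: Grid
    sss_class_winter: Grid
    prod_summer: Grid
    prod_winter: Grid
    bathymetry: Grid
    terrigenous: Grid

    FIELDS = (
        "sst_summer",
        "sst_winter",
        "sss_class_summer",
        "sss_class_winter",
        "prod_summer",
        "prod_winter",
        "bathymetry",
        "terrigenous",
    )

    def grids(self) -> dict[str, Grid]:
        return {name: getattr(self, name) for name in self.FIELDS}

    @property
    def lat(self) -> np.ndarray:
        return self.sst_summer.lat

    @property
    def lon(self) -> np.ndarray:
        return self.sst_summer.lon

    @property
    def shape(self) -> tuple[int, int]:
        return self.sst_summer.shape

    def ocean(self) -> np.ndarray:
        """Boolean array: cells with non-negative, finite water depth."""
        z = self.bathymetry.values
        return np.isfinite(z) & (z >= 0)

    def validate(self) -> None:
        ref = self.sst_summer
        for name, g in self.grids().items():
            if not g.same_lattice(ref):
                raise ValueError(f"field {name!r} is not on the shared lattice")
        ocean = self.ocean()
        ss, sw = self.sst_summer.values, self.sst_winter.values
        both = ocean & np.isfinite(ss) & np.isfinite(sw)
        if np.any(ss[both] < sw[both] - 1e-9):
            raise ValueError("sst_summer < sst_winter at some ocean cell (seasons are local)")
        for name in ("prod_summer", "prod_winter"):
            p = getattr(self, name).values
            if np.any(p[ocean & np.isfinite(p)] < 0):
                raise ValueError(f"{name} has negative values")
        for name in ("sss_class_summer", "sss_class_winter"):
            c = getattr(self, name).values
            valid = ocean & np.isfinite(c)
            if valid.any() and (c[valid].min() < 1 or c[valid].max() > 8):
                raise ValueError(f"{name} outside classes 1..8")


@dataclass
class MaskSet:
    """Per-factory eligibility plus the two shelf masks (0-100 m, 0-200 m)."""

    eligible: dict[str, np.ndarray] = field(default_factory=dict)
    shelf_100: np.ndarray | None = None
    shelf_200: np.ndarray | None = None


# ---------------------------------------------------------------------------
# IO

def _check_format(path: str | Path, format_hint: str | None) -> None:
    hint = (format_hint or Path(path).suffix.lstrip(".")).lower()
    if hint in ("geotiff", "tif", "tiff"):
        raise ValueError(
            f"{path}: GeoTIFF is not supported by this build; convert to NetCDF "
            "(CF-style lat/lon) first"
        )


def read_grid(path: str | Path, format_hint: str | None = None, var: str | None = None) -> Grid:
    """Read a single-band NetCDF raster into a :class:`Grid`.

    ``var`` selects the variable; by default the first 2-D data variable
    is used. No-data values are mapped to NaN by the NetCDF fill-value
    conventions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_format(path, format_hint)
    try:
        ds = xr.open_dataset(path, engine="scipy")
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise ValueError(f"{path}: unreadable as NetCDF ({exc})") from exc
    with ds:
        if var is None:
            candidates = [n for n, v in ds.data_vars.items() if v.ndim == 2]
            if not candidates:
                raise ValueError(f"{path}: no 2-D data variable found")
            var = candidates[0]
        try:
            grid = Grid.from_dataarray(ds[var])
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: missing or malformed georeferencing: {exc}") from exc
    return grid


def write_grid(
    grid: Grid,
    path: str | Path,
    format_hint: str | None = None,
    name: str = "value",
    attrs: Mapping[str, str] | None = None,
    code_table: Mapping[str, int] | None = None,
) -> None:
    """Write a grid to NetCDF; categorical grids get a JSON sidecar code table.

    Integer-valued grids are written as integers. ``code_table`` (e.g.
    :data:`FACTORY_CODES`) is embedded in the variable attributes and
    mirrored to ``<path>.codes.json``.
    """
    path = Path(path)
    _check_format(path, format_hint)
    da = grid.to_dataarray(name=name)
    if attrs:
        da.attrs.update(attrs)
    encoding = {}
    if code_table is not None:
        da.attrs["code_table"] = json.dumps(dict(code_table))
        Path(str(path) + ".codes.json").write_text(json.dumps(dict(code_table), indent=1))
    if np.issubdtype(grid.values.dtype, np.floating):
        encoding[name] = {"_FillValue": np.float64(-9.969209968386869e36)}
    da.to_dataset().to_netcdf(path, engine="scipy", encoding=encoding)


def write_env_stack(env: EnvStack, path: str | Path) -> None:
    """Write all stack fields into one NetCDF dataset."""
    ds = xr.Dataset({name: g.to_dataarray(name) for name, g in env.grids().items()})
    ds["terrigenous"].attrs["code_table"] = json.dumps({v: k for k, v in TERR_LABELS.items()})
    ds.to_netcdf(Path(path), engine="scipy")


def read_env_stack(path: str | Path) -> EnvStack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with xr.open_dataset(path, engine="scipy") as ds:
        kwargs = {}
        for name in EnvStack.FIELDS:
            if name not in ds:
                raise ValueError(f"{path}: field {name!r} missing from stack")
            kwargs[name] = Grid.from_dataarray(ds[name])
    env = EnvStack(**kwargs)
    env.validate()
    return env


# ---------------------------------------------------------------------------
# co-registration

def _target_axes(grids: Mapping[str, Grid], resolution: float) -> tuple[np.ndarray, np.ndarray]:
    lat_lo = max(float(g.lat.min()) for g in grids.values())
    lat_hi = min(float(g.lat.max()) for g in grids.values())
    lon_lo = max(float(g.lon.min()) for g in grids.values())
    lon_hi = min(float(g.lon.max()) for g in grids.values())
    if lat_lo > lat_hi or lon_lo > lon_hi:
        raise ValueError("input grids do not share a common domain")
    n_lat = int(np.floor((lat_hi - lat_lo) / resolution + 1e-9)) + 1
    n_lon = int(np.floor((lon_hi - lon_lo) / resolution + 1e-9)) + 1
    return lat_lo + resolution * np.arange(n_lat), lon_lo + resolution * np.arange(n_lon)


def _resample(grid: Grid, lat_t: np.ndarray, lon_t: np.ndarray, method: str) -> Grid:
    target = Grid(np.zeros((lat_t.size, lon_t.size)), lat_t, lon_t)
    if grid.same_lattice(target):
        return grid.copy()
    da = grid.to_dataarray().interp(
        lat=lat_t, lon=lon_t, method="linear" if method == "bilinear" else "nearest",
        kwargs={"fill_value": None},
    )
    return Grid(da.values, lat_t, lon_t)


_CONTINUOUS = {"sst_summer", "sst_winter", "prod_summer", "prod_winter", "bathymetry",
               "sss_summer", "sss_winter"}
_CATEGORICAL = {"terrigenous", "sss_class_summer", "sss_class_winter"}


def align_stack(grids: Mapping[str, Grid], target_resolution: float) -> EnvStack:
    """Resample named input grids onto one lattice and assemble an :class:`EnvStack`.

    Continuous fields are resampled bilinearly, categorical fields by
    nearest neighbour. Salinity may be supplied either in psu
    (``sss_summer``/``sss_winter``; reclassified after resampling) or
    already as classes (``sss_class_*``).
    """
    unknown = set(grids) - _CONTINUOUS - _CATEGORICAL
    if unknown:
        raise ValueError(f"unknown field name(s): {sorted(unknown)}")
    lat_t, lon_t = _target_axes(grids, target_resolution)
    out: dict[str, Grid] = {}
    for name, g in grids.items():
        method = "bilinear" if name in _CONTINUOUS else "nearest"
        out[name] = _resample(g, lat_t, lon_t, method)
    for season in ("summer", "winter"):
        psu = out.pop(f"sss_{season}", None)
        if psu is not None:
            out[f"sss_class_{season}"] = psu.like(reclassify_salinity(psu.values))
    missing = [f for f in EnvStack.FIELDS if f not in out]
    if missing:
        raise ValueError(f"stack is incomplete; missing field(s): {missing}")
    env = EnvStack(**{f: out[f] for f in EnvStack.FIELDS})
    env.validate()
    return env


# ---------------------------------------------------------------------------
# reclassification and masks

def reclassify_salinity(psu):
    """Map practical salinity to the ordinal classes 1-8.

    Bins are left-closed, right-open except the open-topped class 8
    (>=37.5 psu): 1: <31.5 | 2: 31.5-33 | 3: 33-34 | 4: 34-35 |
    5: 35-35.5 | 6: 35.5-36.5 | 7: 36.5-37.5 | 8: >=37.5. Values below
    30 psu clamp to class 1 (logged); non-finite values stay missing.
    """
    psu = np.asarray(psu, dtype=float)
    scalar = psu.ndim == 0
    psu = np.atleast_1d(psu)
    finite = np.isfinite(psu)
    if np.any(psu[finite] < 30.0):
        logger.warning(
            "%d salinity value(s) below 30 psu clamped to class 1", int((psu[finite] < 30).sum())
        )
    cls = np.full(psu.shape, np.nan)
    cls[finite] = 1.0 + np.digitize(psu[finite], _SSS_EDGES)
    return float(cls[0]) if scalar else cls


def build_masks(env: EnvStack, params_all: Mapping[str, object]) -> MaskSet:
    """Per-factory eligibility from the bathymetric interval and terrigenous map.

    A cell is eligible for a factory when its depth lies in [0, depth_max],
    the terrigenous category is neither "high" nor "arctic", and "low"
    terrigenous is only allowed for factories that tolerate it. Each
    ``params_all`` value must expose ``depth_max`` and
    ``tolerates_low_terrigenous``.
    """
    z = env.bathymetry.values
    terr = env.terrigenous.values
    finite = np.isfinite(z)
    not_inhibited = np.isin(terr, (TERR_NONE, TERR_LOW))
    masks = MaskSet(
        shelf_100=finite & (z >= 0) & (z <= 100.0),
        shelf_200=finite & (z >= 0) & (z <= 200.0),
    )
    for name, p in params_all.items():
        elig = finite & (z >= 0) & (z <= float(p.depth_max)) & not_inhibited
        if not p.tolerates_low_terrigenous:
            elig &= terr != TERR_LOW
        masks.eligible[name] = elig
    return masks
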