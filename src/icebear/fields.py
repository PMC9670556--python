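"""Gridded environmental fields (wind, tide, scalar rasters) and track containers.

Fields are regular rectangular space-time rasters held in :class:`xarray.Dataset`
objects with dims ``(time, y, x)``; time is hours since a reference datetime,
x/y are km on the local projected plane, and velocities are km/h. Interpolation
is multilinear (bilinear in space, linear in time) through
:class:`scipy.interpolate.RegularGridInterpolator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

DEFAULT_ORIGIN_TIME = np.datetime64("2020-01-05T00:00:00")
#: reference lon/lat used to derive geographic covariates from planar km
DEFAULT_LONLAT_ORIGIN = (-90.5, 58.5)
KM_PER_DEG_LAT = 111.32


@dataclass(frozen=True)
class GridSpec:
    """Regular space-time grid: time in hours, x/y in km."""

    t0: float = 0.0
    dt: float = 1.0
    nt: int = 24
    x0: float = -800.0
    dx: float = 50.0
    nx: int = 33
    y0: float = -800.0
    dy: float = 50.0
    ny: int = 33

    def __post_init__(self):
        if self.dt <= 0 or self.dx <= 0 or self.dy <= 0:
            raise ValueError("grid spacings must be positive")

    @property
    def time(self):
        return self.t0 + self.dt * np.arange(self.nt)

    @property
    def x(self):
        return self.x0 + self.dx * np.arange(self.nx)

    @property
    def y(self):
        return self.y0 + self.dy * np.arange(self.ny)


def _make_interp(coords, values):
    return RegularGridInterpolator(coords, values, method="linear",
                                   bounds_error=True)


class _InterpMixin:
    def _points(self, t_hours, x_km, y_km, clamp):
        t = np.asarray(t_hours, dtype=float)
        x = np.asarray(x_km, dtype=float)
        y = np.asarray(y_km, dtype=float)
        t, x, y = np.broadcast_arrays(t, x, y)
        if clamp:
            tc, yc, xc = self._axes
            t = np.clip(t, tc[0], tc[-1])
            x = np.clip(x, xc[0], xc[-1])
            y = np.clip(y, yc[0], yc[-1])
        else:
            tc, yc, xc = self._axes
            if (t.min() < tc[0] or t.max() > tc[-1] or x.min() < xc[0]
                    or x.max() > xc[-1] or y.min() < yc[0] or y.max() > yc[-1]):
                raise ValueError("query point outside the field extent")
        return np.stack([t, y, x], axis=-1)


@dataclass
class FlowField(_InterpMixin):
    """Space-time vector field (u, v in km/h) of kind wind, tide or ice."""

    ds: xr.Dataset
    kind: str = "wind"

    def __post_init__(self):
        if self.kind not in ("wind", "tide", "ice"):
            raise ValueError(f"unknown flow kind {self.kind!r}")
        t = self.ds["time"].values.astype(float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time axis must be strictly increasing")
        for var in ("u", "v"):
            if not np.all(np.isfinite(self.ds[var].values)):
                raise ValueError(f"non-finite velocities in {var!r}")
        self._axes = (t, self.ds["y"].values.astype(float),
                      self.ds["x"].values.astype(float))
        self._iu = _make_interp(self._axes, self.ds["u"].values)
        self._iv = _make_interp(self._axes, self.ds["v"].values)

    @classmethod
    def from_arrays(cls, grid: GridSpec, u, v, kind="wind",
                    origin_time=DEFAULT_ORIGIN_TIME):
        ds = xr.Dataset(
            {"u": (("time", "y", "x"), np.asarray(u, dtype=float)),
             "v": (("time", "y", "x"), np.asarray(v, dtype=float))},
            coords={"time": grid.time, "y": grid.y, "x": grid.x},
            attrs={"kind": kind, "units": "km h-1",
                   "origin_time": str(origin_time)},
        )
        return cls(ds, kind=kind)

    @property
    def origin_time(self) -> np.datetime64:
        return np.datetime64(self.ds.attrs.get("origin_time",
                                               str(DEFAULT_ORIGIN_TIME)))

    def sample(self, t_hours, x_km, y_km, clamp=True):
        """Velocity (u, v) in km/h at the query points."""
        pts = self._points(t_hours, x_km, y_km, clamp)
        u, v = self._iu(pts), self._iv(pts)
        if pts.ndim == 1:
            return u.item(), v.item()
        return u, v

    def to_netcdf(self, path):
        self.ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path, kind=None):
        ds = xr.load_dataset(path, engine="scipy")
        return cls(ds, kind=kind or ds.attrs.get("kind", "wind"))


@dataclass
class ScalarField(_InterpMixin):
    """Space-time scalar raster (e.g. ice concentration, distance to shore)."""

    ds: xr.Dataset
    name: str = "value"

    def __post_init__(self):
        t = self.ds["time"].values.astype(float)
        self._axes = (t, self.ds["y"].values.astype(float),
                      self.ds["x"].values.astype(float))
        self._iv = _make_interp(self._axes, self.ds[self.name].values)

    @classmethod
    def from_arrays(cls, grid: GridSpec, values, name="value",
                    origin_time=DEFAULT_ORIGIN_TIME):
        values = np.asarray(values, dtype=float)
        if values.ndim == 2:  # static raster: constant in time
            values = np.broadcast_to(values, (2,) + values.shape).copy()
            time = np.array([grid.t0, grid.t0 + grid.dt * max(grid.nt - 1, 1)])
        else:
            time = grid.time
        ds = xr.Dataset({name: (("time", "y", "x"), values)},
                        coords={"time": time, "y": grid.y, "x": grid.x},
                        attrs={"origin_time": str(origin_time)})
        return cls(ds, name=name)

    def sample(self, t_hours, x_km, y_km, clamp=True):
        pts = self._points(t_hours, x_km, y_km, clamp)
        out = self._iv(pts)
        return out.item() if pts.ndim == 1 else out

    def to_netcdf(self, path):
        self.ds.to_netcdf(path, engine="scipy")


@dataclass
class Track:
    """Ordered time-stamped planar locations for one animal.

    ``data`` has columns ``timestamp`` (datetime64, UTC), ``x_km``, ``y_km``
    and, after drift correction, ``drift_dx_km``/``drift_dy_km``.
    """

    animal_id: str
    data: pd.DataFrame
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        req = {"timestamp", "x_km", "y_km"}
        missing = req - set(self.data.columns)
        if missing:
            raise ValueError(f"track missing columns {sorted(missing)}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self):
        return len(self.data)

    @property
    def timestamps(self):
        return pd.DatetimeIndex(self.data["timestamp"])

    @property
    def xy(self):
        return self.data[["x_km", "y_km"]].to_numpy(dtype=float)

    def hours_since(self, origin_time) -> np.ndarray:
        dt = self.timestamps - pd.Timestamp(origin_time)
        return dt.total_seconds().to_numpy() / 3600.0

    def to_csv(self, path):
        out = self.data.copy()
        out.insert(0, "animal_id", self.animal_id)
        for k, v in self.attributes.items():
            out[k] = v
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, attribute_columns=("age", "cubs")):
        df = pd.read_csv(path, parse_dates=["timestamp"])
        tracks = []
        for aid, g in df.groupby("animal_id", sort=False):
            attrs = {c: g[c].iloc[0] for c in attribute_columns
                     if c in g.columns}
            cols = [c for c in g.columns
                    if c not in ("animal_id",) + tuple(attribute_columns)]
            tracks.append(cls(str(aid), g[cols].reset_index(drop=True), attrs))
        return tracks


def local_lonlat(x_km, y_km, origin=DEFAULT_LONLAT_ORIGIN):
    """Approximate lon/lat of local planar km coordinates (equirectangular)."""
    lon0, lat0 = origin
    lat = lat0 + np.asarray(y_km, dtype=float) / KM_PER_DEG_LAT
    lon = lon0 + np.asarray(x_km, dtype=float) / (
        KM_PER_DEG_LAT * np.cos(np.deg2rad(lat0)))
    return lon, lat
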