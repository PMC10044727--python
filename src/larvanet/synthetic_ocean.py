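"""Idealized seasonally reversing coastal-current velocity fields.

The generator emulates the circulation features that drive alongshore larval
transport on the East China Sea shelf: a coastal jet of order 0.1-0.2 m/s
hugging a slanted coastline, strong and equatorward (southward) in winter and
spring, weaker and poleward in summer and autumn, with speeds decaying from
the surface downward and an optional divergence-free eddy perturbation.  It
is deliberately kinematic — no pressure gradients, wind stress or tides — and
exists so that the full release/advection/connectivity pipeline runs and is
testable without an ocean-model hindcast.

Fields are stored as monthly snapshots on a regular lon/lat grid with a small
set of fixed depth layers; `sample_velocity` interpolates bilinearly in the
horizontal, linearly in time, and picks the nearest depth layer (species are
fixed at one living depth, so vertical interpolation buys nothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np
import xarray as xr
from scipy.ndimage import gaussian_filter

from larvanet.errors import InvalidConfigError, OutOfDomainError

#: meters per degree of latitude (and of longitude at the equator); the
#: local equirectangular metric used throughout the package.
M_PER_DEG = 111_320.0


@dataclass(frozen=True)
class SyntheticOceanConfig:
    """Parameters of the synthetic coastal-current generator.

    The coastline is the straight line lon = coast_lon0 + coast_slope *
    (lat - coast_lat0); cells west of it are land.  The alongshore jet has a
    Gaussian cross-shore profile of e-folding ``jet_width_deg`` and peak
    ``core_speed_ms`` at the coast, directed along the coastline tangent.
    During ``southward_months`` the jet runs toward decreasing latitude at
    full strength; in the remaining months it reverses and is scaled by
    ``northward_speed_factor`` (the summer counter-current is weaker).
    """

    lon_min: float = 117.5
    lon_max: float = 126.0
    lat_min: float = 24.0
    lat_max: float = 36.5
    grid_spacing_deg: float = 0.1
    depth_layers_m: tuple[float, ...] = (5.0, 15.0, 30.0, 60.0, 100.0)
    depth_attenuation: tuple[float, ...] = (1.0, 0.85, 0.70, 0.55, 0.40)
    coast_lon0: float = 118.0
    coast_lat0: float = 24.0
    coast_slope: float = 0.3  # deg lon per deg lat
    core_speed_ms: float = 0.15
    jet_width_deg: float = 0.8
    southward_months: tuple[int, ...] = (11, 12, 1, 2, 3, 4)
    northward_speed_factor: float = 0.5
    time_start: str = "2016-01-01"
    n_months: int = 18
    noise_amplitude_ms: float = 0.02
    noise_smoothing_cells: float = 3.0
    seed: int = 0
    speed_cap_ms: float = 3.0

    def coast_lon(self, lat):
        """Longitude of the coastline at latitude ``lat`` (degrees)."""
        return self.coast_lon0 + self.coast_slope * (np.asarray(lat) - self.coast_lat0)

    def validate(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise InvalidConfigError("domain bounds inverted")
        if self.grid_spacing_deg <= 0:
            raise InvalidConfigError("grid spacing must be positive")
        if self.core_speed_ms < 0:
            raise InvalidConfigError("core speed must be >= 0")
        if self.jet_width_deg <= 0:
            raise InvalidConfigError("jet width must be positive")
        if len(self.depth_layers_m) != len(self.depth_attenuation):
            raise InvalidConfigError("one attenuation factor per depth layer")
        if any(not (0 < a <= 1) for a in self.depth_attenuation):
            raise InvalidConfigError("attenuation factors must lie in (0, 1]")
        for lat in (self.lat_min, self.lat_max):
            c = float(self.coast_lon(lat))
            if not (self.lon_min <= c <= self.lon_max):
                raise InvalidConfigError(
                    f"coastline lies outside the domain at lat {lat} (lon {c:.2f})"
                )


@dataclass
class VelocityField:
    """Gridded horizontal velocities with a land mask.

    ``u``/``v`` are eastward/northward velocities in m/s on a
    (time, depth, lat, lon) grid; ``land_mask`` is True on land, where
    velocities are identically zero.
    """

    lon_axis: np.ndarray
    lat_axis: np.ndarray
    depth_axis: np.ndarray
    time_axis: np.ndarray  # datetime64[ns]
    u: np.ndarray
    v: np.ndarray
    land_mask: np.ndarray

    def __post_init__(self):
        for name in ("lon_axis", "lat_axis", "depth_axis"):
            ax = np.asarray(getattr(self, name), dtype=float)
            if ax.ndim != 1 or ax.size < 1 or np.any(np.diff(ax) <= 0):
                raise InvalidConfigError(f"{name} must be 1-D strictly ascending")
            setattr(self, name, ax)
        self.time_axis = np.asarray(self.time_axis, dtype="datetime64[ns]")
        if np.any(np.diff(self.time_axis).astype(np.int64) <= 0):
            raise InvalidConfigError("time_axis must be strictly ascending")
        shape = (self.time_axis.size, self.depth_axis.size,
                 self.lat_axis.size, self.lon_axis.size)
        if self.u.shape != shape or self.v.shape != shape:
            raise InvalidConfigError(f"u/v must have shape {shape}")
        if self.land_mask.shape != shape[2:]:
            raise InvalidConfigError("land_mask must have shape (lat, lon)")

    # -- bounds ------------------------------------------------------------
    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(lon_min, lon_max, lat_min, lat_max) of the grid."""
        return (float(self.lon_axis[0]), float(self.lon_axis[-1]),
                float(self.lat_axis[0]), float(self.lat_axis[-1]))

    def covers_time(self, t0, t1) -> bool:
        t0 = np.datetime64(t0, "ns")
        t1 = np.datetime64(t1, "ns")
        return self.time_axis[0] <= t0 and t1 <= self.time_axis[-1]

    # -- NetCDF round trip -------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "u": (("time", "depth", "lat", "lon"), self.u),
                "v": (("time", "depth", "lat", "lon"), self.v),
                "land_mask": (("lat", "lon"), self.land_mask.astype(np.int8)),
            },
            coords={
                "lon": self.lon_axis,
                "lat": self.lat_axis,
                "depth": self.depth_axis,
                "time": self.time_axis,
            },
            attrs={"Conventions": "CF-like", "title": "larvanet synthetic ocean"},
        )

    def save(self, path) -> None:
        """Write the field as a self-describing NetCDF file."""
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "VelocityField":
        return cls(
            lon_axis=ds["lon"].values.astype(float),
            lat_axis=ds["lat"].values.astype(float),
            depth_axis=ds["depth"].values.astype(float),
            time_axis=ds["time"].values,
            u=ds["u"].values.astype(float),
            v=ds["v"].values.astype(float),
            land_mask=ds["land_mask"].values.astype(bool),
        )

    @classmethod
    def load(cls, path) -> "VelocityField":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


def _month_starts(start: str, n: int) -> np.ndarray:
    t0 = np.datetime64(start, "M")
    return (t0 + np.arange(n)).astype("datetime64[ns]")


def _divergence_free_noise(rng, nlat, nlon, sigma, dlat_m, dlon_m):
    """Streamfunction-derived (u, v) perturbation; divergence-free on the grid."""
    psi = gaussian_filter(rng.standard_normal((nlat, nlon)), sigma=sigma,
                          mode="reflect")
    dpsi_dlat, dpsi_dlon = np.gradient(psi, dlat_m, dlon_m)
    return -dpsi_dlat, dpsi_dlon  # u = -dψ/dy, v = +dψ/dx


def generate_field(config: SyntheticOceanConfig) -> VelocityField:
    """Build the synthetic velocity field described by ``config``.

    Deterministic for a fixed config (including seed): the same config
    always yields bit-identical arrays.
    """
    config.validate()
    lon = np.arange(config.lon_min, config.lon_max + config.grid_spacing_deg / 2,
                    config.grid_spacing_deg)
    lat = np.arange(config.lat_min, config.lat_max + config.grid_spacing_deg / 2,
                    config.grid_spacing_deg)
    depth = np.asarray(config.depth_layers_m, dtype=float)
    times = _month_starts(config.time_start, config.n_months)

    lon2d, lat2d = np.meshgrid(lon, lat)
    coast = config.coast_lon(lat2d)
    land = lon2d < coast
    offshore = lon2d - coast  # degrees seaward of the coastline

    # Gaussian cross-shore jet profile, maximal at the coast.
    profile = np.exp(-0.5 * (offshore / config.jet_width_deg) ** 2)
    profile[land] = 0.0

    # Unit tangent along the coastline toward increasing latitude.
    hyp = float(np.hypot(config.coast_slope, 1.0))
    tang_lon, tang_lat = config.coast_slope / hyp, 1.0 / hyp

    rng = np.random.default_rng(config.seed)
    nlat, nlon = lat.size, lon.size
    u = np.zeros((times.size, depth.size, nlat, nlon))
    v = np.zeros_like(u)
    dlat_m = config.grid_spacing_deg * M_PER_DEG
    dlon_m = config.grid_spacing_deg * M_PER_DEG * np.cos(np.radians(
        0.5 * (config.lat_min + config.lat_max)))

    months = times.astype("datetime64[M]").astype(int) % 12 + 1
    for it, month in enumerate(months):
        if month in config.southward_months:
            amp = -config.core_speed_ms
        else:
            amp = config.core_speed_ms * config.northward_speed_factor
        u_jet = amp * tang_lon * profile
        v_jet = amp * tang_lat * profile
        for iz in range(depth.size):
            att = config.depth_attenuation[iz]
            uu = u_jet * att
            vv = v_jet * att
            if config.noise_amplitude_ms > 0:
                un, vn = _divergence_free_noise(
                    rng, nlat, nlon, config.noise_smoothing_cells, dlat_m, dlon_m)
                rms = np.sqrt(np.mean(un[~land] ** 2 + vn[~land] ** 2)) or 1.0
                scale = config.noise_amplitude_ms * att / rms
                uu = uu + un * scale
                vv = vv + vn * scale
            uu[land] = 0.0
            vv[land] = 0.0
            u[it, iz] = uu
            v[it, iz] = vv

    np.clip(u, -config.speed_cap_ms, config.speed_cap_ms, out=u)
    np.clip(v, -config.speed_cap_ms, config.speed_cap_ms, out=v)
    return VelocityField(lon, lat, depth, times, u, v, land)


class FieldSampler:
    """Vectorized interpolation into a VelocityField.

    Bilinear in lon/lat, linear in time, nearest layer in depth.  Positions
    are clipped to the grid for stencil lookups; bounds policing is the
    caller's job (`sample_velocity` raises, the advection loop flags exits).
    """

    def __init__(self, field: VelocityField):
        self.field = field
        self.t_ns = field.time_axis.astype("datetime64[ns]").astype(np.int64)
        self.lon0 = field.lon_axis[0]
        self.lat0 = field.lat_axis[0]
        self.dlon = float(field.lon_axis[1] - field.lon_axis[0]) \
            if field.lon_axis.size > 1 else 1.0
        self.dlat = float(field.lat_axis[1] - field.lat_axis[0]) \
            if field.lat_axis.size > 1 else 1.0

    def depth_index(self, depth_m: float) -> int:
        return int(np.argmin(np.abs(self.field.depth_axis - depth_m)))

    def time_bracket(self, t_ns: int) -> tuple[int, int, float]:
        ts = self.t_ns
        if ts.size == 1:
            return 0, 0, 0.0
        i = int(np.searchsorted(ts, t_ns, side="right") - 1)
        i = min(max(i, 0), ts.size - 2)
        w = (t_ns - ts[i]) / (ts[i + 1] - ts[i])
        return i, i + 1, float(np.clip(w, 0.0, 1.0))

    def _bilinear(self, grid2d, ix, iy, fx, fy):
        g = grid2d
        return ((1 - fx) * (1 - fy) * g[iy, ix]
                + fx * (1 - fy) * g[iy, ix + 1]
                + (1 - fx) * fy * g[iy + 1, ix]
                + fx * fy * g[iy + 1, ix + 1])

    def uv(self, lon, lat, depth_m: float, t_ns: int):
        """(u, v) in m/s at positions (lon, lat) [arrays], one depth and time."""
        f = self.field
        lon = np.clip(np.asarray(lon, dtype=float), f.lon_axis[0], f.lon_axis[-1])
        lat = np.clip(np.asarray(lat, dtype=float), f.lat_axis[0], f.lat_axis[-1])
        ix = np.clip(((lon - self.lon0) / self.dlon).astype(int), 0,
                     max(f.lon_axis.size - 2, 0))
        iy = np.clip(((lat - self.lat0) / self.dlat).astype(int), 0,
                     max(f.lat_axis.size - 2, 0))
        fx = np.clip((lon - f.lon_axis[ix]) / self.dlon, 0.0, 1.0)
        fy = np.clip((lat - f.lat_axis[iy]) / self.dlat, 0.0, 1.0)
        if f.lon_axis.size == 1:
            ix = np.zeros_like(ix)
            fx = np.zeros_like(fx)
        if f.lat_axis.size == 1:
            iy = np.zeros_like(iy)
            fy = np.zeros_like(fy)
        iz = self.depth_index(depth_m)
        i0, i1, wt = self.time_bracket(t_ns)
        u0 = self._bilinear(f.u[i0, iz], ix, iy, fx, fy)
        v0 = self._bilinear(f.v[i0, iz], ix, iy, fx, fy)
        if wt == 0.0:
            return u0, v0
        u1 = self._bilinear(f.u[i1, iz], ix, iy, fx, fy)
        v1 = self._bilinear(f.v[i1, iz], ix, iy, fx, fy)
        return (1 - wt) * u0 + wt * u1, (1 - wt) * v0 + wt * v1

    def is_land(self, lon, lat):
        """Land-mask value at the nearest grid node to each position."""
        f = self.field
        ix = np.clip(np.rint((lon - self.lon0) / self.dlon).astype(int),
                     0, f.lon_axis.size - 1)
        iy = np.clip(np.rint((lat - self.lat0) / self.dlat).astype(int),
                     0, f.lat_axis.size - 1)
        return f.land_mask[iy, ix]


def sample_velocity(field: VelocityField, lon: float, lat: float,
                    depth: float, time) -> tuple[float, float]:
    """Interpolated (u, v) in m/s at one query point.

    Raises OutOfDomainError when the point is outside the grid bounds or the
    time span; the caller decides the particle's fate.
    """
    lon_min, lon_max, lat_min, lat_max = field.bounds
    if not (lon_min <= lon <= lon_max and lat_min <= lat <= lat_max):
        raise OutOfDomainError(
            f"({lon:.4f}, {lat:.4f}) outside grid "
            f"[{lon_min}, {lon_max}] x [{lat_min}, {lat_max}]")
    t = np.datetime64(time, "ns")
    if not field.covers_time(t, t):
        raise OutOfDomainError(f"time {t} outside field span "
                               f"[{field.time_axis[0]}, {field.time_axis[-1]}]")
    sampler = FieldSampler(field)
    u, v = sampler.uv(np.array([lon]), np.array([lat]), depth,
                      t.astype(np.int64))
    return float(u[0]), float(v[0])
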