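"""Regular latitude-longitude grids and area weighting.

Fields are plain :class:`xarray.DataArray` objects with ``lat``/``lon``
coordinates at cell centers (degrees).  Masked cells are NaN.  Global
integrals use exact spherical cell areas, so every budget in this package
is cos-latitude weighted by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

EARTH_RADIUS_M = 6.371e6


@dataclass(frozen=True)
class GridSpec:
    """Extent and resolution of a regular lat-lon grid.

    The extent must divide into whole cells; coordinates refer to cell
    centers.  The analysis convention is 0.1 deg globally, but any
    resolution works and the test suite runs at 2 deg.
    """

    lat_min: float = -90.0
    lat_max: float = 90.0
    lon_min: float = -180.0
    lon_max: float = 180.0
    resolution: float = 2.0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for lo, hi, name in (
            (self.lat_min, self.lat_max, "lat"),
            (self.lon_min, self.lon_max, "lon"),
        ):
            ncells = (hi - lo) / self.resolution
            if ncells < 1 or abs(ncells - round(ncells)) > 1e-9:
                raise ValueError(
                    f"{name} extent [{lo}, {hi}] does not divide into whole "
                    f"cells at resolution {self.resolution}"
                )

    @property
    def nlat(self) -> int:
        return round((self.lat_max - self.lat_min) / self.resolution)

    @property
    def nlon(self) -> int:
        return round((self.lon_max - self.lon_min) / self.resolution)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def lats(self) -> np.ndarray:
        """Cell-center latitudes, south to north."""
        return self.lat_min + self.resolution * (np.arange(self.nlat) + 0.5)

    @property
    def lons(self) -> np.ndarray:
        return self.lon_min + self.resolution * (np.arange(self.nlon) + 0.5)

    def field(self, values, name: str = "field", units: str = "") -> xr.DataArray:
        """Wrap an array of shape (nlat, nlon) as a grid field."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise ValueError(f"values shape {values.shape} != grid {self.shape}")
        return xr.DataArray(
            values,
            dims=("lat", "lon"),
            coords={"lat": self.lats, "lon": self.lons},
            name=name,
            attrs={"units": units} if units else {},
        )

    def full(self, value: float, name: str = "field", units: str = "") -> xr.DataArray:
        return self.field(np.full(self.shape, float(value)), name, units)

    def cell_index(self, lat, lon) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (ilat, ilon) cell indices.

        Cells are half-open [edge, edge) in both axes; points exactly on the
        maximum edge fall in the last cell.  Points outside the extent raise.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        bad = (
            (lat < self.lat_min) | (lat > self.lat_max)
            | (lon < self.lon_min) | (lon > self.lon_max)
        )
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"point (lat={lat.flat[i]}, lon={lon.flat[i]}) outside grid extent"
            )
        ilat = np.minimum(
            ((lat - self.lat_min) / self.resolution).astype(int), self.nlat - 1
        )
        ilon = np.minimum(
            ((lon - self.lon_min) / self.resolution).astype(int), self.nlon - 1
        )
        return ilat, ilon

    @classmethod
    def from_field(cls, field: xr.DataArray) -> "GridSpec":
        """Recover the spec from a field's cell-center coordinates."""
        lat = np.asarray(field["lat"])
        lon = np.asarray(field["lon"])
        if lat.size < 2 and lon.size < 2:
            raise ValueError(
                "cannot infer grid resolution from a single-cell field; "
                "construct the GridSpec explicitly"
            )
        res = float(lat[1] - lat[0]) if lat.size > 1 else float(lon[1] - lon[0])
        return cls(
            lat_min=float(lat[0]) - res / 2,
            lat_max=float(lat[-1]) + res / 2,
            lon_min=float(lon[0]) - res / 2,
            lon_max=float(lon[-1]) + res / 2,
            resolution=res,
        )


def cell_areas(spec: GridSpec) -> xr.DataArray:
    """Spherical cell areas in m^2: R^2 * dlon * (sin(lat2) - sin(lat1))."""
    res = np.deg2rad(spec.resolution)
    lat_edges = np.deg2rad(spec.lat_min + spec.resolution * np.arange(spec.nlat + 1))
    band = EARTH_RADIUS_M**2 * res * np.diff(np.sin(lat_edges))
    return spec.field(np.repeat(band[:, None], spec.nlon, axis=1), "cell_area", "m2")


def require_aligned(*fields: xr.DataArray) -> None:
    """Raise if the fields do not share identical lat/lon coordinates."""
    ref = fields[0]
    for f in fields[1:]:
        if ref.shape != f.shape or not (
            np.allclose(ref["lat"], f["lat"]) and np.allclose(ref["lon"], f["lon"])
        ):
            raise ValueError("grid fields are not aligned on the same lat/lon grid")


def global_total_tg(flux: xr.DataArray, spec: GridSpec | None = None) -> float:
    """Area-integrate an areal flux (g N m^-2 yr^-1) to Tg N yr^-1."""
    if spec is None:
        spec = GridSpec.from_field(flux)
    area = cell_areas(spec)
    return float((flux * area).sum(skipna=True)) * 1e-12
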