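"""Gridded effect maps: inverse distance weighting onto a 5 km grid.

Each grid cell is the distance-decayed weighted mean of the survey-location
average effects within a 20 km search radius; cells supported by fewer than
the minimum point count are null.  Grids are written as ESRI ASCII rasters
with a companion metadata file naming the scenario and units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import REPORT_YEARS
from .synthetic import SurveyFrame

CENTROID_SNAP_KM = 0.001  # 1 m: a point this close to the centroid wins outright


@dataclass
class GridSpec:
    origin_x: float
    origin_y: float
    cell_size: float
    nx: int
    ny: int

    @classmethod
    def covering(cls, x: np.ndarray, y: np.ndarray, cell_size: float = 5.0, pad: float = 0.0) -> "GridSpec":
        x0, y0 = float(np.min(x)) - pad, float(np.min(y)) - pad
        nx = int(np.ceil((np.max(x) + pad - x0) / cell_size)) + 1
        ny = int(np.ceil((np.max(y) + pad - y0) / cell_size)) + 1
        return cls(x0, y0, cell_size, nx, ny)

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        cx = self.origin_x + (np.arange(self.nx) + 0.5) * self.cell_size
        cy = self.origin_y + (np.arange(self.ny) + 0.5) * self.cell_size
        return cx, cy


@dataclass
class EffectGrid:
    spec: GridSpec
    values: np.ndarray  # (ny, nx), NaN = null
    scenario: str
    units: str = "t C ha-1 yr-1"


def idw_interpolate(
    points: pd.DataFrame,
    grid_spec: GridSpec,
    radius_km: float = 20.0,
    min_points: int = 5,
    power: float = 2.0,
    scenario: str = "",
) -> EffectGrid:
    """Inverse-distance-weighted interpolation of point values onto a grid.

    Cell value = sum(w_i v_i)/sum(w_i) with w_i = d_i^-power over points
    within ``radius_km`` of the cell centroid; cells with fewer than
    ``min_points`` in-radius points are null.  A point within 1 m of the
    centroid short-circuits to its own value.  An empty point set yields an
    all-null grid.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    vals = np.full((grid_spec.ny, grid_spec.nx), np.nan)
    if len(points) == 0:
        return EffectGrid(spec=grid_spec, values=vals, scenario=scenario)
    px = points["x_km"].to_numpy(dtype=float)
    py = points["y_km"].to_numpy(dtype=float)
    pv = points["value"].to_numpy(dtype=float)
    cx, cy = grid_spec.centroids()
    r2 = radius_km**2
    for iy in range(grid_spec.ny):
        dy2 = (py - cy[iy]) ** 2
        near_y = dy2 <= r2
        if not near_y.any():
            continue
        pxn, dy2n, pvn = px[near_y], dy2[near_y], pv[near_y]
        for ix in range(grid_spec.nx):
            d2 = (pxn - cx[ix]) ** 2 + dy2n
            inr = d2 <= r2
            k = int(inr.sum())
            if k < min_points:
                continue
            d = np.sqrt(d2[inr])
            v = pvn[inr]
            snap = d < CENTROID_SNAP_KM
            if snap.any():
                vals[iy, ix] = v[snap][0]
                continue
            w = d ** (-power)
            vals[iy, ix] = float(np.sum(w * v) / np.sum(w))
    return EffectGrid(spec=grid_spec, values=vals, scenario=scenario)


def average_effect_map(
    effects: pd.DataFrame,
    frame: SurveyFrame,
    scenario: str,
    report_years: tuple[int, int] = REPORT_YEARS,
) -> pd.DataFrame:
    """Per-location mean annual effect over the assessment window, joined
    with planar coordinates; locations with partial year coverage are
    excluded with a warning."""
    import warnings

    sub = effects[(effects["scenario"] == scenario)
                  & (effects["year"] >= report_years[0])
                  & (effects["year"] <= report_years[1])]
    n_years = report_years[1] - report_years[0] + 1
    counts = sub.groupby("location_id")["year"].nunique()
    full = counts[counts == n_years].index
    if len(full) < len(counts):
        warnings.warn(f"excluding {len(counts) - len(full)} locations with partial coverage",
                      stacklevel=2)
    means = sub[sub["location_id"].isin(full)].groupby("location_id")["effect"].mean()
    coords = frame.table.set_index("location_id")[["x_km", "y_km"]]
    out = coords.join(means.rename("value"), how="inner").reset_index()
    return out


def write_asc(grid: EffectGrid, path: str, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII raster plus a .meta.txt sidecar with scenario
    and units."""
    spec = grid.spec
    vals = np.where(np.isnan(grid.values), nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.nx}\n")
        fh.write(f"nrows {spec.ny}\n")
        fh.write(f"xllcorner {spec.origin_x}\n")
        fh.write(f"yllcorner {spec.origin_y}\n")
        fh.write(f"cellsize {spec.cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in vals[::-1]:  # ASCII grids run north to south
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")
    with open(path + ".meta.txt", "w") as fh:
        fh.write(f"scenario: {grid.scenario}\nunits: {grid.units}\n")


def read_asc(path: str) -> EffectGrid:
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        k, v = line.split()
        header[k.lower()] = float(v)
    vals = np.loadtxt(lines[6:])
    vals = np.atleast_2d(vals)[::-1]
    vals = np.where(vals == header["nodata_value"], np.nan, vals)
    spec = GridSpec(
        origin_x=header["xllcorner"], origin_y=header["yllcorner"],
        cell_size=header["cellsize"], nx=int(header["ncols"]), ny=int(header["nrows"]),
    )
    return EffectGrid(spec=spec, values=vals, scenario="")
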