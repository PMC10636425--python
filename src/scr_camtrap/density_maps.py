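"""Spatial posterior products.

The posterior distribution of *realised* activity centres (rows with
z = 1 at each retained draw) is summarised two ways: a raster of
expected centres per pixel per draw (with 1-km pixels this is a density
surface in individuals/km2), and a single density for the minimum
convex polygon (MCP) of the trap array — realised centres falling in
the MCP, averaged over draws, divided by the MCP area.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon

from .types import DensityRaster, MCPResult, StateSpace, TrapSite
from .scr_core import _trap_xy

__all__ = ["mcp_polygon", "activity_center_raster", "mcp_density", "raster_to_ascii"]


def mcp_polygon(traps) -> MCPResult:
    """Minimum convex polygon (convex hull) of the trap coordinates."""
    xy = _trap_xy(traps)
    if xy.shape[0] < 3:
        raise ValueError("need at least 3 traps for a convex polygon")
    hull = MultiPoint([tuple(p) for p in xy]).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0.0:
        raise ValueError("traps are collinear; MCP is degenerate")
    verts = np.asarray(hull.exterior.coords)[:-1]
    return MCPResult(vertices=verts, area_km2=float(hull.area))


def _snap_extent(bounds, pixel: float):
    """Expand bounds outward to the pixel-aligned lattice."""
    xmin, ymin, xmax, ymax = bounds
    x0 = math.floor(xmin / pixel) * pixel
    y0 = math.floor(ymin / pixel) * pixel
    nx = max(1, int(math.ceil((xmax - x0) / pixel)))
    ny = max(1, int(math.ceil((ymax - y0) / pixel)))
    return x0, y0, nx, ny


def activity_center_raster(
    draws: Sequence[np.ndarray],
    extent,
    pixel_km: float = 1.0,
) -> DensityRaster:
    """Expected realised activity centres per pixel per posterior draw.

    ``draws`` holds, per retained (thinned) draw, the (n_i, 2) realised
    centres.  ``extent`` is an (xmin, ymin, xmax, ymax) tuple, a
    StateSpace or an MCPResult; the grid is aligned to the integer
    ``pixel_km`` lattice and covers the extent.  Pixel membership is
    half-open, [x0, x0 + pixel) x [y0, y0 + pixel), so pixels partition
    the plane; centres outside the extent are ignored.
    """
    draws = list(draws)
    if len(draws) == 0:
        raise ValueError("no posterior draws provided")
    if pixel_km <= 0:
        raise ValueError("pixel size must be positive")
    if isinstance(extent, StateSpace):
        bounds = extent.bounds
    elif isinstance(extent, MCPResult):
        v = extent.vertices
        bounds = (v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max())
    else:
        bounds = tuple(extent)
    x0, y0, nx, ny = _snap_extent(bounds, pixel_km)

    counts = np.zeros((ny, nx), dtype=float)
    for s in draws:
        s = np.asarray(s, dtype=float).reshape(-1, 2)
        if s.shape[0] == 0:
            continue
        ix = np.floor((s[:, 0] - x0) / pixel_km).astype(int)
        iy = np.floor((s[:, 1] - y0) / pixel_km).astype(int)
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        np.add.at(counts, (iy[ok], ix[ok]), 1.0)
    return DensityRaster(x0=x0, y0=y0, pixel_km=pixel_km, values=counts / len(draws))


def mcp_density(draws: Sequence[np.ndarray], mcp: MCPResult) -> float:
    """Realised-centre density over the MCP, per 100 km2.

    Counts realised activity centres inside the MCP (boundary points
    count as inside) summed over draws, divides by the number of draws,
    then by the MCP area, and scales to 100 km2.
    """
    draws = list(draws)
    if len(draws) == 0:
        raise ValueError("no posterior draws provided")
    if mcp.area_km2 <= 0:
        raise ValueError("degenerate MCP")
    poly = Polygon(mcp.vertices)
    total = 0
    for s in draws:
        s = np.asarray(s, dtype=float).reshape(-1, 2)
        if s.shape[0] == 0:
            continue
        pts = shapely.points(s)
        total += int(shapely.covers(poly, pts).sum())
    return total / len(draws) / mcp.area_km2 * 100.0


def raster_to_ascii(raster: DensityRaster, path) -> None:
    """Write an ESRI ASCII grid (rows north to south)."""
    v = raster.values
    lines = [
        f"ncols {v.shape[1]}",
        f"nrows {v.shape[0]}",
        f"xllcorner {raster.x0}",
        f"yllcorner {raster.y0}",
        f"cellsize {raster.pixel_km}",
        "NODATA_value -9999",
    ]
    for row in v[::-1]:
        lines.append(" ".join(format(x, ".6g") for x in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_ascii_raster(path) -> DensityRaster:
    """Read back an ESRI ASCII grid written by :func:`raster_to_ascii`."""
    with open(path) as fh:
        header = {}
        rows = []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
    values = np.asarray(rows)[::-1]
    return DensityRaster(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        pixel_km=header["cellsize"],
        values=values,
    )


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
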