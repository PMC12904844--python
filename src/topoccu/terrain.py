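"""Terrain variables derived from an elevation grid.

Slope and aspect come from Horn's 8-neighbour finite differences (the moving
window used by essentially every GIS); ruggedness is Riley's Terrain
Ruggedness Index; solar gain is a clear-sky daily insolation model for
tilted surfaces, averaged over twelve representative days (one per month).

All computations skip border cells and any cell whose 3x3 neighbourhood
touches a nodata cell — those cells are returned as NaN rather than filled
by one-sided differences.
"""

from __future__ import annotations

import numpy as np

from .raster import ElevationGrid, TerrainLayer

__all__ = [
    "EmptyBufferError",
    "compute_slope_aspect",
    "compute_tri",
    "compute_solar_gain",
    "buffer_extract",
    "daily_insolation",
    "MONTHLY_MID_DAYS",
]

SOLAR_CONSTANT = 1367.0  # W/m^2


class EmptyBufferError(ValueError):
    """No valid cell center fell inside the requested buffer."""

#: Day-of-year of the 15th of each month (non-leap year).
MONTHLY_MID_DAYS = (15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349)


def _neighbour_stack(grid: ElevationGrid) -> tuple[np.ndarray, np.ndarray]:
    """Interior view of the grid plus its 8 shifted neighbour arrays.

    Returns ``(center, neighbours)`` where ``neighbours`` has shape
    ``(8, nrows-2, ncols-2)`` ordered (NW, N, NE, W, E, SW, S, SE).
    """
    z = np.where(grid.valid, grid.values, np.nan)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("grid must have at least 3x3 cells")
    center = z[1:-1, 1:-1]
    shifts = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    nbrs = np.stack(
        [z[1 + dr : z.shape[0] - 1 + dr, 1 + dc : z.shape[1] - 1 + dc] for dr, dc in shifts]
    )
    return center, nbrs


def compute_slope_aspect(grid: ElevationGrid) -> tuple[TerrainLayer, TerrainLayer]:
    """Slope (degrees) and downslope aspect (degrees clockwise from north).

    Horn's method: with the 3x3 window labelled

        a b c
        d e f
        g h i

    (row 0 north), the eastward and northward gradients at ``e`` are

        dz/dx = ((c + 2f + i) - (a + 2d + g)) / (8 * cell_size)
        dz/dy = ((a + 2b + c) - (g + 2h + i)) / (8 * cell_size)

    Slope is ``atan(hypot(dz/dx, dz/dy))``; aspect is the compass bearing of
    the downslope direction, NaN (undefined) where the gradient is zero.
    Border cells and cells adjacent to nodata are NaN in both layers.
    """
    center, n = _neighbour_stack(grid)
    nw, nn, ne, w, e, sw, s, se = n
    cs = grid.cell_size
    dzdx = ((ne + 2 * e + se) - (nw + 2 * w + sw)) / (8 * cs)
    dzdy = ((nw + 2 * nn + ne) - (sw + 2 * s + se)) / (8 * cs)

    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # downslope vector is -(gradient); bearing measured clockwise from north
    with np.errstate(invalid="ignore"):
        aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect = np.where(np.hypot(dzdx, dzdy) == 0, np.nan, aspect)

    full_slope = np.full(grid.values.shape, np.nan)
    full_aspect = np.full(grid.values.shape, np.nan)
    full_slope[1:-1, 1:-1] = slope
    full_aspect[1:-1, 1:-1] = aspect
    # a nodata cell has no terrain of its own (Horn's window never reads it)
    full_slope[~grid.valid] = np.nan
    full_aspect[~grid.valid] = np.nan
    return (
        TerrainLayer("slope", full_slope, grid),
        TerrainLayer("aspect", full_aspect, grid),
    )


def compute_tri(grid: ElevationGrid) -> TerrainLayer:
    """Riley's Terrain Ruggedness Index.

    For each interior cell: ``sqrt(sum over the 8 neighbours of
    (z_center - z_neighbour)^2)``.
    """
    center, nbrs = _neighbour_stack(grid)
    tri = np.sqrt(np.sum((center[None] - nbrs) ** 2, axis=0))
    full = np.full(grid.values.shape, np.nan)
    full[1:-1, 1:-1] = tri
    return TerrainLayer("ruggedness", full, grid)


def _declination(day_of_year: float) -> float:
    """Solar declination (radians), Cooper's formula."""
    return np.radians(23.45) * np.sin(2 * np.pi * (284 + day_of_year) / 365.0)


def daily_insolation(
    slope_deg: np.ndarray,
    aspect_deg: np.ndarray,
    latitude: float,
    day_of_year: float,
    *,
    transmittance: float = 0.75,
    diffuse_fraction: float = 0.3,
    step_minutes: float = 6.0,
) -> np.ndarray:
    """Clear-sky insolation (Wh/m^2) on tilted surfaces for one day.

    Direct-beam irradiance is ``S0 * tau**m`` (tau = atmospheric
    transmittance per unit air mass, m = 1/cos(zenith)) projected on the
    surface via the cosine of the incidence angle and clamped to zero when
    the sun is below the horizon or behind the surface.  An isotropic
    diffuse term ``diffuse_fraction * S0 * cos(zenith) * (1 - tau**m)``
    is added, scaled by the sky-view factor ``(1 + cos(slope)) / 2``.
    Terrain shadowing is not modelled.

    Flat cells (undefined aspect) are treated as horizontal.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude must be in [-90, 90], got {latitude}")
    beta = np.radians(np.asarray(slope_deg, dtype=float))
    aspect = np.asarray(aspect_deg, dtype=float)
    # surface azimuth measured from south, positive toward west (solar convention)
    gamma = np.radians(np.where(np.isnan(aspect), 0.0, aspect) - 180.0)
    beta = np.where(np.isnan(beta), np.nan, beta)

    phi = np.radians(latitude)
    delta = _declination(day_of_year)

    # per-cell coefficients so cos(incidence) = u1*sin(d) + (u2*cos(w) + u3*sin(w))*cos(d)
    u1 = np.sin(phi) * np.cos(beta) - np.cos(phi) * np.sin(beta) * np.cos(gamma)
    u2 = np.cos(phi) * np.cos(beta) + np.sin(phi) * np.sin(beta) * np.cos(gamma)
    u3 = np.sin(beta) * np.sin(gamma)
    svf = (1.0 + np.cos(beta)) / 2.0

    dt_h = step_minutes / 60.0
    # hour angles at interval midpoints over the full day
    n_steps = int(round(24 * 60 / step_minutes))
    hours = (np.arange(n_steps) + 0.5) * dt_h
    omega = np.radians((hours - 12.0) * 15.0)

    energy = np.zeros(np.broadcast(beta, gamma).shape, dtype=float)
    sin_d, cos_d = np.sin(delta), np.cos(delta)
    for w in omega:
        cos_zen = np.sin(phi) * sin_d + np.cos(phi) * cos_d * np.cos(w)
        if cos_zen <= 0:
            continue  # sun below horizon
        airmass = 1.0 / cos_zen
        dni = SOLAR_CONSTANT * transmittance**airmass
        cos_inc = u1 * sin_d + (u2 * np.cos(w) + u3 * np.sin(w)) * cos_d
        direct = dni * np.maximum(cos_inc, 0.0)
        diffuse = diffuse_fraction * SOLAR_CONSTANT * cos_zen * (1.0 - transmittance**airmass) * svf
        energy += (direct + diffuse) * dt_h
    return energy


def compute_solar_gain(
    slope: TerrainLayer,
    aspect: TerrainLayer,
    latitude: float,
    days: tuple[int, ...] = MONTHLY_MID_DAYS,
    *,
    transmittance: float = 0.75,
    diffuse_fraction: float = 0.3,
    step_minutes: float = 6.0,
) -> TerrainLayer:
    """Mean daily solar gain (Wh/m^2) over representative days.

    Defaults to one cloud-free day per month (the 15th), averaged to an
    annual mean, matching how annual insolation maps are usually built.
    Cells where slope is NaN (border/nodata) are NaN in the result.
    """
    total = np.zeros_like(slope.values)
    for day in days:
        total += daily_insolation(
            slope.values,
            aspect.values,
            latitude,
            day,
            transmittance=transmittance,
            diffuse_fraction=diffuse_fraction,
            step_minutes=step_minutes,
        )
    values = total / len(days)
    values = np.where(np.isnan(slope.values), np.nan, values)
    return TerrainLayer("solar_gain", values, slope.grid)


def buffer_extract(layer: TerrainLayer, point: tuple[float, float], radius: float) -> float:
    """Mean of a layer over cells whose centers fall within ``radius`` of a point.

    For the ``aspect`` layer the circular mean of angles is used (an
    arithmetic mean is wrong across the 0/360 wrap); cells with undefined
    aspect are excluded.  Raises ``ValueError`` if no valid cell lies in
    the buffer.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    x, y = point
    if not layer.grid.contains(x, y):
        raise ValueError(f"point {point} outside grid extent")
    cx, cy = layer.grid.cell_centers()
    inside = (cx - x) ** 2 + (cy - y) ** 2 <= radius**2
    vals = layer.values[inside]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise EmptyBufferError(f"no valid {layer.variable} cell within {radius} m of {point}")
    if layer.variable == "aspect":
        rad = np.radians(vals)
        mean = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0
        return float(mean if mean < 360.0 else 0.0)
    return float(vals.mean())
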