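"""Per-site topographic covariates.

For each camera site the four terrain variables are extracted from the DEM
within a buffer (100 m by default) and averaged — the circular mean for
aspect — then classified into ordered categories whose breakpoints are
natural breaks of the empirical distribution across sites.  Continuous
variables are additionally z-standardized across sites for use as model
covariates.  Landscape-unit labels are taken as input (they come from
geomorphological mapping, not from the DEM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    DEFAULT_CLASS_LABELS,
    SLOPE_LABELS_4,
    ClassificationScheme,
    classify_aspect,
    classify_value,
    jenks_breaks,
)
from .raster import ElevationGrid
from .terrain import (
    EmptyBufferError,
    buffer_extract,
    compute_slope_aspect,
    compute_solar_gain,
    compute_tri,
)

__all__ = ["SiteCovariates", "compute_site_covariates", "LANDSCAPE_UNITS"]

LANDSCAPE_UNITS = (
    "alluvial fans",
    "canyon floors",
    "floodplains",
    "hillslopes",
    "plateaus",
    "valleys",
)

#: Number of natural-breaks classes per continuous variable.
DEFAULT_CLASS_COUNTS = {"slope": 4, "ruggedness": 3, "solar": 4}

CONTINUOUS = ("slope", "ruggedness", "solar")
CATEGORICAL = ("aspect_class", "slope_class", "ruggedness_class", "solar_class", "landscape_unit")


@dataclass
class SiteCovariates:
    """Continuous and classified terrain covariates for every site.

    ``table`` has one row per site with columns ``site_id``, the buffered
    means (``slope_mean``, ``aspect_mean``, ``tri_mean``, ``solar_mean``),
    their z-scores (``slope_z``, ``tri_z``, ``solar_z``), the class columns
    (``aspect_class``, ``slope_class``, ``ruggedness_class``,
    ``solar_class``, ``landscape_unit``), and ``x``/``y`` coordinates.
    """

    table: pd.DataFrame
    schemes: dict[str, ClassificationScheme] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("slope_z", "tri_z", "solar_z"):
            if col in self.table and len(self.table) > 1:
                v = self.table[col].to_numpy(dtype=float)
                if np.all(v == 0):  # constant covariate stays all-zero
                    continue
                if abs(v.mean()) > 1e-9 or abs(v.std(ddof=0) - 1) > 1e-9:
                    raise ValueError(f"{col} is not z-standardized")

    @property
    def site_ids(self) -> list:
        return list(self.table["site_id"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SiteCovariates":
        return cls(table=pd.read_csv(path))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd <= 1e-9 * max(1.0, float(np.abs(x).max())):  # constant up to float noise
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def compute_site_covariates(
    grid: ElevationGrid,
    sites: pd.DataFrame,
    *,
    latitude: float,
    buffer_radius: float = 100.0,
    class_counts: dict[str, int] | None = None,
    landscape_units: pd.Series | dict | None = None,
    transmittance: float = 0.75,
    solar_step_minutes: float = 6.0,
) -> SiteCovariates:
    """Run the full terrain pipeline for a table of sites.

    ``sites`` needs columns ``site_id``, ``x``, ``y`` (projected meters in
    the DEM's coordinate system).  ``landscape_units`` maps site_id to a
    landform label; missing labels are left NaN.  Natural-breaks schemes
    are fitted to the buffered site means (the empirical distribution the
    model actually sees).
    """
    counts = dict(DEFAULT_CLASS_COUNTS)
    if class_counts:
        counts.update(class_counts)

    slope, aspect = compute_slope_aspect(grid)
    tri = compute_tri(grid)
    solar = compute_solar_gain(
        slope, aspect, latitude, transmittance=transmittance, step_minutes=solar_step_minutes
    )

    rows = []
    for rec in sites.itertuples(index=False):
        point = (float(rec.x), float(rec.y))
        rows.append(
            {
                "site_id": rec.site_id,
                "x": point[0],
                "y": point[1],
                "slope_mean": buffer_extract(slope, point, buffer_radius),
                "aspect_mean": _safe_aspect(aspect, point, buffer_radius),
                "tri_mean": buffer_extract(tri, point, buffer_radius),
                "solar_mean": buffer_extract(solar, point, buffer_radius),
            }
        )
    table = pd.DataFrame(rows)

    def scheme_for(values, k, variable, labels=None):
        # a (near-)constant variable cannot support k classes; fall back.
        # differences below float resolution of the data scale do not count
        v = np.sort(np.asarray(values, dtype=float))
        tol = 1e-9 * max(1.0, np.abs(v).max())
        distinct = 1 + int(np.sum(np.diff(v) > tol))
        k = min(k, distinct)
        if k < len(labels or []):
            labels = None
        return jenks_breaks(values, k, labels=labels, variable=variable)

    schemes = {
        "slope": scheme_for(
            table["slope_mean"], counts["slope"], "slope",
            labels=SLOPE_LABELS_4 if counts["slope"] == 4 else None,
        ),
        "ruggedness": scheme_for(table["tri_mean"], counts["ruggedness"], "ruggedness"),
        "solar": scheme_for(table["solar_mean"], counts["solar"], "solar"),
    }
    table["slope_class"] = [classify_value(v, schemes["slope"]) for v in table["slope_mean"]]
    table["ruggedness_class"] = [
        classify_value(v, schemes["ruggedness"]) for v in table["tri_mean"]
    ]
    table["solar_class"] = [classify_value(v, schemes["solar"]) for v in table["solar_mean"]]
    table["aspect_class"] = [classify_aspect(a) for a in table["aspect_mean"]]

    table["slope_z"] = _zscore(table["slope_mean"].to_numpy())
    table["tri_z"] = _zscore(table["tri_mean"].to_numpy())
    table["solar_z"] = _zscore(table["solar_mean"].to_numpy())

    if landscape_units is not None:
        lu = pd.Series(landscape_units)
        table["landscape_unit"] = table["site_id"].map(lu)
    else:
        table["landscape_unit"] = pd.NA

    return SiteCovariates(table=table, schemes=schemes)


def _safe_aspect(aspect_layer, point, radius) -> float:
    """Buffered circular-mean aspect, NaN when every cell in the buffer is flat."""
    try:
        return buffer_extract(aspect_layer, point, radius)
    except EmptyBufferError:
        return float("nan")
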