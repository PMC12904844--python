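"""Synthetic landscapes, communities, and camera-trap surveys.

Everything the pipeline consumes can be generated here with known ground
truth: a sinusoidal ridge-and-valley DEM with smooth random relief, camera
sites spaced >= 1 km apart, per-species occupancy/detection coefficients on
the logit scale, and timestamped photo records emitted in short bursts so
the 30-minute independence filter is exercised realistically.

The default scale loosely mirrors a semi-arid mountain camera-trap study:
131 sites on a 30 m DEM, a few dozen species, five-day occasions.  The
generator does not attempt behavioural realism (diel activity, home
ranges, trap-shyness) — detections are conditionally independent Bernoulli
draws given occupancy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import SiteCovariates, compute_site_covariates
from .detections import Deployment
from .msom import CLASS_COLUMNS, _expit
from .raster import ElevationGrid

__all__ = ["SyntheticTruth", "generate_landscape", "make_truth", "simulate_survey"]

#: study-area latitude emulated by the generator (semi-arid, southern hemisphere)
DEFAULT_LATITUDE = -33.6
DEFAULT_CELL_SIZE = 30.0
MIN_SPACING = 1000.0  # m between cameras


def generate_landscape(
    n_sites: int,
    seed: int,
    *,
    cell_size: float = DEFAULT_CELL_SIZE,
    latitude: float = DEFAULT_LATITUDE,
    relief: float = 180.0,
    flat: bool = False,
    solar_step_minutes: float = 6.0,
) -> tuple[ElevationGrid, SiteCovariates]:
    """Synthetic DEM plus per-site covariates computed through the real pipeline.

    The DEM is a sum of two orthogonal ridge/valley sinusoids and a handful
    of smooth random waves.  Sites sit on a jittered lattice with >= 1 km
    spacing.  Covariates (slope, aspect, TRI, solar gain, classes) are
    produced by :func:`topoccu.covariates.compute_site_covariates`, i.e.
    the same code path real data would take; landscape-unit labels are
    assigned from simple elevation/slope rules.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    rng = np.random.default_rng(seed)

    m = int(np.ceil(np.sqrt(n_sites)))
    spacing = 1.5 * MIN_SPACING  # jitter below keeps pairs >= MIN_SPACING apart
    margin = 300.0
    extent = m * spacing + 2 * margin
    n_cells = int(np.ceil(extent / cell_size))
    xs = (np.arange(n_cells) + 0.5) * cell_size
    ys = (n_cells - np.arange(n_cells) - 0.5) * cell_size
    gx, gy = np.meshgrid(xs, ys)

    if flat:
        z = np.full_like(gx, 500.0)
    else:
        z = (
            relief * np.sin(2 * np.pi * gx / 3500.0)
            + 0.7 * relief * np.sin(2 * np.pi * gy / 5000.0)
            + 0.0002 * gx  # gentle regional tilt
        )
        for _ in range(6):  # smooth random relief
            wl = rng.uniform(1500.0, 6000.0)
            theta = rng.uniform(0, 2 * np.pi)
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(10.0, 45.0)
            z += amp * np.sin(2 * np.pi * (gx * np.cos(theta) + gy * np.sin(theta)) / wl + phase)
        z += 500.0
    grid = ElevationGrid(values=z, cell_size=cell_size, origin=(0.0, 0.0))

    # jittered lattice keeps any two sites >= spacing - 2*jitter >= 1 km apart
    jitter = 0.15 * spacing
    lattice = [(i, j) for i in range(m) for j in range(m)]
    order = rng.permutation(len(lattice))[:n_sites]
    sites = []
    for k, idx in enumerate(order):
        i, j = lattice[idx]
        sites.append(
            {
                "site_id": f"S{k+1:03d}",
                "x": margin + (i + 0.5) * spacing + rng.uniform(-jitter, jitter),
                "y": margin + (j + 0.5) * spacing + rng.uniform(-jitter, jitter),
            }
        )
    site_df = pd.DataFrame(sites)

    covs = compute_site_covariates(
        grid,
        site_df,
        latitude=latitude,
        solar_step_minutes=solar_step_minutes,
        class_counts=None,
    )
    covs.table["landscape_unit"] = _landscape_units(grid, covs.table)
    return grid, covs


def _landscape_units(grid: ElevationGrid, table: pd.DataFrame) -> list[str]:
    """Assign landform labels from site elevation percentile and slope.

    Synthetic stand-in for geomorphological mapping: low flat ground is
    floodplain/valley, low steep ground canyon floor or alluvial fan, high
    ground splits into hillslopes (steep) and plateaus (flat).
    """
    nrows, ncols = grid.shape
    elevs = []
    for rec in table.itertuples(index=False):
        c = min(int(rec.x / grid.cell_size), ncols - 1)
        r = min(int((nrows * grid.cell_size - rec.y) / grid.cell_size), nrows - 1)
        elevs.append(grid.values[r, c])
    elevs = np.asarray(elevs)
    q25, q50 = np.percentile(elevs, [25, 50])
    units = []
    for elev, slope in zip(elevs, table["slope_mean"]):
        if elev < q25:
            units.append("floodplains" if slope < 8 else "canyon floors")
        elif elev < q50:
            units.append("valleys" if slope < 10 else "alluvial fans")
        else:
            units.append("plateaus" if slope < 12 else "hillslopes")
    return units


@dataclass
class SyntheticTruth:
    """Generating parameters of a simulated community.

    ``beta``/``alpha`` are (species x terms) occupancy/detection
    coefficients on the logit scale; ``psi``/``p_site`` are the implied
    probabilities per species x site, and ``z`` the realized occupancy
    states.  Bursts control how each detection is materialized as records.
    """

    species: list[str]
    site_ids: list[str]
    variable: str
    occ_names: list[str]
    det_names: list[str]
    beta: np.ndarray
    alpha: np.ndarray
    psi: np.ndarray      # (S, N)
    p_site: np.ndarray   # (S, N)
    z: np.ndarray        # (S, N)
    seed: int
    burst_max_records: int = 4
    burst_gap_minutes: float = 10.0

    def to_json(self, path) -> None:
        payload = {
            "species": self.species,
            "site_ids": self.site_ids,
            "variable": self.variable,
            "occ_names": self.occ_names,
            "det_names": self.det_names,
            "beta": self.beta.tolist(),
            "alpha": self.alpha.tolist(),
            "psi": self.psi.tolist(),
            "p_site": self.p_site.tolist(),
            "z": self.z.tolist(),
            "seed": self.seed,
            "burst_max_records": self.burst_max_records,
            "burst_gap_minutes": self.burst_gap_minutes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        for key in ("beta", "alpha", "psi", "p_site", "z"):
            d[key] = np.asarray(d[key])
        return cls(**d)


def make_truth(
    covariates: SiteCovariates,
    n_species: int,
    variable: str = "ruggedness",
    seed: int = 0,
    *,
    coef_range: float = 1.5,
    detection_intercept_range: tuple[float, float] = (-1.0, 0.5),
) -> SyntheticTruth:
    """Draw a community of logit-linear species responses to one variable.

    Coefficients are uniform on [-coef_range, coef_range] (detection
    intercepts on ``detection_intercept_range`` so occasion-level p stays
    in a realistic 0.27-0.62 band); occupancy and detection share the
    categorical design, matching the fitted per-variable model.
    """
    rng = np.random.default_rng(seed)
    tab = covariates.table
    col = CLASS_COLUMNS[variable]
    labels = tab[col].astype(str)
    classes = sorted(labels.unique())
    X = np.column_stack(
        [np.ones(len(tab))] + [(labels == c).to_numpy(float) for c in classes[1:]]
    )
    occ_names = ["intercept"] + [f"{variable}[{c}]" for c in classes[1:]]

    S, N, P = n_species, len(tab), X.shape[1]
    beta = rng.uniform(-coef_range, coef_range, (S, P))
    alpha = rng.uniform(-coef_range, coef_range, (S, P))
    alpha[:, 0] = rng.uniform(*detection_intercept_range, S)
    psi = _expit(beta @ X.T)
    p_site = _expit(alpha @ X.T)
    z = (rng.random((S, N)) < psi).astype(np.uint8)

    return SyntheticTruth(
        species=[f"species_{k+1:02d}" for k in range(S)],
        site_ids=list(tab["site_id"]),
        variable=variable,
        occ_names=occ_names,
        det_names=list(occ_names),
        beta=beta,
        alpha=alpha,
        psi=psi,
        p_site=p_site,
        z=z,
        seed=seed,
    )


def simulate_survey(
    truth: SyntheticTruth,
    covariates: SiteCovariates,
    n_occasions: int = 12,
    occasion_length: int = 5,
    *,
    start: date = date(2020, 1, 15),
    gap_probability: float = 0.2,
    end_trim_max_days: int = 3,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[Deployment]]:
    """Simulate a camera survey and materialize detections as photo records.

    Each site runs for ``n_occasions`` five-day occasions from ``start``;
    with probability ``gap_probability`` a site loses one interior occasion
    (camera failure -> zero effort, masked downstream), and the final
    occasion may be trimmed by up to ``end_trim_max_days`` days (fractional
    terminal effort).  Per unmasked occasion, species s is detected with
    probability ``z * p``; a detection becomes a burst of 1-4 records less
    than 30 minutes apart, and bursts are >= 30 minutes from each other, so
    the independence filter recovers exactly one event per detection.
    """
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    tab = covariates.table.set_index("site_id").loc[truth.site_ids]
    S, N = truth.psi.shape

    records = []
    deployments = []
    for i, sid in enumerate(truth.site_ids):
        trim = int(rng.integers(0, end_trim_max_days + 1))
        total_days = n_occasions * occasion_length - trim
        gap_occ = None
        if n_occasions > 2 and rng.random() < gap_probability:
            gap_occ = int(rng.integers(1, n_occasions - 1))
        intervals = []
        if gap_occ is None:
            intervals.append((start, start + timedelta(total_days - 1)))
        else:
            gap_start = gap_occ * occasion_length
            intervals.append((start, start + timedelta(gap_start - 1)))
            resume = gap_start + occasion_length
            if resume < total_days:
                intervals.append(
                    (start + timedelta(resume), start + timedelta(total_days - 1))
                )
        deployments.append(
            Deployment(site_id=sid, x=float(tab.loc[sid, "x"]), y=float(tab.loc[sid, "y"]),
                       intervals=intervals)
        )
        active = deployments[-1].active_days()

        for j in range(n_occasions):
            occ_days = [
                start + timedelta(j * occasion_length + d)
                for d in range(occasion_length)
                if start + timedelta(j * occasion_length + d) in active
            ]
            if not occ_days:
                continue
            det = rng.random(S) < truth.z[:, i] * truth.p_site[:, i]
            for s in np.flatnonzero(det):
                day = occ_days[int(rng.integers(len(occ_days)))]
                hour = int(rng.integers(0, 23))
                minute = int(rng.integers(0, 60))
                t0 = pd.Timestamp(day) + pd.Timedelta(hours=hour, minutes=minute)
                n_rec = int(rng.integers(1, truth.burst_max_records + 1))
                t = t0
                for r in range(n_rec):
                    records.append((sid, truth.species[s], t))
                    t = t + pd.Timedelta(minutes=float(rng.uniform(1, truth.burst_gap_minutes)))

    rec_df = pd.DataFrame(records, columns=["site_id", "species", "timestamp"])
    rec_df = rec_df.sort_values(["site_id", "species", "timestamp"]).reset_index(drop=True)
    return rec_df, deployments
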