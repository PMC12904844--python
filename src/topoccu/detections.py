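"""From raw camera-trap records to detection histories.

Raw records are one row per photograph.  Consecutive records of the same
species at the same site are collapsed into *independent events* using a
rolling 30-minute rule, events are binned into fixed-length sampling
occasions (5 days) tiled over each site's active span, and per-occasion
effort (camera-nights) is tracked so the detection model can absorb uneven
sampling.  Occasions with zero effort are masked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "DetectionHistory",
    "read_records",
    "read_deployments",
    "filter_independent_events",
    "build_detection_history",
    "total_trap_nights",
    "apply_species_inclusion",
]

log = logging.getLogger(__name__)

RECORD_COLUMNS = ("site_id", "species", "timestamp")


@dataclass
class EventTable:
    """Independent capture events: one row per (site, species, event_start)."""

    events: pd.DataFrame  # columns: site_id, species, event_start (datetime64)
    threshold_minutes: float = 30.0

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def species(self) -> list[str]:
        return sorted(self.events["species"].unique())

    def counts_by_species(self) -> pd.Series:
        return self.events.groupby("species").size().sort_index()


@dataclass
class Deployment:
    """One camera site: where it stood and when it was working."""

    site_id: str
    x: float
    y: float
    intervals: list[tuple[date, date]]  # inclusive active date ranges
    functional_nights: float | None = None

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)
        for (s1, e1), (s2, _) in zip(self.intervals, self.intervals[1:]):
            if s2 <= e1:
                raise ValueError(f"site {self.site_id}: overlapping active intervals")
        if self.functional_nights is None:
            self.functional_nights = float(sum((e - s).days + 1 for s, e in self.intervals))
        if self.functional_nights < 0:
            raise ValueError(f"site {self.site_id}: negative functional nights")

    def active_days(self) -> set[date]:
        days: set[date] = set()
        for s, e in self.intervals:
            days.update(s + timedelta(n) for n in range((e - s).days + 1))
        return days


@dataclass
class DetectionHistory:
    """Binary species x site x occasion detections with per-occasion effort.

    ``y[s, i, j]`` is 1 iff at least one independent event of species ``s``
    occurred at site ``i`` during occasion ``j``.  ``effort[i, j]`` counts
    active camera-nights in the occasion (the final occasion of a span may
    be partial); ``mask[i, j]`` is True where the occasion is usable
    (effort > 0).  ``y`` is always 0 on masked-out occasions.
    """

    y: np.ndarray          # (S, N, J) uint8
    effort: np.ndarray     # (N, J) float
    mask: np.ndarray       # (N, J) bool; True = usable
    species: list[str]
    site_ids: list[str]
    occasion_length: int = 5
    occasion_starts: dict[str, date] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.y.shape != (len(self.species), len(self.site_ids), self.effort.shape[1]):
            raise ValueError("y shape inconsistent with species/site/occasion dimensions")
        if np.any(self.y[:, ~self.mask]):
            raise ValueError("detections present in masked occasions")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_occasions(self) -> int:
        return self.y.shape[2]

    def naive_occupancy(self) -> pd.Series:
        """Proportion of sites with >= 1 detection, per species."""
        seen = self.y.any(axis=2).mean(axis=1)
        return pd.Series(seen, index=self.species, name="naive_occupancy")

    def to_wide_frame(self, species: str) -> pd.DataFrame:
        """Wide-format history for one species: sites x occasions, with -1
        marking masked (zero-effort) occasions."""
        s = self.species.index(species)
        arr = self.y[s].astype(int)
        arr = np.where(self.mask, arr, -1)
        return pd.DataFrame(
            arr,
            index=pd.Index(self.site_ids, name="site_id"),
            columns=[f"occ_{j+1}" for j in range(self.n_occasions)],
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (site, species, occasion)."""
        S, N, J = self.y.shape
        idx = pd.MultiIndex.from_product(
            [self.species, self.site_ids, range(J)], names=["species", "site_id", "occasion"]
        )
        df = pd.DataFrame(
            {
                "y": self.y.reshape(-1),
                "effort": np.broadcast_to(self.effort, (S, N, J)).reshape(-1),
                "masked": ~np.broadcast_to(self.mask, (S, N, J)).reshape(-1),
            },
            index=idx,
        )
        return df.reset_index()


def read_records(path) -> pd.DataFrame:
    """Read a capture-record CSV (site_id, species, timestamp ISO 8601)."""
    df = pd.read_csv(path, dtype={"site_id": str})
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file missing columns: {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if ts.isna().any():
        bad = df.loc[ts.isna()].iloc[0]
        raise ValueError(
            f"unparseable timestamp {bad['timestamp']!r} "
            f"(site {bad['site_id']}, species {bad['species']})"
        )
    df = df.assign(timestamp=ts)
    return df


def read_deployments(path) -> list[Deployment]:
    """Read a deployment CSV (site_id, x, y, start_date, end_date[, functional_nights]).

    A site may repeat across rows (multiple sessions); rows are merged into
    one :class:`Deployment` per site with concatenated active intervals.
    """
    df = pd.read_csv(path, dtype={"site_id": str})
    deployments = []
    for site_id, group in df.groupby("site_id", sort=True):
        intervals = [
            (pd.Timestamp(s).date(), pd.Timestamp(e).date())
            for s, e in zip(group["start_date"], group["end_date"])
        ]
        nights = None
        if "functional_nights" in group and group["functional_nights"].notna().all():
            nights = float(group["functional_nights"].sum())
        deployments.append(
            Deployment(
                site_id=site_id,
                x=float(group["x"].iloc[0]),
                y=float(group["y"].iloc[0]),
                intervals=intervals,
                functional_nights=nights,
            )
        )
    return deployments


def filter_independent_events(
    records: pd.DataFrame, threshold_minutes: float = 30.0
) -> EventTable:
    """Collapse raw records into temporally independent events.

    Within each (site, species) stream sorted by time, the first record
    opens an event; each later record opens a new event iff it falls at
    least ``threshold_minutes`` after the *most recent* record of the
    current event (retained or absorbed — the camtrapR "delta time"
    convention); otherwise it is absorbed into the current event and
    becomes the new reference point.
    """
    if threshold_minutes < 0:
        raise ValueError("threshold must be >= 0")
    if not np.issubdtype(records["timestamp"].dtype, np.datetime64):
        records = records.assign(
            timestamp=pd.to_datetime(records["timestamp"], format="ISO8601")
        )
    thr = pd.Timedelta(minutes=threshold_minutes)
    out = []
    for (site, species), group in records.groupby(["site_id", "species"], sort=True):
        times = group["timestamp"].sort_values().to_list()
        last = None
        for t in times:
            if last is None or t - last >= thr:
                out.append((site, species, t))
            last = t
    events = pd.DataFrame(out, columns=["site_id", "species", "event_start"])
    return EventTable(events=events, threshold_minutes=threshold_minutes)


def build_detection_history(
    events: EventTable,
    deployments: list[Deployment],
    occasion_length: int = 5,
    species: list[str] | None = None,
) -> DetectionHistory:
    """Bin independent events into fixed-length occasions per site.

    Occasions tile each site's active span (first to last active day,
    sessions concatenated) in ``occasion_length``-day bins starting at the
    first active day.  Effort per occasion is the number of active nights
    falling in the bin; a partial terminal occasion keeps its partial
    effort.  Bins with zero effort (gaps between sessions) are masked.
    Events outside any active interval are dropped with a warning.
    """
    if not deployments:
        raise ValueError("no deployments given")
    deployments = sorted(deployments, key=lambda d: d.site_id)
    site_ids = [d.site_id for d in deployments]
    site_index = {s: i for i, s in enumerate(site_ids)}
    if species is None:
        species = events.species
    sp_index = {s: k for k, s in enumerate(species)}

    active = {d.site_id: d.active_days() for d in deployments}
    starts = {d.site_id: d.intervals[0][0] for d in deployments}
    spans = {d.site_id: (d.intervals[-1][1] - d.intervals[0][0]).days + 1 for d in deployments}
    n_occ = max(int(np.ceil(spans[s] / occasion_length)) for s in site_ids)

    N, J, S = len(site_ids), n_occ, len(species)
    effort = np.zeros((N, J))
    for i, sid in enumerate(site_ids):
        for day in active[sid]:
            j = (day - starts[sid]).days // occasion_length
            effort[i, j] += 1
    mask = effort > 0

    y = np.zeros((S, N, J), dtype=np.uint8)
    dropped = 0
    for rec in events.events.itertuples(index=False):
        sid = rec.site_id
        if sid not in site_index:
            dropped += 1
            continue
        day = pd.Timestamp(rec.event_start).date()
        if day not in active[sid]:
            dropped += 1
            continue
        if rec.species not in sp_index:
            continue
        j = (day - starts[sid]).days // occasion_length
        y[sp_index[rec.species], site_index[sid], j] = 1
    if dropped:
        log.warning(
            "%d event(s) fell outside their site's active intervals and were dropped", dropped
        )

    return DetectionHistory(
        y=y,
        effort=effort,
        mask=mask,
        species=list(species),
        site_ids=site_ids,
        occasion_length=occasion_length,
        occasion_starts={s: starts[s] for s in site_ids},
    )


def total_trap_nights(deployments: list[Deployment]) -> float:
    """Total survey effort: the sum of functional camera nights."""
    nights = [d.functional_nights for d in deployments]
    if any(n < 0 for n in nights):
        raise ValueError("negative functional nights")
    return float(sum(nights))


def apply_species_inclusion(
    events: EventTable, min_events: int = 5
) -> tuple[list[str], list[str]]:
    """Split species into (modelled, excluded) by independent-event count.

    Species with strictly more than ``min_events`` independent events are
    included in occupancy models; the rest are excluded from modelling but
    remain in descriptive summaries and richness counts.
    """
    if min_events < 0:
        raise ValueError("min_events must be >= 0")
    counts = events.counts_by_species()
    included = sorted(counts[counts > min_events].index)
    excluded = sorted(counts[counts <= min_events].index)
    return included, excluded
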