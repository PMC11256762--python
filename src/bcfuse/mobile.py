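"""Mobile-monitoring aggregation: 1-Hz drive logs to a time-averaged
pollutant × location matrix.

The reduction is the field-standard "median of drive-pass means": 1-Hz points
are snapped to ~30 m road segments, consecutive points on one segment from
one vehicle form a *pass*, each pass is averaged, and each segment's final
value per pollutant is the median over its passes.  Segments visited fewer
than ``min_visits`` times (15 by default) are dropped entirely — too few
repeat visits and the median is not a stable estimate of the time-averaged
concentration.

Input coordinates must already be in a planar metric projection shared with
the road-segment geometries; this module never reprojects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

__all__ = [
    "RoadSegment",
    "SegmentConcentrationMap",
    "snap_to_segments",
    "drive_pass_means",
    "median_of_means",
]

META_COLUMNS = ("timestamp", "vehicle_id", "x", "y", "segment_id")


@dataclass(frozen=True)
class RoadSegment:
    """A short road polyline with a unique id (planar meters)."""

    segment_id: str
    geometry: LineString

    def __post_init__(self) -> None:
        if self.geometry.length <= 0:
            raise ValueError(f"segment {self.segment_id!r} has zero length")

    @property
    def length(self) -> float:
        return self.geometry.length

    @property
    def midpoint(self) -> tuple[float, float]:
        p = self.geometry.interpolate(0.5, normalized=True)
        return (p.x, p.y)


@dataclass
class SegmentConcentrationMap:
    """The pollutant × location matrix of time-averaged concentrations.

    Rows are pollutants, columns are locations (road segments, optionally
    extended with sensor sites by kriging).  ``visit_counts`` holds the
    number of drive passes behind each retained segment (0 for locations
    that were interpolated rather than driven).
    """

    pollutants: list[str]
    locations: list[str]
    values: np.ndarray
    visit_counts: np.ndarray
    coords: np.ndarray | None = None
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.visit_counts = np.asarray(self.visit_counts, dtype=int)
        p, l = self.values.shape
        if len(self.pollutants) != p or len(self.locations) != l:
            raise ValueError("values shape does not match pollutants × locations")
        if len(self.pollutants) < 2:
            raise ValueError("need at least 2 pollutants")
        if self.visit_counts.shape != (l,):
            raise ValueError("visit_counts must have one entry per location")
        if not np.isfinite(self.values).all():
            raise ValueError("map has missing or non-finite cells")
        if (self.values < 0).any():
            raise ValueError("map has negative cells")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (l, 2):
                raise ValueError("coords must be (locations, 2)")

    @property
    def n_pollutants(self) -> int:
        return len(self.pollutants)

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    def location_index(self, ids) -> np.ndarray:
        lookup = {loc: i for i, loc in enumerate(self.locations)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"location {exc.args[0]!r} not in map") from None


def snap_to_segments(
    points: pd.DataFrame,
    segments: list[RoadSegment],
    max_dist: float = 30.0,
) -> pd.Series:
    """Assign each drive point to its nearest road segment.

    Returns a Series of segment ids aligned with ``points`` (NA where no
    segment lies within ``max_dist`` meters).  Ties in distance break
    lexicographically by segment id, so the assignment is deterministic.
    """
    if not segments:
        raise ValueError("empty segment set")
    # sort segments by id up front: stable tie-break falls out of the sort below
    segs = sorted(segments, key=lambda s: s.segment_id)
    tree = STRtree([s.geometry for s in segs])
    pts = shapely.points(points["x"].to_numpy(), points["y"].to_numpy())
    pt_idx, seg_idx = tree.query(pts, predicate="dwithin", distance=max_dist)
    out = pd.Series(pd.NA, index=points.index, dtype="object")
    if len(pt_idx) == 0:
        return out
    dist = shapely.distance(pts[pt_idx], tree.geometries[seg_idx])
    cand = pd.DataFrame({"pt": pt_idx, "seg": seg_idx, "dist": dist})
    # round-off guard so exact geometric ties are true ties
    cand["dist"] = np.round(cand["dist"], 9)
    best = cand.sort_values(["pt", "dist", "seg"]).drop_duplicates("pt")
    out.iloc[best["pt"].to_numpy()] = [segs[i].segment_id for i in best["seg"]]
    return out


def drive_pass_means(points: pd.DataFrame, *, max_gap_s: float = 60.0) -> pd.DataFrame:
    """Group snapped drive points into passes and average each pass.

    A pass is a maximal run of consecutive points from one vehicle on one
    segment with inter-point gaps of at most ``max_gap_s`` seconds; a longer
    gap means the vehicle left and came back, i.e. a fresh visit.  Points
    with no segment assignment are ignored.

    Returns one row per pass with the pass mean of every pollutant column,
    plus ``segment_id``, ``vehicle_id``, ``start`` and ``n_points``.
    """
    pollutant_cols = [c for c in points.columns if c not in META_COLUMNS]
    if "segment_id" not in points.columns:
        raise ValueError("points must carry a segment_id column (run snap_to_segments)")
    pts = points.dropna(subset=["segment_id"]).copy()
    if pts.empty:
        return pd.DataFrame(
            columns=["segment_id", "vehicle_id", "start", "n_points", *pollutant_cols]
        )
    pts["timestamp"] = pd.to_datetime(pts["timestamp"])
    pts = pts.sort_values(["vehicle_id", "timestamp"], kind="stable")
    gap = pts.groupby("vehicle_id")["timestamp"].diff().dt.total_seconds()
    new_pass = (
        gap.isna()
        | (gap > max_gap_s)
        | (pts["segment_id"] != pts["segment_id"].shift())
        | (pts["vehicle_id"] != pts["vehicle_id"].shift())
    )
    pts["pass_id"] = new_pass.cumsum()
    grouped = pts.groupby("pass_id")
    agg = {c: "mean" for c in pollutant_cols}
    agg |= {"segment_id": "first", "vehicle_id": "first", "timestamp": "first"}
    out = grouped.agg(agg)
    out["n_points"] = grouped.size()
    out = out.rename(columns={"timestamp": "start"}).reset_index(drop=True)
    return out[["segment_id", "vehicle_id", "start", "n_points", *pollutant_cols]]


def median_of_means(
    pass_means: pd.DataFrame,
    *,
    min_visits: int = 15,
    pollutants: list[str] | None = None,
    segment_coords: dict[str, tuple[float, float]] | None = None,
) -> SegmentConcentrationMap:
    """Median over pass means per segment; drop thin segments; clip negatives.

    Segments with fewer than ``min_visits`` passes are removed from the map
    entirely (all pollutants — the location set must be common across maps).
    Negative medians, possible when instrument noise dominates a clean
    segment, are clipped to zero and the clip count is logged.
    """
    if min_visits < 1:
        raise ValueError("min_visits must be >= 1")
    if pollutants is None:
        pollutants = [
            c
            for c in pass_means.columns
            if c not in ("segment_id", "vehicle_id", "start", "n_points")
        ]
    counts = pass_means.groupby("segment_id").size()
    keep = counts[counts >= min_visits]
    if keep.empty:
        raise ValueError("no segment meets visit threshold")
    sub = pass_means[pass_means["segment_id"].isin(keep.index)]
    med = sub.groupby("segment_id")[pollutants].median().sort_index()
    values = med.to_numpy().T
    n_neg = int((values < 0).sum())
    if n_neg:
        logger.info("median_of_means: clipped %d negative medians to 0", n_neg)
        values = np.clip(values, 0.0, None)
    locations = list(med.index)
    coords = None
    if segment_coords is not None:
        coords = np.array([segment_coords[s] for s in locations], dtype=float)
    return SegmentConcentrationMap(
        pollutants=list(pollutants),
        locations=locations,
        values=values,
        visit_counts=keep.sort_index().to_numpy(),
        coords=coords,
        n_clipped=n_neg,
    )
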