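"""Model evaluation: error metrics, Lagrangian mobile comparisons,
leave-site-out cross-validation, and the sensitivity experiment drivers.

The model output is spatiotemporally complete while every measurement is
sparse in space and/or time, so each comparison is made at a matched
resolution: Lagrangian windows follow the vehicle's actual path within one
time bin; the campaign-integrated comparison applies the same
median-of-pass-means aggregation to model samples taken along the drive
trajectory; leave-site-out cross-validation refits the fusion without a
random subset of sensor sites and scores the reconstructed time series at
the held-out sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from bcfuse.factorization import nmf
from bcfuse.fusion import BCField, build_sampling_matrix, fit_reprojection, fuse
from bcfuse.kriging import krige_map
from bcfuse.mobile import SegmentConcentrationMap, drive_pass_means, median_of_means
from bcfuse.sensors import SensorMatrix

__all__ = [
    "MetricReport",
    "metrics",
    "lagrangian_compare",
    "campaign_spatial_compare",
    "leave_sites_out_cv",
    "sensitivity_site_count",
    "sensitivity_pollutant_count",
    "car_holdout",
    "temporal_subset_report",
]


@dataclass(frozen=True)
class MetricReport:
    """Standard model-evaluation metrics against observations.

    pearson_r : sample Pearson correlation (NaN when either series has
        zero variance — correlation is undefined there, not zero)
    nmb : normalized mean bias, Σ(pred − obs) / Σ obs
    nmae : normalized mean absolute error, Σ|pred − obs| / Σ obs
    nrmse : RMSE / mean(obs)
    n : number of pairs
    """

    pearson_r: float
    nmb: float
    nmae: float
    nrmse: float
    n: int

    def as_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "nmb": self.nmb,
            "nmae": self.nmae,
            "nrmse": self.nrmse,
            "n": self.n,
        }


def metrics(obs, pred) -> MetricReport:
    """Compute the four standard metrics over paired finite values."""
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must have equal length")
    ok = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[ok], pred[ok]
    n = obs.size
    if n < 2:
        raise ValueError("need at least 2 finite pairs")
    if obs.std() == 0 or pred.std() == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(obs, pred)[0, 1])
    denom = obs.sum()
    if denom == 0:
        nmb = nmae = nrmse = float("nan")
    else:
        nmb = float((pred - obs).sum() / denom)
        nmae = float(np.abs(pred - obs).sum() / denom)
        nrmse = float(np.sqrt(np.mean((pred - obs) ** 2)) / obs.mean())
    return MetricReport(pearson_r=r, nmb=nmb, nmae=nmae, nrmse=nrmse, n=int(n))


def _window_table(
    points: pd.DataFrame,
    field: BCField,
    *,
    bin_width: int,
    min_points: int,
    bc_col: str,
    areawide: bool,
) -> pd.DataFrame:
    pts = points.dropna(subset=["segment_id"]).copy()
    pts = pts[pts["segment_id"].isin(set(field.location_order))]
    if pts.empty:
        raise ValueError("no drive points overlap the field's locations")
    pts["timestamp"] = pd.to_datetime(pts["timestamp"])
    t0 = field.time_bins[0]
    sec = (pts["timestamp"] - t0).dt.total_seconds()
    pts["bin"] = np.floor(sec / (bin_width * 60)).astype(int)
    pts = pts[(pts["bin"] >= 0) & (pts["bin"] < len(field.time_bins))]
    if pts.empty:
        raise ValueError("no drive points overlap the field's time span")
    loc_idx = field.location_index(pts["segment_id"])
    pts["loc_idx"] = loc_idx
    spatial_mean = field.values.mean(axis=0)

    rows = []
    for (veh, b), grp in pts.groupby(["vehicle_id", "bin"]):
        if len(grp) < min_points:
            continue
        segs = grp["loc_idx"].unique()
        predicted = spatial_mean[b] if areawide else field.values[segs, b].mean()
        rows.append(
            {
                "vehicle_id": veh,
                "bin": int(b),
                "window_start": field.time_bins[b],
                "measured_mean": grp[bc_col].mean(),
                "predicted_mean": predicted,
                "n_points": len(grp),
                "n_segments": len(segs),
            }
        )
    if not rows:
        raise ValueError("no window meets the min_points threshold")
    return pd.DataFrame(rows)


def lagrangian_compare(
    points: pd.DataFrame,
    field: BCField,
    *,
    bin_width: int = 15,
    min_points: int = 300,
    bc_col: str = "bc",
    areawide: bool = False,
) -> tuple[pd.DataFrame, MetricReport]:
    """Windowed comparison along the vehicle's sampling path.

    Per (vehicle, time bin): the measured side is the mean of the 1-Hz BC
    points in the window; the predicted side is the mean of the model's
    values at the distinct segments traversed (each segment counted once,
    no dwell-time weighting).  Windows with fewer than ``min_points``
    one-hertz points (default 300 ≈ 5 min of data) are dropped as too thin
    to define a stable window average.

    With ``areawide=True`` the prediction is replaced by the domain-wide
    spatial mean of the field in that bin — the baseline that checks
    whether the model tracks more than the shared urban-background signal.
    """
    table = _window_table(
        points, field, bin_width=bin_width, min_points=min_points, bc_col=bc_col, areawide=areawide
    )
    return table, metrics(table["measured_mean"], table["predicted_mean"])


def campaign_spatial_compare(
    points: pd.DataFrame,
    field: BCField,
    *,
    min_visits: int = 15,
    max_gap_s: float = 60.0,
    bin_width: int = 15,
    bc_col: str = "bc",
) -> tuple[pd.DataFrame, MetricReport]:
    """Campaign-integrated spatial comparison per road segment.

    Measured side: the median-of-pass-means BC map from the drive points.
    Predicted side: for each segment, the median over its passes of the
    model value at (segment, bin of the pass) — i.e. the model sampled
    along the same Lagrangian trajectory, then aggregated identically.
    """
    passes = drive_pass_means(points, max_gap_s=max_gap_s)
    counts = passes.groupby("segment_id").size()
    keep = set(counts[counts >= min_visits].index) & set(field.location_order)
    passes = passes[passes["segment_id"].isin(keep)].copy()
    if passes.empty:
        raise ValueError("no segment meets the visit threshold within the field")
    t0 = field.time_bins[0]
    bins = np.floor(
        (pd.to_datetime(passes["start"]) - t0).dt.total_seconds() / (bin_width * 60)
    ).astype(int)
    in_span = (bins >= 0) & (bins < len(field.time_bins))
    passes, bins = passes[in_span], bins[in_span]
    loc_idx = field.location_index(passes["segment_id"])
    passes["model_value"] = field.values[loc_idx, bins.to_numpy()]
    agg = passes.groupby("segment_id").agg(
        measured_median=(bc_col, "median"), predicted_median=("model_value", "median")
    )
    # same clipping rule as the measured map: a negative median is noise
    agg["measured_median"] = agg["measured_median"].clip(lower=0.0)
    table = agg.reset_index()
    return table, metrics(table["measured_median"], table["predicted_median"])


@dataclass
class CVResult:
    """Leave-site-out cross-validation output."""

    per_site: pd.DataFrame  # iteration, site_id, pearson_r, nmb, nmae, nrmse
    summary: dict

    @property
    def median_r(self) -> float:
        return self.summary["median_r"]


class _FusionCache:
    """Krige + pollutant-map NMF once; only the sensor side changes across
    site subsets (the mobile side never sees the sensor values)."""

    def __init__(
        self,
        segment_map: SegmentConcentrationMap,
        sensor_matrix: SensorMatrix,
        sites: pd.DataFrame | None,
        *,
        k: int,
        rcond: float,
        seed: int,
        nmf_tol: float,
        nmf_max_iter: int,
        variogram_kind: str = "exponential",
    ):
        missing = [s for s in sensor_matrix.sites if s not in segment_map.locations]
        if missing:
            if sites is None:
                raise ValueError("sensor sites absent from map and no site table given")
            sub = sites.set_index("site_id").loc[missing]
            segment_map, _ = krige_map(
                segment_map, missing, sub[["x", "y"]].to_numpy(), kind=variogram_kind
            )
        self.ext_map = segment_map
        self.sensor_matrix = sensor_matrix
        self.k = min(k, min(segment_map.values.shape))
        self.rcond = rcond
        self.seed = seed
        self.nmf_tol = nmf_tol
        self.nmf_max_iter = nmf_max_iter
        self.site_loc_idx = segment_map.location_index(sensor_matrix.sites)
        self._H_L_cache: dict[tuple, np.ndarray] = {}

    def H_L(self, pollutant_idx: tuple[int, ...] | None = None, k: int | None = None) -> np.ndarray:
        key = (pollutant_idx, k)
        if key not in self._H_L_cache:
            X = self.ext_map.values
            if pollutant_idx is not None:
                X = X[list(pollutant_idx)]
            model = nmf(
                X, k or self.k, seed=self.seed, tol=self.nmf_tol, max_iter=self.nmf_max_iter
            )
            self._H_L_cache[key] = model.right
        return self._H_L_cache[key]

    def predict_locations(
        self,
        train_idx: np.ndarray,
        loc_rows: np.ndarray,
        q: int,
        *,
        pollutant_idx: tuple[int, ...] | None = None,
        k: int | None = None,
    ) -> np.ndarray:
        """Refit the sensor-side factorization on the training sites and
        return the reconstructed series at the given location rows of the
        extended map."""
        X_F = self.sensor_matrix.values[train_idx]
        q = min(q, min(X_F.shape))
        sm = nmf(X_F, q, seed=self.seed, tol=self.nmf_tol, max_iter=self.nmf_max_iter)
        H_L = self.H_L(pollutant_idx, k)
        train_sites = [self.sensor_matrix.sites[i] for i in train_idx]
        phi = build_sampling_matrix(train_sites, self.ext_map.locations)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rank warnings expected in bulk refits
            coeff = fit_reprojection(H_L, phi, sm.left, rcond=self.rcond)
        pred = (H_L[:, loc_rows].T @ coeff.matrix) @ sm.right
        return np.clip(pred, 0.0, None)

    def predict_at(
        self,
        train_idx: np.ndarray,
        eval_idx: np.ndarray,
        q: int,
        *,
        pollutant_idx: tuple[int, ...] | None = None,
        k: int | None = None,
    ) -> np.ndarray:
        """Reconstructed series at the sites indexed by ``eval_idx``."""
        return self.predict_locations(
            train_idx, self.site_loc_idx[eval_idx], q, pollutant_idx=pollutant_idx, k=k
        )


def leave_sites_out_cv(
    segment_map: SegmentConcentrationMap,
    sensor_matrix: SensorMatrix,
    sites: pd.DataFrame | None = None,
    *,
    holdout_fraction: float = 0.3,
    n_iter: int = 50,
    seed: int = 0,
    k: int = 5,
    q: int = 16,
    rcond: float = 1e-10,
    nmf_tol: float = 1e-6,
    nmf_max_iter: int = 500,
) -> CVResult:
    """Random leave-sites-out cross-validation of the full fusion.

    Each iteration trains on a random ``1 − holdout_fraction`` subset of
    the sensor sites, refits the sensor-side factorization and the
    reprojection, and scores the reconstructed time series at every
    held-out site (temporal Pearson r plus NMB / NMAE / NRMSE).
    """
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in (0, 1)")
    cache = _FusionCache(
        segment_map, sensor_matrix, sites,
        k=k, rcond=rcond, seed=seed, nmf_tol=nmf_tol, nmf_max_iter=nmf_max_iter,
    )
    s = sensor_matrix.n_sites
    n_hold = max(1, int(round(holdout_fraction * s)))
    if s - n_hold < cache.k:
        raise ValueError(f"training-site count {s - n_hold} < k={cache.k}")
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n_iter):
        perm = rng.permutation(s)
        hold, train = perm[:n_hold], perm[n_hold:]
        pred = cache.predict_at(np.sort(train), np.sort(hold), q)
        for j, si in enumerate(np.sort(hold)):
            rep = metrics(sensor_matrix.values[si], pred[j])
            rows.append({"iteration": it, "site_id": sensor_matrix.sites[si], **rep.as_dict()})
    per_site = pd.DataFrame(rows)
    r = per_site["pearson_r"]
    summary = {
        "median_r": float(r.median()),
        "p10_r": float(r.quantile(0.1)),
        "p90_r": float(r.quantile(0.9)),
        "median_nmb": float(per_site["nmb"].median()),
        "median_nmae": float(per_site["nmae"].median()),
        "median_nrmse": float(per_site["nrmse"].median()),
        "n_iter": n_iter,
        "n_holdout": n_hold,
    }
    return CVResult(per_site=per_site, summary=summary)


def sensitivity_site_count(
    segment_map: SegmentConcentrationMap,
    sensor_matrix: SensorMatrix,
    sites: pd.DataFrame | None = None,
    *,
    site_counts=(10, 20, 30, 40, 50),
    n_iter: int = 20,
    seed: int = 0,
    k: int = 5,
    q: int = 16,
    rcond: float = 1e-10,
    nmf_tol: float = 1e-6,
    nmf_max_iter: int = 500,
) -> pd.DataFrame:
    """Model skill versus the number of (randomly chosen) training sites.

    For each size, ``n_iter`` random training subsets are fitted and the
    held-out-site temporal r distribution is summarized (median and IQR).
    Sizes below the pollutant-side rank k are skipped with a warning.
    """
    cache = _FusionCache(
        segment_map, sensor_matrix, sites,
        k=k, rcond=rcond, seed=seed, nmf_tol=nmf_tol, nmf_max_iter=nmf_max_iter,
    )
    s = sensor_matrix.n_sites
    rng = np.random.default_rng(seed)
    out = []
    for size in site_counts:
        if size < cache.k:
            warnings.warn(f"site count {size} < k={cache.k}; skipped", stacklevel=2)
            continue
        rs = []
        for _ in range(n_iter):
            perm = rng.permutation(s)
            train = np.sort(perm[: min(size, s)])
            hold = np.sort(perm[min(size, s):])
            if hold.size == 0:  # degenerate all-sites subset: score at train sites
                hold = train
            pred = cache.predict_at(train, hold, q)
            for j, si in enumerate(hold):
                rs.append(metrics(sensor_matrix.values[si], pred[j]).pearson_r)
        rs = pd.Series(rs)
        out.append(
            {
                "n_sites": size,
                "median_r": rs.median(),
                "q25_r": rs.quantile(0.25),
                "q75_r": rs.quantile(0.75),
                "n_scores": len(rs),
            }
        )
    return pd.DataFrame(out)


def sensitivity_pollutant_count(
    segment_map: SegmentConcentrationMap,
    sensor_matrix: SensorMatrix,
    sites: pd.DataFrame | None = None,
    *,
    pollutant_counts=None,
    n_iter: int = 10,
    holdout_fraction: float = 0.3,
    seed: int = 0,
    k: int = 5,
    q: int = 16,
    rcond: float = 1e-10,
    nmf_tol: float = 1e-6,
    nmf_max_iter: int = 500,
    bc_name: str = "bc",
) -> pd.DataFrame:
    """Model skill versus the number of pollutants in the mobile maps.

    Every subset must contain BC (the target species).  The pollutant-side
    rank is capped at ``max(1, p_subset − 1)`` so the factorization stays
    meaningful down to the degenerate BC-only case (p = 1, k = 1).
    Skill is the held-out-site temporal r over random site splits.
    """
    cache = _FusionCache(
        segment_map, sensor_matrix, sites,
        k=k, rcond=rcond, seed=seed, nmf_tol=nmf_tol, nmf_max_iter=nmf_max_iter,
    )
    pollutants = cache.ext_map.pollutants
    if bc_name not in pollutants:
        raise ValueError(f"{bc_name!r} not among map pollutants")
    bc_i = pollutants.index(bc_name)
    others = [i for i in range(len(pollutants)) if i != bc_i]
    if pollutant_counts is None:
        pollutant_counts = range(2, len(pollutants) + 1)
    s = sensor_matrix.n_sites
    n_hold = max(1, int(round(holdout_fraction * s)))
    rng = np.random.default_rng(seed)
    out = []
    for count in pollutant_counts:
        if not 1 <= count <= len(pollutants):
            raise ValueError(f"pollutant count {count} out of range")
        rs = []
        for _ in range(n_iter):
            chosen = (bc_i,) if count == 1 else (
                bc_i, *sorted(rng.choice(others, size=count - 1, replace=False).tolist())
            )
            k_c = min(k, max(1, count - 1))
            perm = rng.permutation(s)
            hold, train = np.sort(perm[:n_hold]), np.sort(perm[n_hold:])
            pred = cache.predict_at(train, hold, q, pollutant_idx=chosen, k=k_c)
            for j, si in enumerate(hold):
                rs.append(metrics(sensor_matrix.values[si], pred[j]).pearson_r)
        rs = pd.Series(rs)
        out.append(
            {
                "n_pollutants": count,
                "k_used": min(k, max(1, count - 1)),
                "median_r": rs.median(),
                "q25_r": rs.quantile(0.25),
                "q75_r": rs.quantile(0.75),
                "n_scores": len(rs),
            }
        )
    return pd.DataFrame(out)


def car_holdout(
    points: pd.DataFrame,
    sensor_matrix: SensorMatrix,
    sites: pd.DataFrame,
    held_vehicle: str,
    *,
    segment_coords: dict[str, tuple[float, float]] | None = None,
    min_visits: int = 15,
    k: int = 5,
    q: int = 16,
    min_points: int = 300,
    bc_col: str = "bc",
    seed: int = 0,
    **fuse_kwargs,
) -> tuple[pd.DataFrame, MetricReport]:
    """Train the mobile map on every vehicle except one; evaluate the fused
    model Lagrangian-style against the held vehicle's 1-Hz data."""
    vehicles = points["vehicle_id"].unique()
    if held_vehicle not in vehicles:
        raise ValueError(f"held vehicle {held_vehicle!r} not present")
    if len(vehicles) < 2:
        raise ValueError("need at least 2 vehicles for a car holdout")
    train_pts = points[points["vehicle_id"] != held_vehicle]
    held_pts = points[points["vehicle_id"] == held_vehicle]
    passes = drive_pass_means(train_pts)
    seg_map = median_of_means(passes, min_visits=min_visits, segment_coords=segment_coords)
    model = fuse(seg_map, sensor_matrix, sites, k=k, q=q, seed=seed, **fuse_kwargs)
    return lagrangian_compare(held_pts, model.bc_field, min_points=min_points, bc_col=bc_col)


def temporal_subset_report(
    obs: np.ndarray,
    pred: np.ndarray,
    time_bins: pd.DatetimeIndex,
    *,
    day_window: tuple[int, int] = (9, 16),
) -> dict[str, MetricReport]:
    """Metrics split by weekday/weekend × daytime/nighttime.

    Daytime defaults to local 09:00–16:00 (the mobile-campaign evaluation
    window); all times are local-clock.  The four categories partition the
    time bins; empty categories are simply absent from the result.
    """
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    if obs.shape != pred.shape or obs.shape[1] != len(time_bins):
        raise ValueError("obs/pred must be (series, time) aligned with time_bins")
    hours = time_bins.hour
    day = (hours >= day_window[0]) & (hours < day_window[1])
    weekday = time_bins.dayofweek < 5
    masks = {
        "weekday_day": weekday & day,
        "weekday_night": weekday & ~day,
        "weekend_day": ~weekday & day,
        "weekend_night": ~weekday & ~day,
    }
    out = {}
    for name, mask in masks.items():
        if mask.sum() < 2:
            continue
        out[name] = metrics(obs[:, mask], pred[:, mask])
    return out
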