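"""Fixed-site sensor preprocessing: raw black-carbon series to a complete
site × time matrix.

Raw low-cost-sensor BC streams (native 0.5 Hz, or any regular cadence) are
averaged into half-open time bins ``[start, start + width)`` of a fixed width
(default 15 min), then interior gaps are filled by linear interpolation in
time so the downstream factorization sees a complete matrix.  All timestamps
are treated as local standard time: day/night and weekday/weekend subsetting
are local-clock concepts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["SensorMatrix", "bin_series", "impute_gaps"]


@dataclass
class SensorMatrix:
    """Site × time matrix of binned BC concentrations (µg/m³).

    ``values[i, j]`` is the mean BC at ``sites[i]`` during the half-open bin
    starting at ``time_bins[j]``; NaN marks a bin that failed the coverage
    rule and has not yet been imputed.  ``observed_mask`` is True exactly
    where the value came from data rather than imputation.
    """

    sites: list[str]
    time_bins: pd.DatetimeIndex
    bin_width: int
    values: np.ndarray
    observed_mask: np.ndarray
    imputed_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        s, t = self.values.shape
        if len(self.sites) != s or len(self.time_bins) != t:
            raise ValueError("values shape does not match sites × time_bins")
        if self.observed_mask.shape != (s, t):
            raise ValueError("observed_mask shape mismatch")
        if 1440 % self.bin_width:
            raise ValueError("bin_width must divide 1440 minutes")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_bins(self) -> int:
        return len(self.time_bins)

    @property
    def is_complete(self) -> bool:
        return bool(np.isfinite(self.values).all())

    def subset_sites(self, idx) -> "SensorMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            sites=[self.sites[i] for i in idx],
            values=self.values[idx],
            observed_mask=self.observed_mask[idx],
            imputed_fraction=self.imputed_fraction[idx],
        )


def bin_series(
    raw: pd.DataFrame,
    *,
    bin_width: int = 15,
    min_coverage: float = 0.5,
    sample_interval_s: float | None = None,
    start: pd.Timestamp | str | None = None,
    days: int | None = None,
) -> SensorMatrix:
    """Average raw ``(site_id, timestamp, bc_ugm3)`` samples into time bins.

    A bin is kept only when the fraction of expected raw samples present is
    at least ``min_coverage`` (expected count = bin seconds / sampling
    interval; the interval is inferred per site from the median timestamp
    spacing when not given).  Negative raw values participate in the mean,
    after which bin values are clipped at zero — sub-zero readings in
    low-cost optical BC data are instrument noise, not concentrations.

    The campaign window is ``days`` whole days from ``start`` (midnight of
    the earliest sample by default), so the output always has exactly
    ``days * 1440 / bin_width`` columns regardless of data gaps.
    """
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    if 1440 % bin_width:
        raise ValueError("bin_width must divide 1440 minutes")
    required = {"site_id", "timestamp", "bc_ugm3"}
    if missing := required - set(raw.columns):
        raise ValueError(f"raw series missing columns: {sorted(missing)}")
    raw = raw.copy()
    raw["timestamp"] = pd.to_datetime(raw["timestamp"])
    counts_per_site = raw.groupby("site_id").size()
    empty = counts_per_site[counts_per_site == 0]
    if raw.empty:
        raise ValueError("no raw samples supplied")

    if start is None:
        start = raw["timestamp"].min().normalize()
    start = pd.Timestamp(start)
    if days is None:
        days = int(np.ceil(((raw["timestamp"].max() - start) / pd.Timedelta(days=1))))
        days = max(days, 1)
    n_bins = days * (1440 // bin_width)
    time_bins = pd.date_range(start, periods=n_bins, freq=f"{bin_width}min")

    sites = sorted(raw["site_id"].unique())
    values = np.full((len(sites), n_bins), np.nan)
    mask = np.zeros((len(sites), n_bins), dtype=bool)
    bin_seconds = bin_width * 60

    for i, site in enumerate(sites):
        sub = raw[raw["site_id"] == site]
        if sub.empty:
            raise ValueError(f"site {site!r} has zero raw samples")
        if sample_interval_s is None:
            if len(sub) < 2:
                raise ValueError(
                    f"site {site!r}: cannot infer sampling interval from one sample; "
                    "pass sample_interval_s"
                )
            interval = float(np.median(np.diff(np.sort(sub["timestamp"].values)) / np.timedelta64(1, "s")))
        else:
            interval = float(sample_interval_s)
        expected = bin_seconds / interval
        offset_s = (sub["timestamp"] - start) / pd.Timedelta(seconds=1)
        bin_idx = np.floor(offset_s / bin_seconds).astype(int)
        in_range = (bin_idx >= 0) & (bin_idx < n_bins)
        bin_idx = bin_idx[in_range]
        vals = sub["bc_ugm3"].to_numpy()[in_range.to_numpy()]
        sums = np.bincount(bin_idx, weights=vals, minlength=n_bins)
        counts = np.bincount(bin_idx, minlength=n_bins)
        ok = counts / expected >= min_coverage
        with np.errstate(invalid="ignore"):
            means = np.where(ok, sums / np.maximum(counts, 1), np.nan)
        values[i] = np.clip(means, 0.0, None, where=ok, out=means)
        mask[i] = ok

    if empty.size:  # pragma: no cover - groupby drops empty groups; defensive
        raise ValueError(f"sites with zero raw samples: {list(empty.index)}")
    return SensorMatrix(
        sites=sites,
        time_bins=time_bins,
        bin_width=bin_width,
        values=values,
        observed_mask=mask,
        imputed_fraction=np.zeros(len(sites)),
    )


def impute_gaps(matrix: SensorMatrix, *, min_observed: float = 0.8) -> SensorMatrix:
    """Fill unobserved bins so the matrix is complete.

    Interior gaps are linearly interpolated in time per site; leading and
    trailing gaps take the site's observed median (no extrapolation).  Sites
    with less than ``min_observed`` of their bins observed are rejected —
    their temporal structure is too thin to impute honestly.
    """
    frac = matrix.observed_mask.mean(axis=1)
    bad = [s for s, f in zip(matrix.sites, frac) if f < min_observed]
    if bad:
        raise ValueError(
            f"sites below the {min_observed:.0%} observed threshold: {bad}"
        )
    values = matrix.values.copy()
    t = np.arange(matrix.n_bins, dtype=float)
    for i in range(matrix.n_sites):
        obs = matrix.observed_mask[i]
        if obs.all():
            continue
        v = values[i]
        med = float(np.median(v[obs]))
        filled = np.interp(t, t[obs], v[obs], left=med, right=med)
        # np.interp clamps interior edges too; restore observed cells bit-exactly
        filled[obs] = v[obs]
        first, last = np.argmax(obs), matrix.n_bins - 1 - np.argmax(obs[::-1])
        filled[:first] = med
        filled[last + 1 :] = med
        values[i] = filled
    return replace(
        matrix,
        values=values,
        imputed_fraction=1.0 - frac,
    )
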