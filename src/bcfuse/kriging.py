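"""Ordinary kriging of segment-level pollutant maps to sensor-site locations.

The fusion model needs the mobile pollutant maps and the sensor matrix to
share locations, so each pollutant's segment map is extended to the sensor
sites with ordinary kriging: a variogram is fitted per pollutant to the
segment values (weighted least squares over the empirical semivariances) and
the kriging system is solved with a global neighborhood — a few hundred
segments is small enough that no search-radius truncation is needed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform

from bcfuse.mobile import SegmentConcentrationMap

logger = logging.getLogger(__name__)

__all__ = [
    "VariogramModel",
    "EmpiricalVariogram",
    "KrigeResult",
    "empirical_variogram",
    "fit_variogram",
    "ordinary_krige",
    "krige_map",
]

_KINDS = ("exponential", "spherical", "gaussian")


@dataclass(frozen=True)
class VariogramModel:
    """Isotropic variogram γ(h) = nugget + partial_sill · g(h / range).

    ``g`` is 1 − exp(−h/a) (exponential), the spherical polynomial, or
    1 − exp(−(h/a)²) (gaussian). Units: nugget and partial_sill in
    concentration², range in meters.
    """

    kind: str
    nugget: float
    partial_sill: float
    range_: float

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_ <= 0:
            raise ValueError("need nugget >= 0, partial_sill >= 0, range > 0")

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        r = self.range_
        if self.kind == "exponential":
            g = 1.0 - np.exp(-h / r)
        elif self.kind == "gaussian":
            g = 1.0 - np.exp(-((h / r) ** 2))
        else:  # spherical
            hr = np.minimum(h / r, 1.0)
            g = 1.5 * hr - 0.5 * hr**3
        out = self.nugget + self.partial_sill * g
        return np.where(h == 0, 0.0, out)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "VariogramModel":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class EmpiricalVariogram:
    lag_centers: np.ndarray
    semivariances: np.ndarray
    pair_counts: np.ndarray


def empirical_variogram(
    coords: np.ndarray,
    values: np.ndarray,
    *,
    n_lags: int = 15,
    max_lag: float | None = None,
) -> EmpiricalVariogram:
    """Distance-binned semivariances γ(h) = mean of ½(zᵢ − zⱼ)² over pairs.

    Bins with no pairs are omitted.  ``max_lag`` defaults to half the
    maximum pairwise distance (the usual reliability rule of thumb).
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least 2 points")
    d = pdist(coords)
    if np.all(d == 0):
        raise ValueError("all pairwise distances are zero")
    if max_lag is None:
        max_lag = float(d.max()) / 2.0
    if max_lag <= 0:
        raise ValueError("max_lag must be > 0")
    dv = pdist(values[:, None], metric="sqeuclidean") / 2.0
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    which = np.digitize(d, edges[1:-1])
    in_range = d <= max_lag
    counts = np.bincount(which[in_range], minlength=n_lags)
    sums = np.bincount(which[in_range], weights=dv[in_range], minlength=n_lags)
    keep = counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(
        lag_centers=centers[keep],
        semivariances=sums[keep] / counts[keep],
        pair_counts=counts[keep],
    )


def fit_variogram(emp: EmpiricalVariogram, kind: str = "exponential") -> VariogramModel:
    """Weighted least-squares variogram fit (weights = pair counts).

    Deterministic given the empirical curve: a single bounded
    least-squares solve from moment-based starting values.
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}")
    h, g, w = emp.lag_centers, emp.semivariances, emp.pair_counts
    if len(h) < 3:
        raise ValueError("need at least 3 non-empty lag bins")
    sill0 = max(float(np.mean(g[-max(1, len(g) // 3):])), 1e-12)
    nugget0 = max(float(g[0]) if h[0] < h[-1] / 4 else 0.0, 0.0)
    nugget0 = min(nugget0, sill0)
    range0 = float(h[-1]) / 3.0
    sw = np.sqrt(w.astype(float))

    def resid(theta):
        nug, psill, rng = theta
        m = VariogramModel(kind=kind, nugget=nug, partial_sill=psill, range_=max(rng, 1e-9))
        return sw * (m(h) - g)

    res = least_squares(
        resid,
        x0=[nugget0, max(sill0 - nugget0, 1e-12), range0],
        bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
        method="trf",
    )
    if not res.success:
        raise RuntimeError(
            f"variogram fit failed ({res.message}); empirical curve: "
            f"h={h.tolist()}, gamma={g.tolist()}"
        )
    nug, psill, rng = res.x
    return VariogramModel(kind=kind, nugget=float(nug), partial_sill=float(psill), range_=float(rng))


@dataclass(frozen=True)
class KrigeResult:
    predictions: np.ndarray
    variances: np.ndarray
    weights: np.ndarray  # (n_train, n_query) kriging weights
    n_clipped: int


def ordinary_krige(
    train_coords: np.ndarray,
    train_values: np.ndarray,
    model: VariogramModel,
    query_coords: np.ndarray,
) -> KrigeResult:
    """Solve the ordinary-kriging system for every query point.

    The semivariance system with the unbiasedness constraint (weights sum
    to one, enforced via a Lagrange multiplier) is assembled once for the
    training set and solved against all query right-hand sides together.
    With a zero nugget this is an exact interpolator at training locations.
    Negative predictions are clipped to zero and counted.
    """
    train_coords = np.asarray(train_coords, dtype=float)
    query_coords = np.asarray(query_coords, dtype=float)
    z = np.asarray(train_values, dtype=float)
    n = len(train_coords)
    if n < 2:
        raise ValueError("need at least 2 training points")
    dists = squareform(pdist(train_coords))
    if (dists[np.triu_indices(n, 1)] == 0).any():
        raise ValueError("coincident training points; deduplicate first")
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = model(dists)
    A[n, :n] = A[:n, n] = 1.0
    A[n, n] = 0.0
    b = np.empty((n + 1, len(query_coords)))
    b[:n] = model(cdist(train_coords, query_coords))
    b[n] = 1.0
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular kriging system; jitter coincident points or add a nugget"
        ) from exc
    w, mu = sol[:n], sol[n]
    pred = w.T @ z
    var = np.einsum("ij,ij->j", w, b[:n]) + mu
    n_clip = int((pred < 0).sum())
    if n_clip:
        logger.info("ordinary_krige: clipped %d negative predictions to 0", n_clip)
        pred = np.clip(pred, 0.0, None)
    return KrigeResult(predictions=pred, variances=var, weights=w, n_clipped=n_clip)


def krige_map(
    seg_map: SegmentConcentrationMap,
    site_ids: list[str],
    site_coords: np.ndarray,
    *,
    kind: str = "exponential",
    n_lags: int = 15,
    max_lag: float | None = None,
    coincident_tol: float = 1.0,
) -> tuple[SegmentConcentrationMap, dict[str, VariogramModel]]:
    """Extend a segment map to sensor sites, one independent kriging per
    pollutant, returning the combined segments + sites map and the fitted
    variograms (exportable for provenance).

    Sites within ``coincident_tol`` meters of a segment location simply copy
    that segment's value — they are the same place at 30 m resolution, and
    a coincident query would otherwise defeat the exact-interpolation path.
    """
    if seg_map.coords is None:
        raise ValueError("segment map has no coordinates; cannot krige")
    site_coords = np.asarray(site_coords, dtype=float)
    d_site_seg = cdist(site_coords, seg_map.coords)
    nearest = d_site_seg.argmin(axis=1)
    coincident = d_site_seg[np.arange(len(site_ids)), nearest] < coincident_tol
    far_idx = np.nonzero(~coincident)[0]

    p = seg_map.n_pollutants
    site_values = np.empty((p, len(site_ids)))
    variograms: dict[str, VariogramModel] = {}
    for pi, pol in enumerate(seg_map.pollutants):
        vals = seg_map.values[pi]
        emp = empirical_variogram(seg_map.coords, vals, n_lags=n_lags, max_lag=max_lag)
        model = fit_variogram(emp, kind=kind)
        variograms[pol] = model
        if far_idx.size:
            res = ordinary_krige(seg_map.coords, vals, model, site_coords[far_idx])
            site_values[pi, far_idx] = res.predictions
        site_values[pi, coincident] = vals[nearest[coincident]]

    return (
        SegmentConcentrationMap(
            pollutants=list(seg_map.pollutants),
            locations=list(seg_map.locations) + list(site_ids),
            values=np.hstack([seg_map.values, site_values]),
            visit_counts=np.concatenate(
                [seg_map.visit_counts, np.zeros(len(site_ids), dtype=int)]
            ),
            coords=np.vstack([seg_map.coords, site_coords]),
            n_clipped=seg_map.n_clipped,
        ),
        variograms,
    )
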