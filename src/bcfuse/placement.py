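"""Data-driven sensor placement via pivoted QR on a spatial basis.

Following the compressive-sensing placement literature, the candidate
locations' rows of a low-rank spatial basis (leading left singular vectors
of a location × time data matrix) are ranked by QR column pivoting of the
basis transpose: the first m pivots are the m locations that best condition
the inversion from m point samples back to the basis coefficients — a
greedy determinant surrogate for the combinatorial optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr

from bcfuse.evaluation import _FusionCache, metrics
from bcfuse.mobile import SegmentConcentrationMap
from bcfuse.sensors import SensorMatrix

__all__ = ["PlacementResult", "svd_basis", "qr_pivot_select", "placement_benchmark"]


@dataclass(frozen=True)
class PlacementResult:
    """Chosen location indices, in selection (pivot) order."""

    indices: np.ndarray
    basis: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.indices.tolist())) != len(self.indices):
            raise ValueError("selected indices must be distinct")


def svd_basis(data: np.ndarray, r: int) -> np.ndarray:
    """Leading ``r`` left singular vectors of a location × time matrix."""
    if not 1 <= r <= min(data.shape):
        raise ValueError(f"r must be in [1, {min(data.shape)}]")
    U, _, _ = np.linalg.svd(np.asarray(data, dtype=float), full_matrices=False)
    return U[:, :r]


def qr_pivot_select(
    basis: np.ndarray,
    m: int,
    *,
    data: np.ndarray | None = None,
    pad: bool = False,
) -> PlacementResult:
    """Select ``m`` measurement locations by pivoted QR on ``basisᵀ``.

    ``basis`` is locations × r.  scipy's Householder QR pivots on the
    largest remaining column norm, so repeated calls agree exactly.  For
    m > r the selection continues with a D-optimal greedy (largest-leverage
    row first), since QR residuals are all zero once the basis rank is
    exhausted.  With ``pad=True`` the basis is instead padded to m left
    singular vectors of ``data`` before pivoting; only advisable when the
    trailing singular vectors still carry signal rather than noise.
    """
    basis = np.asarray(basis, dtype=float)
    n_loc, r = basis.shape
    if m > n_loc:
        raise ValueError(f"cannot place {m} sensors over {n_loc} locations")
    if m < 1:
        raise ValueError("m must be >= 1")
    if pad and m > r:
        if data is None:
            raise ValueError("pad=True with m > basis rank requires `data`")
        basis = svd_basis(data, min(m, min(data.shape)))
        r = basis.shape[1]
    _, _, piv = qr(basis.T, pivoting=True, mode="economic")
    chosen = list(piv[: min(m, r)])
    if m > r:
        # QR residuals vanish once the basis rank is exhausted, so the pivot
        # order beyond r is numerically arbitrary; continue with a D-optimal
        # greedy instead: add the row of largest leverage x M⁻¹ xᵀ, which
        # maximizes the determinant gain of the information matrix BᵀSᵀSB
        M = basis[chosen].T @ basis[chosen] + 1e-12 * np.eye(r)
        remaining = np.array([i for i in range(n_loc) if i not in set(chosen)])
        for _ in range(m - len(chosen)):
            Minv = np.linalg.inv(M)
            lev = np.einsum("ij,jk,ik->i", basis[remaining], Minv, basis[remaining])
            j = int(np.argmax(lev))  # argmax takes the first index on ties
            x = basis[remaining[j]]
            M = M + np.outer(x, x)
            chosen.append(int(remaining[j]))
            remaining = np.delete(remaining, j)
    return PlacementResult(indices=np.asarray(chosen), basis=basis)


def placement_benchmark(
    segment_map: SegmentConcentrationMap,
    sensor_matrix: SensorMatrix,
    sites: pd.DataFrame | None = None,
    *,
    truth_at_segments: np.ndarray | None = None,
    m_values=(10, 20, 30, 40),
    n_random: int = 10,
    basis_rank: int = 8,
    seed: int = 0,
    k: int = 5,
    q: int = 8,
    match_tolerance: float = 0.25,
    nmf_tol: float = 1e-6,
    nmf_max_iter: int = 500,
    rcond: float = 1e-10,
) -> dict:
    """Optimal (QR-pivot) versus random sensor placement.

    For each network size m, the fusion is refitted using only the chosen
    (resp. randomly chosen, ``n_random`` draws) sensor sites and scored by
    held-out-location reconstruction: relative Frobenius error of the
    reconstructed field against ``truth_at_segments`` (locations × time,
    aligned with the map's segment locations) over segments that host no
    sensor, plus the mean temporal r at the unused sensor sites.  Returns
    both curves and the smallest m whose optimal-placement error is within
    a relative ``match_tolerance`` of the all-sites model's error.
    """
    cache = _FusionCache(
        segment_map, sensor_matrix, sites,
        k=k, rcond=rcond, seed=seed, nmf_tol=nmf_tol, nmf_max_iter=nmf_max_iter,
    )
    s = sensor_matrix.n_sites
    basis_rank = min(basis_rank, min(sensor_matrix.values.shape))
    basis = svd_basis(sensor_matrix.values, basis_rank)
    rng = np.random.default_rng(seed)
    all_idx = np.arange(s)
    site_set = set(sensor_matrix.sites)
    segment_rows = np.asarray(
        [i for i, loc in enumerate(cache.ext_map.locations) if loc not in site_set]
    )

    def score(train: np.ndarray) -> float:
        if truth_at_segments is not None:
            # spatial gap-fill skill: error against truth at non-sensor segments
            pred = cache.predict_locations(train, segment_rows, q)
            t = truth_at_segments
            return float(np.linalg.norm(pred - t) / np.linalg.norm(t))
        held = np.setdiff1d(all_idx, train)
        eval_idx = held if held.size else train
        pred = cache.predict_at(train, eval_idx, q)
        rs = [metrics(sensor_matrix.values[si], pred[j]).pearson_r for j, si in enumerate(eval_idx)]
        return 1.0 - float(np.nanmean(rs))

    full_score = score(all_idx)
    optimal_curve, random_curves = [], []
    for m in m_values:
        if m > s:
            raise ValueError(f"m={m} exceeds {s} candidate sites")
        chosen = qr_pivot_select(basis, m).indices
        optimal_curve.append(score(np.sort(chosen)))
        rand_m = [
            score(np.sort(rng.choice(s, size=m, replace=False))) for _ in range(n_random)
        ]
        random_curves.append(rand_m)
    optimal_curve = np.asarray(optimal_curve)
    random_curves = np.asarray(random_curves)  # len(m_values) × n_random

    def crossover(errs) -> int | None:
        for m, e in zip(m_values, errs):
            if e <= full_score * (1.0 + match_tolerance):
                return int(m)
        return None

    return {
        "m_values": list(m_values),
        "optimal_error": optimal_curve,
        "random_errors": random_curves,
        "random_median_error": np.median(random_curves, axis=1),
        "full_model_error": full_score,
        "optimal_crossover_m": crossover(optimal_curve),
        "random_crossover_m": crossover(np.median(random_curves, axis=1)),
    }
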