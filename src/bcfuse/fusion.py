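"""Core fusion: link the two factorizations at the sensor sites and
reconstruct the complete black-carbon field.

Notation (field-standard): X_M = W_P H_L is the pollutant × location system,
X_F = W_S H_T the site × time system.  A binary sampling matrix Φ restricts
the full location set to the sensor sites; the reprojection coefficients

    C = (Φ H_Lᵀ)⁺ W_S

express each time-invariant spatial pattern (column of W_S) as the
least-squares combination of the pollutant-invariant spatial patterns
(rows of H_L) evaluated at the sites.  The reconstruction

    X_BC = H_Lᵀ C H_T

then carries the temporally complete sensor dynamics onto the spatially
dense mobile location set.  Because C is fitted by a pseudoinverse, any
positive per-factor rescaling of H_L or W_S cancels and X_BC is invariant
to the NMF normalization convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bcfuse.factorization import FactorModel, nmf, select_rank_knee
from bcfuse.kriging import VariogramModel, krige_map
from bcfuse.mobile import SegmentConcentrationMap
from bcfuse.sensors import SensorMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SamplingMatrix",
    "ReprojectionCoefficients",
    "BCField",
    "FusionModel",
    "build_sampling_matrix",
    "fit_reprojection",
    "reconstruct",
    "fuse",
]


@dataclass(frozen=True)
class SamplingMatrix:
    """Binary s × l row-selection operator Φ.

    Row i holds a single 1 at the column of site i's location, so
    ``phi.matrix @ v`` turns a location-indexed vector into a site-indexed
    one.
    """

    matrix: np.ndarray
    site_order: list[str]
    location_order: list[str]

    def __post_init__(self) -> None:
        m = self.matrix
        if not ((m == 0) | (m == 1)).all():
            raise ValueError("sampling matrix must be binary")
        if not (m.sum(axis=1) == 1).all():
            raise ValueError("each row must select exactly one location")
        if (m.sum(axis=0) > 1).any():
            raise ValueError("a location may host at most one site")

    @property
    def site_indices(self) -> np.ndarray:
        return self.matrix.argmax(axis=1)


@dataclass(frozen=True)
class ReprojectionCoefficients:
    """The k × q coefficient matrix C with the SV cutoff used to fit it."""

    matrix: np.ndarray
    rcond: float
    effective_rank: int
    residual_norm: float  # ||Φ H_Lᵀ C − W_S||_F


@dataclass
class BCField:
    """The reconstructed location × time BC field (µg/m³)."""

    values: np.ndarray
    location_order: list[str]
    time_bins: pd.DatetimeIndex
    n_clipped: int = 0
    augmented_patterns: np.ndarray | None = None  # H_Lᵀ C, l × q

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("BC field contains non-finite values")

    def location_index(self, ids) -> np.ndarray:
        lookup = {loc: i for i, loc in enumerate(self.location_order)}
        return np.array([lookup[i] for i in ids], dtype=int)


def build_sampling_matrix(site_ids: list[str], locations: list[str]) -> SamplingMatrix:
    """Build Φ mapping the ordered location set onto the ordered site set."""
    lookup = {loc: i for i, loc in enumerate(locations)}
    mat = np.zeros((len(site_ids), len(locations)))
    for r, sid in enumerate(site_ids):
        if sid not in lookup:
            raise ValueError(f"site {sid!r} not present in the location set")
        mat[r, lookup[sid]] = 1.0
    return SamplingMatrix(matrix=mat, site_order=list(site_ids), location_order=list(locations))


def fit_reprojection(
    H_L: np.ndarray,
    phi: SamplingMatrix,
    W_S: np.ndarray,
    *,
    rcond: float = 1e-10,
) -> ReprojectionCoefficients:
    """Least-squares fit C = (Φ H_Lᵀ)⁺ W_S via the SVD pseudoinverse.

    Each column of C represents one time-invariant spatial pattern as a
    combination of the k pollutant-invariant patterns at the sites.  The
    system should be overdetermined (s ≥ k); a rank-deficient design is
    tolerated (the pseudoinverse picks the minimum-norm solution) but
    warned about.
    """
    H_L = np.asarray(H_L, dtype=float)
    W_S = np.asarray(W_S, dtype=float)
    k = H_L.shape[0]
    s = phi.matrix.shape[0]
    if W_S.shape[0] != s:
        raise ValueError(f"W_S has {W_S.shape[0]} rows but Φ selects {s} sites")
    zero_cols = np.nonzero(~W_S.any(axis=0))[0]
    if zero_cols.size:
        raise ValueError(f"W_S column(s) {zero_cols.tolist()} are all zero (degenerate factor)")
    if s < k:
        warnings.warn(
            f"underdetermined reprojection: {s} sites for {k} spatial patterns",
            stacklevel=2,
        )
    A = phi.matrix @ H_L.T  # s × k
    U, sv, Vt = np.linalg.svd(A, full_matrices=False)
    cutoff = rcond * sv[0] if sv.size else 0.0
    keep = sv > cutoff
    eff_rank = int(keep.sum())
    if eff_rank < k:
        warnings.warn(
            f"Φ H_Lᵀ has effective rank {eff_rank} < k={k}; "
            "minimum-norm least-squares solution used",
            stacklevel=2,
        )
    inv = np.zeros_like(sv)
    inv[keep] = 1.0 / sv[keep]
    C = (Vt.T * inv) @ (U.T @ W_S)
    resid = float(np.linalg.norm(A @ C - W_S))
    return ReprojectionCoefficients(
        matrix=C, rcond=rcond, effective_rank=eff_rank, residual_norm=resid
    )


def reconstruct(
    H_L: np.ndarray,
    C: np.ndarray | ReprojectionCoefficients,
    H_T: np.ndarray,
    *,
    location_order: list[str] | None = None,
    time_bins: pd.DatetimeIndex | None = None,
) -> BCField:
    """X_BC = H_Lᵀ C H_T, with negatives clipped to zero and counted.

    The augmented patterns H_Lᵀ C (the time-invariant patterns extended to
    the full location set) are retained on the result for inspection.
    """
    if isinstance(C, ReprojectionCoefficients):
        C = C.matrix
    H_L = np.asarray(H_L, dtype=float)
    H_T = np.asarray(H_T, dtype=float)
    if H_L.shape[0] != C.shape[0] or C.shape[1] != H_T.shape[0]:
        raise ValueError(
            f"shape mismatch: H_L {H_L.shape}, C {C.shape}, H_T {H_T.shape}"
        )
    augmented = H_L.T @ C
    values = augmented @ H_T
    n_clip = int((values < 0).sum())
    if n_clip:
        logger.info("reconstruct: clipped %d negative field values to 0", n_clip)
        values = np.clip(values, 0.0, None)
    l, t = values.shape
    if location_order is None:
        location_order = [str(i) for i in range(l)]
    if time_bins is None:
        time_bins = pd.RangeIndex(t)
    return BCField(
        values=values,
        location_order=list(location_order),
        time_bins=time_bins,
        n_clipped=n_clip,
        augmented_patterns=augmented,
    )


@dataclass
class FusionModel:
    """Everything one fusion run produced, retained for provenance."""

    segment_map: SegmentConcentrationMap  # extended over segments + sites
    pollutant_model: FactorModel | None
    sensor_model: FactorModel | None
    phi: SamplingMatrix
    coefficients: ReprojectionCoefficients
    bc_field: BCField
    k: int
    q: int
    variograms: dict[str, VariogramModel] = field(default_factory=dict)
    H_L: np.ndarray | None = None
    W_S: np.ndarray | None = None
    H_T: np.ndarray | None = None
    rank_curves: dict[str, object] = field(default_factory=dict)

    @property
    def site_predictions(self) -> np.ndarray:
        """Φ X_BC — the reconstructed field read back at the sensor sites."""
        return self.phi.matrix @ self.bc_field.values


def fuse(
    segment_map: SegmentConcentrationMap,
    sensor_matrix: SensorMatrix,
    sites: pd.DataFrame | None = None,
    *,
    k: int | str = 5,
    q: int | str = 16,
    k_candidates=range(2, 10),
    q_candidates=range(2, 41),
    rcond: float = 1e-10,
    variogram_kind: str = "exponential",
    seed: int = 0,
    nmf_tol: float = 1e-6,
    nmf_max_iter: int = 2000,
    oracle_factors: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> FusionModel:
    """End-to-end fusion of a mobile map and a sensor matrix.

    Stages: krige each pollutant to the sensor sites (when the map does not
    already cover them) → NMF of the extended pollutant × location matrix at
    rank ``k`` → NMF of the site × time matrix at rank ``q`` → build Φ →
    fit C → reconstruct X_BC.  ``k``/``q`` may be ``"auto"`` to pick the
    rank at the knee of the reconstruction-error curve.

    ``oracle_factors=(H_L, W_S, H_T)`` bypasses both NMFs and injects known
    factors — a first-class testing hook for exact-span experiments.
    """
    if not sensor_matrix.is_complete:
        raise ValueError("fuse: sensor matrix has gaps; run impute_gaps first")

    variograms: dict[str, VariogramModel] = {}
    ext_map = segment_map
    missing_sites = [s for s in sensor_matrix.sites if s not in segment_map.locations]
    if missing_sites:
        if sites is None:
            raise ValueError(
                f"fuse: sites {missing_sites[:3]}... not in the map and no site table given"
            )
        sub = sites.set_index("site_id").loc[missing_sites]
        try:
            ext_map, variograms = krige_map(
                segment_map,
                missing_sites,
                sub[["x", "y"]].to_numpy(),
                kind=variogram_kind,
            )
        except Exception as exc:
            raise RuntimeError(f"fuse: kriging stage failed: {exc}") from exc

    rank_curves: dict[str, object] = {}
    if oracle_factors is not None:
        H_L, W_S, H_T = (np.asarray(a, dtype=float) for a in oracle_factors)
        pollutant_model = sensor_model = None
        k_used, q_used = H_L.shape[0], W_S.shape[1]
    else:
        try:
            if k == "auto":
                cand = [r for r in k_candidates if r <= min(ext_map.values.shape)]
                knee = select_rank_knee(
                    ext_map.values, cand, seed=seed, tol=nmf_tol, max_iter=nmf_max_iter
                )
                k_used, rank_curves["k"] = knee.rank, knee
            else:
                k_used = int(k)
            pollutant_model = nmf(
                ext_map.values, k_used, seed=seed, tol=nmf_tol, max_iter=nmf_max_iter
            )
        except Exception as exc:
            raise RuntimeError(f"fuse: pollutant-map NMF stage failed: {exc}") from exc
        try:
            if q == "auto":
                cand = [r for r in q_candidates if r <= min(sensor_matrix.values.shape)]
                knee = select_rank_knee(
                    sensor_matrix.values, cand, seed=seed, tol=nmf_tol, max_iter=nmf_max_iter
                )
                q_used, rank_curves["q"] = knee.rank, knee
            else:
                q_used = int(q)
            sensor_model = nmf(
                sensor_matrix.values, q_used, seed=seed, tol=nmf_tol, max_iter=nmf_max_iter
            )
        except Exception as exc:
            raise RuntimeError(f"fuse: sensor-matrix NMF stage failed: {exc}") from exc
        H_L, W_S, H_T = pollutant_model.right, sensor_model.left, sensor_model.right

    phi = build_sampling_matrix(sensor_matrix.sites, ext_map.locations)
    coeff = fit_reprojection(H_L, phi, W_S, rcond=rcond)
    field_ = reconstruct(
        H_L,
        coeff,
        H_T,
        location_order=ext_map.locations,
        time_bins=sensor_matrix.time_bins,
    )
    return FusionModel(
        segment_map=ext_map,
        pollutant_model=pollutant_model,
        sensor_model=sensor_model,
        phi=phi,
        coefficients=coeff,
        bc_field=field_,
        k=k_used,
        q=q_used,
        variograms=variograms,
        H_L=H_L,
        W_S=W_S,
        H_T=H_T,
        rank_curves=rank_curves,
    )
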