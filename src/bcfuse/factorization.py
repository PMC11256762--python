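"""Non-negative matrix factorization with deterministic initialization and
knee-point rank selection.

Two NMFs drive the fusion model: the pollutant × location map matrix is split
into source signatures (columns of ``left``) and pollutant-invariant spatial
patterns (rows of ``right``); the site × time sensor matrix is split into
time-invariant spatial patterns (columns of ``left``) and characteristic time
signals (rows of ``right``).  Both use the plain Frobenius objective

    min_{W,H >= 0}  ||X - W H||_F

solved by monotone HALS coordinate-descent sweeps from an NNDSVD-style
initialization, which makes every fit a deterministic function of
(X, rank, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FactorModel",
    "KneeResult",
    "nmf",
    "select_rank_knee",
    "normalize_factors",
]

_EPS = 1e-12


@dataclass(frozen=True)
class FactorModel:
    """One NMF result: ``left @ right`` approximates the input matrix.

    Attributes
    ----------
    left : (rows, rank) non-negative array
    right : (rank, cols) non-negative array
    rank : number of factors
    objective_trace : Frobenius loss ``||X - WH||_F`` after each update sweep
    seed : seed recorded for provenance (the default init is deterministic)
    converged : whether the relative objective change fell below ``tol``
    """

    left: np.ndarray
    right: np.ndarray
    rank: int
    objective_trace: np.ndarray
    seed: int
    converged: bool

    @property
    def reconstruction(self) -> np.ndarray:
        return self.left @ self.right

    @property
    def relative_error(self) -> float:
        """Final ``||X - WH||_F / ||X||_F`` (norm of X backed out of trace)."""
        return float(self.objective_trace[-1] / self._input_norm)

    @property
    def _input_norm(self) -> float:
        # stashed at fit time; dataclass is frozen so it lives in __dict__ via object.__setattr__
        return self.__dict__["input_norm"]


def _nndsvd_init(X: np.ndarray, rank: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative double SVD initialization (dense variant).

    Splits each singular pair into its positive and negative parts and keeps
    the dominant one; zero entries are filled with a small fraction of the
    matrix mean so multiplicative updates cannot lock them at zero.
    """
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    W = np.zeros((X.shape[0], rank))
    H = np.zeros((rank, X.shape[1]))
    W[:, 0] = np.sqrt(s[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(s[0]) * np.abs(Vt[0, :])
    for j in range(1, rank):
        u, v = U[:, j], Vt[j, :]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        norm_p = np.linalg.norm(up) * np.linalg.norm(vp)
        norm_n = np.linalg.norm(un) * np.linalg.norm(vn)
        if norm_p >= norm_n:
            sig = np.sqrt(s[j] * norm_p) if norm_p > 0 else 0.0
            bu = up / np.linalg.norm(up) if norm_p > 0 else up
            bv = vp / np.linalg.norm(vp) if norm_p > 0 else vp
        else:
            sig = np.sqrt(s[j] * norm_n)
            bu = un / np.linalg.norm(un)
            bv = vn / np.linalg.norm(vn)
        W[:, j] = sig * bu
        H[j, :] = sig * bv
    fill = max(X.mean(), _EPS) * 1e-4
    W[W <= 0] = fill
    H[H <= 0] = fill
    return W, H


def nmf(
    X: np.ndarray,
    rank: int,
    *,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> FactorModel:
    """Factor a complete non-negative matrix as ``X ≈ W H``.

    HALS coordinate-descent sweeps on the Frobenius objective: each factor
    column (resp. row) is updated in turn by its non-negatively-projected
    exact minimizer, which makes the objective monotone non-increasing.
    Iteration stops when the relative objective change drops below ``tol``
    or after ``max_iter`` sweeps.

    Raises
    ------
    ValueError
        If ``X`` has negative or non-finite entries, or ``rank`` is outside
        ``[1, min(X.shape)]``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite entries; complete the matrix first")
    if (X < 0).any():
        raise ValueError("X contains negative entries; NMF requires X >= 0")
    if not 1 <= rank <= min(X.shape):
        raise ValueError(f"rank must be in [1, {min(X.shape)}], got {rank}")

    W, H = _nndsvd_init(X, rank)
    norm_x = np.linalg.norm(X)
    trace = []
    converged = False
    prev = np.linalg.norm(X - W @ H)
    for _ in range(max_iter):
        HHt = H @ H.T
        XHt = X @ H.T
        for j in range(rank):
            num = XHt[:, j] - W @ HHt[:, j] + W[:, j] * HHt[j, j]
            W[:, j] = np.clip(num / max(HHt[j, j], _EPS), 0.0, None)
        WtW = W.T @ W
        WtX = W.T @ X
        for j in range(rank):
            num = WtX[j] - WtW[j] @ H + WtW[j, j] * H[j]
            H[j] = np.clip(num / max(WtW[j, j], _EPS), 0.0, None)
        loss = np.linalg.norm(X - W @ H)
        trace.append(loss)
        if prev > 0 and (prev - loss) / max(prev, _EPS) < tol:
            converged = True
            break
        prev = loss
    model = FactorModel(
        left=W,
        right=H,
        rank=rank,
        objective_trace=np.asarray(trace),
        seed=seed,
        converged=converged,
    )
    object.__setattr__(model, "input_norm", max(norm_x, _EPS))
    return model


@dataclass(frozen=True)
class KneeResult:
    rank: int
    candidate_ranks: tuple[int, ...]
    errors: np.ndarray
    clear_knee: bool
    models: tuple[FactorModel, ...] | None = None


def knee_index(x: np.ndarray, y: np.ndarray) -> tuple[int, bool]:
    """Index of maximum perpendicular distance from the chord joining the
    endpoints of the curve (x, y), after normalizing both axes to [0, 1].

    Returns ``(index, clear)`` where ``clear`` is False when the curve is flat
    or the knee lands on an endpoint (no interior curvature).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x[-1] == x[0] or y.max() == y.min():
        return 0, False
    xn = (x - x[0]) / (x[-1] - x[0])
    yn = (y - y.min()) / (y.max() - y.min())
    # chord from first to last point; distance ∝ |cross product|
    dx, dy = xn[-1] - xn[0], yn[-1] - yn[0]
    dist = np.abs(dx * (yn[0] - yn) - (xn[0] - xn) * dy) / np.hypot(dx, dy)
    idx = int(np.argmax(dist))
    clear = 0 < idx < len(x) - 1 and dist[idx] > 1e-12
    return idx, clear


def select_rank_knee(
    X: np.ndarray,
    candidate_ranks,
    *,
    seed: int = 0,
    keep_models: bool = False,
    monotone_tol: float = 1e-3,
    **nmf_kwargs,
) -> KneeResult:
    """Choose the factorization rank at the knee of the error-vs-rank curve.

    Fits :func:`nmf` at each candidate rank, forms the relative Frobenius
    error curve, and picks the point of maximum perpendicular distance from
    the chord joining the curve's endpoints (Kneedle-style).  The error curve
    should be non-increasing in rank; violations beyond ``monotone_tol`` are
    warned about but the knee is still computed.
    """
    ranks = tuple(int(r) for r in candidate_ranks)
    if len(ranks) < 4:
        raise ValueError("need at least 4 candidate ranks")
    if any(b <= a for a, b in zip(ranks, ranks[1:])):
        raise ValueError("candidate ranks must be strictly increasing")
    models = [nmf(X, r, seed=seed, **nmf_kwargs) for r in ranks]
    errors = np.array([m.relative_error for m in models])
    increases = np.diff(errors)
    if (increases > monotone_tol).any():
        warnings.warn(
            "reconstruction-error curve is not monotone non-increasing in rank; "
            "knee computed anyway",
            stacklevel=2,
        )
    idx, clear = knee_index(np.asarray(ranks, dtype=float), errors)
    if not clear:
        warnings.warn("no clear knee in the error curve", stacklevel=2)
    return KneeResult(
        rank=ranks[idx],
        candidate_ranks=ranks,
        errors=errors,
        clear_knee=clear,
        models=tuple(models) if keep_models else None,
    )


def normalize_factors(model: FactorModel, convention: str = "left_columns") -> FactorModel:
    """Rescale a factor pair by a positive diagonal without changing the product.

    Under ``"left_columns"`` (default) each column of ``left`` is scaled to
    sum to 1 (fractional-abundance convention) and the matching row of
    ``right`` absorbs the scale; ``"right_rows"`` is the converse.
    """
    W, H = model.left.copy(), model.right.copy()
    if convention == "left_columns":
        d = W.sum(axis=0)
        which = "left"
    elif convention == "right_rows":
        d = H.sum(axis=1)
        which = "right"
    else:
        raise ValueError(f"unknown convention {convention!r}")
    zero = np.nonzero(d <= 0)[0]
    if zero.size:
        raise ValueError(f"factor {zero[0]} of the {which} matrix sums to zero; cannot normalize")
    if convention == "left_columns":
        W /= d
        H *= d[:, None]
    else:
        H /= d[:, None]
        W *= d
    out = replace(model, left=W, right=H)
    object.__setattr__(out, "input_norm", model._input_norm)
    return out
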