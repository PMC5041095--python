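"""Robust PCA of the vectorized frame matrix by inexact ALM.

Stacking the n frames of a series as columns of an m×n matrix M (m = pixels
per frame), patient motion — slow, global — is well modelled by a low-rank
component L, while contrast enhancement — fast, spatially localized, possibly
large in magnitude — is modelled by a sparse component S.  The decomposition
solves the convex program

    min  ||L||_*  +  lambda ||S||_1    s.t.  M = L + S

with lambda = C / sqrt(max(m, n)), C usually 1.  The inexact augmented
Lagrange multiplier (IALM) method alternates singular-value shrinkage of
M - S + Y/mu and entrywise soft-thresholding of M - L + Y/mu while growing
the penalty mu geometrically; it needs only one SVD per iteration on the thin
m×n matrix, which is cheap for image series (n << m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import FrameSeries

__all__ = [
    "SeriesMatrix",
    "Decomposition",
    "matrixize",
    "unmatrixize",
    "default_lambda",
    "rpca_ialm",
]

# Standard IALM schedule (mu growth and initial scaling); exposed for config.
IALM_RHO = 1.6
IALM_MU0_SCALE = 1.25
DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 500


@dataclass
class SeriesMatrix:
    """Vectorized series: column i is frame i flattened row-major."""

    data: np.ndarray  # (m, n)
    frame_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        h, w = self.frame_shape
        if self.data.ndim != 2 or self.data.shape[0] != h * w:
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with frame shape {self.frame_shape}"
            )
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("matrix contains non-finite entries")

    @property
    def m(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[1]


@dataclass
class Decomposition:
    """Low-rank + sparse split of a SeriesMatrix."""

    low_rank: np.ndarray
    sparse: np.ndarray
    lam: float
    iterations: int
    residual: float
    converged: bool = True


def matrixize(series: FrameSeries | np.ndarray) -> SeriesMatrix:
    """Stack frames as columns of the m×n series matrix (row-major flatten)."""
    frames = series.frames if isinstance(series, FrameSeries) else np.asarray(series, float)
    if frames.ndim != 3:
        raise ValueError(f"expected a (n_t, H, W) stack, got shape {frames.shape}")
    n, h, w = frames.shape
    if n < 2:
        raise ValueError("need at least 2 frames")
    return SeriesMatrix(frames.reshape(n, h * w).T.copy(), (h, w))


def unmatrixize(mat: SeriesMatrix | np.ndarray, frame_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Re-fold columns into a (n_t, H, W) frame stack; inverse of matrixize."""
    if isinstance(mat, SeriesMatrix):
        data, frame_shape = mat.data, mat.frame_shape
    else:
        if frame_shape is None:
            raise ValueError("frame_shape required for a raw matrix")
        data = np.asarray(mat, dtype=np.float64)
    h, w = frame_shape
    return data.T.reshape(-1, h, w).copy()


def default_lambda(m: int, n: int, C: float = 1.0) -> float:
    """Sparsity trade-off lambda = C / sqrt(max(m, n))."""
    if m < 1 or n < 1:
        raise ValueError(f"matrix dimensions must be >= 1, got {m}×{n}")
    if not C > 0:
        raise ValueError(f"C must be positive, got {C}")
    return C / np.sqrt(max(m, n))


def _soft_threshold(x: np.ndarray, tau: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)


def _svd_shrink(x: np.ndarray, tau: float) -> np.ndarray:
    # economy SVD on the thin dimension; n << m for image series
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    return (u[:, keep] * s[keep]) @ vt[keep]


def rpca_ialm(
    M: SeriesMatrix | np.ndarray,
    lam: float | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    rho: float = IALM_RHO,
) -> Decomposition:
    """Decompose M into low-rank L + sparse S by inexact ALM.

    Terminates when ||M - L - S||_F / ||M||_F <= tol or at the iteration cap
    (flagged via ``converged=False``, no exception).  ``rho`` is the
    geometric growth factor of the penalty mu; the fast default favors
    speed, while values near 1 track the convex optimum closely at the cost
    of more iterations.
    """
    A = M.data if isinstance(M, SeriesMatrix) else np.asarray(M, dtype=np.float64)
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix contains non-finite entries")
    m, n = A.shape
    if lam is None:
        lam = default_lambda(m, n)
    if not lam > 0:
        raise ValueError(f"lambda must be positive, got {lam}")

    norm_f = np.linalg.norm(A)
    if norm_f == 0.0:
        z = np.zeros_like(A)
        return Decomposition(z, z.copy(), lam, 1, 0.0)

    sigma1 = np.linalg.norm(A, 2)
    # dual ascent init: Y0 = M / max(sigma1, ||M||_inf / lambda)
    Y = A / max(sigma1, np.abs(A).max() / lam)
    mu = IALM_MU0_SCALE / sigma1
    mu_bar = mu * 1e7
    S = np.zeros_like(A)
    L = np.zeros_like(A)

    it = 0
    residual = np.inf
    for it in range(1, max_iter + 1):
        L = _svd_shrink(A - S + Y / mu, 1.0 / mu)
        S = _soft_threshold(A - L + Y / mu, lam / mu)
        Z = A - L - S
        residual = np.linalg.norm(Z) / norm_f
        if residual <= tol:
            return Decomposition(L, S, lam, it, float(residual))
        Y = Y + mu * Z
        mu = min(mu * rho, mu_bar)

    return Decomposition(L, S, lam, it, float(residual), converged=False)
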