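"""Cubic B-spline free-form deformation (FFD) with the RC cost.

A transform is a grid of control-point displacements at spacing ``s`` pixels;
the dense displacement field is the tensor-product cubic B-spline expansion
of the grid.  All transforms use the backward (pull-back) convention: the
field u sends fixed-grid coordinates x to moving-frame coordinates x + u(x),
and warping resamples the moving image there with bilinear interpolation and
edge clamping.  Coordinates are 0-based, pixel-centered, (row, col) order;
displacements are in pixels.

``register_pair`` minimizes RC(fixed, warp(moving, u)) over the control-point
displacements with L-BFGS and the analytic RC gradient chained through the
B-spline basis, coarse-to-fine over an image pyramid with grid refinement.
No explicit regularization is applied by default — on a geodesic path the
hops are small, which supplies implicit regularity — but an optional
bending-energy penalty is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .similarity import RCParams, rc_gradient, rc_similarity, ssd_gradient, ssd_similarity

__all__ = [
    "FFDTransform",
    "DisplacementField",
    "RegistrationConfig",
    "bspline_kernel",
    "realize",
    "warp",
    "compose",
    "chain_along_path",
    "jacobian_determinant",
    "register_pair",
]


def bspline_kernel(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline basis beta3(t), support |t| < 2, partition of unity."""
    t = np.abs(np.asarray(t, dtype=np.float64))
    out = np.zeros_like(t)
    near = t <= 1.0
    mid = (t > 1.0) & (t < 2.0)
    out[near] = 2.0 / 3.0 - t[near] ** 2 + 0.5 * t[near] ** 3
    out[mid] = (2.0 - t[mid]) ** 3 / 6.0
    return out


def _n_controls(extent: int, spacing: float) -> int:
    # controls at (j - 1) * spacing, j = 0..G-1; cubic support needs G >= 4
    return int(np.floor((extent - 1) / spacing)) + 4


def _basis_matrix(extent: int, spacing: float) -> np.ndarray:
    """Dense (extent × G) cubic B-spline basis; rows sum to 1."""
    g = _n_controls(extent, spacing)
    x = np.arange(extent, dtype=np.float64) / spacing
    j = np.arange(g, dtype=np.float64)
    return bspline_kernel(x[:, None] - (j[None, :] - 1.0))


@dataclass
class FFDTransform:
    """B-spline control grid for one frame pair.

    coefficients : ndarray (Gy, Gx, 2)
        Control-point displacements in pixels, (row, col) components.
    """

    grid_spacing: float
    coefficients: np.ndarray
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        h, w = self.image_shape
        gy, gx = _n_controls(h, self.grid_spacing), _n_controls(w, self.grid_spacing)
        if self.coefficients.shape != (gy, gx, 2):
            raise ValueError(
                f"coefficients shape {self.coefficients.shape} != expected ({gy}, {gx}, 2)"
            )
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite control-point displacements")

    @classmethod
    def identity(cls, image_shape: tuple[int, int], grid_spacing: float) -> "FFDTransform":
        h, w = image_shape
        gy, gx = _n_controls(h, grid_spacing), _n_controls(w, grid_spacing)
        return cls(grid_spacing, np.zeros((gy, gx, 2)), image_shape)


@dataclass
class DisplacementField:
    """Dense backward-mapping displacement u, shape (H, W, 2) in pixels."""

    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 3 or self.u.shape[-1] != 2:
            raise ValueError(f"field must be (H, W, 2), got {self.u.shape}")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("non-finite displacement field")

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.u.shape[0], self.u.shape[1]

    @classmethod
    def identity(cls, image_shape: tuple[int, int]) -> "DisplacementField":
        return cls(np.zeros((*image_shape, 2)))

    def max_abs(self) -> float:
        return float(np.abs(self.u).max())


def realize(t: FFDTransform) -> DisplacementField:
    """Dense field from the tensor-product expansion of the control grid."""
    h, w = t.image_shape
    by = _basis_matrix(h, t.grid_spacing)  # (H, Gy)
    bx = _basis_matrix(w, t.grid_spacing)  # (W, Gx)
    u = np.einsum("hg,gkc,wk->hwc", by, t.coefficients, bx, optimize=True)
    return DisplacementField(u)


def _sample(image: np.ndarray, coords_y: np.ndarray, coords_x: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(
        np.asarray(image, dtype=np.float64), [coords_y, coords_x], order=1, mode="nearest"
    )


def warp(image: np.ndarray, field: DisplacementField | np.ndarray, order: int = 1) -> np.ndarray:
    """Backward-warp: output(x) = image(x + u(x)), bilinear, edge-clamped.

    order=0 gives nearest-neighbor resampling (for label masks).
    """
    u = field.u if isinstance(field, DisplacementField) else np.asarray(field, float)
    image = np.asarray(image, dtype=np.float64)
    if image.shape != u.shape[:2]:
        raise ValueError(f"image shape {image.shape} != field shape {u.shape[:2]}")
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    return ndimage.map_coordinates(
        image, [yy + u[..., 0], xx + u[..., 1]], order=order, mode="nearest"
    )


def compose(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Composite field with u(x) = u_inner(x) + u_outer(x + u_inner(x)).

    Satisfies warp(I, compose(outer, inner)) ≈ warp(warp(I, outer), inner):
    ``inner`` is the template-side field, applied second in sequential
    warping but evaluated first on the template grid.
    """
    if outer.image_shape != inner.image_shape:
        raise ValueError(f"field shapes differ: {outer.image_shape} vs {inner.image_shape}")
    h, w = inner.image_shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy = yy + inner.u[..., 0]
    cx = xx + inner.u[..., 1]
    uo_y = _sample(outer.u[..., 0], cy, cx)
    uo_x = _sample(outer.u[..., 1], cy, cx)
    return DisplacementField(inner.u + np.stack([uo_y, uo_x], axis=-1))


def chain_along_path(
    transforms: dict[tuple[int, int], FFDTransform | DisplacementField],
    path: list[int],
) -> DisplacementField:
    """Single field pulling the first node of ``path`` onto the last (template).

    ``transforms`` is keyed by directed edge (moving, fixed) with fixed the
    node nearer the template; each maps the fixed grid into the moving frame.
    Composition runs right-to-left from the template-adjacent edge.
    """
    if len(path) < 2:
        raise ValueError("path must contain at least two nodes")

    def as_field(t) -> DisplacementField:
        return realize(t) if isinstance(t, FFDTransform) else t

    total = as_field(transforms[(path[-2], path[-1])])
    for a, b in zip(path[-3::-1], path[-2::-1]):
        total = compose(as_field(transforms[(a, b)]), total)
    return total


def jacobian_determinant(field: DisplacementField) -> np.ndarray:
    """det of d(x+u)/dx by central differences; 1 everywhere for identity."""
    u = field.u
    duy_dy, duy_dx = np.gradient(u[..., 0])
    dux_dy, dux_dx = np.gradient(u[..., 1])
    return (1.0 + duy_dy) * (1.0 + dux_dx) - duy_dx * dux_dy


# ---------------------------------------------------------------------------
# Pairwise registration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegistrationConfig:
    """Multi-resolution FFD registration settings.

    pyramid : tuple of int
        Downsampling factors, coarse to fine.
    grid_spacings : tuple of float
        Control spacing in full-resolution pixels per level.
    max_iter : int
        L-BFGS iteration cap per level.
    ftol : float
        Relative cost-change stopping tolerance per level.
    bending_weight : float
        Bending-energy penalty weight on the control lattice (0 disables
        it).  A light penalty keeps per-hop deformations smooth, which is
        what protects enhancing structures when residual contrast leaks
        into the low-rank frames.
    metric : str
        "rc" (default) or "ssd" (comparator for bias experiments).
    """

    pyramid: tuple[int, ...] = (4, 2, 1)
    grid_spacings: tuple[float, ...] = (32.0, 16.0, 8.0)
    max_iter: int = 100
    ftol: float = 1e-5
    rc: RCParams = field(default_factory=RCParams)
    bending_weight: float = 0.1
    metric: str = "rc"

    def __post_init__(self) -> None:
        if len(self.pyramid) != len(self.grid_spacings):
            raise ValueError("pyramid and grid_spacings must have equal length")
        if self.pyramid[-1] != 1:
            raise ValueError("finest pyramid level must have factor 1")
        if self.metric not in ("rc", "ssd"):
            raise ValueError(f"unknown metric {self.metric!r}")


def _downsample(image: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return np.asarray(image, dtype=np.float64)
    sm = ndimage.gaussian_filter(np.asarray(image, float), sigma=0.5 * factor)
    return sm[::factor, ::factor]


def _fit_coefficients(u: np.ndarray, spacing: float) -> np.ndarray:
    """Least-squares B-spline grid approximating a dense field (init transfer)."""
    h, w = u.shape[:2]
    by = np.linalg.pinv(_basis_matrix(h, spacing))
    bx = np.linalg.pinv(_basis_matrix(w, spacing))
    return np.einsum("gh,hwc,kw->gkc", by, u, bx, optimize=True)


def _bending_energy_and_grad(coef: np.ndarray) -> tuple[float, np.ndarray]:
    """Discrete thin-plate bending energy on the control lattice."""
    e = 0.0
    g = np.zeros_like(coef)
    for axis in (0, 1):
        d2 = np.diff(coef, n=2, axis=axis)
        e += float(np.sum(d2 * d2))
        # adjoint of the second difference
        pad = [(0, 0)] * coef.ndim
        pad[axis] = (2, 2)
        d2p = np.pad(d2, pad)
        sl0 = [slice(None)] * coef.ndim
        sl1 = [slice(None)] * coef.ndim
        sl2 = [slice(None)] * coef.ndim
        sl0[axis] = slice(0, coef.shape[axis])
        sl1[axis] = slice(1, coef.shape[axis] + 1)
        sl2[axis] = slice(2, coef.shape[axis] + 2)
        g += 2.0 * (d2p[tuple(sl0)] - 2.0 * d2p[tuple(sl1)] + d2p[tuple(sl2)])
    return e, g


def _register_level(
    fixed: np.ndarray,
    moving: np.ndarray,
    spacing: float,
    coef0: np.ndarray,
    cfg: RegistrationConfig,
    level_history: list[float],
) -> np.ndarray:
    h, w = fixed.shape
    by = _basis_matrix(h, spacing)
    bx = _basis_matrix(w, spacing)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    gy, gx = np.gradient(moving)

    if cfg.metric == "rc":
        sim, sim_grad = rc_similarity, rc_gradient
        metric_args = (cfg.rc,)
    else:
        sim, sim_grad = ssd_similarity, ssd_gradient
        metric_args = ()

    shape = coef0.shape
    last_eval: dict = {"x": None, "f": None}

    def cost_and_grad(flat: np.ndarray):
        coef = flat.reshape(shape)
        u = np.einsum("hg,gkc,wk->hwc", by, coef, bx, optimize=True)
        cy, cx = yy + u[..., 0], xx + u[..., 1]
        warped = _sample(moving, cy, cx)
        c = sim(fixed, warped, *metric_args)
        dwarped = sim_grad(fixed, warped, *metric_args)  # d cost / d warped
        gys = _sample(gy, cy, cx)
        gxs = _sample(gx, cy, cx)
        du = np.stack([dwarped * gys, dwarped * gxs], axis=-1)
        grad = np.einsum("hg,hwc,wk->gkc", by, du, bx, optimize=True)
        if cfg.bending_weight > 0.0:
            be, bg = _bending_energy_and_grad(coef)
            c = c + cfg.bending_weight * be
            grad = grad + cfg.bending_weight * bg
        if not np.isfinite(c):
            raise FloatingPointError(
                f"non-finite registration cost at spacing {spacing} (|coef|max="
                f"{np.abs(coef).max():.3g})"
            )
        last_eval["x"], last_eval["f"] = flat.copy(), float(c)
        return c, grad.ravel()

    def record_accepted(xk: np.ndarray) -> None:
        # L-BFGS-B evaluates the accepted point last in its line search, so
        # the cache normally hits; recompute otherwise.
        if last_eval["x"] is not None and np.array_equal(xk, last_eval["x"]):
            level_history.append(last_eval["f"])
        else:
            level_history.append(float(cost_and_grad(xk)[0]))

    record_accepted(coef0.ravel())
    res = optimize.minimize(
        cost_and_grad,
        coef0.ravel(),
        jac=True,
        method="L-BFGS-B",
        callback=record_accepted,
        options={"maxiter": cfg.max_iter, "ftol": cfg.ftol, "gtol": 1e-12},
    )
    return res.x.reshape(shape)


def register_pair(
    fixed: np.ndarray,
    moving: np.ndarray,
    params: RegistrationConfig = RegistrationConfig(),
) -> FFDTransform:
    """Estimate the FFD aligning ``moving`` to ``fixed``.

    Runs coarse-to-fine over ``params.pyramid``; at each level the control
    grid from the previous level initializes the next via a dense-field
    least-squares refit.  Returns the finest-level transform; its realized
    field maps fixed-grid coordinates into the moving frame.  Per-level
    accepted-iterate cost traces are attached as ``result.cost_history``.
    """
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape:
        raise ValueError(f"frame shapes differ: {fixed.shape} vs {moving.shape}")
    if fixed.ndim != 2:
        raise ValueError("frames must be 2D")

    cost_history: list[list[float]] = []
    coef = None
    prev_factor = None
    for factor, spacing_full in zip(params.pyramid, params.grid_spacings):
        f_lvl = _downsample(fixed, factor)
        m_lvl = _downsample(moving, factor)
        spacing_lvl = spacing_full / factor
        gy, gx = _n_controls(f_lvl.shape[0], spacing_lvl), _n_controls(f_lvl.shape[1], spacing_lvl)
        if coef is None:
            coef0 = np.zeros((gy, gx, 2))
        else:
            # carry the coarse solution: realize, upsample, refit at new grid
            u_prev = np.einsum(
                "hg,gkc,wk->hwc",
                _basis_matrix(prev_shape[0], prev_spacing),
                coef,
                _basis_matrix(prev_shape[1], prev_spacing),
                optimize=True,
            )
            scale = prev_factor / factor
            u_up = np.stack(
                [
                    ndimage.zoom(u_prev[..., c], (f_lvl.shape[0] / prev_shape[0], f_lvl.shape[1] / prev_shape[1]), order=1)
                    for c in range(2)
                ],
                axis=-1,
            ) * scale
            coef0 = _fit_coefficients(u_up, spacing_lvl)
        level_history: list[float] = []
        coef = _register_level(f_lvl, m_lvl, spacing_lvl, coef0, params, level_history)
        cost_history.append(level_history)
        prev_shape = f_lvl.shape
        prev_spacing = spacing_lvl
        prev_factor = factor

    out = FFDTransform(params.grid_spacings[-1], coef, fixed.shape)
    out.cost_history = cost_history
    return out
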