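"""Synthetic DCE liver-slice phantom with exact ground truth.

The generator emulates the structure of a clinical liver DCE-MRI slice
acquisition: 22 frames of which 6 are pre-contrast, a body/liver/tumor/vessel
geometry, tissue-specific enhancement curves (vessels enhance early and
strongly, the tumor rim enhances while the core barely does), smooth
inter-frame breathing motion of a few pixels with occasional larger
breath-hold shifts, and additive noise.  Unlike clinical data, every
corrupting factor is known exactly: per-frame ground-truth displacement
fields, binary tissue masks, and noise-free enhancement curves are returned
alongside the observed series, replacing the manually adjusted pseudo ground
truth that clinical evaluation has to rely on.

Construction of a clean frame: a piecewise-constant tissue value map
(baseline + enhancement at frame t) is modulated by a fixed multiplicative
texture field, ``clean_t = values_t * (1 + tex)``.  Because the texture is
constant in time and multiplicative, it cancels in baseline-normalized
time-intensity curves, so the stored per-tissue truth curves
``(b + e(t)) / b`` are exact for any ROI inside one tissue.

Motion: per-frame displacements follow a smooth random walk in B-spline
control-point space (scaled to a maximum magnitude), with two seeded "jump"
frames receiving an extra transient shift, mimicking mistimed breath holds.
The observed frame is ``warp(clean_t, u_t) + noise``; u_t maps observed-frame
coordinates into the motion-free reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .ffd import DisplacementField, FFDTransform, realize, warp
from .io import FrameSeries

__all__ = ["EnhancementParams", "PhantomSpec", "PhantomTruth", "enhancement_curve", "generate"]


@dataclass(frozen=True)
class EnhancementParams:
    """Logistic uptake curve for one tissue.

    amplitude : plateau intensity gain (image units; >= 0)
    onset : frame index of the half-maximum
    rate : logistic steepness per frame
    start : first frame with nonzero enhancement (bolus arrival); the curve
        is exactly zero before it, so pre-contrast frames are truly flat.
    """

    amplitude: float
    onset: float
    rate: float
    start: int = 6

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def enhancement_curve(t: float | np.ndarray, params: EnhancementParams) -> np.ndarray:
    """Tissue enhancement at frame t: truncated logistic uptake."""
    t = np.asarray(t, dtype=np.float64)
    val = params.amplitude / (1.0 + np.exp(-params.rate * (t - params.onset)))
    return np.where(t < params.start, 0.0, val)


def _default_tissues(n_pre: int) -> dict[str, tuple[float, EnhancementParams]]:
    """(baseline intensity, enhancement) per tissue; image units in [0, 1]."""
    return {
        "background": (0.05, EnhancementParams(0.0, 0.0, 1.0, n_pre)),
        "body": (0.35, EnhancementParams(0.06, n_pre + 4.0, 0.5, n_pre)),
        "liver": (0.55, EnhancementParams(0.18, n_pre + 4.0, 0.7, n_pre)),
        "vessel": (0.60, EnhancementParams(0.55, n_pre + 1.5, 1.8, n_pre)),
        "tumor_rim": (0.50, EnhancementParams(0.35, n_pre + 3.0, 0.9, n_pre)),
        "tumor_core": (0.45, EnhancementParams(0.05, n_pre + 5.0, 0.5, n_pre)),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic acquisition."""

    shape: tuple[int, int] = (128, 128)
    n_frames: int = 22
    n_pre: int = 6
    # geometry, as fractions of the image extent (center_y, center_x, semi_y, semi_x)
    body: tuple[float, float, float, float] = (0.50, 0.50, 0.46, 0.42)
    liver: tuple[float, float, float, float] = (0.46, 0.44, 0.27, 0.24)
    tumor_center: tuple[float, float] = (0.52, 0.50)
    tumor_radius: float = 0.12
    rim_width: float = 0.03
    vessels: tuple[tuple[float, float, float], ...] = (
        (0.36, 0.34, 0.030),
        (0.56, 0.32, 0.024),
        (0.38, 0.55, 0.026),
    )
    tissues: dict[str, tuple[float, EnhancementParams]] | None = None
    texture_sigma: float = 2.0
    texture_amplitude: float = 0.2
    # motion
    motion_amplitude: float = 2.5
    jump_scale: float = 2.0
    n_jumps: int = 2
    motion_spacing: float = 32.0
    local_motion_fraction: float = 0.4
    # noise
    noise_sigma: float = 0.01
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_pre < self.n_frames:
            raise ValueError("need 0 < n_pre < n_frames")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.jump_scale < 1.0:
            raise ValueError("jump_scale must be >= 1")

    def tissue_table(self) -> dict[str, tuple[float, EnhancementParams]]:
        return self.tissues if self.tissues is not None else _default_tissues(self.n_pre)

    @classmethod
    def default(cls, seed: int = 0, **kw) -> "PhantomSpec":
        return cls(seed=seed, **kw)

    @classmethod
    def no_enhancement(cls, seed: int = 0, **kw) -> "PhantomSpec":
        """Motion only: every tissue keeps its baseline across all frames."""
        base = _default_tissues(kw.get("n_pre", 6))
        flat = {k: (b, replace(p, amplitude=0.0)) for k, (b, p) in base.items()}
        return cls(seed=seed, tissues=flat, **kw)

    @classmethod
    def strong_enhancement(cls, seed: int = 0, gain: float = 2.5, **kw) -> "PhantomSpec":
        """Enhancement-dominated regime: uptake amplitudes scaled by ``gain``.

        Contrast variance then rivals the motion signal, the regime in which
        enhancement leaks into the RPCA low-rank component and direct
        template registration distorts enhancing structures.
        """
        base = _default_tissues(kw.get("n_pre", 6))
        strong = {k: (b, replace(p, amplitude=gain * p.amplitude)) for k, (b, p) in base.items()}
        return cls(seed=seed, tissues=strong, **kw)


@dataclass
class PhantomTruth:
    """Generator output: observed data plus exact ground truth."""

    spec: PhantomSpec
    clean_series: FrameSeries  # motion-free, noise-free
    observed_series: FrameSeries  # motion + noise applied
    true_fields: list[DisplacementField]  # observed -> motion-free reference
    masks: dict[str, np.ndarray]  # boolean, reference geometry
    true_tics: dict[str, np.ndarray]  # baseline-normalized, per tissue
    jump_frames: tuple[int, ...] = ()


def _ellipse(shape, cy, cx, sy, sx) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy * h) / (sy * h)) ** 2 + ((xx - cx * w) / (sx * w)) ** 2 <= 1.0


def _build_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    h, w = spec.shape
    scale = min(h, w)
    body = _ellipse(spec.shape, *spec.body)
    liver = _ellipse(spec.shape, *spec.liver) & body
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - spec.tumor_center[0] * h, xx - spec.tumor_center[1] * w)
    tumor = r <= spec.tumor_radius * scale
    core = r <= (spec.tumor_radius - spec.rim_width) * scale
    if not tumor.any():
        raise ValueError("tumor geometry lies outside the image")
    if not np.array_equal(tumor & liver, tumor):
        raise ValueError("tumor must lie inside the liver")
    rim = tumor & ~core
    vessel = np.zeros(spec.shape, dtype=bool)
    for vy, vx, vr in spec.vessels:
        vessel |= np.hypot(yy - vy * h, xx - vx * w) <= vr * scale
    if not np.array_equal(vessel & liver, vessel):
        raise ValueError("vessels must lie inside the liver")
    vessel &= ~tumor
    liver_only = liver & ~tumor & ~vessel
    body_only = body & ~liver
    return {
        "background": ~body,
        "body": body_only,
        "liver": liver_only,
        "vessel": vessel,
        "tumor_rim": rim,
        "tumor_core": core,
        "tumor": tumor,
    }


def _smooth_field_stack(
    rng: np.random.Generator, spec: PhantomSpec, n: int, max_abs: float, walk: bool
) -> np.ndarray:
    """(n, H, W, 2) smooth B-spline fields, scaled to a max magnitude."""
    proto = FFDTransform.identity(spec.shape, spec.motion_spacing)
    gy, gx, _ = proto.coefficients.shape
    coefs = rng.standard_normal((n, gy, gx, 2))
    if walk:
        coefs = np.cumsum(coefs, axis=0)
    fields = np.stack(
        [realize(FFDTransform(spec.motion_spacing, c, spec.shape)).u for c in coefs]
    )
    peak = np.abs(fields).max()
    if peak > 0 and max_abs > 0:
        fields *= max_abs / peak
    elif max_abs == 0:
        fields[:] = 0.0
    return fields


def generate(spec: PhantomSpec) -> PhantomTruth:
    """Build the phantom: masks, clean frames, motion, noise, exact truth."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    masks = _build_masks(spec)
    tissues = spec.tissue_table()

    tex = ndimage.gaussian_filter(rng.standard_normal(spec.shape), spec.texture_sigma)
    tex *= spec.texture_amplitude / max(tex.std(), 1e-12)
    tex = np.clip(tex, -0.5, 0.5)

    t_idx = np.arange(spec.n_frames, dtype=float)
    clean = np.zeros((spec.n_frames, h, w))
    true_tics: dict[str, np.ndarray] = {}
    for name, (baseline, enh) in tissues.items():
        curve = enhancement_curve(t_idx, enh)
        m = masks[name]
        clean += m[None, :, :] * (baseline + curve)[:, None, None]
        true_tics[name] = (baseline + curve) / baseline
    clean *= (1.0 + tex)[None, :, :]

    # motion: bulk breathing translation (random walk) plus a smaller local
    # B-spline deformation, both anchored at frame 0; jump frames add a
    # transient translation-dominated shift (mistimed breath hold)
    trans = np.cumsum(rng.normal(0.0, 1.0, (spec.n_frames, 2)), axis=0)
    trans -= trans[0:1]
    if np.abs(trans).max() > 0:
        trans /= np.abs(trans).max()
    local = _smooth_field_stack(rng, spec, spec.n_frames, 1.0, walk=True)
    local -= local[0:1]
    if np.abs(local).max() > 0:
        local *= spec.local_motion_fraction / np.abs(local).max()
    fields = trans[:, None, None, :] + local
    peak = np.abs(fields).max()
    if peak > 0:
        fields *= spec.motion_amplitude / peak
    else:
        fields[:] = 0.0
    jump_frames: tuple[int, ...] = ()
    if spec.n_jumps > 0 and spec.motion_amplitude > 0:
        candidates = np.arange(1, spec.n_frames)
        jump_frames = tuple(
            int(i) for i in sorted(rng.choice(candidates, size=spec.n_jumps, replace=False))
        )
        extra_mag = (spec.jump_scale - 1.0) * spec.motion_amplitude
        for i in jump_frames:
            direction = rng.normal(size=2)
            direction *= extra_mag / max(np.abs(direction).max(), 1e-12)
            wobble = _smooth_field_stack(rng, spec, 1, 0.25 * extra_mag, walk=False)[0]
            fields[i] += direction[None, None, :] + wobble

    true_fields = [DisplacementField(u) for u in fields]
    observed = np.stack([warp(clean[i], true_fields[i]) for i in range(spec.n_frames)])

    if spec.noise_sigma > 0:
        if spec.noise_model == "gaussian":
            observed = observed + rng.normal(0.0, spec.noise_sigma, observed.shape)
        else:  # rician: magnitude of a complex gaussian perturbation
            re = observed + rng.normal(0.0, spec.noise_sigma, observed.shape)
            im = rng.normal(0.0, spec.noise_sigma, observed.shape)
            observed = np.hypot(re, im)
    observed = np.clip(observed, 0.0, None)

    prov = {"generator": "geodereg.phantom", "seed": spec.seed}
    return PhantomTruth(
        spec=spec,
        clean_series=FrameSeries(clean, n_pre=spec.n_pre, provenance=dict(prov, kind="clean")),
        observed_series=FrameSeries(observed, n_pre=spec.n_pre, provenance=dict(prov, kind="observed")),
        true_fields=true_fields,
        masks=masks,
        true_tics=true_tics,
        jump_frames=jump_frames,
    )
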