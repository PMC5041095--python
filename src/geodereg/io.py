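"""Series container, file I/O and run manifests.

A DCE-MRI acquisition is handled as a :class:`FrameSeries`: an ordered stack of
co-sized 2D frames (one anatomical slice through time), the count of
pre-contrast frames, and acquisition metadata.  Images and displacement fields
are read and written as NIfTI through nibabel; curves as TSV; reports and
manifests as JSON.  All intensities are promoted to float64 internally
regardless of the on-disk dtype.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np

__all__ = [
    "FrameSeries",
    "read_series",
    "write_series",
    "write_field",
    "read_field",
    "write_report",
    "write_tsv",
    "config_hash",
    "write_manifest",
]


@dataclass
class FrameSeries:
    """Ordered 2D+t image series for one slice.

    Parameters
    ----------
    frames : ndarray, shape (n_t, H, W)
        Frame stack, time first.
    n_pre : int
        Number of pre-contrast frames (acquired before contrast injection).
    timepoints : ndarray, shape (n_t,)
        Acquisition times in seconds, or frame indices when unknown.
    spacing : tuple of float
        In-plane pixel spacing in mm (row, col); purely metadata.
    provenance : dict
        Source path, config hash, or generator parameters.
    """

    frames: np.ndarray
    n_pre: int
    timepoints: np.ndarray | None = None
    spacing: tuple[float, float] = (1.0, 1.0)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (n_t, H, W), got shape {self.frames.shape}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if not (0 < self.n_pre < self.n_frames):
            raise ValueError(f"n_pre={self.n_pre} must satisfy 0 < n_pre < n_t={self.n_frames}")
        if self.timepoints is None:
            self.timepoints = np.arange(self.n_frames, dtype=float)
        else:
            self.timepoints = np.asarray(self.timepoints, dtype=float)
            if self.timepoints.shape != (self.n_frames,):
                raise ValueError("timepoints length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    def with_frames(self, frames: np.ndarray) -> "FrameSeries":
        """Copy of this series with replaced pixel data, metadata preserved."""
        return replace(self, frames=np.asarray(frames, dtype=np.float64))


_IMAGE_EXTS = {".png", ".tif", ".tiff"}


def _load_2d(path: Path) -> np.ndarray:
    if "".join(path.suffixes[-2:]) in (".nii.gz",) or path.suffix == ".nii":
        import nibabel as nib

        arr = np.asanyarray(nib.load(str(path)).dataobj)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.squeeze(np.asarray(arr, dtype=np.float64))
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2D frame, got shape {arr.shape}")
    return arr


def read_series(path: str | os.PathLike, n_pre: int) -> FrameSeries:
    """Load a 2D+t series from a NIfTI stack or a directory of 2D images.

    For NIfTI input the last non-singleton axis is taken as time (singleton
    z-axes from single-slice exports are squeezed).  For a directory, frames
    are the lexicographically ordered image files inside it.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p
            for p in path.iterdir()
            if p.suffix.lower() in _IMAGE_EXTS or p.name.endswith((".nii", ".nii.gz"))
        )
        if len(files) < 2:
            raise ValueError(f"{path}: need at least 2 frame files, found {len(files)}")
        frames = []
        shape = None
        for f in files:
            a = _load_2d(f)
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise ValueError(f"{f.name}: frame shape {a.shape} differs from {shape}")
            frames.append(a)
        return FrameSeries(np.stack(frames), n_pre=n_pre, provenance={"source": str(path)})

    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    arr = np.squeeze(arr)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected 2D+t after squeezing, got shape {arr.shape}")
    # nibabel axis order is (x, y, t); internal convention is (t, row, col).
    frames = np.moveaxis(arr, -1, 0)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1])) if len(zooms) >= 2 else (1.0, 1.0)
    return FrameSeries(frames, n_pre=n_pre, spacing=spacing, provenance={"source": str(path)})


def write_series(series: FrameSeries, path: str | os.PathLike) -> None:
    """Write a series as a 3D NIfTI with time on the last axis."""
    import nibabel as nib

    arr = np.moveaxis(series.frames, 0, -1)
    affine = np.diag([series.spacing[0], series.spacing[1], 1.0, 1.0])
    img = nib.Nifti1Image(arr.astype(np.float64), affine)
    img.header.set_zooms((series.spacing[0], series.spacing[1], 1.0))
    nib.save(img, str(path))


def write_field(u: np.ndarray, path: str | os.PathLike, spacing=(1.0, 1.0)) -> None:
    """Write a displacement field (H, W, 2) as an H×W×1×2 NIfTI, float32."""
    import nibabel as nib

    u = np.asarray(u)
    if u.ndim != 3 or u.shape[-1] != 2:
        raise ValueError(f"field must be (H, W, 2), got {u.shape}")
    arr = u.astype(np.float32)[:, :, None, :]
    img = nib.Nifti1Image(arr, np.diag([spacing[0], spacing[1], 1.0, 1.0]))
    nib.save(img, str(path))


def read_field(path: str | os.PathLike) -> np.ndarray:
    import nibabel as nib

    arr = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    arr = np.squeeze(arr)
    if arr.ndim != 3 or arr.shape[-1] != 2:
        raise ValueError(f"{path}: expected an H×W×2 field, got shape {arr.shape}")
    return arr


class _NumpyJSON(json.JSONEncoder):
    def default(self, o: Any) -> Any:
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_report(report: dict, path: str | os.PathLike) -> None:
    """Serialize an evaluation/run report as indented JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, cls=_NumpyJSON)
        fh.write("\n")


def write_tsv(rows: Sequence[Sequence], header: Sequence[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(repr(v) if isinstance(v, float) else str(v) for v in row) + "\n")


def config_hash(config: Any) -> str:
    """Stable short hash of a configuration object for provenance stamps."""
    if hasattr(config, "__dict__"):
        payload = {k: v for k, v in vars(config).items()}
    else:
        payload = config
    blob = json.dumps(payload, sort_keys=True, default=repr).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir: str | os.PathLike, *, inputs: dict, config: Any, seed: int | None) -> str:
    """Write the machine-readable run manifest; returns the config hash."""
    import geodereg

    h = config_hash(config)
    manifest = {
        "inputs": inputs,
        "config": vars(config) if hasattr(config, "__dict__") else config,
        "config_hash": h,
        "seed": seed,
        "versions": {"geodereg": geodereg.__version__, "numpy": np.__version__},
    }
    write_report(manifest, Path(outdir) / "manifest.json")
    return h
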