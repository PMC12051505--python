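"""Universal back-projection (UBP) reconstruction and slice handling.

The back-projection term for detector ``i`` is

    b_i(t) = 2 p_i(t) - 2 t dp_i/dt,

the classic universal filtered back-projection integrand.  Each voxel sums
``b_i`` evaluated (by linear interpolation) at its acoustic delay
``tau = |r - r_i| / c``, with uniform detector weights 1/N — on a uniform
full sphere the solid-angle weighting reduces to a constant.  The operator is
linear in the channel data; images are never rescaled here.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import tifffile

from .forward import ChannelData, SPEED_OF_SOUND, _c_mm
from .geometry import DetectorArray, ReconGrid

__all__ = ["ReconImage", "ubp_backproject", "extract_slices", "restack",
           "save_tiff", "load_tiff", "save_nifti", "load_nifti"]

PROVENANCES = ("full", "subset1", "subset2", "other")

AXES = {"x": 0, "y": 1, "z": 2}


@dataclasses.dataclass(frozen=True)
class ReconImage:
    """A scalar field on a reconstruction grid (2-D slice or 3-D volume)."""

    values: np.ndarray
    grid_ref: ReconGrid | None = None
    provenance: str = "other"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim not in (2, 3):
            raise ValueError("values must be 2-D or 3-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("image values must be finite")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")
        if self.grid_ref is not None and v.ndim == 3 and tuple(v.shape) != self.grid_ref.shape:
            raise ValueError("values shape must match grid shape")
        object.__setattr__(self, "values", v)

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def shape(self):
        return self.values.shape


def ubp_backproject(
    data: ChannelData,
    array: DetectorArray,
    grid: ReconGrid,
    c: float = SPEED_OF_SOUND,
    provenance: str = "other",
) -> ReconImage:
    """Back-project channel data onto ``grid``.

    Preconditions: the grid must lie inside the detector sphere and the time
    window must cover every voxel-detector delay; violations raise
    ``ValueError``.
    """
    if data.n_detectors == 0:
        raise ValueError("channel data has no detectors")
    if data.n_detectors != array.n_detectors:
        raise ValueError("channel data row count must equal the array element count")
    cm = _c_mm(c)
    pts = grid.voxel_centers()
    if np.linalg.norm(pts, axis=1).max() >= array.radius:
        raise ValueError("grid points must lie strictly inside the array surface")
    t = data.times
    # universal back-projection term b(t) = 2 p - 2 t dp/dt
    dpdt = np.gradient(data.samples, data.dt, axis=1)
    b = 2.0 * data.samples - 2.0 * t[None, :] * dpdt
    img = np.zeros(len(pts))
    w = 1.0 / data.n_detectors
    pts_sq = np.einsum("ij,ij->i", pts, pts)
    n_t = data.n_t
    b_flat = b.ravel()
    # detectors in chunks: distances via the expanded square, delays looked
    # up by direct uniform-grid linear interpolation (the time axis is
    # uniform, so no per-sample search is needed)
    chunk = max(1, int(4e6 // len(pts)))
    scratch = np.empty((2, chunk, len(pts)))
    for i0 in range(0, data.n_detectors, chunk):
        det = array.positions[i0:i0 + chunk]
        m = len(det)
        pos, frac = scratch[0, :m], scratch[1, :m]
        # pos <- delay in samples
        np.matmul(det, pts.T, out=pos)
        pos *= -2.0
        pos += pts_sq[None, :]
        pos += np.einsum("ij,ij->i", det, det)[:, None]
        np.maximum(pos, 0.0, out=pos)
        np.sqrt(pos, out=pos)
        pos /= cm
        if pos.min() < t[0] or pos.max() > t[-1]:
            bad = i0 + int(np.unravel_index(np.argmax(pos), pos.shape)[0])
            raise ValueError(
                f"delay range [{pos.min():.3e}, {pos.max():.3e}] s of detector "
                f"{bad} falls outside the time window "
                f"[{t[0]:.3e}, {t[-1]:.3e}] s")
        pos -= data.t0
        pos /= data.dt
        k = pos.astype(np.int64)
        np.minimum(k, n_t - 2, out=k)
        np.subtract(pos, k, out=frac)
        k += (np.arange(i0, i0 + m) * n_t)[:, None]
        lo = np.take(b_flat, k)
        hi = np.take(b_flat, k + 1)
        hi -= lo
        hi *= frac
        lo += hi
        img += w * lo.sum(axis=0)
    return ReconImage(img.reshape(grid.shape), grid, provenance)


def extract_slices(volume: ReconImage, axis: str = "z") -> list[ReconImage]:
    """Split a 3-D volume into ordered 2-D slices along ``axis``."""
    if volume.ndim != 3:
        raise ValueError("extract_slices requires a 3-D volume")
    ax = AXES[axis] if isinstance(axis, str) else int(axis)
    return [ReconImage(np.take(volume.values, k, axis=ax), None, volume.provenance)
            for k in range(volume.shape[ax])]


def restack(slices, axis: str = "z", grid: ReconGrid | None = None,
            provenance: str = "other") -> ReconImage:
    """Inverse of :func:`extract_slices`: stack 2-D slices back into a volume."""
    ax = AXES[axis] if isinstance(axis, str) else int(axis)
    vals = np.stack([s.values if isinstance(s, ReconImage) else np.asarray(s)
                     for s in slices], axis=ax)
    return ReconImage(vals, grid, provenance)


# ---------------------------------------------------------------------------
# on-disk formats


def save_tiff(image: ReconImage, path: str | Path):
    tifffile.imwrite(str(path), image.values.astype(np.float32),
                     photometric="minisblack")


def load_tiff(path: str | Path, grid: ReconGrid | None = None) -> ReconImage:
    return ReconImage(tifffile.imread(str(path)).astype(float), grid)


def save_nifti(image: ReconImage, path: str | Path):
    if image.ndim != 3:
        raise ValueError("NIfTI export expects a 3-D volume")
    grid = image.grid_ref
    spacing = grid.spacing if grid is not None else 1.0
    origin = grid.origin if grid is not None else (0.0, 0.0, 0.0)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = origin
    nib.save(nib.Nifti1Image(image.values.astype(np.float32), affine), str(path))


def load_nifti(path: str | Path) -> ReconImage:
    img = nib.load(str(path))
    affine = img.affine
    spacing = float(affine[0, 0])
    vals = np.asarray(img.dataobj, dtype=float)
    grid = ReconGrid(tuple(affine[:3, 3]), spacing, vals.shape)
    return ReconImage(vals, grid)


def save_h5(image: ReconImage, path: str | Path):
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("recon", data=image.values)
        if image.grid_ref is not None:
            ds.attrs["origin"] = image.grid_ref.origin
            ds.attrs["spacing"] = image.grid_ref.spacing
        ds.attrs["provenance"] = image.provenance


def load_h5(path: str | Path) -> ReconImage:
    with h5py.File(path, "r") as f:
        ds = f["recon"]
        vals = ds[()]
        grid = None
        if "origin" in ds.attrs:
            grid = ReconGrid(tuple(ds.attrs["origin"]), float(ds.attrs["spacing"]),
                             vals.shape)
        return ReconImage(vals, grid, str(ds.attrs.get("provenance", "other")))
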