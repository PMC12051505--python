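"""Detector-array geometries, synthetic absorber phantoms and reconstruction grids.

All coordinates are in millimetres in a right-handed frame whose origin sits at
the centre of the (hemi)spherical detector array.  Voxel coordinates refer to
voxel *centres*.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

__all__ = [
    "DetectorArray",
    "Phantom",
    "ReconGrid",
    "make_spherical_array",
    "uniform_downsample",
    "make_simple_phantom",
    "make_vessel_phantom",
    "save_array",
    "load_array",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

COVERAGES = ("full_sphere", "hemisphere")


@dataclasses.dataclass(frozen=True)
class DetectorArray:
    """An array of point detectors on a sphere (or hemispherical cap).

    Parameters
    ----------
    positions : (N, 3) float array
        Cartesian element positions in mm.
    radius : float
        Sphere radius in mm; every position lies at this distance from the
        origin (relative tolerance 1e-9).
    coverage : {"full_sphere", "hemisphere"}
    """

    positions: np.ndarray
    radius: float
    coverage: str = "full_sphere"

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 1:
            raise ValueError("positions must be a non-empty (N, 3) array")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.coverage not in COVERAGES:
            raise ValueError(f"coverage must be one of {COVERAGES}")
        r = np.linalg.norm(pos, axis=1)
        if not np.allclose(r, self.radius, rtol=1e-9, atol=0.0):
            raise ValueError("every detector must lie at the stated radius")
        if len(np.unique(pos, axis=0)) != len(pos):
            raise ValueError("detector positions must be pairwise distinct")
        object.__setattr__(self, "positions", pos)

    @property
    def n_detectors(self) -> int:
        return self.positions.shape[0]

    def __len__(self) -> int:
        return self.n_detectors


@dataclasses.dataclass(frozen=True)
class Phantom:
    """A collection of uniform spherical optical absorbers.

    ``absorbers`` is an (K, 5) array of rows ``(cx, cy, cz, radius, amplitude)``
    in mm / arbitrary units; ``bounding_box`` is a (2, 3) array of the lower and
    upper corner.  Every absorber sphere must lie entirely inside the box.
    """

    absorbers: np.ndarray
    bounding_box: np.ndarray

    def __post_init__(self):
        ab = np.asarray(self.absorbers, dtype=float).reshape(-1, 5)
        box = np.asarray(self.bounding_box, dtype=float).reshape(2, 3)
        if np.any(box[1] <= box[0]):
            raise ValueError("bounding_box must have positive extent on every axis")
        if ab.size:
            if not np.all(np.isfinite(ab)):
                raise ValueError("absorber parameters must be finite")
            if np.any(ab[:, 3] <= 0):
                raise ValueError("absorber radii must be positive")
            lo = ab[:, :3] - ab[:, 3:4]
            hi = ab[:, :3] + ab[:, 3:4]
            if np.any(lo < box[0]) or np.any(hi > box[1]):
                raise ValueError("every absorber must lie entirely inside the bounding box")
        object.__setattr__(self, "absorbers", ab)
        object.__setattr__(self, "bounding_box", box)

    @property
    def n_absorbers(self) -> int:
        return self.absorbers.shape[0]

    @property
    def centers(self) -> np.ndarray:
        return self.absorbers[:, :3]

    @property
    def radii(self) -> np.ndarray:
        return self.absorbers[:, 3]

    @property
    def amplitudes(self) -> np.ndarray:
        return self.absorbers[:, 4]

    def scaled(self, k: float) -> "Phantom":
        """Return a phantom with all amplitudes multiplied by ``k``."""
        ab = self.absorbers.copy()
        ab[:, 4] *= k
        return Phantom(ab, self.bounding_box)


@dataclasses.dataclass(frozen=True)
class ReconGrid:
    """A regular isotropic voxel grid; ``origin`` is the centre of voxel (0,0,0)."""

    origin: tuple
    spacing: float
    shape: tuple

    def __post_init__(self):
        origin = tuple(float(v) for v in np.asarray(self.origin, dtype=float).reshape(3))
        shape = tuple(int(v) for v in self.shape)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError("shape must be three counts >= 1")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "shape", shape)

    @classmethod
    def centered(cls, shape, spacing: float, center=(0.0, 0.0, 0.0)) -> "ReconGrid":
        """Grid of ``shape`` voxels at ``spacing`` mm, centred on ``center``."""
        shape = tuple(int(s) for s in shape)
        center = np.asarray(center, dtype=float)
        origin = center - spacing * (np.asarray(shape) - 1) / 2.0
        return cls(tuple(origin), spacing, shape)

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing * np.arange(self.shape[axis])

    def voxel_centers(self) -> np.ndarray:
        """All voxel-centre coordinates as an (n_voxels, 3) array (C order)."""
        xs, ys, zs = (self.axis_coords(a) for a in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


def make_spherical_array(
    n: int,
    radius: float = 60.0,
    coverage: str = "full_sphere",
    seed: int | None = None,
) -> DetectorArray:
    """Place ``n`` detectors near-uniformly on a sphere (Fibonacci lattice).

    For ``coverage="hemisphere"`` the lattice is restricted to the lower
    (z <= 0) cap.  The construction is deterministic; ``seed`` is accepted for
    interface symmetry with the stochastic generators and ignored.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    i = np.arange(n, dtype=float)
    if coverage == "full_sphere":
        z = 1.0 - 2.0 * (i + 0.5) / n
    elif coverage == "hemisphere":
        z = -(i + 0.5) / n
    else:
        raise ValueError(f"coverage must be one of {COVERAGES}")
    phi = _GOLDEN_ANGLE * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pos = radius * np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    # renormalise so the radius invariant holds to tight tolerance
    pos *= (radius / np.linalg.norm(pos, axis=1))[:, None]
    return DetectorArray(pos, radius, coverage)


def uniform_downsample(array: DetectorArray, m: int) -> DetectorArray:
    """Keep ``m`` detectors by even index striding over the ordered element list."""
    n = array.n_detectors
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, {n}], got {m}")
    idx = (np.arange(m) * n) // m
    return DetectorArray(array.positions[idx], array.radius, array.coverage)


_DEFAULT_BOX = np.array([[-12.8, -12.8, -12.8], [12.8, 12.8, 12.8]])


def make_simple_phantom(
    seed: int = 0,
    n_spheres: int | None = None,
    box: np.ndarray | None = None,
) -> Phantom:
    """A few disjoint spheres of radius 0.5-2 mm — the 'simple phantom' fixture."""
    box = _DEFAULT_BOX if box is None else np.asarray(box, dtype=float).reshape(2, 3)
    rng = np.random.default_rng(seed)
    if n_spheres is None:
        n_spheres = int(rng.integers(3, 7))
    rows = []
    attempts = 0
    while len(rows) < n_spheres and attempts < 10000:
        attempts += 1
        r = rng.uniform(0.5, 2.0)
        lo, hi = box[0] + r, box[1] - r
        c = rng.uniform(lo, hi)
        if all(np.linalg.norm(c - np.asarray(row[:3])) > r + row[3] for row in rows):
            rows.append((*c, r, rng.uniform(0.5, 1.0)))
    return Phantom(np.array(rows).reshape(-1, 5), box)


def make_vessel_phantom(
    seed: int = 0,
    n_branches: int = 6,
    box: np.ndarray | None = None,
    *,
    step_fraction: float = 0.6,
    max_depth: int = 3,
) -> Phantom:
    """A random branching vessel tree rasterised as chains of overlapping spheres.

    ``n_branches`` root branches start at random positions; each meanders with
    a tapering radius and may split into two children up to ``max_depth``
    levels.  Sphere centres are spaced ``step_fraction`` radii apart so the
    chain reads as a continuous tube.  Growth reflects off the box walls, so
    thin (slab-like) boxes grow quasi-planar networks instead of truncated
    stubs; all spheres lie inside ``box``.
    """
    box = _DEFAULT_BOX if box is None else np.asarray(box, dtype=float).reshape(2, 3)
    if np.any(box[1] <= box[0]):
        raise ValueError("box must have positive extent on every axis")
    if n_branches < 0:
        raise ValueError("n_branches must be >= 0")
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []

    def unit(v):
        return v / np.linalg.norm(v)

    def grow(p, direction, radius, amplitude, depth):
        d = unit(direction)
        r = radius
        n_steps = int(rng.integers(25, 45))
        for _ in range(n_steps):
            # reflect the heading off any wall the tube is pressing against
            low = p - r - d * (step_fraction * r) < box[0]
            high = p + r + d * (step_fraction * r) > box[1]
            d[(low & (d < 0)) | (high & (d > 0))] *= -1.0
            p_clipped = np.clip(p, box[0] + r, box[1] - r)
            if not np.all((p_clipped - r >= box[0]) & (p_clipped + r <= box[1])):
                return  # tube is thicker than the box
            p = p_clipped
            rows.append((*p, r, amplitude))
            d = unit(d + rng.normal(0.0, 0.25, 3))
            p = p + d * (step_fraction * r)
            r *= rng.uniform(0.985, 0.999)
            if r < 0.15:
                return
        if depth < max_depth and rng.random() < 0.8:
            for _ in range(2):
                child_dir = unit(d + rng.normal(0.0, 0.6, 3))
                grow(p, child_dir, r * rng.uniform(0.6, 0.85), amplitude, depth + 1)

    span = box[1] - box[0]
    for _ in range(n_branches):
        start = box[0] + span * rng.uniform(0.2, 0.8, 3)
        grow(start, rng.normal(size=3), rng.uniform(0.5, 0.9), rng.uniform(0.7, 1.0), 0)
    return Phantom(np.array(rows).reshape(-1, 5), box)


# ---------------------------------------------------------------------------
# serialisation


def _array_to_dict(array: DetectorArray, inline: bool) -> dict:
    d = {"radius": float(array.radius), "coverage": array.coverage,
         "n_detectors": array.n_detectors}
    if inline:
        d["positions"] = array.positions.tolist()
    return d


def save_array(array: DetectorArray, path: str | Path, *, inline_positions: bool = True):
    """Write a detector array to YAML/JSON; large position sets can go to an
    HDF5 side file (``<path>.h5`` with datasets ``positions/radius/coverage``)."""
    path = Path(path)
    doc = _array_to_dict(array, inline_positions)
    if not inline_positions:
        side = path.with_suffix(path.suffix + ".h5")
        with h5py.File(side, "w") as f:
            f.create_dataset("positions", data=array.positions)
            f.create_dataset("radius", data=float(array.radius))
            f.create_dataset("coverage", data=array.coverage)
        doc["positions_file"] = side.name
    text = (json.dumps(doc, indent=1) if path.suffix == ".json"
            else yaml.safe_dump(doc, sort_keys=True))
    path.write_text(text)


def load_array(path: str | Path) -> DetectorArray:
    path = Path(path)
    doc = (json.loads(path.read_text()) if path.suffix == ".json"
           else yaml.safe_load(path.read_text()))
    if "positions" in doc:
        pos = np.asarray(doc["positions"], dtype=float)
    else:
        with h5py.File(path.parent / doc["positions_file"], "r") as f:
            pos = f["positions"][()]
    return DetectorArray(pos, float(doc["radius"]), doc["coverage"])


def save_phantom(phantom: Phantom, path: str | Path):
    doc = {"absorbers": phantom.absorbers.tolist(),
           "bounding_box": phantom.bounding_box.tolist()}
    path = Path(path)
    text = (json.dumps(doc, indent=1) if path.suffix == ".json"
            else yaml.safe_dump(doc, sort_keys=True))
    path.write_text(text)


def load_phantom(path: str | Path) -> Phantom:
    path = Path(path)
    doc = (json.loads(path.read_text()) if path.suffix == ".json"
           else yaml.safe_load(path.read_text()))
    return Phantom(np.asarray(doc["absorbers"], dtype=float),
                   np.asarray(doc["bounding_box"], dtype=float))
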