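"""Closed-form photoacoustic forward model for uniform spherical absorbers.

A uniformly heated sphere of radius ``a`` at distance ``d`` from a point
detector emits the classic bipolar "N-shaped" pressure pulse

    p(t) = A * (d - c*t) / (2*d)   for |d - c*t| <= a,   0 otherwise,

which is linear in the absorber amplitude ``A`` and changes sign at the
centre's acoustic delay ``t = d/c``.  Channel data are the superposition of
these pulses over all absorbers, sampled pointwise on the time axis (no
band-limiting), so a scalar oracle can reproduce every trace exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np

from .geometry import DetectorArray, Phantom

__all__ = ["ChannelData", "simulate_channels", "restrict_channels",
           "save_channels", "load_channels", "SPEED_OF_SOUND"]

SPEED_OF_SOUND = 1500.0  # m/s, water coupling
DEFAULT_DT = 25e-9  # s (40 MS/s)


@dataclasses.dataclass(frozen=True)
class ChannelData:
    """Time-resolved pressure traces for every detector of an array.

    ``samples`` is (n_detectors, n_t); the time axis is ``t0 + dt * k`` in
    seconds.  ``array_ref`` identifies the generating geometry.
    """

    samples: np.ndarray
    t0: float
    dt: float
    array_ref: str = ""

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] < 2:
            raise ValueError("samples must be 2-D with at least two time samples")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(s)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", s)

    @property
    def n_detectors(self) -> int:
        return self.samples.shape[0]

    @property
    def n_t(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_t)


def _c_mm(c: float) -> float:
    """Speed of sound converted to mm/s (geometry is in mm)."""
    return c * 1e3


def default_time_window(phantom: Phantom, array: DetectorArray, dt: float, c: float):
    """(t0, n_t) covering the acoustic delay of every point of the phantom's
    bounding box from every detector, with one sample of padding per side.

    Fitting the window to the box (rather than just the absorber pulses) lets
    the same channel data be back-projected onto any grid inside the box.
    """
    cm = _c_mm(c)
    lo, hi = phantom.bounding_box
    corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                        for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    pos = array.positions
    d_max = np.linalg.norm(pos[:, None, :] - corners[None, :, :], axis=2).max()
    nearest = np.clip(pos, lo, hi)
    d_min = np.linalg.norm(pos - nearest, axis=1).min()
    t_min = d_min / cm - dt
    t_max = d_max / cm + dt
    n_t = int(np.ceil((t_max - max(t_min, 0.0)) / dt)) + 1
    return max(t_min, 0.0), max(n_t, 2)


def simulate_channels(
    phantom: Phantom,
    array: DetectorArray,
    t0: float | None = None,
    dt: float = DEFAULT_DT,
    n_t: int | None = None,
    c: float = SPEED_OF_SOUND,
    noise_std: float = 0.0,
    noise_seed: int = 0,
) -> ChannelData:
    """Simulate noise-free channel data; optionally add white Gaussian noise.

    If ``t0``/``n_t`` are omitted the window is auto-fitted to cover every
    pulse.  An explicitly requested window that clips a pulse raises a
    ``ValueError`` naming the offending absorber-detector pair.
    """
    if c <= 0:
        raise ValueError("speed of sound must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    cm = _c_mm(c)
    auto_t0, auto_nt = default_time_window(phantom, array, dt, c)
    if t0 is None:
        t0 = auto_t0
    if n_t is None:
        n_t = max(auto_nt, int(np.ceil((auto_t0 + auto_nt * dt - t0) / dt)) + 1)
    if n_t < 2:
        raise ValueError("n_t must be >= 2")
    t = t0 + dt * np.arange(n_t)
    samples = np.zeros((array.n_detectors, n_t))
    for k in range(phantom.n_absorbers):
        center = phantom.centers[k]
        a = phantom.radii[k]
        amp = phantom.amplitudes[k]
        d = np.linalg.norm(array.positions - center[None, :], axis=1)
        lo, hi = (d.min() - a) / cm, (d.max() + a) / cm
        if lo < t[0] or hi > t[-1]:
            i = int(np.argmin(d)) if lo < t[0] else int(np.argmax(d))
            raise ValueError(
                f"time window [{t[0]:.3e}, {t[-1]:.3e}] s does not cover the pulse "
                f"of absorber {k} at detector {i} (support [{(d[i]-a)/cm:.3e}, "
                f"{(d[i]+a)/cm:.3e}] s)")
        u = d[:, None] - cm * t[None, :]
        samples += np.where(np.abs(u) <= a, amp * u / (2.0 * d[:, None]), 0.0)
    if noise_std > 0:
        rng = np.random.default_rng(noise_seed)
        samples = samples + rng.normal(0.0, noise_std, samples.shape)
    return ChannelData(samples, float(t0), float(dt))


def restrict_channels(data: ChannelData, subset) -> ChannelData:
    """Rows of ``data`` at the subset's detector indices, in subset order.

    ``subset`` may be a :class:`~zsa2a.model.DetectorSubset` or a plain index
    sequence.  The time axis is unchanged.
    """
    indices = np.asarray(getattr(subset, "indices", subset), dtype=int)
    if indices.size and (indices.min() < 0 or indices.max() >= data.n_detectors):
        raise ValueError("subset indices out of range for this channel data")
    return ChannelData(data.samples[indices], data.t0, data.dt, data.array_ref)


def save_channels(data: ChannelData, path: str | Path,
                  array: DetectorArray | None = None):
    """HDF5 sinogram: dataset "samples", attrs "t0"/"dt", optional group
    "array" carrying the geometry."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("samples", data=data.samples)
        ds.attrs["t0"] = data.t0
        ds.attrs["dt"] = data.dt
        if array is not None:
            g = f.create_group("array")
            g.create_dataset("positions", data=array.positions)
            g.attrs["radius"] = array.radius
            g.attrs["coverage"] = array.coverage


def load_channels(path: str | Path):
    """Returns ``(ChannelData, DetectorArray | None)``."""
    with h5py.File(path, "r") as f:
        ds = f["samples"]
        data = ChannelData(ds[()], float(ds.attrs["t0"]), float(ds.attrs["dt"]))
        array = None
        if "array" in f:
            g = f["array"]
            array = DetectorArray(g["positions"][()], float(g.attrs["radius"]),
                                  str(g.attrs["coverage"]))
    return data, array
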