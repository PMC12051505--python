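"""Image-quality metrics: PSNR, SSIM, CNR and maximum amplitude projection.

Conventions (they matter when comparing absolute numbers across studies):

* PSNR uses ``MAX = max(reference)`` — the reference image's peak value, not
  a fixed bit-depth range — and returns ``inf`` for identical images.
* SSIM is the mean local SSIM with an 11x11 Gaussian window (sigma = 1.5),
  K1 = 0.01, K2 = 0.03 and dynamic range ``reference.max() - reference.min()``
  (the Wang et al. settings, delegated to scikit-image).
* CNR is ``|mean(signal) - mean(background)| / std(background)`` with the
  population (ddof = 0) standard deviation; regions are explicit inputs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.metrics import structural_similarity

from .recon import AXES, ReconImage

__all__ = ["psnr", "ssim", "cnr", "map_projection", "MetricsReport"]


def _values(image) -> np.ndarray:
    return np.asarray(image.values if isinstance(image, ReconImage) else image,
                      dtype=float)


def _check_same_shape(reference, test):
    r, t = _values(reference), _values(test)
    if r.shape != t.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {t.shape}")
    return r, t


def psnr(reference, test) -> float:
    """Peak signal-to-noise ratio in dB, ``10 log10(MAX^2 / MSE)``.

    ``MAX`` is the reference maximum; identical images return ``inf``.
    """
    r, t = _check_same_shape(reference, test)
    peak = float(r.max())
    if peak <= 0:
        raise ValueError("reference must have a positive maximum value")
    mse = float(np.mean((r - t) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak ** 2 / mse)


def ssim(reference, test) -> float:
    """Mean structural similarity (Gaussian window sigma=1.5, 11x11)."""
    r, t = _check_same_shape(reference, test)
    if min(r.shape) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    drange = float(r.max() - r.min())
    if drange == 0:
        raise ValueError("reference has zero dynamic range")
    return float(structural_similarity(
        r, t, gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
        K1=0.01, K2=0.03, data_range=drange))


def _roi_values(image: np.ndarray, roi) -> np.ndarray:
    """A region is a boolean mask or a box of per-axis (start, stop) pairs."""
    if isinstance(roi, np.ndarray) and roi.dtype == bool:
        if roi.shape != image.shape:
            raise ValueError("mask shape must match the image")
        return image[roi]
    slicer = tuple(slice(int(a), int(b)) for a, b in roi)
    return image[slicer].ravel()


def _roi_mask(image: np.ndarray, roi) -> np.ndarray:
    if isinstance(roi, np.ndarray) and roi.dtype == bool:
        return roi
    m = np.zeros(image.shape, dtype=bool)
    m[tuple(slice(int(a), int(b)) for a, b in roi)] = True
    return m


def cnr(image, signal_roi, background_roi) -> float:
    """Contrast-to-noise ratio between two disjoint regions.

    Returns ``inf`` when the background has zero spread but the means differ,
    and 0 when both regions are identical constants.
    """
    img = _values(image)
    m_sig = _roi_mask(img, signal_roi)
    m_bg = _roi_mask(img, background_roi)
    if not m_sig.any() or not m_bg.any():
        raise ValueError("regions must be non-empty")
    if (m_sig & m_bg).any():
        raise ValueError("signal and background regions must be disjoint")
    sig = img[m_sig]
    bg = img[m_bg]
    contrast = abs(float(sig.mean()) - float(bg.mean()))
    spread = float(bg.std(ddof=0))
    if spread == 0.0:
        return 0.0 if contrast == 0.0 else float("inf")
    return contrast / spread


def map_projection(volume, axis: str = "z") -> np.ndarray:
    """Maximum amplitude projection: per-pixel maximum along one axis
    (values as-is, no absolute value)."""
    v = _values(volume)
    if v.ndim != 3:
        raise ValueError("map_projection requires a 3-D volume")
    ax = AXES[axis] if isinstance(axis, str) else int(axis)
    return v.max(axis=ax)


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    """A scored comparison of a test image against a reference."""

    psnr: float
    ssim: float
    cnr: float | None = None
    roi_spec: dict | None = None
    reference_id: str = ""

    def __post_init__(self):
        if self.ssim > 1.0 + 1e-12:
            raise ValueError("ssim cannot exceed 1")
        if self.cnr is not None and self.cnr < 0:
            raise ValueError("cnr must be non-negative")

    @classmethod
    def compute(cls, reference, test, signal_roi=None, background_roi=None,
                reference_id: str = "") -> "MetricsReport":
        c = None
        spec = None
        if signal_roi is not None and background_roi is not None:
            c = cnr(test, signal_roi, background_roi)
            spec = {"signal": np.asarray(signal_roi).tolist()
                    if not isinstance(signal_roi, np.ndarray) else "mask",
                    "background": np.asarray(background_roi).tolist()
                    if not isinstance(background_roi, np.ndarray) else "mask"}
        return cls(psnr(reference, test), ssim(reference, test), c, spec,
                   reference_id)
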