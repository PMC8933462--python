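"""Global and local binarization operators for 8-bit en-face images.

Implements the ImageJ-style operators the flow pipelines compose: Huang's
minimum-fuzziness global threshold, Kapur's maximum-entropy ("MaxEntropy")
global threshold, local-median binarization, and Phansalkar's local
threshold for low-contrast capillary textures.  Conventions throughout:

* global thresholds work on 256-bin histograms of 8-bit levels and break
  ties toward the lower level;
* local operators use a circular window of a given pixel radius with edge
  replication at the borders;
* a pixel is foreground iff its value is STRICTLY greater than its
  threshold, so a perfectly flat image binarizes to all-background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

__all__ = [
    "DegenerateHistogramError",
    "BinaryMap",
    "PhansalkarParams",
    "image_histogram",
    "huang_threshold",
    "maxentropy_threshold",
    "median_local_binarize",
    "phansalkar_binarize",
]


class DegenerateHistogramError(ValueError):
    """Raised when a global threshold is requested for a single-level image."""


@dataclass
class BinaryMap:
    """A boolean flow/no-flow map plus the operator chain that produced it."""

    pixels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2 or p.dtype != bool:
            raise ValueError("BinaryMap requires a 2-D boolean grid")
        self.pixels = p

    @property
    def shape(self):
        return self.pixels.shape

    def foreground_count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class PhansalkarParams:
    """Published Phansalkar parameters, intensities normalised to [0, 1]."""

    radius_px: int = 15
    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ValueError("window radius must be >= 1 px")
        if self.r <= 0:
            raise ValueError("dynamic-range normaliser r must be > 0")


def _disk(radius: int) -> np.ndarray:
    y, x = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (x * x + y * y) <= radius * radius


def image_histogram(img: np.ndarray) -> np.ndarray:
    """256-bin histogram of an image given in [0, 1] or as 8-bit levels."""
    a = np.asarray(img)
    if a.dtype == np.uint8:
        levels = a
    else:
        a = a.astype(float)
        if a.min() < 0 or a.max() > 1:
            raise ValueError("float images must be normalised to [0, 1]")
        levels = np.round(a * 255.0).astype(np.uint8)
    return np.bincount(levels.ravel(), minlength=256).astype(np.int64)


def _check_histogram(hist) -> np.ndarray:
    h = np.asarray(hist, dtype=float)
    if h.shape != (256,):
        raise ValueError("histogram must have 256 bins (8-bit levels)")
    if (h < 0).any():
        raise ValueError("histogram counts must be nonnegative")
    if h.sum() <= 0:
        raise ValueError("histogram total must be positive")
    if np.count_nonzero(h) < 2:
        raise DegenerateHistogramError(
            "histogram has a single occupied level; no threshold separates it")
    return h


def huang_threshold(hist) -> int:
    """Huang–Wang minimum-fuzziness threshold of an 8-bit histogram.

    For each candidate level ``t`` the image is split into the classes
    ``g <= t`` and ``g > t`` with means ``mu0``, ``mu1``; each level's
    membership is ``u(g) = 1 / (1 + |g - mu_class| / C)`` with ``C`` the
    occupied dynamic range, and the candidate minimising the total Shannon
    fuzziness ``sum counts(g) * S(u(g))`` is returned (ties toward the
    lower level).
    """
    h = _check_histogram(hist)
    g = np.arange(256, dtype=float)
    occ = np.nonzero(h)[0]
    c = float(occ[-1] - occ[0])
    w = np.cumsum(h)
    wg = np.cumsum(h * g)
    total, total_g = w[-1], wg[-1]

    best_t, best_f = None, np.inf
    for t in range(int(occ[0]), int(occ[-1])):
        n0 = w[t]
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = wg[t] / n0
        mu1 = (total_g - wg[t]) / n1
        dist = np.where(g <= t, np.abs(g - mu0), np.abs(g - mu1))
        u = 1.0 / (1.0 + dist / c)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = -(u * np.log(u) + (1.0 - u) * np.log(1.0 - u))
        s[~np.isfinite(s)] = 0.0  # u == 1 contributes zero fuzziness
        f = float(np.sum(h * s))
        if f < best_f - 1e-12:
            best_f, best_t = f, t
    return int(best_t)


def maxentropy_threshold(hist) -> int:
    """Kapur maximum-entropy threshold of an 8-bit histogram.

    Returns the level ``t`` maximising the sum of Shannon entropies of the
    normalised class distributions below and above ``t`` (zero-probability
    bins skipped; ties toward the lower level).
    """
    h = _check_histogram(hist)
    p = h / h.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    cp = np.cumsum(p)
    cplogp = np.cumsum(plogp)
    occ = np.nonzero(h)[0]

    best_t, best_h = None, -np.inf
    for t in range(int(occ[0]), int(occ[-1])):
        p0 = cp[t]
        p1 = 1.0 - p0
        if p0 <= 0 or p1 <= 0:
            continue
        h0 = np.log(p0) - cplogp[t] / p0
        h1 = np.log(p1) - (cplogp[-1] - cplogp[t]) / p1
        tot = h0 + h1
        if tot > best_h + 1e-12:
            best_h, best_t = tot, t
    return int(best_t)


def _is_quantized(img: np.ndarray) -> bool:
    lv = img * 255.0
    return bool(np.allclose(lv, np.round(lv), atol=1e-9))


def median_local_binarize(img: np.ndarray, radius_px: int = 15) -> BinaryMap:
    """Foreground where a pixel strictly exceeds its circular-window median.

    The window has the given pixel radius and the border is handled by edge
    replication.  Images already on the 8-bit grid take a fast histogram
    rank-filter path; the result is identical to the direct median.
    """
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2-D image")
    if radius_px < 1:
        raise ValueError("window radius must be >= 1 px")
    if radius_px > min(a.shape):
        raise ValueError(
            f"window radius {radius_px} exceeds the image side {min(a.shape)}")
    fp = _disk(radius_px)
    if _is_quantized(a) and a.min() >= 0 and a.max() <= 1:
        from skimage.filters.rank import median as _rank_median
        lv = np.round(a * 255.0).astype(np.uint8)
        padded = np.pad(lv, radius_px, mode="edge")
        med = _rank_median(padded, fp)[radius_px:-radius_px, radius_px:-radius_px]
        fg = lv > med
    else:
        med = ndimage.median_filter(a, footprint=fp, mode="nearest")
        fg = a > med
    return BinaryMap(fg, provenance=f"median-local(r={radius_px})")


def _local_mean_std(img: np.ndarray, radius_px: int):
    """Circular-window mean and standard deviation with edge replication."""
    fp = _disk(radius_px).astype(float)
    fp /= fp.sum()
    pad = np.pad(img, radius_px, mode="edge")
    m = fftconvolve(pad, fp, mode="valid")
    m2 = fftconvolve(pad * pad, fp, mode="valid")
    var = np.clip(m2 - m * m, 0.0, None)
    return m, np.sqrt(var)


def phansalkar_binarize(img: np.ndarray,
                        params: PhansalkarParams | None = None) -> BinaryMap:
    """Phansalkar local threshold for low-contrast bright-on-dark textures.

    The per-pixel threshold is

        t = m * (1 + p * exp(-q * m) + k * (s / r - 1))

    with ``m``, ``s`` the local circular-window mean and standard deviation
    (edge replication) and the published parameter defaults
    ``k=0.25, r=0.5, p=2, q=10`` for intensities in [0, 1].  A pixel is
    flow (white) iff its value strictly exceeds ``t``.
    """
    params = params or PhansalkarParams()
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2-D image")
    if a.size == 0:
        raise ValueError("empty image")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("Phansalkar input must be normalised to [0, 1]")
    if params.radius_px > min(a.shape):
        raise ValueError("window radius exceeds the image side")
    m, s = _local_mean_std(a, params.radius_px)
    t = m * (1.0 + params.p * np.exp(-params.q * m)
             + params.k * (s / params.r - 1.0))
    return BinaryMap(a > t,
                     provenance=f"phansalkar(r={params.radius_px})")
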