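"""Render en-face OCTA slab images from a phantom under an acquisition setting.

The intensity model per pixel is

    I = clip(T_eff * template * speckle + noise_floor * N(0, 1), 0, 1)

quantised to 8-bit levels, where ``T_eff = 10**(-OD * sensitivity)`` is the
effective neutral-density-filter transmittance.  ``template`` encodes the
slab's flow structure: SCP large vessels are fully decorrelated (level 1.0),
retinal capillaries sit lower (faster fringe washout at capillary flow
speeds), the DCP optionally carries an attenuated projection of the SCP
large vessels, and the CC texture is shadowed under the large vessels.
Speckle is a bounded symmetric multiplicative term (0.55 + 0.45 * Beta(2,2)):
bounded tails keep noise-free renders strictly ordered (every true-flow
pixel brighter than every background pixel), which an unbounded heavy-tailed
speckle would break.

Signal strength (SS) maps the image's contrast-to-noise ratio onto the 0-10
scale devices report.  Devices do not publish their SS formula; only the
endpoints of the scale are meaningful here: a noise-free unattenuated render
scores 10 and a structureless pure-noise image scores 0, with SS monotone in
the signal-to-noise ratio in between.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import ndimage

from .optics import AcquisitionSetting
from .phantom import SubjectPhantom

__all__ = ["EnFaceImage", "render_slab", "signal_strength", "SLABS"]

SLABS = ("SCP", "DCP", "CC")
_SLAB_CODE = {"SCP": 1, "DCP": 2, "CC": 3}

#: template amplitudes, relative to a fully decorrelated large vessel
PROJECTION_LEVEL = 0.35   # residual SCP large-vessel projection in the DCP
CC_SHADOW_DEPTH = 0.35    # intensity lost under a large vessel in the CC

#: device display floor: flow pixels whose decorrelation signal stays below
#: this multiple of the noise floor are exported as black (no flow), the way
#: OCTA devices suppress low or noisy pixels before display
DISPLAY_FLOOR_SNR = 2.5

# SS calibration: contrast-to-noise of 3 (structureless noise field) maps to
# 0; 60 (clean unattenuated render at the default noise floor) maps to 10.
_SNR_AT_ZERO = 3.0
_SNR_AT_TEN = 60.0
_SIGMA_FLOOR = 1e-3  # quantisation-scale floor for noise-free images


@dataclass
class EnFaceImage:
    """A 2-D grayscale en-face slab image with physical pixel pitch."""

    pixels: np.ndarray            # float in [0, 1], quantised to 8-bit levels
    pixel_pitch_um: float
    slab: str
    acquisition: AcquisitionSetting

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("en-face image must be a square 2-D grid")
        if p.shape[0] < 64:
            raise ValueError("en-face image side must be >= 64 px")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")
        if self.slab not in SLABS:
            raise ValueError(f"unknown slab {self.slab!r}")
        side = p.shape[0]
        width = self.pixel_pitch_um * side
        if abs(width - self.acquisition.scan_width_um) > self.pixel_pitch_um:
            raise ValueError(
                "pixel pitch x side must equal the scan width within one pixel")
        self.pixels = p

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def _quantize(img: np.ndarray) -> np.ndarray:
    """Quantise to the 256 intensity levels of an 8-bit export."""
    return np.round(np.clip(img, 0.0, 1.0) * 255.0) / 255.0


def _ndtr(z: np.ndarray) -> np.ndarray:
    from scipy.special import ndtr
    return ndtr(z)


def _correlated_field(rng: np.random.Generator, shape, sigma: float
                      ) -> np.ndarray:
    """Unit-variance Gaussian field with correlation length ~sigma px."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _template(phantom: SubjectPhantom, slab: str, projection_removal: bool
              ) -> np.ndarray:
    if slab == "SCP":
        return np.where(phantom.large_vessel_map, 1.0,
                        phantom.scp_capillary_brightness)
    if slab == "DCP":
        tmpl = phantom.dcp_capillary_brightness.astype(float)
        if not projection_removal:
            tmpl = np.maximum(tmpl, PROJECTION_LEVEL * phantom.large_vessel_map)
        return tmpl
    if slab == "CC":
        scale = phantom.params.cc_scale
        vessels = phantom.large_vessel_map
        if scale > 1:
            vessels = np.kron(vessels, np.ones((scale, scale), dtype=bool))
        shadow = 1.0 - CC_SHADOW_DEPTH * ndimage.gaussian_filter(
            vessels.astype(float), sigma=1.5 * scale)
        return phantom.cc_texture * shadow
    raise ValueError(f"unknown slab {slab!r}")


def render_slab(
    phantom: SubjectPhantom,
    slab: str,
    acq: AcquisitionSetting,
    repeat: int = 0,
    projection_removal: bool = True,
) -> EnFaceImage:
    """Render one slab image; deterministic given (phantom, acq, repeat).

    Parameters
    ----------
    phantom : SubjectPhantom
    slab : {"SCP", "DCP", "CC"}
    acq : AcquisitionSetting
        Device model, NDF optical density, noise floor and seed.
    repeat : int
        Repeat-scan index; repeats share the template and differ only in the
        speckle and noise draws.
    projection_removal : bool
        When True (the devices' embedded default) the DCP render carries no
        projected copy of the SCP large vessels.
    """
    if slab not in SLABS:
        raise ValueError(f"unknown slab {slab!r}; expected one of {SLABS}")
    tmpl = _template(phantom, slab, projection_removal)
    side = tmpl.shape[0]

    rng = np.random.default_rng(np.random.SeedSequence(
        [int(phantom.seed), int(acq.seed), _SLAB_CODE[slab], int(repeat)]))
    # speckle and noise are correlated at the PSF scale: a faint vessel
    # segment fades as a contiguous piece, not as salt-and-pepper holes
    speckle = 0.55 + 0.45 * _ndtr(_correlated_field(rng, tmpl.shape, 1.5))
    img = acq.effective_transmittance * tmpl * speckle
    if acq.noise_floor > 0:
        img = img + acq.noise_floor * _correlated_field(rng, tmpl.shape, 1.0)
        # device-side suppression of low/noisy pixels before display
        img = np.where(img < DISPLAY_FLOOR_SNR * acq.noise_floor, 0.0, img)
    pitch = acq.scan_width_um / side
    return EnFaceImage(pixels=_quantize(img), pixel_pitch_um=pitch,
                       slab=slab, acquisition=acq)


def signal_strength(img: EnFaceImage) -> float:
    """Device-style signal strength on the 0-10 scale.

    The score is a clamped log mapping of the image's contrast-to-noise
    ratio (99th minus 10th intensity percentile over the acquisition noise
    floor).  It is monotone nondecreasing in the signal-to-noise ratio,
    scores 10 for a noise-free unattenuated render and 0 for a structureless
    pure-noise image, and — being built from percentile differences — is
    invariant to any constant intensity offset.
    """
    p = img.pixels
    if p.size == 0:
        raise ValueError("empty image")
    amplitude = float(np.percentile(p, 99) - np.percentile(p, 10))
    sigma = max(float(img.acquisition.noise_floor), _SIGMA_FLOOR)
    snr = amplitude / sigma
    if snr <= 0:
        return 0.0
    score = 10.0 * (np.log10(snr / _SNR_AT_ZERO)
                    / np.log10(_SNR_AT_TEN / _SNR_AT_ZERO))
    return float(np.clip(score, 0.0, 10.0))
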