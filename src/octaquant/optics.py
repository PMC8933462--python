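"""Acquisition optics: neutral-density-filter attenuation and sampling grids.

A neutral density filter (NDF) of optical density ``OD`` transmits a fraction
``10**(-OD)`` of the illumination light.  OD 0.3 therefore cuts the beam by
about 50 % and OD 0.6 by about 75 %, which is how commercial NDFs used on
OCTA devices are specified.  The en-face sampling grid of a 6 x 6 mm volume
scan is ``scan_width_um / n_ascans`` microns per A-scan: 6000/350 = 17.1 um
for a 350-A-scan spectral-domain protocol and 6000/420 = 14.3 um for a
420-A-scan swept-source protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AcquisitionSetting",
    "ndf_transmittance",
    "ndf_reduction_percent",
    "grid_separation",
    "DEVICE_N_ASCANS",
    "DEVICE_SENSITIVITY",
]

#: A-scans per B-scan for the two simulated device classes (spectral-domain
#: and swept-source 6 x 6 mm protocols).
DEVICE_N_ASCANS = {"SD": 350, "SS": 420}

#: How strongly each device's reported signal degrades per unit optical
#: density.  The spectral-domain model loses more signal per OD step than the
#: swept-source model (fewer A-scans, shorter wavelength); 1.5 puts the SD
#: trajectory near a signal strength of 4 at OD 0.6 while the swept-source
#: model stays above 6.  Qualitative device asymmetry only.
DEVICE_SENSITIVITY = {"SD": 1.5, "SS": 1.0}


def ndf_transmittance(od: float) -> float:
    """Fraction of light transmitted by a neutral density filter.

    Parameters
    ----------
    od : float
        Optical density (>= 0).  OD 0 is no filter.

    Returns
    -------
    float
        ``10**(-od)``, in (0, 1].
    """
    if od < 0:
        raise ValueError(f"optical density must be >= 0, got {od}")
    return 10.0 ** (-od)


def ndf_reduction_percent(od: float) -> float:
    """Percent reduction of illumination, ``(1 - 10**(-od)) * 100``."""
    return (1.0 - ndf_transmittance(od)) * 100.0


def grid_separation(scan_width_um: float, n_ascans: int) -> float:
    """Separation of the homogeneous en-face sampling grid in microns."""
    if n_ascans < 1:
        raise ValueError(f"n_ascans must be >= 1, got {n_ascans}")
    if scan_width_um <= 0:
        raise ValueError(f"scan width must be positive, got {scan_width_um}")
    return scan_width_um / n_ascans


@dataclass(frozen=True)
class AcquisitionSetting:
    """One scan condition: device model, NDF, noise floor and seed.

    Attributes
    ----------
    device_model : {"SD", "SS"}
        Spectral-domain or swept-source device class.
    scan_width_um : float
        Field width (6 x 6 mm protocol by default).
    n_ascans : int
        A-scans per B-scan (350 for SD, 420 for SS).
    ndf_od : float
        Optical density of the attached neutral density filter (0 = none).
    noise_floor : float
        Standard deviation of the additive acquisition noise, on the [0, 1]
        intensity scale.
    seed : int
        Seed for all stochastic terms of renders under this setting.
    attenuation_sensitivity : float
        Device-specific multiplier on the optical density; the effective
        transmittance of a render is ``10**(-ndf_od * attenuation_sensitivity)``.
    """

    device_model: str = "SD"
    scan_width_um: float = 6000.0
    n_ascans: int = 350
    ndf_od: float = 0.0
    noise_floor: float = 0.015
    seed: int = 0
    attenuation_sensitivity: float = 1.0

    def __post_init__(self) -> None:
        if self.device_model not in DEVICE_N_ASCANS:
            raise ValueError(f"unknown device model {self.device_model!r}")
        if self.ndf_od < 0:
            raise ValueError("ndf_od must be >= 0")
        if not 0.0 <= self.noise_floor <= 1.0:
            raise ValueError("noise_floor must be in [0, 1]")
        # trigger the domain checks
        grid_separation(self.scan_width_um, self.n_ascans)

    @classmethod
    def for_device(
        cls,
        device_model: str,
        ndf_od: float = 0.0,
        seed: int = 0,
        noise_floor: float = 0.015,
        scan_width_um: float = 6000.0,
    ) -> "AcquisitionSetting":
        """Build a setting with the device-class defaults filled in."""
        if device_model not in DEVICE_N_ASCANS:
            raise ValueError(f"unknown device model {device_model!r}")
        return cls(
            device_model=device_model,
            scan_width_um=scan_width_um,
            n_ascans=DEVICE_N_ASCANS[device_model],
            ndf_od=ndf_od,
            noise_floor=noise_floor,
            seed=seed,
            attenuation_sensitivity=DEVICE_SENSITIVITY[device_model],
        )

    @property
    def grid_separation_um(self) -> float:
        return grid_separation(self.scan_width_um, self.n_ascans)

    @property
    def transmittance(self) -> float:
        """Single-pass NDF transmittance, ``10**(-ndf_od)``."""
        return ndf_transmittance(self.ndf_od)

    @property
    def effective_transmittance(self) -> float:
        """Transmittance including the device sensitivity multiplier."""
        return ndf_transmittance(self.ndf_od * self.attenuation_sensitivity)
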