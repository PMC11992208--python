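"""Photoexcitation and jet-geometry budget for pump-probe serial crystallography.

Closed-form estimates of how strongly a microcrystal in a lipidic cubic
phase (LCP) microjet is photoexcited by a millisecond pump-laser flash,
and how far the jet carries it between flashes:

* fluence averaged across the laser's FWHM focal spot (for a Gaussian
  beam exactly half the total power falls within the FWHM circle);
* absorption cross-section from the molar extinction coefficient;
* the dimensionless photons-absorbed-per-chromophore product F*sigma/(h*nu);
* the depth-averaged attenuation through a crystal of given optical
  density (Beer-Lambert, averaged over a uniform path);
* jet velocity from volumetric flow and nozzle diameter, the translation
  between consecutive flashes, and the height of the photoactivated
  column swept past the X-ray beam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AVOGADRO",
    "PLANCK_J_S",
    "SPEED_OF_LIGHT_M_S",
    "LaserConfig",
    "CrystalOptics",
    "JetConfig",
    "JetKinematics",
    "mean_fluence_within_fwhm",
    "absorption_cross_section",
    "photons_per_chromophore",
    "depth_average_factor",
    "jet_kinematics",
    "budget_report",
]

AVOGADRO = 6.02214076e23        # 1/mol
PLANCK_J_S = 6.62607015e-34     # J s
SPEED_OF_LIGHT_M_S = 2.99792458e8

# unit conversions used below
_MW_TO_W = 1e-3
_MS_TO_S = 1e-3
_UM_TO_CM = 1e-4
_NM_TO_M = 1e-9
_UL_PER_MIN_TO_UM3_PER_S = 1e9 / 60.0


@dataclass(frozen=True)
class LaserConfig:
    """Pump laser: power (mW), wavelength (nm), FWHM spot diameter (um), pulse (ms)."""

    power_mw: float
    wavelength_nm: float
    fwhm_diameter_um: float
    pulse_ms: float

    def __post_init__(self):
        for name in ("power_mw", "wavelength_nm", "fwhm_diameter_um", "pulse_ms"):
            if getattr(self, name) < 0 or (name != "power_mw" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CrystalOptics:
    """Chromophore optics: molar extinction (1/(M cm)), OD, crystal path (um)."""

    extinction_m1_cm1: float
    od: float
    path_um: float

    def __post_init__(self):
        if self.extinction_m1_cm1 < 0 or self.od < 0 or self.path_um < 0:
            raise ValueError("optical parameters must be non-negative")


@dataclass(frozen=True)
class JetConfig:
    """LCP microjet: flow (ul/min), nozzle diameter (um), flash repetition (Hz)."""

    flow_ul_per_min: float
    jet_diameter_um: float
    repetition_hz: float

    def __post_init__(self):
        if min(self.flow_ul_per_min, self.jet_diameter_um, self.repetition_hz) <= 0:
            raise ValueError("jet parameters must be positive")


@dataclass(frozen=True)
class JetKinematics:
    velocity_um_per_s: float
    translation_per_flash_um: float

    def column_height_um(self, t_loss_ms: float) -> float:
        """Height of jet photoactivated within ``t_loss_ms`` of passing the laser."""
        return self.velocity_um_per_s * t_loss_ms * _MS_TO_S


def mean_fluence_within_fwhm(laser: LaserConfig) -> float:
    """Pulse fluence in mJ/cm^2 averaged across the FWHM focal circle.

    Half of a Gaussian beam's total power falls inside the FWHM circle,
    so F = 0.5 * P * t_pulse / (pi * (FWHM/2)^2).
    """
    energy_mj = laser.power_mw * laser.pulse_ms * _MS_TO_S  # mW * s = mJ
    radius_cm = 0.5 * laser.fwhm_diameter_um * _UM_TO_CM
    return 0.5 * energy_mj / (math.pi * radius_cm**2)


def absorption_cross_section(extinction_m1_cm1: float) -> float:
    """Absorption cross-section in cm^2 from molar extinction in 1/(M cm).

    sigma = 1000 * ln(10) * eps / N_A  (the 1000 converts litres to cm^3).
    """
    if extinction_m1_cm1 < 0:
        raise ValueError("extinction must be non-negative")
    return 1000.0 * math.log(10.0) * extinction_m1_cm1 / AVOGADRO


def photons_per_chromophore(
    fluence_mj_cm2: float, cross_section_cm2: float, wavelength_nm: float
) -> float:
    """Dimensionless photons absorbed per chromophore, F*sigma/(h*nu)."""
    if min(fluence_mj_cm2, cross_section_cm2, wavelength_nm) < 0:
        raise ValueError("arguments must be non-negative")
    photon_energy_j = PLANCK_J_S * SPEED_OF_LIGHT_M_S / (wavelength_nm * _NM_TO_M)
    return fluence_mj_cm2 * 1e-3 * cross_section_cm2 / photon_energy_j


def depth_average_factor(od: float) -> float:
    """Mean Beer-Lambert transmission over a uniform path through OD ``od``.

    (1/L) int_0^L 10^(-od*x/L) dx = (1 - 10^-od) / (od * ln 10); 1 at od=0.
    Monotonically decreasing, -> 0 as od -> infinity.
    """
    if od < 0:
        raise ValueError("od must be non-negative")
    if od == 0:
        return 1.0
    return (1.0 - 10.0 ** (-od)) / (od * math.log(10.0))


def jet_kinematics(jet: JetConfig) -> JetKinematics:
    """Average jet velocity, per-flash translation (from flow and nozzle size)."""
    area_um2 = math.pi * (0.5 * jet.jet_diameter_um) ** 2
    v = jet.flow_ul_per_min * _UL_PER_MIN_TO_UM3_PER_S / area_um2
    return JetKinematics(
        velocity_um_per_s=v,
        translation_per_flash_um=v / jet.repetition_hz,
    )


def budget_report(
    laser: LaserConfig,
    optics: CrystalOptics,
    jet: JetConfig,
    t_loss_ms: float = 120.0,
) -> dict:
    """All budget quantities in one dictionary (the CLI's JSON payload)."""
    fluence = mean_fluence_within_fwhm(laser)
    sigma = absorption_cross_section(optics.extinction_m1_cm1)
    surface = photons_per_chromophore(fluence, sigma, laser.wavelength_nm)
    depth = depth_average_factor(optics.od)
    kin = jet_kinematics(jet)
    return {
        "fluence_mj_cm2": fluence,
        "cross_section_cm2": sigma,
        "photons_per_chromophore_surface": surface,
        "depth_average_factor": depth,
        "photons_per_chromophore_volume": surface * depth,
        "jet_velocity_um_per_s": kin.velocity_um_per_s,
        "translation_per_flash_um": kin.translation_per_flash_um,
        "column_height_um": kin.column_height_um(t_loss_ms),
        "column_t_loss_ms": t_loss_ms,
    }
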