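"""Hydrodynamic size models: Stokes-Einstein, Perrin prolate ellipsoids,
molecular-weight comparison and oligomeric-state assignment.

A dynamic-light-scattering measurement yields a translational diffusion
coefficient D; the hydrodynamic radius of the equivalent sphere is
R_H = kT / (6 pi eta D). For an elongated particle the measured R_H exceeds
the radius of the equal-volume sphere by the Perrin translational friction
factor F(p) >= 1, a function of the axial ratio p of the prolate spheroid.

Because the hydration and specific-volume assumptions behind any particular
instrument-reported radius are rarely known, the module supports a
calibration mode: anchor the equivalent-sphere radius to one measured
state, then predict other oligomers by volume scaling (radius ~ V^(1/3))
and shape. Units: D in m^2/s, R_H in nm, molar masses in kDa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BOLTZMANN",
    "water_viscosity",
    "HydroMeasurement",
    "HydroParticle",
    "OligomerCandidate",
    "stokes_einstein_rh",
    "diffusion_from_rh",
    "perrin_factor_prolate",
    "ellipsoid_rh",
    "calibrate_equivalent_radius",
    "mass_discrepancy",
    "assign_oligomeric_state",
]

BOLTZMANN = 1.380649e-23  # J/K

# Dynamic viscosity of water, 0-40 degC, in mPa*s (CRC handbook values).
_WATER_VISC_C = np.arange(0.0, 41.0, 5.0)
_WATER_VISC_MPAS = np.array(
    [1.792, 1.519, 1.307, 1.138, 1.002, 0.890, 0.797, 0.719, 0.653]
)


def water_viscosity(temperature_k: float) -> float:
    """Viscosity of water at the given temperature (K), in Pa*s.

    Linear interpolation on a 0-40 degC table; outside that range the
    tabulation does not apply and an error is raised.
    """
    t_c = temperature_k - 273.15
    if not 0.0 <= t_c <= 40.0:
        raise ValueError(
            f"water viscosity table covers 0-40 degC, got {t_c:.1f} degC"
        )
    return float(np.interp(t_c, _WATER_VISC_C, _WATER_VISC_MPAS)) * 1e-3


@dataclass(frozen=True)
class HydroMeasurement:
    """A translational diffusion coefficient with its solvent conditions."""

    d: float  # m^2/s
    temperature: float = 297.0  # K
    viscosity: Optional[float] = None  # Pa*s; water at `temperature` if None

    def __post_init__(self) -> None:
        if self.d <= 0 or self.temperature <= 0:
            raise ValueError("D and T must be positive")
        if self.viscosity is not None and self.viscosity <= 0:
            raise ValueError("viscosity must be positive")

    @property
    def eta(self) -> float:
        return (
            self.viscosity
            if self.viscosity is not None
            else water_viscosity(self.temperature)
        )


def stokes_einstein_rh(measurement: HydroMeasurement) -> float:
    """Hydrodynamic radius R_H = kT / (6 pi eta D), in nm."""
    m = measurement
    return BOLTZMANN * m.temperature / (6.0 * np.pi * m.eta * m.d) * 1e9


def diffusion_from_rh(
    rh_nm: float, temperature: float = 297.0, viscosity: Optional[float] = None
) -> float:
    """Inverse of :func:`stokes_einstein_rh`: D (m^2/s) from R_H (nm)."""
    if rh_nm <= 0:
        raise ValueError("R_H must be positive")
    eta = viscosity if viscosity is not None else water_viscosity(temperature)
    return BOLTZMANN * temperature / (6.0 * np.pi * eta * rh_nm * 1e-9)


def perrin_factor_prolate(p: float) -> float:
    """Perrin translational friction factor of a prolate spheroid.

    For axial ratio p = a/b >= 1 (a the long semi-axis),

        F(p) = p^(-1/3) sqrt(p^2 - 1) / ln(p + sqrt(p^2 - 1)),

    the ratio of the particle's R_H to the radius of the equal-volume
    sphere. F(1) = 1 by the continuous limit; F is strictly increasing.
    """
    if p < 1.0:
        raise ValueError(f"axial ratio must be >= 1 (prolate), got {p}")
    if p == 1.0:
        return 1.0
    xi = np.sqrt(p * p - 1.0)
    return float(p ** (-1.0 / 3.0) * xi / np.log(p + xi))


@dataclass(frozen=True)
class HydroParticle:
    """A particle model for predicting hydrodynamic size.

    The equivalent-sphere radius is computed from the hydrated molecular
    volume M (v_bar + hydration) / N_A, or taken from
    ``calibrated_radius_nm`` when provided (preferred when the instrument's
    volume assumptions are unknown).
    """

    molar_mass: float  # kDa
    axial_ratio: float = 1.0  # p >= 1; 1 = sphere
    partial_specific_volume: float = 0.73  # cm^3/g
    hydration: float = 0.35  # g water / g protein
    calibrated_radius_nm: Optional[float] = None  # equivalent-sphere radius

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar mass must be positive")
        if self.axial_ratio < 1.0:
            raise ValueError("axial ratio must be >= 1")
        if self.partial_specific_volume <= 0 or self.hydration < 0:
            raise ValueError("invalid volume/hydration parameters")
        if self.calibrated_radius_nm is not None and self.calibrated_radius_nm <= 0:
            raise ValueError("calibrated radius must be positive")

    def equivalent_sphere_radius(self) -> float:
        """Radius (nm) of the sphere with the particle's hydrated volume."""
        if self.calibrated_radius_nm is not None:
            return self.calibrated_radius_nm
        mass_g = self.molar_mass * 1e3 / 6.02214076e23  # g per molecule
        vol_cm3 = mass_g * (self.partial_specific_volume + self.hydration * 1.0)
        vol_nm3 = vol_cm3 * 1e21
        return float((3.0 * vol_nm3 / (4.0 * np.pi)) ** (1.0 / 3.0))


def ellipsoid_rh(particle: HydroParticle) -> float:
    """Predicted R_H (nm): equivalent-sphere radius times the Perrin factor."""
    return particle.equivalent_sphere_radius() * perrin_factor_prolate(
        particle.axial_ratio
    )


def calibrate_equivalent_radius(observed_rh_nm: float, axial_ratio: float) -> float:
    """Equivalent-sphere radius that reproduces an observed R_H at shape p.

    Use the result as ``calibrated_radius_nm`` of the anchor state; other
    oligomers follow by radius ~ (volume ratio)^(1/3).
    """
    if observed_rh_nm <= 0:
        raise ValueError("observed R_H must be positive")
    return observed_rh_nm / perrin_factor_prolate(axial_ratio)


def mass_discrepancy(observed_mw: float, predicted_mw: float) -> float:
    """Signed percent deviation 100 (observed - predicted) / predicted."""
    if observed_mw <= 0 or predicted_mw <= 0:
        raise ValueError("molecular weights must be positive")
    return 100.0 * (observed_mw - predicted_mw) / predicted_mw


@dataclass(frozen=True)
class OligomerCandidate:
    """A candidate oligomeric state with its predicted observables."""

    label: str
    predicted_mw: Optional[float] = None  # kDa
    predicted_rh: Optional[float] = None  # nm

    def __post_init__(self) -> None:
        if self.predicted_mw is None and self.predicted_rh is None:
            raise ValueError("candidate needs a predicted Mw and/or R_H")
        for v in (self.predicted_mw, self.predicted_rh):
            if v is not None and v <= 0:
                raise ValueError("predicted values must be positive")


def assign_oligomeric_state(
    candidates: Sequence[OligomerCandidate],
    observed_mw: Optional[float] = None,
    observed_rh: Optional[float] = None,
) -> list[tuple[OligomerCandidate, float]]:
    """Rank candidate oligomeric states against observed Mw and/or R_H.

    The score is the mean absolute relative deviation over the observables
    shared by the measurement and the candidate; smaller is better. Ties
    are broken in favor of the smaller oligomer (lower predicted Mw, then
    label). Returns (candidate, score) pairs sorted best-first.
    """
    if not candidates:
        raise ValueError("at least one candidate is required")
    if observed_mw is None and observed_rh is None:
        raise ValueError("at least one observable is required")
    scored = []
    for cand in candidates:
        devs = []
        if observed_mw is not None and cand.predicted_mw is not None:
            devs.append(abs(observed_mw - cand.predicted_mw) / cand.predicted_mw)
        if observed_rh is not None and cand.predicted_rh is not None:
            devs.append(abs(observed_rh - cand.predicted_rh) / cand.predicted_rh)
        if not devs:
            raise ValueError(
                f"candidate {cand.label!r} shares no observable with the "
                "measurement"
            )
        scored.append((cand, float(np.mean(devs))))
    scored.sort(
        key=lambda t: (
            t[1],
            t[0].predicted_mw if t[0].predicted_mw is not None else np.inf,
            t[0].label,
        )
    )
    return scored
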