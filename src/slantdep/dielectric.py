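"""Clausius-Mossotti factor and time-averaged DEP force for spherical particles.

The dielectric response of a homogeneous sphere in a lossy medium under an AC
field is captured by the complex Clausius-Mossotti (CM) factor

    CM(omega) = (eps_p* - eps_m*) / (eps_p* + 2 eps_m*),

with complex permittivities ``eps* = eps0*eps_r - i*sigma/omega``.  For
micron-scale polystyrene beads the particle conductivity is dominated by
surface conduction, ``sigma_e = 2*K_s/R + sigma_b``.  The real part of CM sets
the sign and magnitude of the time-averaged dielectrophoretic force

    F_DEP = 2*pi*eps_m*R^3 * Re(CM) * grad(E^2),

negative Re(CM) (nDEP) pushing particles toward low field-gradient regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from slantdep.constants import VACUUM_PERMITTIVITY

__all__ = [
    "MediumSpec",
    "ParticleSpec",
    "DriveSettings",
    "complex_permittivity",
    "effective_conductivity",
    "cm_factor",
    "cm_spectrum",
    "dep_force",
    "POLYSTYRENE_BEAD",
    "AQUEOUS_MEDIUM",
]


@dataclass(frozen=True)
class MediumSpec:
    """Suspending-fluid electrical and hydrodynamic properties.

    Parameters
    ----------
    rel_permittivity : float
        Relative permittivity eps_r,m (dimensionless, >= 1).
    conductivity : float
        Electrical conductivity sigma_m in S/m.
    viscosity : float
        Dynamic viscosity mu in Pa*s (default: water at room temperature).
    """

    rel_permittivity: float
    conductivity: float
    viscosity: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.rel_permittivity < 1.0:
            raise ValueError("rel_permittivity must be >= 1")
        if self.conductivity < 0.0:
            raise ValueError("conductivity must be >= 0")
        if self.viscosity <= 0.0:
            raise ValueError("viscosity must be > 0")


@dataclass(frozen=True)
class ParticleSpec:
    """Spherical particle radius and electrical properties.

    Parameters
    ----------
    radius : float
        Particle radius R in m (> 0).
    rel_permittivity : float
        Relative permittivity eps_r,p.
    bulk_conductivity : float
        Bulk conductivity sigma_b in S/m.
    surface_conductance : float
        Surface conductance K_s in S (1e-9 S is typical for polystyrene).
    """

    radius: float
    rel_permittivity: float
    bulk_conductivity: float = 0.0
    surface_conductance: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0.0:
            raise ValueError("radius must be > 0")
        if self.bulk_conductivity < 0.0 or self.surface_conductance < 0.0:
            raise ValueError("conductivities must be >= 0")


@dataclass(frozen=True)
class DriveSettings:
    """AC drive: peak-to-peak voltage and ordinary frequency.

    ``frequency`` is an ordinary frequency f in Hz; the angular frequency
    ``omega = 2*pi*f`` is derived, never supplied directly.
    """

    voltage_peak_to_peak: float
    frequency: float

    def __post_init__(self) -> None:
        if self.voltage_peak_to_peak <= 0.0:
            raise ValueError("voltage_peak_to_peak must be > 0")
        if self.frequency <= 0.0:
            raise ValueError("frequency must be > 0")

    @property
    def amplitude(self) -> float:
        """Voltage amplitude (half the peak-to-peak value), V."""
        return 0.5 * self.voltage_peak_to_peak

    @property
    def angular_frequency(self) -> float:
        """omega = 2*pi*f, rad/s."""
        return 2.0 * math.pi * self.frequency


#: Polystyrene bead of 5 um radius with standard literature properties.
POLYSTYRENE_BEAD = ParticleSpec(
    radius=5e-6,
    rel_permittivity=2.4,
    bulk_conductivity=1e-15,
    surface_conductance=1e-9,
)

#: DI-water-based working fluid (20% glycerol for density matching; its
#: permittivity is taken equal to DI water, conductivity as measured).
AQUEOUS_MEDIUM = MediumSpec(rel_permittivity=76.4, conductivity=2.03e-3)


def complex_permittivity(
    rel_permittivity: float, conductivity: float, angular_frequency: float
) -> complex:
    """Complex permittivity ``eps* = eps0*eps_r - i*sigma/omega`` (F/m).

    Raises
    ------
    ValueError
        If ``angular_frequency`` is not strictly positive.
    """
    if angular_frequency <= 0.0:
        raise ValueError("angular_frequency must be > 0")
    return VACUUM_PERMITTIVITY * rel_permittivity - 1j * conductivity / angular_frequency


def effective_conductivity(particle: ParticleSpec) -> float:
    """Effective conductivity of a surface-conducting sphere, S/m.

    ``sigma_e = 2*K_s/R + sigma_b``; for small beads the surface term
    dominates and sigma_e falls off as 1/R.
    """
    return 2.0 * particle.surface_conductance / particle.radius + particle.bulk_conductivity


def cm_factor(particle: ParticleSpec, medium: MediumSpec, frequency: float) -> complex:
    """Complex Clausius-Mossotti factor at ordinary frequency ``frequency``.

    The particle enters through its effective conductivity (surface + bulk)
    and relative permittivity. The real part lies in [-0.5, 1.0] for any
    physical sphere.
    """
    if frequency <= 0.0:
        raise ValueError("frequency must be > 0")
    omega = 2.0 * math.pi * frequency
    eps_p = complex_permittivity(
        particle.rel_permittivity, effective_conductivity(particle), omega
    )
    eps_m = complex_permittivity(medium.rel_permittivity, medium.conductivity, omega)
    denom = eps_p + 2.0 * eps_m
    if denom == 0:
        raise ZeroDivisionError("degenerate CM denominator")
    return (eps_p - eps_m) / denom


def cm_spectrum(
    particle: ParticleSpec,
    medium: MediumSpec,
    frequencies: "np.ndarray | list[float] | None" = None,
    *,
    f_min: float = 1e3,
    f_max: float = 1e8,
    points_per_decade: int = 60,
) -> pd.DataFrame:
    """Tabulate the CM factor over a frequency grid.

    If ``frequencies`` is omitted a log-spaced grid from ``f_min`` to
    ``f_max`` with ``points_per_decade`` points per decade is used.

    Returns a DataFrame with columns ``frequency_hz``, ``re_cm``, ``im_cm``.
    """
    if frequencies is None:
        n_decades = math.log10(f_max / f_min)
        n = max(2, int(round(n_decades * points_per_decade)) + 1)
        frequencies = np.logspace(math.log10(f_min), math.log10(f_max), n)
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size == 0:
        raise ValueError("frequency list must be non-empty")
    if np.any(freqs <= 0.0):
        raise ValueError("frequencies must be > 0")
    cm = np.array([cm_factor(particle, medium, f) for f in freqs])
    return pd.DataFrame(
        {"frequency_hz": freqs, "re_cm": cm.real, "im_cm": cm.imag}
    )


def dep_force(
    particle: ParticleSpec,
    medium: MediumSpec,
    frequency: float,
    grad_e2: "np.ndarray | float",
) -> np.ndarray:
    """Time-averaged DEP force, N.

    ``F = 2*pi*eps0*eps_r,m*R^3 * Re(CM) * grad(E^2)``; ``grad_e2`` may be a
    scalar, a vector, or a field of gradient values (V^2/m^3). The sign
    follows Re(CM): negative for nDEP.
    """
    grad = np.asarray(grad_e2, dtype=float)
    if not np.all(np.isfinite(grad)):
        raise ValueError("grad_e2 must be finite")
    re_cm = cm_factor(particle, medium, frequency).real
    eps_m = VACUUM_PERMITTIVITY * medium.rel_permittivity
    return 2.0 * math.pi * eps_m * particle.radius**3 * re_cm * grad
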