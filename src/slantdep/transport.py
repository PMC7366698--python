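"""DEP-vs-drag transport model for slanted-electrode particle deflection.

A particle riding along a tilted electrode line experiences the nDEP barrier
force normal to the electrode, F_DEP = 2*pi*eps_m*R^3*|Re(CM)|*grad(E^2)_x,
and the component of Stokes drag normal to the electrode, 6*pi*mu*R*v*sin(theta),
where theta is the electrode angle to the flow.  Balancing the two gives the
critical linear velocity

    v_crit = F_DEP / (6*pi*mu*R*sin(theta)),

below which the particle is deflected along the electrode instead of being
swept over it.  This force balance is the package's operationalization of
"DEP force dominant against the hydrodynamic forces"; it is a model, not a
published equation.  The figure of merit grad(E^2)_x is taken at the channel
top at the 2 Vpp simulation reference and rescaled by (Vpp/2)^2, consistent
with nDEP levitating particles to the top of the channel.

For arrays of electrode pairs, a particle that slips over one electrode gets
another chance at the next pair: the single-barrier crossing survival decays
as exp(-kappa*(v/v_crit - 1)) above v_crit and the overall deflection
probability is 1 - (1 - p_single)^n_pairs.  This retry model is a hypothesis
for why very shallow angles (few pairs) underperform; it is exercised only
through ranking properties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from slantdep.constants import VACUUM_PERMITTIVITY
from slantdep.dielectric import DriveSettings, MediumSpec, ParticleSpec, cm_factor
from slantdep.field_solver import ChannelGeometry

__all__ = [
    "DeflectionScenario",
    "ThroughputPrediction",
    "ModelError",
    "drag_force",
    "scale_fom_to_drive",
    "critical_velocity",
    "angle_tradeoff",
    "height_tradeoff",
    "ANGLE_STUDY_PAIRS",
]

#: Electrode-pair counts of the fabricated angle designs (1 pair at 5 deg and
#: 24 pairs at 45 deg are layout facts; intermediate angles interpolated
#: proportionally to tan(theta), a configuration default, not a derivation).
ANGLE_STUDY_PAIRS: Mapping[float, int] = {5.0: 1, 8.0: 3, 15.0: 6, 30.0: 14, 45.0: 24}

#: Simulation reference drive, V peak-to-peak (+-1 V electrode potentials).
REFERENCE_VPP: float = 2.0


class ModelError(ValueError):
    """The transport model's assumptions do not hold for these inputs."""


@dataclass(frozen=True)
class DeflectionScenario:
    """Everything needed to predict deflection of one particle population.

    ``fom`` is the top-of-channel max |d(E^2)/dx| at ``reference_vpp``
    (V^2/m^3), typically taken from a sweep table.  ``profile_factor``
    converts the mean channel velocity to the slip velocity seen by the
    particle (1.0 = plug/mean-velocity approximation).
    """

    geometry: ChannelGeometry
    particle: ParticleSpec
    medium: MediumSpec
    drive: DriveSettings
    flow_rate: float
    fom: float
    reference_vpp: float = REFERENCE_VPP
    profile_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.flow_rate <= 0.0:
            raise ValueError("flow_rate must be > 0")
        if self.fom < 0.0:
            raise ValueError("fom must be >= 0")
        if self.profile_factor <= 0.0:
            raise ValueError("profile_factor must be > 0")


@dataclass(frozen=True)
class ThroughputPrediction:
    """Outcome of the DEP-vs-drag balance for one scenario."""

    critical_velocity: float
    max_flow_rate: float
    deflected: bool
    dep_lateral: float
    drag_normal: float


def drag_force(medium: MediumSpec, particle: ParticleSpec, slip_velocity: float) -> float:
    """Stokes drag magnitude 6*pi*mu*R*v, N (linear in every argument)."""
    if slip_velocity < 0.0:
        raise ValueError("slip_velocity must be >= 0")
    return 6.0 * math.pi * medium.viscosity * particle.radius * slip_velocity


def scale_fom_to_drive(fom_at_reference: float, reference_vpp: float,
                       drive_vpp: float) -> float:
    """Rescale a field figure of merit to a different drive voltage.

    grad(E^2) scales with the square of the drive amplitude, so
    ``fom * (drive_vpp/reference_vpp)**2``.
    """
    if reference_vpp <= 0.0:
        raise ValueError("reference_vpp must be > 0")
    return fom_at_reference * (drive_vpp / reference_vpp) ** 2


def critical_velocity(scenario: DeflectionScenario) -> ThroughputPrediction:
    """Force balance at the electrode barrier.

    Returns the critical slip velocity, the maximum deflected flow rate
    (v_crit times the channel cross-section area, adjusted by the profile
    factor), and whether the scenario's own flow rate is deflected.

    Raises
    ------
    ModelError
        If Re(CM) > 0 (the nDEP barrier picture does not apply) or the
        electrode angle is degenerate.
    """
    geo = scenario.geometry
    theta = math.radians(geo.electrode_angle)
    if theta <= 0.0:
        raise ModelError("electrode angle must be > 0 for a barrier model")
    re_cm = cm_factor(scenario.particle, scenario.medium,
                      scenario.drive.frequency).real
    if re_cm > 0.0:
        raise ModelError(
            f"Re(CM)={re_cm:.3f} > 0: particle is attracted to the electrodes; "
            "the nDEP barrier model is inapplicable"
        )
    fom_scaled = scale_fom_to_drive(scenario.fom, scenario.reference_vpp,
                                    scenario.drive.voltage_peak_to_peak)
    eps_m = VACUUM_PERMITTIVITY * scenario.medium.rel_permittivity
    r = scenario.particle.radius
    f_dep = 2.0 * math.pi * eps_m * r**3 * abs(re_cm) * fom_scaled
    v_crit = f_dep / (6.0 * math.pi * scenario.medium.viscosity * r * math.sin(theta))
    area = geo.channel_width * geo.height
    slip = scenario.profile_factor * scenario.flow_rate / area
    drag_normal = drag_force(scenario.medium, scenario.particle, slip) * math.sin(theta)
    return ThroughputPrediction(
        critical_velocity=v_crit,
        max_flow_rate=v_crit * area / scenario.profile_factor,
        deflected=f_dep >= drag_normal,
        dep_lateral=f_dep,
        drag_normal=drag_normal,
    )


def angle_tradeoff(
    scenario: DeflectionScenario,
    angles: Iterable[float],
    pairs_per_angle: Mapping[float, int] = ANGLE_STUDY_PAIRS,
    decay_rate: float = 0.2,
    collection_target: float = 0.99,
) -> pd.DataFrame:
    """Maximum collected flow rate per electrode angle.

    Shallow angles win per barrier (drag's normal component shrinks as
    sin(theta)) but fit fewer electrode pairs in a fixed channel length;
    steeper angles give a particle up to ``n_pairs`` chances.  A single pair
    is a hard threshold (max velocity = v_crit); for n pairs the largest
    velocity with overall deflection probability >= ``collection_target``
    follows in closed form from the exponential crossing-survival model.

    Returns a DataFrame with ``angle_deg``, ``n_pairs``, ``critical_velocity``
    and ``max_flow_rate`` columns.
    """
    angles = list(angles)
    if not angles:
        raise ValueError("angle list must be non-empty")
    if not 0.0 < collection_target < 1.0:
        raise ValueError("collection_target must be in (0, 1)")
    rows = []
    area = scenario.geometry.channel_width * scenario.geometry.height
    for theta in angles:
        n = int(pairs_per_angle[theta])
        if n < 0:
            raise ValueError("pair count must be >= 0")
        pred = critical_velocity(
            replace(scenario, geometry=replace(scenario.geometry,
                                               electrode_angle=theta,
                                               n_electrode_pairs=n))
        )
        if n == 0:
            v_max = 0.0
        elif n == 1:
            v_max = pred.critical_velocity
        else:
            p_needed = 1.0 - (1.0 - collection_target) ** (1.0 / n)
            v_max = pred.critical_velocity * (
                1.0 + math.log(1.0 / p_needed) / decay_rate
            )
        rows.append({
            "angle_deg": theta, "n_pairs": n,
            "critical_velocity": pred.critical_velocity,
            "max_flow_rate": v_max * area / scenario.profile_factor,
        })
    return pd.DataFrame(rows)


def height_tradeoff(
    scenario: DeflectionScenario,
    fom_by_height: Mapping[float, float],
    flow_rate: float | None = None,
) -> pd.DataFrame:
    """Deflection outcome per channel height at fixed volumetric throughput.

    Lower channels concentrate the field (larger FOM) but force higher mean
    velocity V/(W*h) at the same volumetric rate; this table resolves the
    competition.  ``fom_by_height`` maps height (m) to the top-line FOM at
    the reference drive (e.g. from a sweep at the chosen widths).

    Returns a DataFrame with one row per height: FOM, critical velocity,
    maximum deflected flow rate, mean velocity at the probed flow rate, and
    the deflection verdict.
    """
    if not fom_by_height:
        raise KeyError("fom_by_height is empty")
    probe = scenario.flow_rate if flow_rate is None else flow_rate
    rows = []
    for h in sorted(fom_by_height):
        geo = replace(scenario.geometry, height=h)
        sc = replace(scenario, geometry=geo, fom=fom_by_height[h], flow_rate=probe)
        pred = critical_velocity(sc)
        area = geo.channel_width * h
        rows.append({
            "height": h, "fom": fom_by_height[h],
            "critical_velocity": pred.critical_velocity,
            "max_flow_rate": pred.max_flow_rate,
            "mean_velocity": probe / area,
            "deflected": pred.deflected,
        })
    return pd.DataFrame(rows)
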