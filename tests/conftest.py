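"""Shared fixtures: standard materials and a session-wide solve cache."""

from __future__ import annotations

import numpy as np
import pytest

from slantdep import ChannelGeometry, MediumSpec, MeshSpec, ParticleSpec
from slantdep.field_solver import solve_fields, top_line_fom


@pytest.fixture(scope="session")
def medium() -> MediumSpec:
    """DI-water working fluid with the measured conductivity."""
    return MediumSpec(rel_permittivity=76.4, conductivity=2.03e-3)


def polystyrene(diameter_um: float) -> ParticleSpec:
    return ParticleSpec(
        radius=diameter_um * 1e-6 / 2.0,
        rel_permittivity=2.4,
        bulk_conductivity=1e-15,
        surface_conductance=1e-9,
    )


@pytest.fixture(scope="session")
def fom_um():
    """Memoized top-line FOM for a cross-section given in um.

    Caching lets the sweep, trend and acceptance tests share the expensive
    Laplace solves within one pytest session.
    """
    cache: dict[tuple, float] = {}

    def _fom(h: float, w: float, g: float, level: int = 0, vpp: float = 2.0) -> float:
        key = (h, w, g, level, vpp)
        if key not in cache:
            geo = ChannelGeometry.from_microns(h, w, g)
            sol = solve_fields(geo, vpp, MeshSpec(refinement_level=level))
            cache[key] = top_line_fom(sol).value
        return cache[key]

    return _fom


def conformal_oracle(x: np.ndarray, y: np.ndarray, gap_half: float,
                     height: float) -> np.ndarray:
    """Closed-form potential for coplanar semi-infinite plates under a
    Neumann ceiling, amplitude 1 V.

    Half-plane finite-gap solution ``-(2/pi) Re asin(z/a)`` (+1 plate at
    x < -a, -1 at x > a) plus the exact zero-gap wall correction: the strip
    of height h with an insulating top is the Neumann reflection of a strip
    of height 2h, which the map ``zeta = exp(pi z / 2h)`` sends to the upper
    half-plane with the segment (-1, 1) at +1 V and the rest of the real
    axis at -1 V.
    """
    z = x + 1j * y
    v_halfplane = -(2.0 / np.pi) * np.real(np.arcsin(z / gap_half))
    zeta = np.exp(np.pi * z / (2.0 * height))
    v_strip_slit = -1.0 + (2.0 / np.pi) * np.angle((zeta - 1.0) / (zeta + 1.0))
    v_halfplane_slit = (2.0 / np.pi) * np.angle(z) - 1.0
    return v_halfplane + (v_strip_slit - v_halfplane_slit)
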