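"""2D electro-quasi-static field solver for coplanar bottom electrodes.

The channel cross-section is the rectangle [0, W_dom] x [0, h] with two
zero-thickness electrode strips on the floor (metal thickness ~100 nm << h).
For a homogeneous fluid the electro-quasi-static equation
``div[(sigma + j*omega*eps) grad V] = 0`` reduces to Laplace's equation
``lap V = 0`` — the complex coefficient is constant and cancels — so a real
Laplace solve suffices and the drive frequency enters the physics only
through the CM factor.

Boundary conditions: Dirichlet +V0 / -V0 on the two electrode segments of the
bottom boundary, homogeneous Neumann (insulating glass/PDMS walls) everywhere
else. Discretization is a 5-point finite-difference Laplacian on a rectilinear
tensor grid graded geometrically toward the four electrode edges (where the
potential has a corner singularity) and toward the electrode plane; the sparse
system is solved by a direct LU factorization.

The design figure of merit is the maximum of |d(E^2)/dx| along the channel
top y = h, where nDEP-levitated particles travel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import pandas as pd

from slantdep.dielectric import DriveSettings

__all__ = [
    "ChannelGeometry",
    "MeshSpec",
    "FieldSolution",
    "FigureOfMerit",
    "solve_potential",
    "electric_field",
    "grad_e2_x",
    "top_line_fom",
    "solve_fields",
    "convergence_study",
]


@dataclass(frozen=True)
class ChannelGeometry:
    """Cross-section and layout parameters of the electrode channel (SI, m).

    ``height``, ``electrode_width`` and ``electrode_gap`` define the simulated
    cross-section; ``lateral_padding`` is the domain extension beyond each
    outer electrode edge (defaults to max(2h, w), far enough that the
    insulating side walls do not perturb the field near the gap).
    ``channel_width``/``channel_length``/``electrode_angle``/
    ``n_electrode_pairs`` describe the device layout used by the transport
    model and do not enter the 2D field solve.
    """

    height: float
    electrode_width: float
    electrode_gap: float
    lateral_padding: float | None = None
    channel_width: float = 700e-6
    channel_length: float = 10e-3
    electrode_angle: float = 5.0
    n_electrode_pairs: int = 1

    def __post_init__(self) -> None:
        for name in ("height", "electrode_width", "electrode_gap",
                     "channel_width", "channel_length"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        if self.lateral_padding is not None and self.lateral_padding <= 0.0:
            raise ValueError("lateral_padding must be > 0")
        if not 0.0 < self.electrode_angle < 90.0:
            raise ValueError("electrode_angle must be in (0, 90) degrees")
        if self.n_electrode_pairs < 0:
            raise ValueError("n_electrode_pairs must be >= 0")

    @classmethod
    def from_microns(cls, height: float, electrode_width: float,
                     electrode_gap: float, **kwargs: float) -> "ChannelGeometry":
        """Convenience constructor taking the cross-section lengths in um."""
        return cls(height * 1e-6, electrode_width * 1e-6, electrode_gap * 1e-6,
                   **kwargs)

    @property
    def padding(self) -> float:
        """Resolved lateral padding, m."""
        if self.lateral_padding is not None:
            return self.lateral_padding
        return max(2.0 * self.height, self.electrode_width)

    @property
    def domain_width(self) -> float:
        """Simulated domain width: gap + 2 widths + 2 paddings, m."""
        return self.electrode_gap + 2.0 * self.electrode_width + 2.0 * self.padding

    @property
    def electrode_edges(self) -> tuple[float, float, float, float]:
        """x-coordinates of the four electrode edges (left to right), m."""
        p, w, g = self.padding, self.electrode_width, self.electrode_gap
        return (p, p + w, p + w + g, p + 2.0 * w + g)


@dataclass(frozen=True)
class MeshSpec:
    """Graded-mesh policy for the structured rectilinear grid.

    ``edge_divisions`` sets the initial spacing at electrode edges and at the
    electrode plane to ``min(g, w, h)/edge_divisions``; spacings grow
    geometrically by ``growth`` away from those features, capped at
    ``h/coarse_divisions``. ``refinement_level`` halves both the initial and
    the cap spacing per level. The gap is always resolved by at least
    ``edge_divisions`` intervals.
    """

    edge_divisions: int = 12
    growth: float = 1.1
    coarse_divisions: int = 8
    refinement_level: int = 0

    def __post_init__(self) -> None:
        if self.edge_divisions < 8:
            raise ValueError("edge_divisions must be >= 8 (gap resolution)")
        if not 1.0 < self.growth <= 2.0:
            raise ValueError("growth must be in (1, 2]")
        if self.coarse_divisions < 2:
            raise ValueError("coarse_divisions must be >= 2")
        if self.refinement_level < 0:
            raise ValueError("refinement_level must be >= 0")

    def spacings(self, geometry: ChannelGeometry) -> tuple[float, float]:
        """(fine, coarse) target spacings in m for this geometry."""
        scale = 2.0 ** self.refinement_level
        fine = min(geometry.electrode_gap, geometry.electrode_width,
                   geometry.height) / self.edge_divisions / scale
        coarse = geometry.height / self.coarse_divisions / scale
        return fine, max(coarse, fine)

    def refined(self, levels: int = 1) -> "MeshSpec":
        return replace(self, refinement_level=self.refinement_level + levels)


@dataclass
class FieldSolution:
    """Discrete potential and derived fields on a rectilinear grid.

    Arrays are shaped ``(ny, nx)``; row ``j`` holds the line y = y[j], with
    j = 0 the electrode plane and j = ny-1 the channel top.
    """

    x: np.ndarray
    y: np.ndarray
    potential: np.ndarray
    geometry: ChannelGeometry
    amplitude: float
    mesh_spacing: float
    refinement_level: int
    e_x: np.ndarray | None = None
    e_y: np.ndarray | None = None
    grad_e2_x: np.ndarray | None = None

    @property
    def top_index(self) -> int:
        return self.y.size - 1


@dataclass(frozen=True)
class FigureOfMerit:
    """Maximum |d(E^2)/dx| along the channel top and where it occurs."""

    value: float
    x_location: float
    geometry: ChannelGeometry


# ---------------------------------------------------------------------------
# Mesh construction


def _one_sided(length: float, h0: float, growth: float, hmax: float) -> np.ndarray:
    """Nodes on [0, length], spacing h0 at 0 growing geometrically to hmax.

    The node set is rescaled to end exactly at ``length``.
    """
    if length <= 0:
        raise ValueError("segment length must be > 0")
    xs = [0.0]
    h = min(h0, length)
    while xs[-1] < length:
        xs.append(xs[-1] + h)
        h = min(h * growth, hmax)
    arr = np.asarray(xs)
    return arr * (length / arr[-1])


def _two_sided(length: float, h0: float, growth: float, hmax: float) -> np.ndarray:
    """Nodes on [0, length] graded from both ends (symmetric)."""
    half = _one_sided(0.5 * length, h0, growth, hmax)
    return np.concatenate([half, length - half[-2::-1]])


def _build_grid(geometry: ChannelGeometry, mesh: MeshSpec) -> tuple[np.ndarray, np.ndarray]:
    fine, coarse = mesh.spacings(geometry)
    g, w, pad = geometry.electrode_gap, geometry.electrode_width, geometry.padding
    x1, x2, x3, x4 = geometry.electrode_edges

    left_pad = x1 - _one_sided(pad, fine, mesh.growth, coarse)[::-1]
    left_el = x1 + _two_sided(w, fine, mesh.growth, coarse)
    gap = x2 + _two_sided(g, fine, mesh.growth, coarse)
    right_el = x3 + _two_sided(w, fine, mesh.growth, coarse)
    right_pad = x4 + _one_sided(pad, fine, mesh.growth, coarse)
    x = np.concatenate(
        [left_pad, left_el[1:], gap[1:], right_el[1:], right_pad[1:]]
    )
    y = _one_sided(geometry.height, fine, mesh.growth, coarse)
    return x, y


def _second_derivative_matrix(coords: np.ndarray) -> sp.csr_matrix:
    """Nonuniform 3-point second-derivative operator with reflecting
    (homogeneous Neumann) end conditions."""
    n = coords.size
    h = np.diff(coords)
    rows, cols, vals = [], [], []
    # interior
    for i in range(1, n - 1):
        hl, hr = h[i - 1], h[i]
        a = 2.0 / (hl * (hl + hr))
        c = 2.0 / (hr * (hl + hr))
        rows += [i, i, i]
        cols += [i - 1, i, i + 1]
        vals += [a, -(a + c), c]
    # reflecting ends: ghost node mirrors the first interior neighbour
    rows += [0, 0, n - 1, n - 1]
    cols += [0, 1, n - 2, n - 1]
    vals += [-2.0 / h[0] ** 2, 2.0 / h[0] ** 2,
             2.0 / h[-1] ** 2, -2.0 / h[-1] ** 2]
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


# ---------------------------------------------------------------------------
# Operations


def solve_potential(
    geometry: ChannelGeometry,
    drive: DriveSettings | float = 2.0,
    mesh: MeshSpec | None = None,
) -> FieldSolution:
    """Solve Laplace's equation for the cross-section potential.

    Parameters
    ----------
    geometry : ChannelGeometry
    drive : DriveSettings or float
        Drive settings, or a bare peak-to-peak voltage in V.  The left
        electrode is held at +Vpp/2, the right at -Vpp/2 (the +-1 V
        simulation reference corresponds to 2 V peak-to-peak).
    mesh : MeshSpec, optional

    Returns
    -------
    FieldSolution
        With ``potential`` filled in; electrode nodes match the imposed
        Dirichlet values exactly and the solve is verified against a relative
        residual of 1e-10.
    """
    mesh = mesh or MeshSpec()
    vpp = drive.voltage_peak_to_peak if isinstance(drive, DriveSettings) else float(drive)
    amplitude = 0.5 * vpp

    x, y = _build_grid(geometry, mesh)
    nx, ny = x.size, y.size
    dxx = _second_derivative_matrix(x)
    dyy = _second_derivative_matrix(y)
    lap = sp.kron(sp.identity(ny), dxx) + sp.kron(dyy, sp.identity(nx))
    lap = lap.tocsr()

    x1, x2, x3, x4 = geometry.electrode_edges
    tol = 1e-9 * geometry.domain_width
    on_left = (x >= x1 - tol) & (x <= x2 + tol)
    on_right = (x >= x3 - tol) & (x <= x4 + tol)
    dirichlet = np.zeros(nx * ny, dtype=bool)
    dirichlet[:nx] = on_left | on_right          # bottom row, j = 0
    values = np.zeros(nx * ny)
    values[:nx][on_left] = amplitude
    values[:nx][on_right] = -amplitude

    # eliminate Dirichlet unknowns: solve only for free nodes so the system
    # stays uniformly scaled (all rows ~ 1/h^2)
    free = ~dirichlet
    lap_csr = lap.tocsr()
    a_ff = lap_csr[free][:, free].tocsc()
    b = -(lap_csr[free][:, dirichlet] @ values[dirichlet])
    u_free = spla.splu(a_ff).solve(b)
    solution = values.copy()
    solution[free] = u_free

    residual = np.linalg.norm(a_ff @ u_free - b)
    # matrix entries scale as 1/h^2, so normalize by ||A||*||x|| + ||b||
    scale = (spla.norm(a_ff, np.inf) * max(np.linalg.norm(u_free, np.inf), 1e-30)
             + np.linalg.norm(b))
    if not np.all(np.isfinite(solution)) or residual > 1e-10 * scale:
        raise RuntimeError(
            f"Laplace solve failed: residual {residual:.3e} "
            f"(n={nx * ny}, geometry={geometry})"
        )

    fine, _ = mesh.spacings(geometry)
    return FieldSolution(
        x=x, y=y, potential=solution.reshape(ny, nx), geometry=geometry,
        amplitude=amplitude, mesh_spacing=fine,
        refinement_level=mesh.refinement_level,
    )


def electric_field(solution: FieldSolution) -> FieldSolution:
    """Fill ``e_x``/``e_y`` with E = -grad V.

    Centred second-order differences on the nonuniform grid in the interior,
    one-sided second-order at the boundaries.
    """
    dv_dy, dv_dx = np.gradient(solution.potential, solution.y, solution.x)
    solution.e_x = -dv_dx
    solution.e_y = -dv_dy
    return solution


def grad_e2_x(solution: FieldSolution) -> FieldSolution:
    """Fill ``grad_e2_x`` with d(E_x^2 + E_y^2)/dx.

    Quadratic in the drive amplitude: doubling the voltage quadruples it.
    """
    if solution.e_x is None or solution.e_y is None:
        raise ValueError("electric field not yet computed; call electric_field")
    e2 = solution.e_x**2 + solution.e_y**2
    solution.grad_e2_x = np.gradient(e2, solution.x, axis=1)
    return solution


def top_line_fom(solution: FieldSolution) -> FigureOfMerit:
    """Maximum |d(E^2)/dx| over the channel-top line y = h.

    The two lateral domain-edge nodes are excluded so that the artificial
    truncation boundary cannot supply the maximum.
    """
    if solution.grad_e2_x is None:
        raise ValueError("grad_e2_x not yet computed; call grad_e2_x")
    top = np.abs(solution.grad_e2_x[-1, 1:-1])
    k = int(np.argmax(top))
    return FigureOfMerit(
        value=float(top[k]),
        x_location=float(solution.x[k + 1]),
        geometry=solution.geometry,
    )


def solve_fields(
    geometry: ChannelGeometry,
    drive: DriveSettings | float = 2.0,
    mesh: MeshSpec | None = None,
) -> FieldSolution:
    """Solve the potential and derive E and d(E^2)/dx in one call."""
    return grad_e2_x(electric_field(solve_potential(geometry, drive, mesh)))


def convergence_study(
    geometry: ChannelGeometry,
    drive: DriveSettings | float = 2.0,
    levels: Sequence[int] = (0, 1, 2),
    mesh: MeshSpec | None = None,
) -> pd.DataFrame:
    """Figure of merit under successive mesh refinement.

    Returns a DataFrame with one row per refinement level (``mesh_spacing``,
    ``fom``, ``rel_change`` vs the previous level) and a ``monotone``
    attribute flagging whether the FOM sequence converged monotonically.
    """
    if len(levels) < 3:
        raise ValueError("need at least 3 refinement levels")
    mesh = mesh or MeshSpec()
    rows = []
    for lvl in levels:
        m = replace(mesh, refinement_level=lvl)
        sol = solve_fields(geometry, drive, m)
        fom = top_line_fom(sol)
        rows.append({"refinement_level": lvl, "mesh_spacing": sol.mesh_spacing,
                     "n_nodes": sol.potential.size, "fom": fom.value})
    table = pd.DataFrame(rows)
    table["rel_change"] = table["fom"].pct_change().abs()
    diffs = np.diff(table["fom"].to_numpy())
    table.attrs["monotone"] = bool(np.all(diffs >= 0) or np.all(diffs <= 0))
    return table
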