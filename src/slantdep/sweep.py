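"""Geometry parameter study: electrode width x spacing x channel height.

Runs the field solver over a Cartesian grid of cross-section geometries,
collects the top-of-channel |d(E^2)/dx| figure of merit per cell, detects the
critical electrode width (onset of the width plateau) per channel height, and
computes enhancement percentages between configurations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, MutableMapping

import numpy as np
import pandas as pd

from slantdep.dielectric import DriveSettings
from slantdep.field_solver import ChannelGeometry, MeshSpec, solve_fields, top_line_fom

__all__ = [
    "PAPER_GRID_HEIGHTS",
    "PAPER_GRID_WIDTHS",
    "PAPER_GRID_GAPS",
    "CHOSEN_WIDTHS",
    "REFERENCE_GAP",
    "run_sweep",
    "critical_width",
    "CriticalWidthResult",
    "enhancement",
    "height_effect",
]

# Default study grid (m): heights 25-75 um, widths 10-110 um, gaps 5-50 um.
PAPER_GRID_HEIGHTS: tuple[float, ...] = (25e-6, 40e-6, 60e-6, 75e-6)
PAPER_GRID_WIDTHS: tuple[float, ...] = tuple(w * 1e-6 for w in range(10, 111, 10))
PAPER_GRID_GAPS: tuple[float, ...] = (5e-6, 10e-6, 15e-6, 20e-6, 30e-6, 40e-6, 50e-6)

#: Electrode width chosen for each channel height (at/above the critical width).
CHOSEN_WIDTHS: Mapping[float, float] = {
    25e-6: 40e-6, 40e-6: 40e-6, 60e-6: 60e-6, 75e-6: 80e-6,
}

#: Reference electrode spacing for width sweeps (fabrication choice), m.
REFERENCE_GAP: float = 10e-6


def _cell_key(h: float, w: float, g: float, vpp: float, mesh: MeshSpec) -> str:
    payload = json.dumps([h, w, g, vpp, mesh.edge_divisions, mesh.growth,
                          mesh.coarse_divisions, mesh.refinement_level])
    return hashlib.sha1(payload.encode()).hexdigest()


def run_sweep(
    heights: Iterable[float] = PAPER_GRID_HEIGHTS,
    widths: Iterable[float] = PAPER_GRID_WIDTHS,
    gaps: Iterable[float] = PAPER_GRID_GAPS,
    drive: DriveSettings | float = 2.0,
    mesh: MeshSpec | None = None,
    cache: MutableMapping[str, dict] | None = None,
) -> pd.DataFrame:
    """Solve the field for every (h, w, g) cell and tabulate the FOM.

    Fully deterministic: re-running with the same configuration reproduces
    the table bit-for-bit.  A failed solve is recorded in the ``error``
    column and the sweep continues.  Pass a dict as ``cache`` to reuse
    already-solved cells across calls (keyed by a parameter hash).

    Returns a tidy DataFrame with columns ``height``, ``width``, ``gap``
    (m), ``fom`` (V^2/m^3), ``x_location`` (m), ``n_nodes``,
    ``mesh_spacing`` (m), ``error``.
    """
    mesh = mesh or MeshSpec()
    vpp = drive.voltage_peak_to_peak if isinstance(drive, DriveSettings) else float(drive)
    rows = []
    for h in heights:
        for w in widths:
            for g in gaps:
                key = _cell_key(h, w, g, vpp, mesh)
                if cache is not None and key in cache:
                    rows.append(cache[key])
                    continue
                row = {"height": h, "width": w, "gap": g, "fom": np.nan,
                       "x_location": np.nan, "n_nodes": 0,
                       "mesh_spacing": np.nan, "error": ""}
                try:
                    geo = ChannelGeometry(height=h, electrode_width=w, electrode_gap=g)
                    sol = solve_fields(geo, vpp, mesh)
                    fom = top_line_fom(sol)
                    row.update(fom=fom.value, x_location=fom.x_location,
                               n_nodes=sol.potential.size,
                               mesh_spacing=sol.mesh_spacing)
                except Exception as exc:  # noqa: BLE001 - per-cell fault isolation
                    row["error"] = f"{type(exc).__name__}: {exc}"
                if cache is not None:
                    cache[key] = row
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CriticalWidthResult:
    """Smallest electrode width whose FOM reaches the width plateau."""

    height: float
    critical_width: float
    plateau_threshold: float
    right_censored: bool


def _lookup(table: pd.DataFrame, h: float, w: float, g: float) -> float:
    tol = 1e-12
    sel = table[(np.abs(table["height"] - h) < tol)
                & (np.abs(table["width"] - w) < tol)
                & (np.abs(table["gap"] - g) < tol)]
    if sel.empty:
        raise KeyError(f"no sweep cell for (h={h}, w={w}, g={g})")
    fom = float(sel["fom"].iloc[0])
    if not np.isfinite(fom):
        raise ValueError(f"sweep cell (h={h}, w={w}, g={g}) failed: "
                         f"{sel['error'].iloc[0]}")
    return fom


def critical_width(
    table: pd.DataFrame,
    height: float,
    plateau_threshold: float = 0.05,
    gap: float = REFERENCE_GAP,
) -> CriticalWidthResult:
    """Plateau onset of FOM(width) at one height and the reference gap.

    The critical width is the smallest swept width whose FOM is within
    ``plateau_threshold`` (relative) of the maximum over the width sweep.
    If only the largest swept width qualifies the result is flagged as
    right-censored: the plateau may start beyond the swept range.
    """
    tol = 1e-12
    sub = table[(np.abs(table["height"] - height) < tol)
                & (np.abs(table["gap"] - gap) < tol)].sort_values("width")
    sub = sub[np.isfinite(sub["fom"])]
    if sub.empty:
        raise KeyError(f"no width sweep at height {height}, gap {gap}")
    fmax = sub["fom"].max()
    ok = sub[sub["fom"] >= (1.0 - plateau_threshold) * fmax]
    w_crit = float(ok["width"].iloc[0])
    censored = w_crit == float(sub["width"].iloc[-1]) and len(sub) > 1
    return CriticalWidthResult(height, w_crit, plateau_threshold, censored)


def enhancement(
    table: pd.DataFrame,
    config_a: tuple[float, float, float],
    config_b: tuple[float, float, float],
) -> float:
    """Percent FOM change from configuration a to b: 100*(f_b - f_a)/f_a.

    Configurations are (height, width, gap) tuples in m and must be present
    in the sweep table.
    """
    fa = _lookup(table, *config_a)
    fb = _lookup(table, *config_b)
    if fa == 0.0:
        raise ZeroDivisionError("baseline FOM is zero; enhancement undefined")
    return 100.0 * (fb - fa) / fa


def height_effect(
    table: pd.DataFrame,
    chosen_widths: Mapping[float, float] = CHOSEN_WIDTHS,
    gap: float = REFERENCE_GAP,
) -> pd.DataFrame:
    """Consecutive-height enhancement percentages at the chosen widths.

    Heights are ordered descending (deepest first); each row reports the
    percent FOM increase obtained by lowering the channel from ``height_from``
    to ``height_to`` with each height's chosen electrode width, at the given
    gap.
    """
    heights = sorted(chosen_widths, reverse=True)
    missing = []
    foms = {}
    for h in heights:
        try:
            foms[h] = _lookup(table, h, chosen_widths[h], gap)
        except (KeyError, ValueError):
            missing.append((h, chosen_widths[h], gap))
    if missing:
        raise KeyError(f"sweep table is missing cells: {missing}")
    rows = []
    for h_from, h_to in zip(heights, heights[1:]):
        rows.append({
            "height_from": h_from, "height_to": h_to,
            "fom_from": foms[h_from], "fom_to": foms[h_to],
            "enhancement_pct": 100.0 * (foms[h_to] - foms[h_from]) / foms[h_from],
        })
    return pd.DataFrame(rows)
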