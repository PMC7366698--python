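"""Synthetic throughput experiments and the voltage-squared linearity fit.

The DEP force scales with the square of the drive voltage, so the maximum
collected volumetric throughput of the device is expected to be proportional
to Vpp^2 for each particle size / height / angle condition.  This module
emulates the structure of those bench measurements — a grid of conditions,
three replicates each, multiplicative measurement noise — and provides the
regression stage that recovers the per-condition slope with a
resampling-based confidence interval, so the linearity analysis is testable
end-to-end without any experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExperimentDesign",
    "height_study_design",
    "angle_study_design",
    "study_designs",
    "generate_measurements",
    "fit_v2_linearity",
]

SlopeSpec = "float | Mapping[tuple, float] | Callable[[float, float, float], float]"


@dataclass(frozen=True)
class ExperimentDesign:
    """Factor grid of a throughput study (SI units; angles in degrees)."""

    particle_diameters: tuple[float, ...]
    voltages_vpp: tuple[float, ...]
    heights: tuple[float, ...]
    angles: tuple[float, ...]
    replicates: int = 3
    frequency: float = 6e6

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for name in ("particle_diameters", "voltages_vpp", "heights", "angles"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")

    @property
    def n_rows(self) -> int:
        return (len(self.particle_diameters) * len(self.voltages_vpp)
                * len(self.heights) * len(self.angles) * self.replicates)


def height_study_design() -> ExperimentDesign:
    """Height/voltage/size study: 5-20 um beads, 2-10 Vpp in five levels,
    four channel heights, 5 deg electrodes, triplicates at 6 MHz."""
    return ExperimentDesign(
        particle_diameters=(5e-6, 10e-6, 15e-6, 20e-6),
        voltages_vpp=(2.0, 4.0, 6.0, 8.0, 10.0),
        heights=(25e-6, 40e-6, 60e-6, 75e-6),
        angles=(5.0,),
    )


def angle_study_design() -> ExperimentDesign:
    """Electrode-angle study: finer 5-10 um bead sizes, fixed 10 Vpp and
    6 MHz, angles from 5 to 45 degrees, triplicates."""
    return ExperimentDesign(
        particle_diameters=(5e-6, 6e-6, 8e-6, 10e-6),
        voltages_vpp=(10.0,),
        heights=(25e-6,),
        angles=(5.0, 8.0, 15.0, 30.0, 45.0),
    )


def study_designs() -> tuple[ExperimentDesign, ExperimentDesign]:
    """The two bench designs: (height/voltage/size study, angle study)."""
    return height_study_design(), angle_study_design()


def _slope_fn(true_model) -> Callable[[float, float, float], float]:
    if callable(true_model):
        return true_model
    if isinstance(true_model, Mapping):
        return lambda d, h, a: true_model[(d, h, a)]
    value = float(true_model)
    return lambda d, h, a: value


def generate_measurements(
    design: ExperimentDesign,
    true_model,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a throughput-vs-voltage measurement table.

    Each measurement is ``slope(d, h, angle) * Vpp^2 * (1 + eps)`` with
    ``eps ~ Normal(0, noise_sd)`` (multiplicative measurement noise),
    truncated at zero.  ``true_model`` is a constant slope, a mapping
    ``(diameter, height, angle) -> slope`` (m^3/s per V^2), or a callable
    with that signature.  All randomness flows through ``seed``; the same
    seed reproduces the table bit-for-bit.
    """
    if noise_sd < 0.0:
        raise ValueError("noise_sd must be >= 0")
    slope_of = _slope_fn(true_model)
    rng = np.random.default_rng(seed)
    rows = []
    for d in design.particle_diameters:
        for h in design.heights:
            for a in design.angles:
                slope = float(slope_of(d, h, a))
                if slope <= 0.0:
                    raise ValueError("slopes must be > 0")
                for v in design.voltages_vpp:
                    eps = rng.normal(0.0, noise_sd, size=design.replicates)
                    thr = np.maximum(slope * v**2 * (1.0 + eps), 0.0)
                    for rep, t in enumerate(thr):
                        rows.append({
                            "diameter": d, "vpp": v, "height": h, "angle": a,
                            "replicate": rep, "throughput": float(t),
                        })
    table = pd.DataFrame(rows)
    table.attrs.update(noise_sd=noise_sd, seed=seed)
    return table


def _bootstrap_slope_se(x: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                        n_boot: int) -> float:
    """Bootstrap SE of the slope, resampling replicates within each voltage.

    ``y`` has shape (n_voltages, n_replicates).  The raw bootstrap SE is
    inflated by sqrt(n_rep/(n_rep - 1)), the standard small-sample correction
    for resampling the mean of n_rep values.
    """
    n_v, n_rep = y.shape
    idx = rng.integers(0, n_rep, size=(n_boot, n_v, n_rep))
    means = np.take_along_axis(y[None, :, :], idx, axis=2).mean(axis=2)
    xc = x - x.mean()
    slopes = (means - means.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
    return float(slopes.std(ddof=1) * np.sqrt(n_rep / max(n_rep - 1, 1)))


def fit_v2_linearity(
    table: pd.DataFrame,
    n_boot: int = 500,
    seed: int = 0,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Per-condition least-squares fit of throughput against Vpp^2.

    For every (diameter, height, angle) condition with at least three voltage
    levels, fits ``throughput = slope * Vpp^2 + intercept`` by ordinary least
    squares over all replicate measurements and attaches a confidence
    interval ``slope +- t * SE_boot``, where the slope standard error comes
    from resampling replicates within each voltage level.

    Returns a DataFrame with columns ``diameter``, ``height``, ``angle``,
    ``slope``, ``intercept``, ``r_squared``, ``ci_low``, ``ci_high``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (d, h, a), grp in table.groupby(["diameter", "height", "angle"]):
        voltages = np.sort(grp["vpp"].unique())
        if voltages.size < 3:
            raise ValueError(
                f"condition (d={d}, h={h}, angle={a}) has {voltages.size} "
                "voltage levels; need >= 3 to fit a line"
            )
        x_all = grp["vpp"].to_numpy() ** 2
        y_all = grp["throughput"].to_numpy()
        fit = stats.linregress(x_all, y_all)
        # replicate matrix (n_voltages, n_rep) for the bootstrap
        piv = grp.pivot_table(index="vpp", columns="replicate",
                              values="throughput")
        n_rep = piv.shape[1]
        se = _bootstrap_slope_se(piv.index.to_numpy() ** 2,
                                 piv.to_numpy(), rng, n_boot)
        # the SE rests on n_rep independent replicates per voltage, so the
        # t reference uses n_rep - 1 degrees of freedom, not the regression df
        t_crit = stats.t.ppf(0.5 + confidence / 2.0, df=max(n_rep - 1, 1))
        rows.append({
            "diameter": d, "height": h, "angle": a,
            "slope": fit.slope, "intercept": fit.intercept,
            "r_squared": fit.rvalue**2,
            "ci_low": fit.slope - t_crit * se,
            "ci_high": fit.slope + t_crit * se,
        })
    return pd.DataFrame(rows)
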