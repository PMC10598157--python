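"""Phantom-rod HU→density calibration.

A tissue-density calibration phantom holds rods of known density (air,
adipose, water, muscle, trabecular bone, cortical bone).  The mean HU of each
segmented rod, paired with its nominal density, is fitted with *bilinear*
regression: two ordinary-least-squares lines split at the mean HU of the
muscle rod, which belongs to both segments.  Soft tissues fall on the lower
segment, bone on the upper one.

Evaluation is single-valued by the rule ``hu <= breakpoint -> lower
segment``; predicted densities are clamped at zero (extrapolating the lower
segment below the air rod can undershoot, and negative mass is unphysical).
The mapping is inverted (density → HU) when voxelizing phantoms of known
composition, so the pipeline's calibration step recovers the phantom
densities exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ctbsp.ct_io import CTVolume, VoxelMask
from ctbsp.errors import (
    ConfigurationError,
    EmptySelectionError,
    FitError,
    InversionError,
)

__all__ = [
    "RodMeasurement",
    "DensityCalibration",
    "rod_mean_hu",
    "fit_bilinear_calibration",
    "hu_to_density",
    "density_to_hu",
    "read_rod_table",
    "write_calibration",
    "read_calibration",
]


@dataclass(frozen=True)
class RodMeasurement:
    """One calibration rod: material label, mean HU, nominal density (kg/m^3)."""

    name: str
    mean_hu: float
    nominal_density: float

    def __post_init__(self) -> None:
        if self.nominal_density < 0:
            raise ConfigurationError(f"rod {self.name!r} has negative density")


@dataclass(frozen=True)
class DensityCalibration:
    """Bilinear HU→density map: two OLS segments split at ``breakpoint_hu``.

    Slopes are kg/m^3 per HU, intercepts kg/m^3.
    """

    breakpoint_hu: float
    lower_slope: float
    lower_intercept: float
    upper_slope: float
    upper_intercept: float


def rod_mean_hu(volume: CTVolume, rod_mask: VoxelMask) -> float:
    """Arithmetic mean HU over the rod mask (border pixels should already be
    excluded by the caller, e.g. with an eroded mask)."""
    if rod_mask.count == 0:
        raise EmptySelectionError("rod mask selects no voxels")
    return float(np.mean(volume.data[rod_mask.data]))


def _ols_line(hu: np.ndarray, density: np.ndarray) -> tuple[float, float]:
    if len(hu) < 2:
        raise FitError("a calibration segment needs at least 2 rods")
    if np.ptp(hu) == 0:
        raise FitError("calibration rods in a segment have identical HU")
    slope, intercept = np.polyfit(hu, density, 1)
    return float(slope), float(intercept)


def fit_bilinear_calibration(rods: list[RodMeasurement]) -> DensityCalibration:
    """Fit the two-segment calibration, split at the muscle rod's mean HU.

    The muscle rod is shared: the lower segment is fitted on rods with
    ``mean_hu <= breakpoint`` and the upper on rods with
    ``mean_hu >= breakpoint``.
    """
    muscle = [r for r in rods if r.name.lower() == "muscle"]
    if not muscle:
        raise ConfigurationError("no rod named 'muscle'; the breakpoint is undefined")
    breakpoint_hu = muscle[0].mean_hu
    hu = np.array([r.mean_hu for r in rods], dtype=float)
    rho = np.array([r.nominal_density for r in rods], dtype=float)
    lower = hu <= breakpoint_hu
    upper = hu >= breakpoint_hu
    lo_slope, lo_int = _ols_line(hu[lower], rho[lower])
    up_slope, up_int = _ols_line(hu[upper], rho[upper])
    return DensityCalibration(
        breakpoint_hu=float(breakpoint_hu),
        lower_slope=lo_slope,
        lower_intercept=lo_int,
        upper_slope=up_slope,
        upper_intercept=up_int,
    )


def hu_to_density(calibration: DensityCalibration, hu):
    """Evaluate the calibration at scalar or array HU; result clamped >= 0."""
    hu = np.asarray(hu, dtype=float)
    lower = calibration.lower_slope * hu + calibration.lower_intercept
    upper = calibration.upper_slope * hu + calibration.upper_intercept
    rho = np.where(hu <= calibration.breakpoint_hu, lower, upper)
    rho = np.maximum(rho, 0.0)
    return float(rho) if rho.ndim == 0 else rho


def density_to_hu(calibration: DensityCalibration, density):
    """Invert the (unclamped) calibration: density (kg/m^3) → HU.

    Requires both slopes strictly positive.  Densities at or below the lower
    segment's value at the breakpoint invert through the lower segment,
    higher densities through the upper one, so
    ``hu_to_density(density_to_hu(rho)) == rho`` wherever the two segments'
    ranges cover ``rho``.
    """
    if calibration.lower_slope <= 0 or calibration.upper_slope <= 0:
        raise InversionError("calibration is not invertible: non-positive segment slope")
    rho = np.asarray(density, dtype=float)
    rho_at_break = (
        calibration.lower_slope * calibration.breakpoint_hu + calibration.lower_intercept
    )
    lower_hu = (rho - calibration.lower_intercept) / calibration.lower_slope
    upper_hu = (rho - calibration.upper_intercept) / calibration.upper_slope
    hu = np.where(rho <= rho_at_break, lower_hu, upper_hu)
    return float(hu) if hu.ndim == 0 else hu


# ---------------------------------------------------------------------------
# Serialization


def read_rod_table(path: str | Path) -> list[RodMeasurement]:
    """Read a rod table CSV with columns name, mean_hu, nominal_density_kg_m3."""
    df = pd.read_csv(path)
    return [
        RodMeasurement(
            name=str(row["name"]),
            mean_hu=float(row["mean_hu"]),
            nominal_density=float(row["nominal_density_kg_m3"]),
        )
        for _, row in df.iterrows()
    ]


def write_calibration(calibration: DensityCalibration, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(
            {
                "breakpoint_hu": calibration.breakpoint_hu,
                "lower_slope": calibration.lower_slope,
                "lower_intercept": calibration.lower_intercept,
                "upper_slope": calibration.upper_slope,
                "upper_intercept": calibration.upper_intercept,
            },
            fh,
            indent=1,
        )
    return path


def read_calibration(path: str | Path) -> DensityCalibration:
    with open(path) as fh:
        raw = json.load(fh)
    return DensityCalibration(**raw)
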