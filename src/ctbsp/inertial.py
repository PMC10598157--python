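"""Voxel masses, center of mass, inertia tensor, and principal moments.

Each segmented voxel is treated as a point mass at its center:
``m_i = rho(HU_i) * voxel_volume`` with the bilinear HU→density calibration.
Air pockets inside a segment (HU below the air threshold, default −500 HU,
e.g. in ex vivo brains) are assigned the mean density of the segment's
non-air voxels; they stay in the mask and count toward volume.

With voxel coordinates expressed in the anatomical coordinate system (ACS),
the inertia tensor about a reference point r is

    I_xx = sum m_i (y_i^2 + z_i^2)      I_xy = -sum m_i x_i y_i   (etc.)

with (x_i, y_i, z_i) relative to r — the negative-integral convention for
the products of inertia.  The tensor about the ACS origin is translated to
the CoM with the parallel-axis theorem in full tensor form,
``I_com = I_acs - M (|d|^2 E - d d^T)``, and its eigendecomposition gives
the principal moments (sorted ascending, I1 <= I2 <= I3) and axes.

Unit bookkeeping: masses kg (kg/m^3 * mm^3 * 1e-9); positions mm; inertia
reported in kg cm^2 (mm^2 → cm^2 is a factor 1e-2).  The per-voxel inertia
of the voxel cube itself is omitted; that term is O(spacing^2), uniform, and
vanishes under grid refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ctbsp.calibration import DensityCalibration, hu_to_density
from ctbsp.ct_io import CTVolume, VoxelMask, voxel_world_coordinates
from ctbsp.errors import DegenerateDensityError, EmptySelectionError, ValidationError

__all__ = [
    "MassMap",
    "InertiaTensor",
    "BodySegmentProperties",
    "compute_voxel_masses",
    "segment_mass_volume",
    "center_of_mass",
    "inertia_tensor_about",
    "translate_inertia_to_com",
    "principal_moments",
]

MM2_TO_CM2 = 1e-2
MM3_TO_M3 = 1e-9
AIR_THRESHOLD_HU = -500.0

_SYM_TOL = 1e-9


@dataclass
class MassMap:
    """Per-voxel masses (kg) and positions (mm, world or ACS)."""

    masses: np.ndarray
    positions: np.ndarray
    voxel_volume_mm3: float

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if len(self.masses) != len(self.positions):
            raise ValidationError("masses and positions lengths differ")
        if np.any(self.masses < 0):
            raise ValidationError("voxel masses must be non-negative")

    def with_positions(self, positions: np.ndarray) -> "MassMap":
        """Same masses, re-expressed coordinates (e.g. after world→ACS)."""
        return MassMap(self.masses, positions, self.voxel_volume_mm3)


@dataclass
class InertiaTensor:
    """Symmetric 3x3 inertia tensor (kg cm^2) about a reference point (mm)."""

    components: np.ndarray
    about: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.about = np.asarray(self.about, dtype=float)
        scale = max(1.0, float(np.abs(self.components).max()))
        if np.abs(self.components - self.components.T).max() > _SYM_TOL * scale:
            raise ValidationError("inertia tensor is not symmetric")
        # exact symmetrization so downstream eigh sees a symmetric matrix
        self.components = (self.components + self.components.T) / 2.0


@dataclass
class BodySegmentProperties:
    """Everything reported per segment (head or brain) per subject."""

    segment: str
    mass_g: float
    volume_cm3: float
    com: np.ndarray  # ACS mm
    inertia_at_com: InertiaTensor
    principal_moments_kg_cm2: np.ndarray  # (I1, I2, I3) ascending
    principal_axes: np.ndarray  # rows = unit axes in ACS

    @property
    def com_distance_mm(self) -> float:
        return float(np.linalg.norm(self.com))


def compute_voxel_masses(
    volume: CTVolume,
    mask: VoxelMask,
    calibration: DensityCalibration,
    air_threshold: float = AIR_THRESHOLD_HU,
) -> MassMap:
    """Convert a segment mask to per-voxel point masses at world positions."""
    if mask.count == 0:
        raise EmptySelectionError("segment mask is empty")
    hu = volume.data[mask.data].astype(float)
    density = hu_to_density(calibration, hu)
    air = hu < air_threshold
    if air.all():
        raise DegenerateDensityError("segment consists entirely of air voxels")
    if air.any():
        density[air] = density[~air].mean()
    masses = density * volume.voxel_volume_mm3 * MM3_TO_M3
    positions = voxel_world_coordinates(volume, mask)
    return MassMap(masses=masses, positions=positions, voxel_volume_mm3=volume.voxel_volume_mm3)


def segment_mass_volume(massmap: MassMap, voxel_volume_mm3: float | None = None) -> tuple[float, float]:
    """Total mass (g) and volume (cm^3) of a segment; air voxels count toward both."""
    vv = massmap.voxel_volume_mm3 if voxel_volume_mm3 is None else voxel_volume_mm3
    mass_g = float(massmap.masses.sum()) * 1e3
    volume_cm3 = len(massmap.masses) * vv * 1e-3
    return mass_g, volume_cm3


def center_of_mass(massmap: MassMap) -> np.ndarray:
    """Mass-weighted mean position, in the frame of ``massmap.positions``."""
    total = massmap.masses.sum()
    if total <= 0:
        raise DegenerateDensityError("total mass is zero; CoM undefined")
    return massmap.masses @ massmap.positions / total


def inertia_tensor_about(massmap: MassMap, about) -> InertiaTensor:
    """Inertia tensor (kg cm^2) about ``about``, positions taken as ACS mm."""
    if massmap.masses.sum() <= 0:
        raise DegenerateDensityError("total mass is zero; inertia undefined")
    rel = massmap.positions - np.asarray(about, dtype=float)
    m = massmap.masses
    x, y, z = rel[:, 0], rel[:, 1], rel[:, 2]
    ixx = float(m @ (y * y + z * z))
    iyy = float(m @ (x * x + z * z))
    izz = float(m @ (x * x + y * y))
    ixy = -float(m @ (x * y))
    ixz = -float(m @ (x * z))
    iyz = -float(m @ (y * z))
    components = np.array(
        [[ixx, ixy, ixz], [ixy, iyy, iyz], [ixz, iyz, izz]]
    ) * MM2_TO_CM2
    return InertiaTensor(components=components, about=np.asarray(about, dtype=float))


def translate_inertia_to_com(
    tensor: InertiaTensor, total_mass_kg: float, com
) -> InertiaTensor:
    """Parallel-axis translation from the tensor's reference point to the CoM.

    ``I_com = I_ref - M (|d|^2 E - d d^T)`` with ``d = com - ref`` in mm and
    the correction converted to kg cm^2.
    """
    com = np.asarray(com, dtype=float)
    d = com - tensor.about
    correction = total_mass_kg * (np.dot(d, d) * np.eye(3) - np.outer(d, d)) * MM2_TO_CM2
    return InertiaTensor(components=tensor.components - correction, about=com)


def principal_moments(tensor: InertiaTensor) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition: ascending principal moments and their axes.

    Axis signs are fixed deterministically: each axis gets a positive dot
    product with the ACS axis of the same rank; on a tie (dot ≈ 0) the first
    nonzero component is made positive.
    """
    moments, vecs = np.linalg.eigh(tensor.components)
    order = np.argsort(moments)
    moments = moments[order]
    axes = vecs[:, order].T  # rows = eigenvectors
    for i in range(3):
        ref = axes[i, i]
        if abs(ref) < 1e-12:
            nz = np.nonzero(np.abs(axes[i]) > 1e-12)[0][0]
            ref = axes[i, nz]
        if ref < 0:
            axes[i] = -axes[i]
    return moments, axes
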