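"""Threshold segmentation, enclosed-cavity extraction, and cutting planes.

The head is everything at or above −300 HU (largest 26-connected component,
which discards disconnected debris such as support padding).  The brain is
the tissue inside the bony skull: a bone mask at ≥ 250 HU is (optionally)
morphologically closed to seal small foramina, the exterior air is flood
filled from the volume border through non-bone voxels with 6-connectivity,
and the largest remaining enclosed non-bone region is the cranial cavity;
brain voxels are the cavity voxels below the bone threshold.

Landmark-defined half-space cuts trim the neck (plane through the left
nuchal tubercle and both occipital condyles) and the ears (tragus,
intertragal notch, anterior notch of auricle, bilaterally) from the head
mask.  A voxel is retained iff its *center* has non-negative signed distance
to the plane; voxels exactly on the plane are retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from ctbsp.ct_io import CTVolume, VoxelMask
from ctbsp.errors import DegeneracyError, EmptySegmentError, TopologyError

__all__ = [
    "CuttingPlane",
    "threshold_mask",
    "largest_component",
    "segment_head",
    "segment_brain",
    "define_cutting_plane",
    "apply_cutting_plane",
]

HEAD_THRESHOLD_HU = -300.0
BONE_THRESHOLD_HU = 250.0

# 26-connectivity for foreground, 6-connectivity for background flood fill:
# a diagonal voxel contact joins tissue but does not let exterior air leak
# into the cranial cavity.
_CONN_26 = ndimage.generate_binary_structure(3, 3)
_CONN_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class CuttingPlane:
    """Oriented plane: voxels with ``(v - point) @ normal >= 0`` are kept."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(self.normal)
        if abs(norm - 1.0) > 1e-9:
            raise DegeneracyError("plane normal must be a unit vector")

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.point) @ self.normal

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump({"point": list(self.point), "normal": list(self.normal)}, fh)
        return path


def threshold_mask(volume: CTVolume, threshold: float, mode: str = "above") -> VoxelMask:
    """Global HU threshold: ``above`` keeps HU >= threshold, ``below`` HU < threshold."""
    if mode == "above":
        data = volume.data >= threshold
    elif mode == "below":
        data = volume.data < threshold
    else:
        raise ValueError(f"mode must be 'above' or 'below', got {mode!r}")
    return VoxelMask(data=data, reference=volume)


def largest_component(mask: VoxelMask) -> VoxelMask:
    """Largest 26-connected foreground component of a mask."""
    labels, n = ndimage.label(mask.data, structure=_CONN_26)
    if n == 0:
        raise EmptySegmentError("mask has no foreground voxels")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return VoxelMask(data=labels == int(np.argmax(counts)), reference=mask.reference)


def segment_head(volume: CTVolume, threshold: float = HEAD_THRESHOLD_HU) -> VoxelMask:
    """Head mask: HU >= −300 (soft tissue + brain + bone), largest component."""
    thresholded = threshold_mask(volume, threshold, mode="above")
    if thresholded.count == 0:
        raise EmptySegmentError(f"no voxels at or above {threshold} HU")
    return largest_component(thresholded)


def segment_brain(
    volume: CTVolume,
    closing_radius: int = 0,
    bone_threshold: float = BONE_THRESHOLD_HU,
) -> VoxelMask:
    """Brain mask: sub-bone-threshold voxels inside the enclosed cranial cavity.

    Parameters
    ----------
    closing_radius
        Radius (voxels) of the ball used to morphologically close the bone
        mask before the cavity search; 0 disables closing.  Real skulls have
        open foramina that need a radius > 0; idealized phantoms do not.
    """
    bone = volume.data >= bone_threshold
    if closing_radius > 0:
        r = int(closing_radius)
        zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
        ball = xx**2 + yy**2 + zz**2 <= r**2
        bone_closed = ndimage.binary_closing(bone, structure=ball)
    else:
        bone_closed = bone

    non_bone = ~bone_closed
    labels, n = ndimage.label(non_bone, structure=_CONN_6)
    if n == 0:
        raise TopologyError("volume is solid bone; no cavity exists")
    border_labels = np.unique(
        np.concatenate(
            [
                labels[0, :, :].ravel(),
                labels[-1, :, :].ravel(),
                labels[:, 0, :].ravel(),
                labels[:, -1, :].ravel(),
                labels[:, :, 0].ravel(),
                labels[:, :, -1].ravel(),
            ]
        )
    )
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    counts[0] = 0
    counts[border_labels[border_labels > 0]] = 0
    if counts.max() == 0:
        raise TopologyError("no enclosed cavity found inside the bone shell")
    cavity = labels == int(np.argmax(counts))
    brain = cavity & (volume.data < bone_threshold)
    if not brain.any():
        raise TopologyError("enclosed cavity contains no sub-threshold tissue")
    return VoxelMask(data=brain, reference=volume)


def define_cutting_plane(p1, p2, p3, keep_point) -> CuttingPlane:
    """Plane through three landmarks, oriented so ``keep_point`` is retained."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    keep_point = np.asarray(keep_point, dtype=float)
    cross = np.cross(p2 - p1, p3 - p1)
    max_edge = max(
        np.linalg.norm(p2 - p1), np.linalg.norm(p3 - p1), np.linalg.norm(p3 - p2)
    )
    # |cross| / max_edge is the smallest triangle altitude (up to a factor of 1)
    if max_edge == 0 or np.linalg.norm(cross) / max_edge <= 1e-6:
        raise DegeneracyError("cutting-plane landmarks are collinear")
    normal = cross / np.linalg.norm(cross)
    if (keep_point - p1) @ normal < 0:
        normal = -normal
    return CuttingPlane(point=p1, normal=normal)


def apply_cutting_plane(mask: VoxelMask, plane: CuttingPlane) -> VoxelMask:
    """Clear mask voxels whose center lies strictly on the discard side.

    The signed distance is linear in the voxel index, so it is evaluated on
    the full grid with three broadcast 1-D terms rather than per voxel.
    """
    vol = mask.reference
    linear = (vol.orientation * vol.spacing[np.newaxis, :]).T @ plane.normal  # per-axis step
    const = (vol.origin - plane.point) @ plane.normal
    ni, nj, nk = vol.data.shape
    di = linear[0] * np.arange(ni)[:, None, None]
    dj = linear[1] * np.arange(nj)[None, :, None]
    dk = linear[2] * np.arange(nk)[None, None, :]
    keep = (const + di + dj + dk) >= 0
    return VoxelMask(data=mask.data & keep, reference=vol)
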