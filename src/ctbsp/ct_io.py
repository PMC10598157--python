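"""CT volume / mask / landmark containers and file I/O.

Conventions
-----------
* ``CTVolume.data`` is indexed ``(i, j, k)`` in the file's fastest-to-slowest
  axis order; the world transform is ``world = origin + orientation @
  (spacing * index)`` with **voxel-center** semantics.
* The world frame is whatever the file stores (no implicit RAS/LPS
  re-orientation).  NIfTI affines are RAS+ by convention and NRRD/SimpleITK
  uses LPS; the package treats either as "the scanner frame" and only
  converts explicitly on FCSV import, where Slicer declares the convention
  in the header.  The configured target convention defaults to LPS.
* Lengths are mm throughout; HU is dimensionless.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from ctbsp.errors import AlignmentError, FormatError, MetadataError, ValidationError

__all__ = [
    "CTVolume",
    "VoxelMask",
    "LandmarkSet",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "voxel_world_coordinates",
]

_ORTHO_TOL = 1e-6


@dataclass
class CTVolume:
    """A 3-D grid of Hounsfield units with its world transform.

    Parameters
    ----------
    data
        3-D array of HU values.
    spacing
        Per-axis voxel edge length in mm, strictly positive.
    origin
        World position (mm) of the *center* of voxel (0, 0, 0).
    orientation
        3x3 direction-cosine matrix; column ``a`` is the world direction of
        index axis ``a``.  Must be orthonormal.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError("volume data must be 3-D with size >= 1 per axis")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValidationError("spacing must be 3 strictly positive lengths")
        if self.orientation.shape != (3, 3) or not np.allclose(
            self.orientation.T @ self.orientation, np.eye(3), atol=_ORTHO_TOL
        ):
            raise MetadataError("orientation must be a 3x3 orthonormal matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """4x4 index->world affine (voxel-center convention)."""
        out = np.eye(4)
        out[:3, :3] = self.orientation * self.spacing[np.newaxis, :]
        out[:3, 3] = self.origin
        return out

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) world points (mm)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * self.spacing @ self.orientation.T + self.origin


@dataclass
class VoxelMask:
    """Boolean voxel selection aligned to a :class:`CTVolume`."""

    data: np.ndarray
    reference: CTVolume

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.reference.data.shape:
            raise AlignmentError(
                f"mask shape {self.data.shape} != volume shape {self.reference.data.shape}"
            )

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        """(N, 3) integer indices of the true voxels."""
        return np.argwhere(self.data)


@dataclass
class LandmarkSet:
    """Named 3-D world points (mm): ACS landmarks (RF/LF/RZ/LZ), cutting-plane
    landmarks (LNT, LOC/ROC; ear triplets RT/RIN/RAN, LT/LIN/LAN), or free
    names."""

    entries: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, point in self.entries.items():
            p = np.asarray(point, dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValidationError(f"landmark {name!r} is not a finite 3-D point")
            if name in clean:
                raise ValidationError(f"duplicate landmark name {name!r}")
            clean[name] = p
        self.entries = clean

    def __getitem__(self, name: str) -> np.ndarray:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Volume I/O


def _volume_from_affine(data: np.ndarray, affine: np.ndarray) -> CTVolume:
    linear = affine[:3, :3]
    spacing = np.linalg.norm(linear, axis=0)
    if np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise MetadataError("file affine has zero or non-finite spacing")
    orientation = linear / spacing[np.newaxis, :]
    return CTVolume(data=data, spacing=spacing, origin=affine[:3, 3].copy(), orientation=orientation)


def read_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd) volume.

    The returned world transform reproduces the file's affine metadata
    exactly; HU values are returned as stored.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    name = path.name.lower()
    try:
        if name.endswith((".nii", ".nii.gz")):
            img = nib.load(str(path))
            data = np.asarray(img.dataobj)
            return _volume_from_affine(data, img.affine)
        if name.endswith(".nrrd"):
            img = sitk.ReadImage(str(path))
            data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
            spacing = np.array(img.GetSpacing())
            origin = np.array(img.GetOrigin())
            orientation = np.array(img.GetDirection()).reshape(3, 3)
            return CTVolume(data=data, spacing=spacing, origin=origin, orientation=orientation)
    except (MetadataError, ValidationError):
        raise
    except Exception as exc:  # unreadable / corrupt file
        raise FormatError(f"cannot read volume {path}: {exc}") from exc
    raise FormatError(f"unsupported volume format: {path.name}")


def write_volume(volume: CTVolume, path: str | Path) -> Path:
    """Write a volume (or a 0/1 mask volume) to NIfTI or NRRD."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(volume.data, volume.affine), str(path))
    elif name.endswith(".nrrd"):
        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in volume.spacing))
        img.SetOrigin(tuple(float(o) for o in volume.origin))
        img.SetDirection(tuple(float(d) for d in volume.orientation.ravel()))
        sitk.WriteImage(img, str(path))
    else:
        raise FormatError(f"unsupported volume format: {path.name}")
    return path


# ---------------------------------------------------------------------------
# Landmark I/O


def _fcsv_to_convention(point: np.ndarray, file_cs: str, convention: str) -> np.ndarray:
    if file_cs == convention:
        return point
    # RAS <-> LPS: negate x and y
    return point * np.array([-1.0, -1.0, 1.0])


def read_landmarks(path: str | Path, convention: str = "LPS") -> LandmarkSet:
    """Read a landmark set from JSON (``{name: [x, y, z]}``) or Slicer FCSV.

    FCSV files declare their coordinate system in the header
    (``# CoordinateSystem = RAS`` or ``LPS``; Slicer also writes ``0`` for
    RAS and ``1`` for LPS); points are converted to `convention` by the
    documented sign flip of x and y.  JSON files are assumed to already be
    in the working convention.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            raw = json.load(fh)
        return LandmarkSet(entries={str(k): np.asarray(v, dtype=float) for k, v in raw.items()})
    if path.suffix.lower() == ".fcsv":
        file_cs = "RAS"  # Slicer default
        entries: dict[str, np.ndarray] = {}
        with open(path, newline="") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    lowered = line.lower().replace(" ", "")
                    if "coordinatesystem=" in lowered:
                        token = lowered.split("coordinatesystem=")[1]
                        file_cs = "LPS" if token.startswith(("lps", "1")) else "RAS"
                    continue
                row = next(csv.reader([line]))
                if len(row) < 12:
                    raise FormatError(f"malformed FCSV row: {line!r}")
                label = row[11].strip()
                point = np.array([float(row[1]), float(row[2]), float(row[3])])
                if label in entries:
                    raise ValidationError(f"duplicate landmark name {label!r}")
                entries[label] = _fcsv_to_convention(point, file_cs, convention)
        return LandmarkSet(entries=entries)
    raise FormatError(f"unsupported landmark format: {path.name}")


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> Path:
    """Write a landmark set as JSON in the working convention."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({k: list(map(float, v)) for k, v in landmarks.entries.items()}, fh, indent=1)
    return path


# ---------------------------------------------------------------------------
# Coordinate mapping


def voxel_world_coordinates(volume: CTVolume, mask: VoxelMask) -> np.ndarray:
    """World coordinates (mm) of the centers of all true mask voxels.

    Returns an (N, 3) array, one row per selected voxel, using
    ``point = origin + orientation @ (spacing * index)``.
    """
    if mask.data.shape != volume.data.shape:
        raise AlignmentError("mask is not aligned to the volume")
    return volume.index_to_world(mask.indices())
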