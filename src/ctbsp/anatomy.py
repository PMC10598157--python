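"""Anatomical coordinate system (ACS) and atlanto-occipital joint (AOJ).

The ACS is built from four palpable skull landmarks: the right and left
frontal processes of the zygomatic bone (RF, LF) and the right and left
zygomatic processes of the frontal bone (RZ, LZ).  The origin is the RZ–LZ
midpoint; +x points ventrally toward the RF–LF midpoint, +y points right
laterally (toward RZ), +z caudally.  Construction: x toward midpoint(RF, LF);
preliminary y toward RZ; z = x × y_prelim; final y = z × x, which restores
exact orthogonality while keeping y on the RZ side and the frame
right-handed.

The AOJ is the midpoint of the most caudal aspects of the right and left
occipital condyles (ROC, LOC) — the same landmarks that anchor the head-neck
cutting plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ctbsp.errors import DegeneracyError

__all__ = ["AnatomicalFrame", "build_acs", "compute_aoj", "world_to_acs", "acs_to_world"]


@dataclass
class AnatomicalFrame:
    """Rigid frame: ``rotation`` rows are the ACS x/y/z axes in world coords,
    so ``world_to_acs`` is a plain rotate-then-translate (no transpose)."""

    origin: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise DegeneracyError("frame rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise DegeneracyError("frame rotation is left-handed")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(
                {"origin": list(self.origin), "rotation": self.rotation.tolist()}, fh, indent=1
            )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "AnatomicalFrame":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(origin=np.array(raw["origin"]), rotation=np.array(raw["rotation"]))


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise DegeneracyError(f"{what} has zero length")
    return v / norm


def build_acs(RF, LF, RZ, LZ) -> AnatomicalFrame:
    """Construct the ACS from the four zygomatic/frontal landmarks."""
    RF, LF, RZ, LZ = (np.asarray(p, dtype=float) for p in (RF, LF, RZ, LZ))
    origin = (RZ + LZ) / 2.0
    x = _unit((RF + LF) / 2.0 - origin, "origin -> midpoint(RF, LF)")
    y_prelim = _unit(RZ - origin, "origin -> RZ")
    z_raw = np.cross(x, y_prelim)
    # sin of the x / y_prelim angle; the frame is undefined if they align
    if np.linalg.norm(z_raw) <= 1e-4:
        raise DegeneracyError("midpoint(RF, LF) lies on the RZ-LZ line")
    z = _unit(z_raw, "x cross preliminary y")
    y = np.cross(z, x)
    return AnatomicalFrame(origin=origin, rotation=np.vstack([x, y, z]))


def compute_aoj(ROC, LOC) -> np.ndarray:
    """Atlanto-occipital joint: midpoint of the two occipital condyle points."""
    return (np.asarray(ROC, dtype=float) + np.asarray(LOC, dtype=float)) / 2.0


def world_to_acs(frame: AnatomicalFrame, points) -> np.ndarray:
    """Map world points (mm) into ACS coordinates (mm)."""
    pts = np.asarray(points, dtype=float)
    out = (np.atleast_2d(pts) - frame.origin) @ frame.rotation.T
    return out[0] if pts.ndim == 1 else out


def acs_to_world(frame: AnatomicalFrame, points) -> np.ndarray:
    """Inverse of :func:`world_to_acs`."""
    pts = np.asarray(points, dtype=float)
    out = np.atleast_2d(pts) @ frame.rotation + frame.origin
    return out[0] if pts.ndim == 1 else out
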