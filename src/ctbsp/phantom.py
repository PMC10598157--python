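"""Synthetic CT head phantoms with closed-form mass properties.

A phantom is an ordered list of geometric primitives (ellipsoid, sphere,
cuboid, spherical shell, cylinder) with assigned densities; later primitives
overwrite earlier ones where they overlap, which is how a skull "shell" is
built from a bone ellipsoid with a brain ellipsoid drawn inside it.  The
phantom is voxelized by sampling the density at voxel centers and mapping it
to HU through the *inverse* of the bilinear calibration, so the pipeline's
HU→density step recovers the assigned densities exactly (up to optional
Gaussian HU noise).

Because every primitive is a classical solid, each named region (head,
brain) has exact mass, centroid and inertia obtained by composing solid
formulas with the parallel-axis theorem; overlaps must resolve to full
containment, which is what makes the composition exact.  These analytic
values are the ground truth the voxel pipeline is validated against.

The default "pig-like" phantom emulates a pre-adolescent pig head at the
study's scale: a soft-tissue ellipsoid (~2 kg) containing an ellipsoidal
bone shell enclosing a ~95 g brain, with a neck cylinder trimmed off by the
landmark-defined head-neck cutting plane, skull landmarks for the ACS, and
condyle/nuchal landmarks defining the cut.  It emulates composition and
scale, not skull morphology, partial-volume blur, or CT physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ctbsp.calibration import DensityCalibration, density_to_hu, fit_bilinear_calibration, read_rod_table
from ctbsp.ct_io import CTVolume, LandmarkSet
from ctbsp.errors import UnsupportedGeometryError, ValidationError
from ctbsp.inertial import MM2_TO_CM2, MM3_TO_M3, InertiaTensor, principal_moments
from ctbsp.tables import rod_table_path

__all__ = [
    "PrimitiveSpec",
    "PhantomSpec",
    "OracleProperties",
    "analytic_properties",
    "generate_phantom",
    "generate_cohort",
    "noise_sd_for_r_squared",
    "pig_like_phantom",
    "default_calibration",
    "BACKGROUND_HU",
]

BACKGROUND_HU = -1000.0
_SHAPES = ("ellipsoid", "sphere", "cuboid", "spherical_shell", "cylinder")
_TOL = 1e-9


@dataclass(frozen=True)
class PrimitiveSpec:
    """One solid: shape, pose, size (mm) and density (kg/m^3).

    ``dimensions`` by shape: ellipsoid (a, b, c) semi-axes; sphere (r,);
    cuboid (lx, ly, lz) full edge lengths; spherical_shell (r_outer,
    r_inner); cylinder (r, h) with the axis along the local z.  List order
    is priority: later primitives overwrite earlier ones.
    """

    name: str
    shape: str
    center: tuple[float, float, float]
    dimensions: tuple[float, ...]
    density: float
    orientation: tuple[tuple[float, ...], ...] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValidationError(f"unknown primitive shape {self.shape!r}")
        if any(d <= 0 for d in self.dimensions):
            raise ValidationError(f"primitive {self.name!r} has non-positive dimension")
        if self.density < 0:
            raise ValidationError(f"primitive {self.name!r} has negative density")
        if self.shape == "spherical_shell" and self.dimensions[1] >= self.dimensions[0]:
            raise ValidationError("shell inner radius must be < outer radius")

    @property
    def R(self) -> np.ndarray:
        return np.asarray(self.orientation, dtype=float)

    @property
    def c(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    # -- solid geometry -----------------------------------------------------

    @property
    def volume_mm3(self) -> float:
        d = self.dimensions
        if self.shape == "ellipsoid":
            return 4.0 / 3.0 * np.pi * d[0] * d[1] * d[2]
        if self.shape == "sphere":
            return 4.0 / 3.0 * np.pi * d[0] ** 3
        if self.shape == "cuboid":
            return d[0] * d[1] * d[2]
        if self.shape == "spherical_shell":
            return 4.0 / 3.0 * np.pi * (d[0] ** 3 - d[1] ** 3)
        return np.pi * d[0] ** 2 * d[1]  # cylinder

    @property
    def mass_kg(self) -> float:
        return self.density * self.volume_mm3 * MM3_TO_M3

    def inertia_at_com_kg_cm2(self, density: float | None = None) -> np.ndarray:
        """Closed-form inertia tensor of the solid about its own centroid."""
        rho = self.density if density is None else density
        m = rho * self.volume_mm3 * MM3_TO_M3
        d = self.dimensions
        if self.shape == "ellipsoid":
            a, b, c = d
            local = m / 5.0 * np.diag([b * b + c * c, a * a + c * c, a * a + b * b])
        elif self.shape == "sphere":
            local = 2.0 / 5.0 * m * d[0] ** 2 * np.eye(3)
        elif self.shape == "cuboid":
            lx, ly, lz = d
            local = m / 12.0 * np.diag([ly * ly + lz * lz, lx * lx + lz * lz, lx * lx + ly * ly])
        elif self.shape == "spherical_shell":
            ro, ri = d
            local = 2.0 / 5.0 * m * (ro**5 - ri**5) / (ro**3 - ri**3) * np.eye(3)
        else:  # cylinder
            r, h = d
            local = m * np.diag(
                [(3 * r * r + h * h) / 12.0, (3 * r * r + h * h) / 12.0, r * r / 2.0]
            )
        return self.R @ local @ self.R.T * MM2_TO_CM2

    # -- bounding geometry --------------------------------------------------

    @property
    def r_out(self) -> float:
        """Circumscribed-sphere radius about the center."""
        d = self.dimensions
        if self.shape in ("ellipsoid",):
            return max(d)
        if self.shape == "sphere":
            return d[0]
        if self.shape == "cuboid":
            return float(np.linalg.norm(d)) / 2.0
        if self.shape == "spherical_shell":
            return d[0]
        return float(np.hypot(d[0], d[1] / 2.0))  # cylinder

    @property
    def r_in(self) -> float:
        """Inscribed-sphere radius of the *material* about the center."""
        d = self.dimensions
        if self.shape == "ellipsoid":
            return min(d)
        if self.shape == "sphere":
            return d[0]
        if self.shape == "cuboid":
            return min(d) / 2.0
        if self.shape == "spherical_shell":
            return 0.0  # the center is in the cavity
        return min(d[0], d[1] / 2.0)

    def world_half_extents(self) -> np.ndarray:
        """Tight half-extent of the solid along each world axis."""
        d = self.dimensions
        R = self.R
        if self.shape in ("ellipsoid", "sphere"):
            semi = np.array(d if self.shape == "ellipsoid" else [d[0]] * 3, dtype=float)
            return np.linalg.norm(R * semi[np.newaxis, :], axis=1)
        if self.shape == "cuboid":
            return np.abs(R) @ (np.asarray(d, dtype=float) / 2.0)
        if self.shape == "spherical_shell":
            return np.full(3, d[0])
        r, h = d  # cylinder
        u = R[:, 2]
        return np.abs(u) * h / 2.0 + r * np.sqrt(np.maximum(0.0, 1.0 - u * u))

    def contains_points(self, pts_local: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
        """Membership of points given in the primitive's local frame."""
        qx, qy, qz = pts_local
        d = self.dimensions
        if self.shape == "ellipsoid":
            return (qx / d[0]) ** 2 + (qy / d[1]) ** 2 + (qz / d[2]) ** 2 <= 1.0
        if self.shape == "sphere":
            return qx * qx + qy * qy + qz * qz <= d[0] ** 2
        if self.shape == "cuboid":
            return (
                (np.abs(qx) <= d[0] / 2.0)
                & (np.abs(qy) <= d[1] / 2.0)
                & (np.abs(qz) <= d[2] / 2.0)
            )
        if self.shape == "spherical_shell":
            rr = qx * qx + qy * qy + qz * qz
            return (rr <= d[0] ** 2) & (rr >= d[1] ** 2)
        return (qx * qx + qy * qy <= d[0] ** 2) & (np.abs(qz) <= d[1] / 2.0)  # cylinder


@dataclass
class PhantomSpec:
    """Full phantom: primitives, grid geometry, landmarks, noise, regions."""

    primitives: list[PrimitiveSpec]
    spacing: tuple[float, float, float]
    extent: tuple[tuple[float, float, float], tuple[float, float, float]]
    landmarks: LandmarkSet
    regions: dict[str, list[str]] = field(default_factory=dict)
    hu_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.spacing) <= 0):
            raise ValidationError("spacing must be positive")
        lo, hi = (np.asarray(e, dtype=float) for e in self.extent)
        for name, p in self.landmarks.entries.items():
            if np.any(p < lo - _TOL) or np.any(p > hi + _TOL):
                raise ValidationError(f"landmark {name!r} lies outside the phantom extent")

    def with_spacing(self, spacing: float) -> "PhantomSpec":
        return replace(self, spacing=(spacing, spacing, spacing))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "primitives": [
                {
                    "name": p.name,
                    "shape": p.shape,
                    "center": [float(x) for x in p.center],
                    "dimensions": [float(x) for x in p.dimensions],
                    "density": float(p.density),
                    "orientation": [[float(x) for x in row] for row in p.orientation],
                }
                for p in self.primitives
            ],
            "spacing": [float(s) for s in self.spacing],
            "extent": [[float(x) for x in self.extent[0]], [float(x) for x in self.extent[1]]],
            "landmarks": {k: [float(x) for x in v] for k, v in self.landmarks.entries.items()},
            "regions": self.regions,
            "hu_noise_sd": self.hu_noise_sd,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            primitives=[
                PrimitiveSpec(
                    name=p["name"],
                    shape=p["shape"],
                    center=tuple(p["center"]),
                    dimensions=tuple(p["dimensions"]),
                    density=p["density"],
                    orientation=tuple(tuple(r) for r in p["orientation"]),
                )
                for p in raw["primitives"]
            ],
            spacing=tuple(raw["spacing"]),
            extent=(tuple(raw["extent"][0]), tuple(raw["extent"][1])),
            landmarks=LandmarkSet(entries={k: np.array(v) for k, v in raw["landmarks"].items()}),
            regions=raw.get("regions", {}),
            hu_noise_sd=raw.get("hu_noise_sd", 0.0),
            seed=raw.get("seed", 0),
        )


@dataclass
class OracleProperties:
    """Analytic ground truth for one region: mass, volume, CoM, inertia."""

    mass_kg: float
    volume_mm3: float
    com: np.ndarray  # phantom world frame, mm
    inertia_at_com: InertiaTensor  # kg cm^2, world axes
    principal_moments_kg_cm2: np.ndarray


# ---------------------------------------------------------------------------
# containment / overlap analysis


def _relation(p: PrimitiveSpec, q: PrimitiveSpec) -> str:
    """Classify the overlap of q's solid with p's *material*.

    Returns ``disjoint``, ``contained`` (q inside p) or ``unknown``.  The
    tests are exact for the supported configurations (co-oriented ellipsoid
    chains, boxes) and conservative otherwise; a conservative ``unknown`` on
    a genuinely contained pair fails loudly rather than silently mis-adding
    mass.
    """
    dvec = q.c - p.c
    dist = float(np.linalg.norm(dvec))
    if dist >= p.r_out + q.r_out - _TOL:
        return "disjoint"
    if p.shape == "spherical_shell" and dist + q.r_out <= p.dimensions[1] + _TOL:
        return "disjoint"  # q sits entirely inside the shell cavity

    if p.shape in ("ellipsoid", "sphere"):
        semi = np.array(
            p.dimensions if p.shape == "ellipsoid" else [p.dimensions[0]] * 3, dtype=float
        )
        S = np.diag(1.0 / semi) @ p.R.T  # maps p to the unit ball
        dd = float(np.linalg.norm(S @ dvec))
        if q.shape in ("ellipsoid", "sphere"):
            q_semi = np.array(
                q.dimensions if q.shape == "ellipsoid" else [q.dimensions[0]] * 3, dtype=float
            )
            sigma = float(np.linalg.norm(S @ q.R @ np.diag(q_semi), ord=2))
            if dd + sigma <= 1.0 + _TOL:
                return "contained"
        elif q.shape == "cuboid":
            half = np.asarray(q.dimensions, dtype=float) / 2.0
            corners = np.array(
                [[sx * half[0], sy * half[1], sz * half[2]] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
            )
            world = q.c + corners @ q.R.T
            if np.all(np.linalg.norm((world - p.c) @ S.T, axis=1) <= 1.0 + _TOL):
                return "contained"
        else:
            if dd + q.r_out / semi.min() <= 1.0 + _TOL:
                return "contained"
        return "unknown"

    if p.shape == "cuboid":
        half_p = np.asarray(p.dimensions, dtype=float) / 2.0
        d_local = p.R.T @ dvec
        if q.shape in ("ellipsoid", "sphere"):
            q_semi = np.array(
                q.dimensions if q.shape == "ellipsoid" else [q.dimensions[0]] * 3, dtype=float
            )
            support = np.linalg.norm(p.R.T @ q.R @ np.diag(q_semi), axis=1)
        elif q.shape == "cuboid":
            support = np.abs(p.R.T @ q.R) @ (np.asarray(q.dimensions, dtype=float) / 2.0)
        else:
            support = np.full(3, q.r_out)
        if np.all(np.abs(d_local) + support <= half_p + _TOL):
            return "contained"
        return "unknown"

    # cylinder / shell as container: inscribed-sphere bound only
    if dist + q.r_out <= p.r_in + _TOL:
        return "contained"
    return "unknown"


def _compose(parts: list[tuple[float, np.ndarray, np.ndarray]]) -> tuple[float, np.ndarray, np.ndarray]:
    """Combine signed (mass, com, I_at_own_com) parts about the joint CoM."""
    total = sum(m for m, _, _ in parts)
    com = sum(m * c for m, c, _ in parts) / total
    tensor = np.zeros((3, 3))
    for m, c, inertia in parts:
        d = c - com
        tensor += inertia + m * (np.dot(d, d) * np.eye(3) - np.outer(d, d)) * MM2_TO_CM2
    return total, com, tensor


def analytic_properties(spec: PhantomSpec, region: str) -> OracleProperties:
    """Closed-form mass properties of a named region of the phantom.

    The region's visible material is each listed primitive minus any
    later-priority primitive contained in it (chains are handled: a solid
    already hidden inside a subtracted solid is not subtracted twice).
    Partial, non-containment overlap with a later primitive is an error —
    only containment composes exactly.
    """
    if region not in spec.regions:
        raise ValidationError(f"phantom defines no region {region!r}")
    names = set(spec.regions[region])
    order = {p.name: i for i, p in enumerate(spec.primitives)}
    parts: list[tuple[float, np.ndarray, np.ndarray]] = []
    volume = 0.0
    for p in spec.primitives:
        if p.name not in names:
            continue
        subtracted: list[PrimitiveSpec] = []
        for q in spec.primitives[order[p.name] + 1 :]:
            rel = _relation(p, q)
            if rel == "disjoint":
                continue
            if rel == "unknown":
                raise UnsupportedGeometryError(
                    f"primitives {p.name!r} and {q.name!r} overlap without containment"
                )
            if any(_relation(s, q) == "contained" for s in subtracted):
                continue  # already hidden inside an earlier subtraction
            subtracted.append(q)
        parts.append((p.mass_kg, p.c, p.inertia_at_com_kg_cm2()))
        volume += p.volume_mm3
        for q in subtracted:
            m_hole = p.density * q.volume_mm3 * MM3_TO_M3
            parts.append((-m_hole, q.c, -q.inertia_at_com_kg_cm2(density=p.density)))
            volume -= q.volume_mm3
    mass, com, tensor = _compose(parts)
    inertia = InertiaTensor(components=tensor, about=com)
    moments, _ = principal_moments(inertia)
    return OracleProperties(
        mass_kg=mass,
        volume_mm3=volume,
        com=com,
        inertia_at_com=inertia,
        principal_moments_kg_cm2=moments,
    )


# ---------------------------------------------------------------------------
# voxelization


def generate_phantom(
    spec: PhantomSpec, calibration: DensityCalibration
) -> tuple[CTVolume, LandmarkSet]:
    """Voxelize the phantom: density at each voxel center → HU (+ noise).

    Deterministic for a fixed ``spec.seed``; the background is air
    (−1000 HU) and the grid is axis-aligned with voxel centers strictly
    inside the extent.
    """
    spacing = np.asarray(spec.spacing, dtype=float)
    lo, hi = (np.asarray(e, dtype=float) for e in spec.extent)
    shape = np.maximum(1, np.floor((hi - lo) / spacing).astype(int))
    origin = lo + spacing / 2.0
    data = np.full(tuple(shape), BACKGROUND_HU, dtype=np.float32)
    axes = [origin[k] + spacing[k] * np.arange(shape[k]) for k in range(3)]

    for prim in spec.primitives:
        hu = float(density_to_hu(calibration, prim.density))
        half = prim.world_half_extents()
        i0 = np.maximum(0, np.floor((prim.c - half - origin) / spacing).astype(int))
        i1 = np.minimum(shape, np.ceil((prim.c - origin + half) / spacing).astype(int) + 1)
        if np.any(i0 >= i1):
            continue
        sub = [axes[k][i0[k] : i1[k]] for k in range(3)]
        dx = (sub[0] - prim.c[0])[:, None, None].astype(np.float32)
        dy = (sub[1] - prim.c[1])[None, :, None].astype(np.float32)
        dz = (sub[2] - prim.c[2])[None, None, :].astype(np.float32)
        RT = prim.R.T.astype(np.float32)
        local = (
            RT[0, 0] * dx + RT[0, 1] * dy + RT[0, 2] * dz,
            RT[1, 0] * dx + RT[1, 1] * dy + RT[1, 2] * dz,
            RT[2, 0] * dx + RT[2, 1] * dy + RT[2, 2] * dz,
        )
        inside = prim.contains_points(local)
        view = data[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]]
        view[inside] = hu

    if spec.hu_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data += spec.hu_noise_sd * rng.standard_normal(data.shape, dtype=np.float32)

    volume = CTVolume(data=data, spacing=spacing, origin=origin, orientation=np.eye(3))
    return volume, spec.landmarks


# ---------------------------------------------------------------------------
# default pig-like phantom


def default_calibration() -> DensityCalibration:
    """Bilinear calibration fitted to the bundled synthetic six-rod table."""
    return fit_bilinear_calibration(read_rod_table(rod_table_path()))


def _euler_rotation(deg_xyz: tuple[float, float, float]) -> np.ndarray:
    ax, ay, az = np.deg2rad(deg_xyz)
    cx, sx, cy, sy, cz, sz = np.cos(ax), np.sin(ax), np.cos(ay), np.sin(ay), np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


# Pig-scale geometry in an anatomy-aligned construction frame
# (+x ventral, +y right lateral, +z caudal), then rigidly moved into the
# scanner frame so the ACS construction is exercised on a non-trivial pose.
_SOFT_SEMI = (70.0, 62.0, 95.0)
_BONE_SEMI = (36.0, 32.0, 34.0)
_BRAIN_SEMI = (30.0, 26.0, 28.0)
_BONE_CENTER = (-10.0, 0.0, 25.0)
_NECK_R, _NECK_H = 25.0, 45.0
_NECK_CENTER = (0.0, 0.0, 95.0 + _NECK_H / 2.0)
_SOFT_RHO, _BONE_RHO, _BRAIN_RHO = 1040.0, 1700.0, 1035.0

_LANDMARKS_CONSTRUCTION = {
    # ACS landmarks on the bone-ellipsoid surface
    "RZ": (-28.0, 22.6274170, 8.0),
    "LZ": (-28.0, -22.6274170, 8.0),
    "RF": (8.0, 22.6274170, 8.0),
    "LF": (8.0, -22.6274170, 8.0),
    # condyles / nuchal tubercle spanning the head-neck cut plane z = 95
    "ROC": (-20.0, 12.0, 95.0),
    "LOC": (-20.0, -12.0, 95.0),
    "LNT": (-45.0, 0.0, 95.0),
    # ear-plane triplets on tangent planes y = +/-63 (the phantom has no
    # ears, so these cuts are exercised but remove nothing)
    "RT": (0.0, 63.0, 20.0),
    "RIN": (10.0, 63.0, 40.0),
    "RAN": (-15.0, 63.0, 10.0),
    "LT": (0.0, -63.0, 20.0),
    "LIN": (10.0, -63.0, 40.0),
    "LAN": (-15.0, -63.0, 10.0),
}


def pig_like_phantom(
    spacing: float = 0.5,
    hu_noise_sd: float = 0.0,
    seed: int = 0,
    pose_rotation_deg: tuple[float, float, float] = (8.0, -12.0, 5.0),
    pose_translation: tuple[float, float, float] = (20.0, -15.0, 10.0),
) -> PhantomSpec:
    """Default pig-scale phantom: soft-tissue ellipsoid + ellipsoidal bone
    shell + brain ellipsoid + neck cylinder, with landmarks."""
    Rg = _euler_rotation(pose_rotation_deg)
    t = np.asarray(pose_translation, dtype=float)
    pose = lambda p: tuple(Rg @ np.asarray(p, dtype=float) + t)  # noqa: E731
    orient = tuple(tuple(row) for row in Rg)
    prims = [
        PrimitiveSpec("neck", "cylinder", pose(_NECK_CENTER), (_NECK_R, _NECK_H), _SOFT_RHO, orient),
        PrimitiveSpec("soft_tissue", "ellipsoid", pose((0.0, 0.0, 0.0)), _SOFT_SEMI, _SOFT_RHO, orient),
        PrimitiveSpec("skull", "ellipsoid", pose(_BONE_CENTER), _BONE_SEMI, _BONE_RHO, orient),
        PrimitiveSpec("brain", "ellipsoid", pose(_BONE_CENTER), _BRAIN_SEMI, _BRAIN_RHO, orient),
    ]
    landmarks = LandmarkSet(entries={k: np.asarray(pose(v)) for k, v in _LANDMARKS_CONSTRUCTION.items()})
    half = np.vstack([p.world_half_extents() for p in prims])
    centers = np.vstack([p.c for p in prims])
    pts = np.vstack([centers - half, centers + half, *landmarks.entries.values()])
    # asymmetric margins keep voxel centers off the exact cut/tangent planes
    lo = pts.min(axis=0) - 5.2
    hi = pts.max(axis=0) + 4.8
    return PhantomSpec(
        primitives=prims,
        spacing=(spacing, spacing, spacing),
        extent=(tuple(lo), tuple(hi)),
        landmarks=landmarks,
        regions={"head": ["soft_tissue", "skull", "brain"], "brain": ["brain"]},
        hu_noise_sd=hu_noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohort generator


def noise_sd_for_r_squared(
    slope: float, target_r2: float, body_mass_range: tuple[float, float] = (18.0, 48.0)
) -> float:
    """Residual SD giving an expected r^2 under the variance decomposition
    r^2 = var(signal) / (var(signal) + sd^2) with uniform body masses."""
    var_body = (body_mass_range[1] - body_mass_range[0]) ** 2 / 12.0
    var_signal = slope**2 * var_body
    return float(np.sqrt(var_signal * (1.0 - target_r2) / target_r2))


def generate_cohort(
    n: int,
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int = 0,
    body_mass_range: tuple[float, float] = (18.0, 48.0),
) -> pd.DataFrame:
    """Paired body-mass / tissue-mass table with a known linear structure.

    Body masses are uniform on ``body_mass_range`` (the study's 18–48 kg by
    default); tissue mass is ``slope * body + intercept`` plus Gaussian
    noise.  Deterministic for a fixed seed.
    """
    if n < 3:
        raise ValidationError("a cohort needs at least 3 subjects")
    rng = np.random.default_rng(seed)
    body = rng.uniform(*body_mass_range, size=n)
    tissue = slope * body + intercept + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame({"body_mass_kg": body, "tissue_mass_g": tissue})
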