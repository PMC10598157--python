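"""Per-subject and cohort orchestration.

``run_subject`` executes the full chain on one CT volume + landmark set:
calibrate (or load) → head/brain segmentation → head-neck cutting plane on
both masks → ear planes on the head mask → voxel masses (air rule) →
mass/volume/CoM → ACS construction → world→ACS transform → inertia about
the ACS origin → parallel-axis translation to the CoM → principal moments →
AOJ.  Every threshold, plane equation and landmark used is recorded in the
run log, since those choices are the main reproducibility risk of
semi-manual CT workflows.

``run_cohort`` aggregates subject records into the summary table and the
four mass/volume-on-body-mass regressions.  ``run_tables`` is the
"table-only" entry point: it builds the same cohort outputs directly from
the bundled per-subject coordinate tables, with no imaging step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from ctbsp import anatomy, inertial, segmentation, summary_stats
from ctbsp.calibration import DensityCalibration, read_calibration
from ctbsp.ct_io import CTVolume, LandmarkSet, read_landmarks, read_volume, voxel_world_coordinates
from ctbsp.errors import CTBSPError, InsufficientDataError, ValidationError
from ctbsp.inertial import BodySegmentProperties
from ctbsp.summary_stats import SubjectRecord, cohort_summary, linear_fit
from ctbsp.tables import load_subject_table

__all__ = ["PipelineConfig", "run_subject", "run_cohort", "run_tables"]

_EAR_PLANES = {"right_ear": ("RT", "RIN", "RAN"), "left_ear": ("LT", "LIN", "LAN")}


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one subject run.

    ``volume``, ``landmarks`` and ``calibration`` may be in-memory objects
    or file paths.  Thresholds must be ordered air < head < bone.
    """

    volume: CTVolume | str | Path
    landmarks: LandmarkSet | str | Path
    calibration: DensityCalibration | str | Path
    subject_id: str = "subject"
    body_mass_kg: float = float("nan")
    head_threshold_hu: float = segmentation.HEAD_THRESHOLD_HU
    bone_threshold_hu: float = segmentation.BONE_THRESHOLD_HU
    air_threshold_hu: float = inertial.AIR_THRESHOLD_HU
    closing_radius: int = 0
    output_dir: str | Path | None = None
    seed: int = 0
    extras: dict[str, Any] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.air_threshold_hu < self.head_threshold_hu < self.bone_threshold_hu):
            raise ValidationError("thresholds must satisfy air < head < bone")

    def resolve(self) -> tuple[CTVolume, LandmarkSet, DensityCalibration]:
        vol = self.volume if isinstance(self.volume, CTVolume) else read_volume(self.volume)
        lm = (
            self.landmarks
            if isinstance(self.landmarks, LandmarkSet)
            else read_landmarks(self.landmarks)
        )
        cal = (
            self.calibration
            if isinstance(self.calibration, DensityCalibration)
            else read_calibration(self.calibration)
        )
        return vol, lm, cal


def _stage(name: str):
    """Decorator-ish context: re-raise package errors with stage context."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, CTBSPError):
                exc.args = (f"[stage {name}] {exc.args[0] if exc.args else ''}",)
            return False

    return _Ctx()


def _segment_properties(
    tag: str,
    volume: CTVolume,
    mask,
    calibration: DensityCalibration,
    frame: anatomy.AnatomicalFrame,
    air_threshold: float,
) -> BodySegmentProperties:
    massmap = inertial.compute_voxel_masses(volume, mask, calibration, air_threshold)
    mass_g, volume_cm3 = inertial.segment_mass_volume(massmap)
    acs_map = massmap.with_positions(anatomy.world_to_acs(frame, massmap.positions))
    com = inertial.center_of_mass(acs_map)
    tensor_origin = inertial.inertia_tensor_about(acs_map, np.zeros(3))
    tensor_com = inertial.translate_inertia_to_com(tensor_origin, mass_g / 1e3, com)
    moments, axes = inertial.principal_moments(tensor_com)
    return BodySegmentProperties(
        segment=tag,
        mass_g=mass_g,
        volume_cm3=volume_cm3,
        com=com,
        inertia_at_com=tensor_com,
        principal_moments_kg_cm2=moments,
        principal_axes=axes,
    )


def run_subject(config: PipelineConfig) -> SubjectRecord:
    """Run the full per-subject pipeline; optionally write CSV/JSON outputs."""
    volume, landmarks, calibration = config.resolve()
    log: dict[str, Any] = {
        "subject": config.subject_id,
        "thresholds_hu": {
            "head": config.head_threshold_hu,
            "bone": config.bone_threshold_hu,
            "air": config.air_threshold_hu,
        },
        "closing_radius": config.closing_radius,
        "landmarks": {k: list(map(float, v)) for k, v in landmarks.entries.items()},
        "planes": {},
    }

    with _stage("segment_head"):
        head = segmentation.segment_head(volume, config.head_threshold_hu)
    with _stage("segment_brain"):
        brain = segmentation.segment_brain(
            volume, config.closing_radius, config.bone_threshold_hu
        )

    with _stage("head_neck_plane"):
        centroid = voxel_world_coordinates(volume, head).mean(axis=0)
        neck_plane = segmentation.define_cutting_plane(
            landmarks["LNT"], landmarks["LOC"], landmarks["ROC"], keep_point=centroid
        )
        log["planes"]["head_neck"] = {
            "point": list(neck_plane.point),
            "normal": list(neck_plane.normal),
            "keep_point": list(map(float, centroid)),
        }
        head = segmentation.apply_cutting_plane(head, neck_plane)
        brain = segmentation.apply_cutting_plane(brain, neck_plane)

    with _stage("build_acs"):
        frame = anatomy.build_acs(
            landmarks["RF"], landmarks["LF"], landmarks["RZ"], landmarks["LZ"]
        )
        log["acs"] = {"origin": list(frame.origin), "rotation": frame.rotation.tolist()}

    with _stage("ear_planes"):
        for tag, (a, b, c) in _EAR_PLANES.items():
            if not all(name in landmarks for name in (a, b, c)):
                continue
            plane = segmentation.define_cutting_plane(
                landmarks[a], landmarks[b], landmarks[c], keep_point=frame.origin
            )
            log["planes"][tag] = {"point": list(plane.point), "normal": list(plane.normal)}
            head = segmentation.apply_cutting_plane(head, plane)

    with _stage("inertial_properties"):
        head_props = _segment_properties(
            "head", volume, head, calibration, frame, config.air_threshold_hu
        )
        brain_props = _segment_properties(
            "brain", volume, brain, calibration, frame, config.air_threshold_hu
        )

    with _stage("aoj"):
        aoj_world = anatomy.compute_aoj(landmarks["ROC"], landmarks["LOC"])
        aoj = anatomy.world_to_acs(frame, aoj_world)

    record = SubjectRecord(
        subject_id=config.subject_id,
        body_mass_kg=config.body_mass_kg if np.isfinite(config.body_mass_kg) else 1.0,
        head=head_props,
        brain=brain_props,
        aoj=aoj,
    )

    if config.output_dir is not None:
        _write_subject_outputs(record, log, Path(config.output_dir))
    return record


def _segment_json(props: BodySegmentProperties) -> dict[str, Any]:
    return {
        "mass_g": props.mass_g,
        "volume_cm3": props.volume_cm3,
        "com_acs_mm": list(map(float, props.com)),
        "com_distance_mm": props.com_distance_mm,
        "inertia_at_com_kg_cm2": props.inertia_at_com.components.tolist(),
        "principal_moments_kg_cm2": list(map(float, props.principal_moments_kg_cm2)),
        "principal_axes": props.principal_axes.tolist(),
    }


def _write_subject_outputs(record: SubjectRecord, log: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    sid = record.subject_id
    rows = []
    for props in (record.head, record.brain):
        com = props.com
        # table-style row: coordinates and distance at 0.1 mm, MoI at 0.01 kg cm^2
        rows.append(
            {
                "segment": props.segment,
                "mass_g": round(props.mass_g, 1),
                "volume_cm3": round(props.volume_cm3, 1),
                "x_mm": round(com[0], 1),
                "y_mm": round(com[1], 1),
                "z_mm": round(com[2], 1),
                "dist_mm": round(props.com_distance_mm, 1),
                "i1_kg_cm2": round(props.principal_moments_kg_cm2[0], 2),
                "i2_kg_cm2": round(props.principal_moments_kg_cm2[1], 2),
                "i3_kg_cm2": round(props.principal_moments_kg_cm2[2], 2),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / f"{sid}_segments.csv", index=False)
    payload = {
        "subject": sid,
        "body_mass_kg": record.body_mass_kg,
        "head": _segment_json(record.head),
        "brain": _segment_json(record.brain),
        "aoj_acs_mm": list(map(float, record.aoj)),
        "log": log,
    }
    with open(outdir / f"{sid}_report.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def _cohort_outputs(records: list[SubjectRecord]) -> dict[str, Any]:
    per_subject, summary = cohort_summary(records)
    out: dict[str, Any] = {"per_subject": per_subject, "summary": summary}
    body = np.array([r.body_mass_kg for r in records])
    fits = {}
    fittable = len(body) >= 3 and np.ptp(body) > 0
    for tag in ("head", "brain"):
        mass = np.array([getattr(r, tag).mass_g for r in records])
        vol = np.array([getattr(r, tag).volume_cm3 for r in records])
        if fittable and np.all(np.isfinite(mass)):
            fits[f"{tag}_mass_on_body_mass"] = linear_fit(body, mass)
        if fittable and np.all(np.isfinite(vol)):
            fits[f"{tag}_volume_on_body_mass"] = linear_fit(body, vol)
    out["regressions"] = fits
    return out


def run_cohort(
    configs: list[PipelineConfig], output_dir: str | Path | None = None
) -> dict[str, Any]:
    """Run every subject, then aggregate (summary table + regressions)."""
    if len(configs) < 2:
        raise InsufficientDataError("a cohort needs at least 2 subjects")
    records = [run_subject(c) for c in configs]
    out = _cohort_outputs(records)
    out["records"] = records
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        out["per_subject"].to_csv(outdir / "cohort_per_subject.csv", index=False)
        out["summary"].to_csv(outdir / "cohort_summary.csv")
    return out


def _record_from_table_rows(
    subject_id: str, body_mass_kg: float, head_row, brain_row, aoj_row
) -> SubjectRecord:
    def props(tag, row):
        moments = np.array([row.get(f"i{k}_kg_cm2", np.nan) for k in (1, 2, 3)])
        return BodySegmentProperties(
            segment=tag,
            mass_g=float("nan"),
            volume_cm3=float("nan"),
            com=np.array([row["x_mm"], row["y_mm"], row["z_mm"]], dtype=float),
            inertia_at_com=inertial.InertiaTensor(np.diag(np.nan_to_num(moments))),
            principal_moments_kg_cm2=moments,
            principal_axes=np.eye(3),
        )

    return SubjectRecord(
        subject_id=subject_id,
        body_mass_kg=body_mass_kg,
        head=props("head", head_row),
        brain=props("brain", brain_row),
        aoj=np.array([aoj_row["x_mm"], aoj_row["y_mm"], aoj_row["z_mm"]], dtype=float),
    )


def run_tables(output_dir: str | Path | None = None) -> dict[str, Any]:
    """Cohort aggregation straight from the bundled per-subject tables.

    No imaging: the published per-subject ACS coordinates and principal
    moments are the inputs, and all derived geometry (distances, separation,
    scatter, mean ± SD) is recomputed from them.
    """
    body, _ = load_subject_table(1)
    head, _ = load_subject_table(2)
    brain, _ = load_subject_table(3)
    aoj, _ = load_subject_table(4)
    records = []
    for i in range(len(head)):
        records.append(
            _record_from_table_rows(
                subject_id=str(head.loc[i, "subject"]),
                body_mass_kg=float(body.loc[i, "body_mass_kg"]),
                head_row=head.loc[i],
                brain_row=brain.loc[i],
                aoj_row=aoj.loc[i],
            )
        )
    out = _cohort_outputs(records)
    out["records"] = records
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        out["per_subject"].to_csv(outdir / "tables_per_subject.csv", index=False)
        out["summary"].to_csv(outdir / "tables_summary.csv")
    return out
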