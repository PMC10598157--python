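"""Cohort-level aggregation and regression.

Given per-subject segment properties in a common anatomical frame, this
module computes the distances the study reports — CoM and AOJ distances to
the ACS origin, head↔brain CoM separation, AOJ↔CoM distances, and each
point's scatter about the cohort mean point — together with mean ± SD
summaries (sample SD, n−1 denominator), and ordinary least-squares
regressions of tissue mass/volume on body mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ctbsp.errors import FitError, InsufficientDataError
from ctbsp.inertial import BodySegmentProperties

__all__ = [
    "SubjectRecord",
    "RegressionResult",
    "point_distance",
    "cohort_summary",
    "linear_fit",
]


@dataclass
class SubjectRecord:
    """One animal: body mass plus head/brain properties and AOJ, all in ACS."""

    subject_id: str
    body_mass_kg: float
    head: BodySegmentProperties
    brain: BodySegmentProperties
    aoj: np.ndarray  # ACS mm

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0:
            raise ValueError("body mass must be positive")
        self.aoj = np.asarray(self.aoj, dtype=float)


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS of y on x: slope, intercept, r^2, two-sided p for slope≠0."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    slope_stderr: float
    n: int
    alpha: float = 0.05

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t confidence interval for the slope."""
        half = sps.t.ppf(0.5 + level / 2.0, self.n - 2) * self.slope_stderr
        return self.slope - half, self.slope + half


def point_distance(p, q) -> float:
    """Euclidean distance (mm) between two 3-D points."""
    return float(np.linalg.norm(np.asarray(p, dtype=float) - np.asarray(q, dtype=float)))


def cohort_summary(records: list[SubjectRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject geometry table plus mean ± sample-SD summary.

    Columns: head/brain CoM and AOJ coordinates, their distances to the ACS
    origin, head↔brain CoM separation, AOJ↔head and AOJ↔brain distances,
    head/brain principal moments, and each point's distance to the
    cohort-mean point (``*_scatter_mm``).

    Returns ``(per_subject, summary)`` where summary is indexed by
    ``mean`` / ``sd``.
    """
    if len(records) < 2:
        raise InsufficientDataError("cohort summary needs at least 2 subjects")
    head = np.vstack([r.head.com for r in records])
    brain = np.vstack([r.brain.com for r in records])
    aoj = np.vstack([r.aoj for r in records])
    origin = np.zeros(3)

    rows: dict[str, np.ndarray | list] = {"subject": [r.subject_id for r in records]}
    for tag, pts in (("head", head), ("brain", brain), ("aoj", aoj)):
        rows[f"{tag}_x_mm"], rows[f"{tag}_y_mm"], rows[f"{tag}_z_mm"] = pts.T
        rows[f"{tag}_dist_mm"] = np.linalg.norm(pts - origin, axis=1)
    rows["head_brain_sep_mm"] = np.linalg.norm(head - brain, axis=1)
    rows["aoj_head_dist_mm"] = np.linalg.norm(aoj - head, axis=1)
    rows["aoj_brain_dist_mm"] = np.linalg.norm(aoj - brain, axis=1)
    for tag, pts in (("head", head), ("brain", brain), ("aoj", aoj)):
        rows[f"{tag}_scatter_mm"] = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    for tag in ("head", "brain"):
        moments = np.vstack([getattr(r, tag).principal_moments_kg_cm2 for r in records])
        if np.all(np.isfinite(moments)):
            for k in range(3):
                rows[f"{tag}_i{k + 1}_kg_cm2"] = moments[:, k]

    per_subject = pd.DataFrame(rows)
    numeric = per_subject.drop(columns="subject")
    summary = pd.DataFrame(
        {"mean": numeric.mean(), "sd": numeric.std(ddof=1)}
    ).T  # sample SD, n-1
    return per_subject, summary


def linear_fit(x, y) -> RegressionResult:
    """OLS regression of y on x (e.g. head mass on body mass)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise FitError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise FitError("x is constant; slope undefined")
    if np.ptp(y) == 0:
        # y carries no variance: flat line, nothing explained
        return RegressionResult(
            slope=0.0,
            intercept=float(y[0]),
            r_squared=0.0,
            p_value=1.0,
            slope_stderr=0.0,
            n=len(x),
        )
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        slope_stderr=float(res.stderr),
        n=len(x),
    )
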