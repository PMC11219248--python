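"""Per-knee joint-line measurements.

Five distances characterise the position of the distal-femoral joint line
relative to the epicondyles:

* ``me_fj`` / ``le_fj`` — perpendicular distance, in the axial plane, from
  the medial / lateral epicondylar prominence to the posterior condylar
  line (the joint line in flexion);
* ``me_ej`` / ``le_ej`` — perpendicular distance, in the coronal plane,
  from the same prominences to the distal articular line (the joint line in
  extension);
* ``ml`` — femoral width, the 3-D chord between the two prominences.

Each distance divided by ``ml`` gives a dimensionless ratio; the ratios are
size-invariant and are what transfers between patients.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .frame import DetectedLandmarks, FemoralFrame
from .geometry import (
    GeometryError,
    Line3,
    in_plane_point_line_distance,
    project_point_onto_plane,
)

__all__ = [
    "KneeMeasurement",
    "CoincidentPointsError",
    "posterior_condylar_line",
    "distal_articular_line",
    "measure_knee",
    "measurements_to_dataframe",
    "write_measurements_csv",
    "read_measurements_csv",
]

DISTANCE_NAMES = ("me_fj", "le_fj", "me_ej", "le_ej", "ml")
RATIO_NAMES = ("ratio_me_fj", "ratio_le_fj", "ratio_me_ej", "ratio_le_ej")
CSV_COLUMNS = ("knee_id", "side") + DISTANCE_NAMES[:4] + ("ml",) + RATIO_NAMES


class CoincidentPointsError(GeometryError):
    """Two support points of a joint-line tangent coincide."""


@dataclass(frozen=True)
class KneeMeasurement:
    """All distances (mm) and ratios for one knee."""

    knee_id: str
    side: str
    me_fj: float
    le_fj: float
    me_ej: float
    le_ej: float
    ml: float
    ratio_me_fj: float
    ratio_le_fj: float
    ratio_me_ej: float
    ratio_le_ej: float

    def __post_init__(self):
        if self.ml <= 0:
            raise ValueError("femoral width ml must be positive")
        for name in DISTANCE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"distance {name} must be non-negative")
        for dname, rname in zip(DISTANCE_NAMES[:4], RATIO_NAMES):
            if abs(getattr(self, rname) - getattr(self, dname) / self.ml) > 1e-12:
                raise ValueError(f"{rname} inconsistent with {dname}/ml")

    @classmethod
    def from_distances(
        cls, knee_id: str, side: str, me_fj, le_fj, me_ej, le_ej, ml
    ) -> "KneeMeasurement":
        if float(ml) <= 0:
            raise ValueError("femoral width ml must be positive")
        return cls(
            knee_id=knee_id,
            side=side,
            me_fj=float(me_fj),
            le_fj=float(le_fj),
            me_ej=float(me_ej),
            le_ej=float(le_ej),
            ml=float(ml),
            ratio_me_fj=float(me_fj) / float(ml),
            ratio_le_fj=float(le_fj) / float(ml),
            ratio_me_ej=float(me_ej) / float(ml),
            ratio_le_ej=float(le_ej) / float(ml),
        )

    def distances(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in DISTANCE_NAMES}

    def ratios(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RATIO_NAMES}

    def as_row(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _line_through(p: np.ndarray, q: np.ndarray) -> Line3:
    if np.linalg.norm(q - p) < 1e-9:
        raise CoincidentPointsError("joint-line support points coincide")
    return Line3(p, q - p)


def posterior_condylar_line(lm: DetectedLandmarks, frame: FemoralFrame) -> Line3:
    """Tangent to the posterior condyles in the axial plane (joint line in flexion)."""
    p = project_point_onto_plane(lm.post_medial, frame.axial_plane)
    q = project_point_onto_plane(lm.post_lateral, frame.axial_plane)
    return _line_through(p, q)


def distal_articular_line(lm: DetectedLandmarks, frame: FemoralFrame) -> Line3:
    """Tangent to the distal condyles in the coronal plane (joint line in extension)."""
    p = project_point_onto_plane(lm.dist_medial, frame.coronal_plane)
    q = project_point_onto_plane(lm.dist_lateral, frame.coronal_plane)
    return _line_through(p, q)


def measure_knee(
    lm: DetectedLandmarks, frame: FemoralFrame, knee_id: str = ""
) -> KneeMeasurement:
    """Compute the five distances and four ratios for one knee.

    The flexion-side distances are perpendiculars dropped in the axial plane
    onto the posterior condylar line; the extension-side distances are
    perpendiculars dropped in the coronal plane onto the distal articular
    line; the femoral width is the 3-D chord between the prominences.
    """
    fj = posterior_condylar_line(lm, frame)
    ej = distal_articular_line(lm, frame)
    me_fj = in_plane_point_line_distance(lm.me, fj, frame.axial_plane)
    le_fj = in_plane_point_line_distance(lm.le, fj, frame.axial_plane)
    me_ej = in_plane_point_line_distance(lm.me, ej, frame.coronal_plane)
    le_ej = in_plane_point_line_distance(lm.le, ej, frame.coronal_plane)
    ml = float(np.linalg.norm(lm.me - lm.le))
    return KneeMeasurement.from_distances(
        knee_id, frame.side, me_fj, le_fj, me_ej, le_ej, ml
    )


def measurements_to_dataframe(measurements) -> pd.DataFrame:
    df = pd.DataFrame([m.as_row() for m in measurements])
    return df[list(CSV_COLUMNS)]


def write_measurements_csv(measurements, path) -> None:
    """One row per knee; distances and ratios written with 3 decimals."""
    df = measurements_to_dataframe(measurements)
    df.to_csv(path, index=False, float_format="%.3f")


def read_measurements_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV missing columns: {sorted(missing)}")
    return df


def measurements_from_dataframe(df: pd.DataFrame) -> list[KneeMeasurement]:
    return [
        KneeMeasurement.from_distances(
            str(r.knee_id), r.side, r.me_fj, r.le_fj, r.me_ej, r.le_ej, r.ml
        )
        for r in df.itertuples()
    ]
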