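"""Exact 3-D primitives for anatomical constructions.

Points and directions are plain ``float64`` numpy arrays of shape ``(3,)``;
lengths are millimetres and angles are degrees at every public interface
(converted to radians internally, once).  The tolerance policy is absolute:
1e-9 for normalised quantities (unit norms, dot products), 1e-6 mm for
lengths — mm-scale anatomy in double precision leaves ample headroom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

TOL_UNIT = 1e-9
TOL_MM = 1e-6

__all__ = [
    "GeometryError",
    "DegenerateLineError",
    "ParallelDirectionsError",
    "Line3",
    "Plane3",
    "RigidTransform",
    "as_point",
    "unit",
    "project_point_onto_plane",
    "project_point_onto_line",
    "in_plane_point_line_distance",
    "rotate_direction",
    "plane_from_two_directions",
    "angle_between_deg",
]


class GeometryError(ValueError):
    """A geometric precondition was violated."""


class DegenerateLineError(GeometryError):
    """A line collapsed to (numerically) zero length under projection."""


class ParallelDirectionsError(GeometryError):
    """Two directions meant to span a plane are parallel."""


def as_point(p) -> np.ndarray:
    """Coerce to a finite float64 3-vector."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise GeometryError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise GeometryError(f"non-finite coordinates: {a}")
    return a


def unit(v) -> np.ndarray:
    """Normalise ``v`` to unit Euclidean length."""
    a = as_point(v)
    n = np.linalg.norm(a)
    if n < TOL_UNIT:
        raise DegenerateLineError("cannot normalise a (near-)zero vector")
    return a / n


@dataclass(frozen=True, eq=False)
class Line3:
    """A line through ``origin`` with unit ``direction``."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", as_point(self.origin))
        object.__setattr__(self, "direction", unit(self.direction))

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


@dataclass(frozen=True, eq=False)
class Plane3:
    """A plane through ``point`` with unit ``normal``."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", as_point(self.point))
        object.__setattr__(self, "normal", unit(self.normal))

    def signed_distance(self, p) -> float:
        return float(np.dot(as_point(p) - self.point, self.normal))


@dataclass(frozen=True, eq=False)
class RigidTransform:
    """A proper rigid motion ``x -> R x + t`` (det R = +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = as_point(self.translation)
        if r.shape != (3, 3):
            raise GeometryError("rotation must be 3x3")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise GeometryError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-9:
            raise GeometryError("rotation determinant must be +1 (no reflection)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def random(cls, rng: np.random.Generator, max_translation: float = 100.0) -> "RigidTransform":
        r = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-max_translation, max_translation, size=3)
        return cls(r, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform one point or an (n, 3) array of points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def apply_direction(self, d: np.ndarray) -> np.ndarray:
        return np.asarray(d, dtype=float) @ self.rotation.T

    def apply_line(self, l: Line3) -> Line3:
        return Line3(self.apply(l.origin), self.apply_direction(l.direction))

    def apply_plane(self, pl: Plane3) -> Plane3:
        return Plane3(self.apply(pl.point), self.apply_direction(pl.normal))

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


def project_point_onto_plane(p, pl: Plane3) -> np.ndarray:
    p = as_point(p)
    return p - pl.signed_distance(p) * pl.normal


def project_point_onto_line(p, l: Line3) -> np.ndarray:
    p = as_point(p)
    return l.origin + np.dot(p - l.origin, l.direction) * l.direction


def _project_line_onto_plane(l: Line3, pl: Plane3) -> Line3:
    o = project_point_onto_plane(l.origin, pl)
    d = l.direction - np.dot(l.direction, pl.normal) * pl.normal
    if np.linalg.norm(d) < TOL_UNIT:
        raise DegenerateLineError(
            "line is perpendicular to the plane; its projection is a point"
        )
    return Line3(o, d)


def in_plane_point_line_distance(p, l: Line3, pl: Plane3) -> float:
    """Perpendicular distance from ``p`` to ``l`` after projecting both into ``pl``.

    This is the measurement primitive behind the epicondyle-to-joint-line
    distances: a perpendicular dropped from a landmark to a condylar tangent
    line, evaluated within a named anatomical plane.
    """
    p2 = project_point_onto_plane(p, pl)
    l2 = _project_line_onto_plane(l, pl)
    r = p2 - l2.origin
    r_perp = r - np.dot(r, l2.direction) * l2.direction
    return float(np.linalg.norm(r_perp))


def rotate_direction(v, axis, angle_deg: float) -> np.ndarray:
    """Rotate direction ``v`` about ``axis`` by ``angle_deg`` (right-hand rule)."""
    axis = unit(axis)
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis)
    return unit(rot.apply(as_point(v)))


def plane_from_two_directions(p, d1, d2) -> Plane3:
    """Plane through ``p`` spanned by directions ``d1`` and ``d2``."""
    d1 = unit(d1)
    d2 = unit(d2)
    n = np.cross(d1, d2)
    if np.linalg.norm(n) <= 1e-6:
        raise ParallelDirectionsError("directions are parallel; plane is underdetermined")
    return Plane3(p, n)


def angle_between_deg(u, v) -> float:
    """Unsigned angle between two directions, in degrees."""
    u = unit(u)
    v = unit(v)
    return float(np.rad2deg(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v))))
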