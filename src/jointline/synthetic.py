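"""Synthetic distal femora with analytic ground truth.

Two fidelity levels stand in for CT-derived anatomy:

* **Landmark level** (:func:`build_landmarks`): exact landmark positions in
  a canonical frame, constructed so that measuring them reproduces the
  generating :class:`FemurSpec` distances to machine precision.  This is the
  oracle for everything downstream.
* **Mesh level** (:func:`build_mesh`): a triangle surface — shaft cylinder,
  two condylar ellipsoids whose posterior-most / distal-most points realise
  the joint-line offsets, and two epicondylar protrusions whose apices
  realise the femoral width — with optional Gaussian vertex jitter.  The
  nearest primitive vertex is snapped onto each exact landmark so that the
  noise-free surface carries the ground-truth extremes.

Cohorts are sampled from a single-factor model: each epicondyle-to-joint-
line distance depends linearly on the femoral width ML plus an independent
normal residual, with the slope and residual variance solved so that every
marginal mean, marginal SD and distance-vs-ML correlation matches the
configuration.  The configuration defaults are the study cohort of 127
osteoarthritic knees (ML 75.1 +- 4.2 mm, ME-FJ 29.4 +- 2.2 mm, LE-FJ
21.2 +- 2.3 mm, ME-EJ 25.1 +- 2.8 mm, LE-EJ 21.3 +- 2.5 mm; correlations
with ML 0.623 / 0.396 / 0.393 / 0.445).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .frame import DetectedLandmarks, FemoralFrame, FrameConfig
from .geometry import Line3, Plane3, RigidTransform, rotate_direction, unit
from .measure import KneeMeasurement, measure_knee

__all__ = [
    "FemurSpec",
    "GroundTruth",
    "CohortConfig",
    "FemurMesh",
    "InfeasibleConfigError",
    "ResolutionError",
    "ConstructionError",
    "sample_cohort_specs",
    "build_landmarks",
    "build_mesh",
    "apply_random_pose",
    "specs_to_dataframe",
    "specs_from_dataframe",
]

# canonical-frame anatomy constants (mm unless noted); chosen once to give a
# plausible distal femur, see docs/methods.md
_CONDYLE_X_FRAC = 0.25        # condyle centre at +-25% of ML from the midline
_CONDYLE_CENTER_AP = -8.0     # anteroposterior centre of the condylar ellipsoids
_CONDYLE_CENTER_AX = -10.0    # axial centre of the condylar ellipsoids
_EPICONDYLE_RADIUS = 6.0      # radius of the epicondylar protrusion spheres
_SHAFT_BASE_AX = -5.0         # shaft starts slightly below the epicondylar level


class InfeasibleConfigError(ValueError):
    """Cohort configuration implies a negative residual variance."""


class ResolutionError(ValueError):
    """Requested mesh resolution is too coarse for reliable detection."""


class ConstructionError(ValueError):
    """Spec distances cannot be realised as a valid femur geometry."""


@dataclass(frozen=True)
class FemurSpec:
    """Generating parameters of one synthetic femur (lengths in mm)."""

    ml: float
    me_fj: float
    le_fj: float
    me_ej: float
    le_ej: float
    side: str = "right"
    shaft_length: float = 200.0
    shaft_radius: float = 16.0
    condyle_radii: tuple[float, float] = (12.0, 12.0)
    surface_noise_sd: float = 0.0
    mesh_resolution: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        for name in ("ml", "me_fj", "le_fj", "me_ej", "le_ej",
                     "shaft_length", "shaft_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ml <= self.me_fj:
            raise ValueError("ml must exceed me_fj (epicondyles lie between condyles)")
        if self.surface_noise_sd < 0:
            raise ValueError("surface_noise_sd must be >= 0")

    def distances(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in ("me_fj", "le_fj", "me_ej", "le_ej", "ml")}


@dataclass(frozen=True, eq=False)
class GroundTruth:
    """Exact landmarks, frame and measurement of one synthetic femur."""

    landmarks: DetectedLandmarks
    true_frame: FemoralFrame
    true_measurement: KneeMeasurement

    def transformed(self, t: RigidTransform) -> "GroundTruth":
        frame = self.true_frame
        return GroundTruth(
            landmarks=self.landmarks.transformed(t),
            true_frame=FemoralFrame(
                anatomical_axis=t.apply_line(frame.anatomical_axis),
                mechanical_axis=t.apply_line(frame.mechanical_axis),
                axial_plane=t.apply_plane(frame.axial_plane),
                coronal_plane=t.apply_plane(frame.coronal_plane),
                c_tea=t.apply_line(frame.c_tea),
                side=frame.side,
            ),
            true_measurement=self.true_measurement,
        )


@dataclass(frozen=True)
class CohortConfig:
    """Moments of the measurement distribution a cohort is sampled from.

    Each of the four epicondyle-to-joint-line distances is specified by its
    marginal ``(mean, sd)`` and its Pearson correlation with ML.
    """

    n: int = 127
    ml: tuple[float, float] = (75.1, 4.2)
    me_fj: tuple[float, float] = (29.4, 2.2)
    le_fj: tuple[float, float] = (21.2, 2.3)
    me_ej: tuple[float, float] = (25.1, 2.8)
    le_ej: tuple[float, float] = (21.3, 2.5)
    corr_with_ml: dict = field(
        default_factory=lambda: {
            "me_fj": 0.623,
            "le_fj": 0.396,
            "me_ej": 0.393,
            "le_ej": 0.445,
        }
    )
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("cohort size n must be >= 2")
        for name in ("ml", "me_fj", "le_fj", "me_ej", "le_ej"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{name}: mean must be > 0 and sd >= 0")
        for k, rho in self.corr_with_ml.items():
            if abs(rho) > 1:
                raise ValueError(f"|corr({k}, ml)| must be <= 1")

    @classmethod
    def study_defaults(cls, n: int = 127, seed: int = 0) -> "CohortConfig":
        return cls(n=n, seed=seed)

    def ratio_means(self) -> dict[str, float]:
        """Configured ratio means (ratio of marginal means)."""
        ml_mean = self.ml[0]
        return {
            f"ratio_{k}": getattr(self, k)[0] / ml_mean
            for k in ("me_fj", "le_fj", "me_ej", "le_ej")
        }


@dataclass(frozen=True, eq=False)
class FemurMesh:
    """A triangle surface in mm; not necessarily watertight."""

    vertices: np.ndarray
    faces: np.ndarray
    side: str

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be (m, 3) index triples")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def save(self, path) -> None:
        """Write STL (binary) or ASCII PLY, chosen by extension."""
        path = Path(path)
        mesh = self.to_trimesh()
        if path.suffix.lower() == ".ply":
            path.write_bytes(mesh.export(file_type="ply", encoding="ascii"))
        else:
            mesh.export(path)

    @classmethod
    def load(cls, path, side: str) -> "FemurMesh":
        mesh = trimesh.load_mesh(str(path), process=False)
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), side)


def sample_cohort_specs(config: CohortConfig) -> list[FemurSpec]:
    """Draw a cohort of femur specs from the single-factor model.

    ``ML ~ N(mu_ML, sd_ML)``; each distance ``D = mu_D + b (ML - mu_ML) + e``
    with ``b = rho sd_D / sd_ML`` and ``e ~ N(0, sd_D sqrt(1 - rho^2))``, so
    the marginal mean, marginal SD and corr(D, ML) all match the config.
    Draws violating positivity or ``ML > ME-FJ`` are resampled.  Fully
    deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=config.n)
    sides = rng.choice(["right", "left"], size=config.n)

    names = ("me_fj", "le_fj", "me_ej", "le_ej")
    ml_mean, ml_sd = config.ml
    slopes, resid_sds = {}, {}
    for name in names:
        d_mean, d_sd = getattr(config, name)
        rho = float(config.corr_with_ml.get(name, 0.0))
        if rho != 0.0 and (ml_sd == 0.0 or d_sd == 0.0):
            raise InfeasibleConfigError(
                f"corr({name}, ml) = {rho} is unachievable with zero variance"
            )
        resid_var = d_sd**2 * (1.0 - rho**2)
        if resid_var < 0:  # |rho| <= 1 already enforced; guard for safety
            raise InfeasibleConfigError(f"negative residual variance for {name}")
        slopes[name] = rho * d_sd / ml_sd if ml_sd > 0 else 0.0
        resid_sds[name] = float(np.sqrt(resid_var))

    specs: list[FemurSpec] = []
    for i in range(config.n):
        for _attempt in range(1000):
            ml = rng.normal(ml_mean, ml_sd)
            d = {
                name: getattr(config, name)[0]
                + slopes[name] * (ml - ml_mean)
                + rng.normal(0.0, resid_sds[name])
                for name in names
            }
            if ml > 0 and all(v > 0 for v in d.values()) and ml > d["me_fj"]:
                break
        else:  # pragma: no cover - astronomically unlikely for sane configs
            raise InfeasibleConfigError("could not draw a geometrically valid spec")
        specs.append(
            FemurSpec(ml=float(ml), side=str(sides[i]), seed=int(seeds[i]), **d)
        )
    return specs


def _canonical_axes(side: str):
    m = 1.0 if side == "right" else -1.0
    medial = np.array([m, 0.0, 0.0])
    anterior = np.array([0.0, 1.0, 0.0])
    proximal = np.array([0.0, 0.0, 1.0])
    return m, medial, anterior, proximal


def _tangent_line_coords(spec: FemurSpec, m: float):
    """In-plane line parameters realising the paired perpendicular distances.

    For epicondyles at (+-ML/2, 0) and a tangent line with unit normal
    ``(m sin t, cos t)`` at signed offset ``c``, the perpendicular distances
    are ``|w sin t - c|`` and ``|-w sin t - c|``; solving for the medial and
    lateral targets gives ``sin t = (d_med - d_lat)/ML``,
    ``c = -(d_med + d_lat)/2``.
    """
    sin_fj = (spec.me_fj - spec.le_fj) / spec.ml
    sin_ej = (spec.me_ej - spec.le_ej) / spec.ml
    if abs(sin_fj) >= 1 or abs(sin_ej) >= 1:
        raise ConstructionError("distance asymmetry exceeds femoral width")
    c_fj = -(spec.me_fj + spec.le_fj) / 2.0
    c_ej = -(spec.me_ej + spec.le_ej) / 2.0

    def y_fj(x):
        return (c_fj - m * sin_fj * x) / np.sqrt(1 - sin_fj**2)

    def z_ej(x):
        return (c_ej - m * sin_ej * x) / np.sqrt(1 - sin_ej**2)

    return y_fj, z_ej


def build_landmarks(
    spec: FemurSpec, frame_cfg: FrameConfig | None = None
) -> tuple[DetectedLandmarks, GroundTruth]:
    """Place exact landmarks in the canonical frame.

    Canonical frame: mechanical axis = +z (proximal), transepicondylar
    direction = x (medial = +x on the right, -x on the left), posterior =
    -y.  The epicondylar prominences sit at ``(+-ML/2, 0, 0)``; the
    posterior and distal condylar support points lie on tangent lines tilted
    so that the perpendicular distances from the prominences equal the spec
    exactly.  Measuring the returned landmarks in the returned frame
    round-trips the spec to machine precision.
    """
    cfg = frame_cfg or FrameConfig()
    m, medial, anterior, proximal = _canonical_axes(spec.side)
    w = spec.ml / 2.0
    me = np.array([m * w, 0.0, 0.0])
    le = np.array([-m * w, 0.0, 0.0])

    y_fj, z_ej = _tangent_line_coords(spec, m)
    x_med = m * _CONDYLE_X_FRAC * spec.ml
    x_lat = -m * _CONDYLE_X_FRAC * spec.ml

    landmarks = DetectedLandmarks(
        me=me,
        le=le,
        post_medial=np.array([x_med, y_fj(x_med), _CONDYLE_CENTER_AX]),
        post_lateral=np.array([x_lat, y_fj(x_lat), _CONDYLE_CENTER_AX]),
        dist_medial=np.array([x_med, _CONDYLE_CENTER_AP, z_ej(x_med)]),
        dist_lateral=np.array([x_lat, _CONDYLE_CENTER_AP, z_ej(x_lat)]),
    )

    anat_dir = rotate_direction(proximal, anterior, -m * cfg.valgus_angle)
    frame = FemoralFrame(
        anatomical_axis=Line3(np.zeros(3), anat_dir),
        mechanical_axis=Line3(np.zeros(3), proximal),
        axial_plane=Plane3(np.zeros(3), proximal),
        coronal_plane=Plane3(me, np.cross(medial, proximal)),
        c_tea=Line3(me, medial),
        side=spec.side,
    )
    truth = GroundTruth(
        landmarks=landmarks,
        true_frame=frame,
        true_measurement=measure_knee(landmarks, frame, knee_id=f"seed{spec.seed}"),
    )
    return landmarks, truth


def _icosphere(center, radii, resolution: float) -> tuple[np.ndarray, np.ndarray]:
    r_max = float(np.max(radii))
    subdiv = int(np.clip(np.ceil(np.log2(1.05 * r_max / resolution)), 2, 6))
    ico = trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)
    v = np.asarray(ico.vertices) * np.asarray(radii, dtype=float) + np.asarray(center)
    return v, np.asarray(ico.faces, dtype=np.int64)


def _shaft_tube(origin, direction, length, radius, resolution) -> tuple[np.ndarray, np.ndarray]:
    """Open cylinder with vertex rings along its full length.

    Rings every ~``resolution`` mm are required because the anatomical-axis
    slices sample surface vertices at arbitrary shaft levels.
    """
    direction = unit(direction)
    n_rings = max(int(np.ceil(length / resolution)) + 1, 2)
    n_sect = max(int(np.ceil(2 * np.pi * radius / resolution)), 12)
    # orthonormal frame around the shaft axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, direction)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = unit(np.cross(direction, helper))
    w = np.cross(direction, u)
    t = np.linspace(0.0, length, n_rings)
    ang = np.linspace(0.0, 2 * np.pi, n_sect, endpoint=False)
    circ = radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), w))
    v = (np.asarray(origin) + t[:, None, None] * direction + circ[None, :, :]).reshape(-1, 3)
    faces = []
    for i in range(n_rings - 1):
        for j in range(n_sect):
            a = i * n_sect + j
            b = i * n_sect + (j + 1) % n_sect
            c = a + n_sect
            d = b + n_sect
            faces.append((a, b, d))
            faces.append((a, d, c))
    return v, np.asarray(faces, dtype=np.int64)


def _snap_nearest(vertices: np.ndarray, start: int, stop: int, target: np.ndarray) -> None:
    block = vertices[start:stop]
    idx = int(np.argmin(np.linalg.norm(block - target, axis=1)))
    vertices[start + idx] = target


def build_mesh(
    spec: FemurSpec, frame_cfg: FrameConfig | None = None
) -> tuple[FemurMesh, GroundTruth]:
    """Assemble the parametric surface in the canonical frame.

    The surface is the union (as overlapping shells; watertightness is not
    required by any detection) of a shaft tube along the anatomical axis,
    two condylar ellipsoids and two epicondylar spheres.  Ellipsoid centres
    and semi-axes are solved so the surface extremes realise the exact
    landmark positions; the nearest vertex of each primitive is then snapped
    onto its landmark, making the noise-free argmax detections exact.
    Gaussian jitter of ``surface_noise_sd`` is applied to all vertices
    afterwards; :class:`GroundTruth` records the pre-noise landmarks.
    """
    if spec.mesh_resolution > 3.0:
        raise ResolutionError("mesh_resolution must be <= 3 mm")
    cfg = frame_cfg or FrameConfig()
    landmarks, truth = build_landmarks(spec, cfg)
    m, _, _, _ = _canonical_axes(spec.side)
    res = spec.mesh_resolution

    parts: list[tuple[np.ndarray, np.ndarray]] = []

    # condylar ellipsoids: centre shares x with both landmark support points,
    # y with the distal point, z with the posterior point, so the -y / -z
    # surface extremes are exactly the landmarks
    for label, post, dist, radius in (
        ("medial", landmarks.post_medial, landmarks.dist_medial, spec.condyle_radii[0]),
        ("lateral", landmarks.post_lateral, landmarks.dist_lateral, spec.condyle_radii[1]),
    ):
        center = np.array([post[0], dist[1], post[2]])
        ay = center[1] - post[1]
        az = center[2] - dist[2]
        if ay <= 0 or az <= 0:
            raise ConstructionError(
                f"{label} condyle semi-axes are non-positive; spec distances "
                "are incompatible with the canonical condyle centres"
            )
        v, f = _icosphere(center, (radius, ay, az), res)
        parts.append((v, f))

    # epicondylar protrusion spheres with apices at the prominences
    for apex, sign in ((landmarks.me, m), (landmarks.le, -m)):
        center = apex - np.array([sign * _EPICONDYLE_RADIUS, 0.0, 0.0])
        v, f = _icosphere(center, (_EPICONDYLE_RADIUS,) * 3, res)
        parts.append((v, f))

    # shaft along the anatomical axis
    anat = truth.true_frame.anatomical_axis
    base = anat.point_at(_SHAFT_BASE_AX)
    v, f = _shaft_tube(base, anat.direction, spec.shaft_length, spec.shaft_radius, res)
    parts.append((v, f))

    offsets = np.cumsum([0] + [p[0].shape[0] for p in parts])
    vertices = np.vstack([p[0] for p in parts])
    faces = np.vstack([p[1] + off for p, off in zip(parts, offsets[:-1])])

    # snap the nearest primitive vertex onto each exact landmark
    snaps = [
        (0, landmarks.post_medial), (0, landmarks.dist_medial),
        (1, landmarks.post_lateral), (1, landmarks.dist_lateral),
        (2, landmarks.me), (3, landmarks.le),
    ]
    for part_idx, target in snaps:
        _snap_nearest(vertices, offsets[part_idx], offsets[part_idx + 1], target)

    if spec.surface_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vertices = vertices + rng.normal(0.0, spec.surface_noise_sd, vertices.shape)

    mesh = FemurMesh(vertices, faces, spec.side)
    if mesh.n_vertices < 500:
        raise ResolutionError("mesh has fewer than 500 vertices; refine resolution")
    return mesh, truth


def apply_random_pose(
    mesh: FemurMesh, seed: int | None = None, max_translation: float = 100.0
) -> tuple[FemurMesh, RigidTransform]:
    """Rigidly repose a mesh; ``seed=None`` is the identity convention."""
    if seed is None:
        t = RigidTransform.identity()
    else:
        t = RigidTransform.random(np.random.default_rng(seed), max_translation)
    return FemurMesh(t.apply(mesh.vertices), mesh.faces, mesh.side), t


_SPEC_CSV_COLUMNS = ("ml", "me_fj", "le_fj", "me_ej", "le_ej", "side", "seed")


def specs_to_dataframe(specs) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(s, c) for c in _SPEC_CSV_COLUMNS} for s in specs]
    )


def specs_from_dataframe(df: pd.DataFrame, **overrides) -> list[FemurSpec]:
    return [
        replace(
            FemurSpec(
                ml=r.ml, me_fj=r.me_fj, le_fj=r.le_fj, me_ej=r.me_ej,
                le_ej=r.le_ej, side=r.side, seed=int(r.seed),
            ),
            **overrides,
        )
        for r in df.itertuples()
    ]
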