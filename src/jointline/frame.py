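"""Measurement-frame construction for the distal femur.

Reconstructs, from a bone-surface vertex cloud, the reference objects the
morphometry is defined in:

* the femoral **anatomical axis** — the line through the midpoints of the
  femoral width at two shaft levels (default 100 mm and 150 mm) proximal to
  the distal joint line;
* the femoral **mechanical axis** — the anatomical axis rotated by a fixed
  valgus angle (default 6°) within the working coronal plane, distal end
  tilting away from the midline;
* the **axial plane** (perpendicular to the mechanical axis) and the
  **coronal plane** (spanned by the clinical transepicondylar axis and the
  mechanical-axis direction, through the epicondyles);
* the landmark detections these require: the medial/lateral epicondylar
  prominences and the posterior-most / distal-most condylar surface points.

The definitions are mutually recursive — the anatomical axis is measured
relative to the distal joint line, which itself needs the mechanical axis —
so :func:`build_frame` resolves them by fixed-point iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    GeometryError,
    Line3,
    Plane3,
    plane_from_two_directions,
    rotate_direction,
    unit,
)

__all__ = [
    "FrameConfig",
    "FemoralFrame",
    "DetectedLandmarks",
    "DegenerateMeshError",
    "EmptySliceError",
    "EmptyBandError",
    "FrameConvergenceError",
    "estimate_initial_long_axis",
    "compute_anatomical_axis",
    "compute_mechanical_axis",
    "detect_epicondyles",
    "detect_condylar_extremes",
    "build_frame",
]

_SIDES = ("left", "right")


class DegenerateMeshError(GeometryError):
    """Vertex cloud has no usable long axis (near-spherical)."""


class EmptySliceError(GeometryError):
    """A shaft slice used for the anatomical axis contains no vertices."""


class EmptyBandError(GeometryError):
    """The epicondylar search band (or a condyle half) contains no vertices."""


class FrameConvergenceError(GeometryError):
    """Frame iteration failed to converge; message carries last displacement."""


@dataclass(frozen=True)
class FrameConfig:
    """Parameters of the frame construction.

    valgus_angle
        Fixed angle between anatomical and mechanical axis, degrees.
    shaft_levels
        Heights (mm, proximal to the distal joint line) of the two shaft
        cross-sections whose width midpoints define the anatomical axis.
    epicondylar_band
        Half-width (mm) of the axial band, centred on the condylar mass, in
        which the epicondylar prominences are searched.
    convergence_tol
        Maximum landmark displacement (mm) between iterations at which the
        fixed-point iteration is declared converged.
    """

    valgus_angle: float = 6.0
    shaft_levels: tuple[float, float] = (100.0, 150.0)
    epicondylar_band: float = 20.0
    convergence_tol: float = 0.1
    max_iterations: int = 25
    slice_halfwidth: float = 2.0
    condylar_region_height: float = 35.0
    refine_landmarks: bool = True
    refine_radius: float = 4.0

    def __post_init__(self):
        lo, hi = self.shaft_levels
        if not (hi > lo > 0):
            raise ValueError("shaft_levels must satisfy 0 < lower < upper")
        if self.valgus_angle < 0:
            raise ValueError("valgus_angle must be >= 0")
        if self.convergence_tol <= 0 or self.max_iterations < 1:
            raise ValueError("invalid convergence settings")


@dataclass(frozen=True, eq=False)
class FemoralFrame:
    """The converged measurement frame for one femur."""

    anatomical_axis: Line3
    mechanical_axis: Line3
    axial_plane: Plane3
    coronal_plane: Plane3
    c_tea: Line3  # through both epicondyles, direction points medial
    side: str

    def __post_init__(self):
        if self.side not in _SIDES:
            raise ValueError(f"side must be one of {_SIDES}")

    @property
    def proximal_dir(self) -> np.ndarray:
        return self.mechanical_axis.direction

    @property
    def medial_dir(self) -> np.ndarray:
        return self.c_tea.direction

    @property
    def anterior_dir(self) -> np.ndarray:
        s = 1.0 if self.side == "right" else -1.0
        return unit(s * np.cross(self.proximal_dir, self.medial_dir))

    def to_dict(self) -> dict:
        def line(l):
            return {"origin": l.origin.tolist(), "direction": l.direction.tolist()}

        def plane(p):
            return {"point": p.point.tolist(), "normal": p.normal.tolist()}

        return {
            "side": self.side,
            "anatomical_axis": line(self.anatomical_axis),
            "mechanical_axis": line(self.mechanical_axis),
            "axial_plane": plane(self.axial_plane),
            "coronal_plane": plane(self.coronal_plane),
            "c_tea": line(self.c_tea),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FemoralFrame":
        def line(j):
            return Line3(np.array(j["origin"]), np.array(j["direction"]))

        def plane(j):
            return Plane3(np.array(j["point"]), np.array(j["normal"]))

        return cls(
            anatomical_axis=line(d["anatomical_axis"]),
            mechanical_axis=line(d["mechanical_axis"]),
            axial_plane=plane(d["axial_plane"]),
            coronal_plane=plane(d["coronal_plane"]),
            c_tea=line(d["c_tea"]),
            side=d["side"],
        )


@dataclass(frozen=True, eq=False)
class DetectedLandmarks:
    """Surface landmarks of one distal femur (mm, any world frame)."""

    me: np.ndarray
    le: np.ndarray
    post_medial: np.ndarray
    post_lateral: np.ndarray
    dist_medial: np.ndarray
    dist_lateral: np.ndarray

    _NAMES = ("me", "le", "post_medial", "post_lateral", "dist_medial", "dist_lateral")

    def __post_init__(self):
        for name in self._NAMES:
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self._NAMES}

    def to_json_dict(self) -> dict:
        return {name: getattr(self, name).tolist() for name in self._NAMES}

    @classmethod
    def from_json_dict(cls, d: dict) -> "DetectedLandmarks":
        return cls(**{name: np.array(d[name]) for name in cls._NAMES})

    def transformed(self, t) -> "DetectedLandmarks":
        return DetectedLandmarks(**{n: t.apply(p) for n, p in self.as_dict().items()})

    def max_displacement(self, other: "DetectedLandmarks") -> float:
        return max(
            float(np.linalg.norm(getattr(self, n) - getattr(other, n)))
            for n in self._NAMES
        )


def _vertices(mesh) -> np.ndarray:
    v = np.asarray(getattr(mesh, "vertices", mesh), dtype=float)
    if v.ndim != 2 or v.shape[1] != 3:
        raise GeometryError("expected an (n, 3) vertex array")
    return v


def estimate_initial_long_axis(mesh) -> Line3:
    """Principal axis of the vertex cloud, oriented to point proximally.

    The distal femur flares into the condylar mass, so the end of the cloud
    with the wider perpendicular cross-section is taken as distal and the
    returned direction points away from it.
    """
    v = _vertices(mesh)
    centroid = v.mean(axis=0)
    cov = np.cov((v - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] < 4.0 * evals[-2]:
        raise DegenerateMeshError("vertex cloud has no dominant long axis")
    d = evecs[:, -1]
    t = (v - centroid) @ d
    lo, hi = np.quantile(t, [0.2, 0.8])
    perp = (v - centroid) - np.outer(t, d)
    perp_norm = np.linalg.norm(perp, axis=1)
    # the condylar end reaches ~half the femoral width off-axis, the shaft
    # only its radius: compare near-maximal radial extents of the two ends
    spread_low = np.quantile(perp_norm[t < lo], 0.98)
    spread_high = np.quantile(perp_norm[t > hi], 0.98)
    if spread_high > spread_low:  # wide (condylar) end must sit at low t (distal)
        d = -d
    return Line3(centroid, d)


def _refine_ridge_1d(
    slab: np.ndarray, p0: np.ndarray, direction: np.ndarray, t_dir: np.ndarray,
    radius: float,
) -> np.ndarray:
    """1-D quadratic refinement of a slice extreme.

    The medial/lateral extreme of a shaft slice lies on a ridge running
    along the shaft, so the paraboloid fit of :func:`_refine_extreme` is
    singular there; instead the extreme is refined along the slice ring
    only: fit ``h = a + b t + c t^2`` (``h`` along the extreme direction,
    ``t`` in-slice perpendicular) and take the apex.
    """
    rel = slab - p0
    t = rel @ t_dir
    h = rel @ direction
    # keep the near-apex patch only: the far side of the shaft has similar
    # in-slice offsets but sits a diameter lower along the extreme direction
    keep = (np.abs(t) <= radius) & (h >= -radius)
    if keep.sum() < 8:
        return p0
    tt, hh = t[keep], h[keep]
    c2, c1, c0 = np.polyfit(tt, hh, 2)
    if c2 > -1e-4:
        return p0
    t_star = -c1 / (2.0 * c2)
    if abs(t_star) > radius:
        return p0
    h_star = c0 + c1 * t_star + c2 * t_star**2
    return p0 + t_star * t_dir + h_star * direction


def _slice_midpoint(
    v: np.ndarray,
    jl_point: np.ndarray,
    proximal: np.ndarray,
    medial: np.ndarray,
    level: float,
    halfwidth: float,
    refine_radius: float = 0.0,
) -> np.ndarray:
    a = (v - jl_point) @ proximal
    mask = np.abs(a - level) <= halfwidth
    if not mask.any():
        raise EmptySliceError(f"no vertices in shaft slice at level {level} mm")
    sl = v[mask]
    m = sl @ medial
    p_med, p_lat = sl[np.argmax(m)], sl[np.argmin(m)]
    if refine_radius > 0:
        t_dir = unit(np.cross(proximal, medial))
        p_med = _refine_ridge_1d(sl, p_med, medial, t_dir, refine_radius)
        p_lat = _refine_ridge_1d(sl, p_lat, -medial, t_dir, refine_radius)
    return 0.5 * (p_med + p_lat)


def compute_anatomical_axis(mesh, jl_point, proximal, medial, cfg: FrameConfig) -> Line3:
    """Line through the femoral-width midpoints at the two shaft levels.

    Each midpoint is the mean of the most medial and most lateral surface
    points of a slice (default thickness +-2 mm) cut perpendicular to the
    current working axis, ``shaft_levels`` mm proximal to the distal joint
    line at ``jl_point``.
    """
    v = _vertices(mesh)
    proximal = unit(proximal)
    medial = unit(medial)
    rr = cfg.refine_radius if cfg.refine_landmarks else 0.0
    mid_lo = _slice_midpoint(v, jl_point, proximal, medial,
                             cfg.shaft_levels[0], cfg.slice_halfwidth, rr)
    mid_hi = _slice_midpoint(v, jl_point, proximal, medial,
                             cfg.shaft_levels[1], cfg.slice_halfwidth, rr)
    d = mid_hi - mid_lo
    if np.linalg.norm(d) < 1e-9:
        raise EmptySliceError("shaft-level midpoints coincide")
    return Line3(mid_lo, d)


def compute_mechanical_axis(
    anat: Line3, side: str, cfg: FrameConfig, coronal_normal, medial
) -> Line3:
    """Rotate the anatomical axis by the valgus angle within the coronal plane.

    The rotation is about the coronal-plane normal (the anteroposterior
    direction) and its sense is chosen so that the proximal end of the axis
    tilts toward the medial side — the mechanical axis runs from the knee
    centre up-and-medially to the femoral head.  The returned line passes
    through the distal anatomical-axis point.
    """
    if side not in _SIDES:
        raise ValueError(f"side must be one of {_SIDES}")
    if cfg.valgus_angle == 0:
        return Line3(anat.origin, anat.direction)
    medial = unit(medial)
    # orthogonalise the rotation axis against the anatomical direction so the
    # resulting angle equals the valgus angle exactly
    n = unit(coronal_normal)
    n = unit(n - np.dot(n, anat.direction) * anat.direction)
    d_plus = rotate_direction(anat.direction, n, cfg.valgus_angle)
    d_minus = rotate_direction(anat.direction, n, -cfg.valgus_angle)
    d = d_plus if np.dot(d_plus, medial) > np.dot(d_minus, medial) else d_minus
    return Line3(anat.origin, d)


def _condylar_band_center(v: np.ndarray, jl_coord: float, axial: np.ndarray, cfg: FrameConfig) -> float:
    a = v @ axial
    region = a[(a >= jl_coord) & (a <= jl_coord + cfg.condylar_region_height)]
    if region.size == 0:
        raise EmptyBandError("no vertices in the condylar region")
    return float(region.mean())


def _extreme_in_band(
    v: np.ndarray,
    direction: np.ndarray,
    axial: np.ndarray,
    band_center: float,
    band_halfwidth: float,
) -> np.ndarray:
    a = v @ axial
    mask = np.abs(a - band_center) <= band_halfwidth
    if not mask.any():
        raise EmptyBandError("epicondylar search band contains no vertices")
    band = v[mask]
    coord = band @ direction
    best = coord.max()
    tied = np.flatnonzero(coord >= best - 1e-9)
    if tied.size > 1:  # tie-break: prefer the vertex closest to the band midline
        axial_off = np.abs(band[tied] @ axial - band_center)
        tied = tied[np.argsort(axial_off, kind="stable")]
    return band[tied[0]]


def _fit_apex_once(v: np.ndarray, p0: np.ndarray, d: np.ndarray, e1, e2, radius: float):
    rel = v - p0
    patch = rel[np.linalg.norm(rel, axis=1) <= radius]
    if patch.shape[0] < 12:
        return None
    t1, t2, h = patch @ e1, patch @ e2, patch @ d
    design = np.column_stack([np.ones_like(t1), t1, t2, t1**2, t1 * t2, t2**2])
    coef, *_ = np.linalg.lstsq(design, h, rcond=None)
    a, b1, b2, c11, c12, c22 = coef
    hess = np.array([[2 * c11, c12], [c12, 2 * c22]])
    if np.linalg.eigvalsh(hess).max() > -1e-4:  # not (numerically) concave
        return None
    t_star = np.linalg.solve(hess, -np.array([b1, b2]))
    if np.linalg.norm(t_star) > radius:
        return None
    h_star = a + b1 * t_star[0] + b2 * t_star[1] + 0.5 * t_star @ hess @ t_star
    return p0 + t_star[0] * e1 + t_star[1] * e2 + h_star * d


def _refine_extreme(v: np.ndarray, p0: np.ndarray, direction: np.ndarray, radius: float) -> np.ndarray:
    """Sub-vertex apex localisation by local quadratic regression.

    Fits ``h = a + b.t + t'Ct`` to the surface patch around the extreme
    vertex ``p0`` (heights ``h`` along ``direction``, in-plane offsets
    ``t``) and returns the apex of the fitted paraboloid.  Averaging over
    the patch removes the outward bias an argmax over jittered vertices
    carries.  The fit is re-centred on its own apex and repeated, which
    makes the result insensitive to which of several near-tied noisy
    vertices seeded it.  Falls back to the seed vertex when the patch is
    too small, the fit is not concave, or the apex leaves the patch.
    """
    d = unit(direction)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, d)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = unit(np.cross(d, helper))
    e2 = np.cross(d, e1)
    p = p0
    for _ in range(3):
        p_new = _fit_apex_once(v, p, d, e1, e2, radius)
        if p_new is None:
            return p0 if p is p0 else p
        if np.linalg.norm(p_new - p) < 0.05:
            return p_new
        p = p_new
    return p


def detect_epicondyles(mesh, frame: FemoralFrame, cfg: FrameConfig | None = None):
    """Medial and lateral epicondylar prominences.

    The prominence (not the sulcus) is used as the reference point: the
    surface vertex extremal along the +-transepicondylar direction within an
    axial band centred on the condylar mass.
    """
    cfg = cfg or FrameConfig()
    v = _vertices(mesh)
    axial = frame.proximal_dir
    medial = frame.medial_dir
    dist_m, dist_l = detect_condylar_extremes(mesh, frame)[2:]
    jl_coord = min(float(dist_m @ axial), float(dist_l @ axial))
    center = _condylar_band_center(v, jl_coord, axial, cfg)
    me = _extreme_in_band(v, medial, axial, center, cfg.epicondylar_band)
    le = _extreme_in_band(v, -medial, axial, center, cfg.epicondylar_band)
    return me, le


def _split_condyles(v: np.ndarray, medial: np.ndarray, sagittal_point: np.ndarray):
    s = (v - sagittal_point) @ medial
    med, lat = v[s > 0], v[s <= 0]
    if med.size == 0 or lat.size == 0:
        raise EmptyBandError("mid-sagittal split produced an empty condyle half")
    return med, lat


def detect_condylar_extremes(mesh, frame: FemoralFrame):
    """Posterior-most and distal-most surface point of each condyle.

    The mesh is split at the mid-sagittal plane (through the c-TEA midpoint,
    normal along the c-TEA); per half, the vertex extremal in the posterior
    direction supports the posterior condylar line (joint line in flexion)
    and the vertex extremal distally along the mechanical axis supports the
    distal articular line (joint line in extension).
    """
    v = _vertices(mesh)
    # the axial-plane anchor is the c-TEA midpoint by construction
    return _condylar_extremes(v, frame.proximal_dir, -frame.anterior_dir,
                              frame.medial_dir, frame.axial_plane.point)


def _condylar_extremes(v, proximal, posterior, medial, sagittal_point,
                       region_height: float = 35.0):
    # restrict to the condylar region so a slightly tilted working direction
    # cannot promote a proximal shaft vertex to "posterior-most"
    a = v @ proximal
    v = v[a <= a.min() + region_height]
    med, lat = _split_condyles(v, unit(medial), sagittal_point)
    post_m = med[np.argmax(med @ posterior)]
    post_l = lat[np.argmax(lat @ posterior)]
    dist_m = med[np.argmin(med @ proximal)]
    dist_l = lat[np.argmin(lat @ proximal)]
    return post_m, post_l, dist_m, dist_l


def _initial_directions(v: np.ndarray, side: str):
    """Bootstrap (proximal, medial, anterior) working directions.

    The condylar mass is both the widest part of the bone (its principal
    in-plane direction seeds the transepicondylar axis) and bulges posterior
    to the shaft axis (orienting anteroposterior).  The medial sign follows
    from the side and the handedness of (medial, anterior, proximal).
    """
    axis = estimate_initial_long_axis(v)
    proximal = axis.direction
    t = (v - axis.origin) @ proximal
    distal_mask = t <= np.quantile(t, 0.2)
    distal = v[distal_mask]
    dc = distal - distal.mean(axis=0)
    dc_perp = dc - np.outer(dc @ proximal, proximal)
    evals, evecs = np.linalg.eigh(np.cov(dc_perp.T))
    ml_seed = evecs[:, -1]  # widest in-plane direction ~ transepicondylar
    offset = distal.mean(axis=0) - axis.origin
    offset_perp = offset - (offset @ proximal) * proximal
    offset_perp -= (offset_perp @ ml_seed) * ml_seed
    if np.linalg.norm(offset_perp) < 1e-6:
        raise DegenerateMeshError("cannot orient anteroposterior direction")
    posterior = unit(offset_perp)  # condylar mass bulges posterior to the shaft
    anterior = -posterior
    s = 1.0 if side == "right" else -1.0
    medial = unit(s * np.cross(anterior, proximal))
    return proximal, medial, anterior


def build_frame(mesh, side: str, cfg: FrameConfig | None = None):
    """Construct the measurement frame of one femur by fixed-point iteration.

    Each pass: (1) condylar extremes and the distal joint-line level in the
    current working directions; (2) anatomical axis from the shaft-width
    midpoints; (3) mechanical axis at the valgus angle; (4) axial plane;
    (5) epicondyles and clinical transepicondylar axis; (6) coronal plane.
    Iteration stops when every detected landmark moves less than
    ``convergence_tol`` between passes.

    Returns ``(FemoralFrame, DetectedLandmarks)``.
    """
    cfg = cfg or FrameConfig()
    if side not in _SIDES:
        raise ValueError(f"side must be one of {_SIDES}")
    v = _vertices(mesh)
    proximal, medial, anterior = _initial_directions(v, side)
    sagittal_point = v.mean(axis=0)
    s = 1.0 if side == "right" else -1.0

    prev: DetectedLandmarks | None = None
    prev2: DetectedLandmarks | None = None
    frame = None
    landmarks = None
    displacement = np.inf
    for _ in range(cfg.max_iterations):
        posterior = -anterior
        post_m, post_l, dist_m, dist_l = _condylar_extremes(
            v, proximal, posterior, medial, sagittal_point, cfg.condylar_region_height
        )
        if cfg.refine_landmarks:
            r = cfg.refine_radius
            post_m = _refine_extreme(v, post_m, posterior, r)
            post_l = _refine_extreme(v, post_l, posterior, r)
            dist_m = _refine_extreme(v, dist_m, -proximal, r)
            dist_l = _refine_extreme(v, dist_l, -proximal, r)
        jl_coord = min(float(dist_m @ proximal), float(dist_l @ proximal))
        ref = v.mean(axis=0)
        jl_point = ref + (jl_coord - float(ref @ proximal)) * proximal

        anat = compute_anatomical_axis(v, jl_point, proximal, medial, cfg)
        mech = compute_mechanical_axis(anat, side, cfg, anterior, medial)
        # under-relaxed working direction; the reported frame keeps the exact
        # valgus construction
        proximal = unit(proximal + mech.direction)

        band_center = _condylar_band_center(v, float(jl_point @ proximal), proximal, cfg)
        me = _extreme_in_band(v, medial, proximal, band_center, cfg.epicondylar_band)
        le = _extreme_in_band(v, -medial, proximal, band_center, cfg.epicondylar_band)
        if cfg.refine_landmarks:
            me = _refine_extreme(v, me, medial, cfg.refine_radius)
            le = _refine_extreme(v, le, -medial, cfg.refine_radius)
        # under-relax the transepicondylar update: damps two-cycles where a
        # micro-rotation of the working direction flips an argmax seed vertex
        medial_reported = unit(me - le)
        medial = unit(medial + medial_reported)
        anterior = unit(s * np.cross(proximal, medial))
        sagittal_point = 0.5 * (me + le)

        # the reported frame uses the exact (undamped) constructions
        c_tea = Line3(me, me - le)
        axial_plane = Plane3(sagittal_point, mech.direction)
        coronal_plane = plane_from_two_directions(me, medial_reported, mech.direction)
        landmarks = DetectedLandmarks(me, le, post_m, post_l, dist_m, dist_l)
        frame = FemoralFrame(
            anatomical_axis=anat,
            mechanical_axis=mech,
            axial_plane=axial_plane,
            coronal_plane=coronal_plane,
            c_tea=c_tea,
            side=side,
        )
        if prev is not None:
            displacement = landmarks.max_displacement(prev)
            if displacement < cfg.convergence_tol:
                return frame, landmarks
        # a period-2 limit cycle of the discrete argmax seeds: the two
        # states agree to sub-tolerance, so either is an acceptable fixed
        # point — accept the current one
        if prev2 is not None and landmarks.max_displacement(prev2) < cfg.convergence_tol:
            return frame, landmarks
        prev2 = prev
        prev = landmarks

    raise FrameConvergenceError(
        f"frame iteration did not converge in {cfg.max_iterations} passes "
        f"(last landmark displacement {displacement:.3f} mm)"
    )
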