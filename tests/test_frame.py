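"""Frame construction: axes, landmark detection and the fixed-point iteration."""

from dataclasses import replace

import numpy as np
import pytest

from jointline.frame import (
    DegenerateMeshError,
    EmptySliceError,
    FrameConfig,
    build_frame,
    compute_anatomical_axis,
    compute_mechanical_axis,
    detect_condylar_extremes,
    detect_epicondyles,
    estimate_initial_long_axis,
)
from jointline.geometry import Line3, RigidTransform, angle_between_deg
from jointline.measure import measure_knee
from jointline.synthetic import FemurMesh, apply_random_pose, build_mesh


class TestInitialAxis:
    def test_close_to_true_shaft_axis(self, clean_mesh):
        mesh, truth = clean_mesh
        axis = estimate_initial_long_axis(mesh)
        anat = truth.true_frame.anatomical_axis.direction
        assert angle_between_deg(axis.direction, anat) < 3.0

    def test_points_proximally(self, clean_mesh):
        mesh, _ = clean_mesh
        axis = estimate_initial_long_axis(mesh)
        assert axis.direction[2] > 0.9  # canonical frame: +z is proximal

    def test_equivariant_under_rotation(self, clean_mesh):
        mesh, _ = clean_mesh
        axis0 = estimate_initial_long_axis(mesh)
        rot = RigidTransform(
            np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]]), np.zeros(3)
        )  # 90 deg about x
        rotated = FemurMesh(rot.apply(mesh.vertices), mesh.faces, mesh.side)
        axis1 = estimate_initial_long_axis(rotated)
        assert angle_between_deg(axis1.direction, rot.apply_direction(axis0.direction)) < 3.0

    def test_degenerate_cloud_rejected(self, rng):
        blob = rng.normal(size=(800, 3))
        with pytest.raises(DegenerateMeshError):
            estimate_initial_long_axis(blob)


class TestAnatomicalAxis:
    def test_recovers_cylinder_axis(self, clean_mesh):
        mesh, truth = clean_mesh
        jl_point = np.array([0.0, 0.0, truth.landmarks.dist_medial[2]])
        axis = compute_anatomical_axis(
            mesh, jl_point, np.array([0, 0, 1.0]), np.array([1.0, 0, 0]), FrameConfig()
        )
        true_dir = truth.true_frame.anatomical_axis.direction
        assert angle_between_deg(axis.direction, true_dir) < 0.5

    def test_translation_equivariance(self, clean_mesh):
        mesh, truth = clean_mesh
        jl_point = np.array([0.0, 0.0, truth.landmarks.dist_medial[2]])
        shift = np.array([13.0, 0.0, 0.0])
        moved = FemurMesh(mesh.vertices + shift, mesh.faces, mesh.side)
        cfg = FrameConfig()
        z, x = np.array([0, 0, 1.0]), np.array([1.0, 0, 0])
        a0 = compute_anatomical_axis(mesh, jl_point, z, x, cfg)
        a1 = compute_anatomical_axis(moved, jl_point + shift, z, x, cfg)
        assert np.allclose(a1.direction, a0.direction, atol=1e-9)
        assert np.allclose(a1.origin, a0.origin + shift, atol=1e-6)

    def test_midpoints_match_brute_force_slice_extremes(self, clean_mesh):
        mesh, truth = clean_mesh
        cfg = replace(FrameConfig(), refine_landmarks=False)
        jl_point = np.array([0.0, 0.0, truth.landmarks.dist_medial[2]])
        z, x = np.array([0, 0, 1.0]), np.array([1.0, 0, 0])
        axis = compute_anatomical_axis(mesh, jl_point, z, x, cfg)
        v = mesh.vertices
        mids = []
        for level in cfg.shaft_levels:
            sl = v[np.abs((v - jl_point) @ z - level) <= cfg.slice_halfwidth]
            mids.append(0.5 * (sl[np.argmax(sl @ x)] + sl[np.argmin(sl @ x)]))
        assert np.allclose(axis.origin, mids[0], atol=1e-6)
        d = mids[1] - mids[0]
        assert angle_between_deg(axis.direction, d) < 1e-6

    def test_truncated_shaft_raises(self, clean_mesh):
        mesh, truth = clean_mesh
        v = mesh.vertices[mesh.vertices[:, 2] < 80.0]
        jl_point = np.array([0.0, 0.0, truth.landmarks.dist_medial[2]])
        with pytest.raises(EmptySliceError):
            compute_anatomical_axis(
                v, jl_point, np.array([0, 0, 1.0]), np.array([1.0, 0, 0]), FrameConfig()
            )


class TestMechanicalAxis:
    def test_zero_valgus_is_identity(self):
        anat = Line3(np.zeros(3), [0.1, 0.0, 1.0])
        cfg = replace(FrameConfig(), valgus_angle=0.0)
        mech = compute_mechanical_axis(anat, "right", cfg, [0, 1.0, 0], [1.0, 0, 0])
        assert np.allclose(mech.direction, anat.direction)

    def test_angle_equals_valgus(self):
        anat = Line3(np.zeros(3), [-0.105, 0.0, 0.995])
        mech = compute_mechanical_axis(
            anat, "right", FrameConfig(), [0, 1.0, 0], [1.0, 0, 0]
        )
        assert angle_between_deg(mech.direction, anat.direction) == pytest.approx(
            6.0, abs=1e-6
        )

    def test_proximal_end_tilts_medially(self):
        anat = Line3(np.zeros(3), [-0.105, 0.0, 0.995])
        mech = compute_mechanical_axis(
            anat, "right", FrameConfig(), [0, 1.0, 0], [1.0, 0, 0]
        )
        assert mech.direction[0] > anat.direction[0]

    def test_mirrored_sides_give_mirrored_axes(self, reference_spec):
        flip = np.array([-1.0, 1.0, 1.0])
        mesh_r, _ = build_mesh(reference_spec)
        mesh_l, _ = build_mesh(replace(reference_spec, side="left"))
        f_r, _ = build_frame(mesh_r, "right")
        f_l, _ = build_frame(mesh_l, "left")
        assert angle_between_deg(
            f_l.mechanical_axis.direction, f_r.mechanical_axis.direction * flip
        ) < 0.2


class TestDetections:
    def test_epicondyles_match_ground_truth(self, clean_mesh, clean_frame):
        mesh, truth = clean_mesh
        frame, _ = clean_frame
        me, le = detect_epicondyles(mesh, frame)
        assert np.linalg.norm(me - truth.landmarks.me) < 0.5
        assert np.linalg.norm(le - truth.landmarks.le) < 0.5

    def test_condylar_extremes_match_ground_truth(self, clean_mesh, clean_frame):
        mesh, truth = clean_mesh
        frame, _ = clean_frame
        post_m, post_l, dist_m, dist_l = detect_condylar_extremes(mesh, frame)
        for got, name in [
            (post_m, "post_medial"), (post_l, "post_lateral"),
            (dist_m, "dist_medial"), (dist_l, "dist_lateral"),
        ]:
            assert np.linalg.norm(got - getattr(truth.landmarks, name)) < 0.5

    def test_condylar_extremes_equal_exhaustive_scan(self, clean_mesh, clean_frame):
        mesh, _ = clean_mesh
        frame, _ = clean_frame
        post_m, post_l, dist_m, dist_l = detect_condylar_extremes(mesh, frame)
        v = mesh.vertices
        a = v @ frame.proximal_dir
        v = v[a <= a.min() + 35.0]
        s = (v - frame.axial_plane.point) @ frame.medial_dir
        med, lat = v[s > 0], v[s <= 0]
        posterior = -frame.anterior_dir
        assert np.allclose(post_m, med[np.argmax(med @ posterior)], atol=1e-9)
        assert np.allclose(post_l, lat[np.argmax(lat @ posterior)], atol=1e-9)
        assert np.allclose(dist_m, med[np.argmin(med @ frame.proximal_dir)], atol=1e-9)
        assert np.allclose(dist_l, lat[np.argmin(lat @ frame.proximal_dir)], atol=1e-9)

    def test_detection_invariant_to_vertex_permutation(self, clean_mesh, clean_frame, rng):
        mesh, _ = clean_mesh
        frame, _ = clean_frame
        perm = rng.permutation(mesh.n_vertices)
        shuffled = mesh.vertices[perm]
        me0, le0 = detect_epicondyles(mesh, frame)
        me1, le1 = detect_epicondyles(shuffled, frame)
        assert np.allclose(me0, me1) and np.allclose(le0, le1)

    def test_symmetric_condyles_have_equal_posterior_offsets(self, reference_spec):
        sym = replace(reference_spec, me_fj=25.0, le_fj=25.0, me_ej=23.0, le_ej=23.0)
        mesh, _ = build_mesh(sym)
        frame, lm = build_frame(mesh, sym.side)
        post = -frame.anterior_dir
        assert abs((lm.post_medial - lm.post_lateral) @ post) < 0.2


class TestBuildFrame:
    def test_recovers_truth_on_clean_mesh(self, clean_mesh, clean_frame, reference_spec):
        _, truth = clean_mesh
        frame, lm = clean_frame
        assert angle_between_deg(
            frame.mechanical_axis.direction, truth.true_frame.mechanical_axis.direction
        ) < 1.0
        for name in lm._NAMES:
            assert np.linalg.norm(
                getattr(lm, name) - getattr(truth.landmarks, name)
            ) < 0.5

    def test_frame_invariants(self, clean_frame):
        frame, _ = clean_frame
        dot = np.dot(frame.axial_plane.normal, frame.mechanical_axis.direction)
        assert abs(abs(dot) - 1) < 1e-9
        assert angle_between_deg(
            frame.mechanical_axis.direction, frame.anatomical_axis.direction
        ) == pytest.approx(6.0, abs=1e-6)
        # c-TEA lies in the coronal plane
        assert abs(np.dot(frame.c_tea.direction, frame.coronal_plane.normal)) < 1e-9

    def test_rigid_equivariance(self, clean_mesh, clean_frame):
        mesh, _ = clean_mesh
        frame0, lm0 = clean_frame
        posed, t = apply_random_pose(mesh, seed=5)
        frame1, lm1 = build_frame(posed, mesh.side)
        assert angle_between_deg(
            frame1.mechanical_axis.direction,
            t.apply_direction(frame0.mechanical_axis.direction),
        ) < 1.0
        assert np.linalg.norm(lm1.me - t.apply(lm0.me)) < 0.5

    def test_measurements_survive_pose_and_noise(self, reference_spec):
        spec = replace(reference_spec, surface_noise_sd=0.2, mesh_resolution=1.0, seed=9)
        mesh, _ = build_mesh(spec)
        posed, _ = apply_random_pose(mesh, seed=10)
        frame, lm = build_frame(posed, spec.side)
        m = measure_knee(lm, frame)
        for name, want in reference_spec.distances().items():
            assert getattr(m, name) == pytest.approx(want, abs=1.0)

    def test_invalid_side_rejected(self, clean_mesh):
        mesh, _ = clean_mesh
        with pytest.raises(ValueError):
            build_frame(mesh, "bilateral")
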