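"""Registration, signed surface deviations, banding, grading and statistics."""

import numpy as np
import pytest
import trimesh

from hto3d import (
    BAND_LABELS,
    DeviationMap,
    ErrorModel,
    RigidTransform,
    TibialAngles,
    angle_deviation_row,
    apply_transform,
    best_fit_register,
    classify_bands,
    crop_by_level,
    grade_specimen,
    simulate_surgical_error,
    summarize_deviations,
    surface_deviation,
)
from hto3d.deviation_analysis import DEFAULT_CROP_BELOW_PLATEAU_MM
from hto3d.errors import InsufficientDataError, RangeError
from hto3d.meshquery import SurfaceQuery
from hto3d.reporting import load_reference_cohort


def _identity_frame():
    from hto3d import AnatomicFrame
    return AnatomicFrame(origin=np.zeros(3), x_axis=[1, 0, 0],
                         y_axis=[0, 1, 0], z_axis=[0, 0, 1])


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

class TestCrop:
    def test_level_below_mesh_returns_whole(self):
        m = trimesh.creation.icosphere(2)
        out = crop_by_level(m, _identity_frame(), -10.0)
        assert len(out.faces) == len(m.faces)

    def test_level_above_mesh_is_range_error(self):
        m = trimesh.creation.icosphere(2)
        with pytest.raises(RangeError):
            crop_by_level(m, _identity_frame(), 10.0)

    def test_midlevel_crop_keeps_upper_half(self):
        m = trimesh.creation.icosphere(3)
        out = crop_by_level(m, _identity_frame(), 0.0)
        frame = _identity_frame()
        assert np.all(frame.z_of(out.vertices) >= 0.0)
        assert abs(len(out.faces) / len(m.faces) - 0.5) < 0.1


# ---------------------------------------------------------------------------
# closest point / signed distance
# ---------------------------------------------------------------------------

def _oracle_point_triangle(p, tri):
    """Independent closest-point oracle: clamped barycentric least squares
    plus explicit edge/vertex candidates."""
    a, b, c = tri
    candidates = [a, b, c]
    e1, e2 = b - a, c - a
    M = np.array([[e1 @ e1, e1 @ e2], [e2 @ e1, e2 @ e2]])
    rhs = np.array([(p - a) @ e1, (p - a) @ e2])
    try:
        s, t = np.linalg.solve(M, rhs)
        if s >= 0 and t >= 0 and s + t <= 1:
            candidates.append(a + s * e1 + t * e2)
    except np.linalg.LinAlgError:
        pass
    for q0, q1 in ((a, b), (a, c), (b, c)):
        e = q1 - q0
        u = np.clip(((p - q0) @ e) / (e @ e), 0.0, 1.0)
        candidates.append(q0 + u * e)
    candidates = np.array(candidates)
    return candidates[np.argmin(np.linalg.norm(candidates - p, axis=1))]


class TestSurfaceQuery:
    def test_matches_brute_force_all_triangle_scan(self):
        mesh = trimesh.creation.icosphere(1)  # 80 triangles
        assert len(mesh.faces) <= 500
        rng = np.random.default_rng(5)
        pts = rng.uniform(-2, 2, (40, 3))
        _, dist, _ = SurfaceQuery(mesh).closest(pts)
        tris = mesh.triangles.view(np.ndarray)
        for p, d in zip(pts, dist):
            brute = min(np.linalg.norm(_oracle_point_triangle(p, tri) - p)
                        for tri in tris)
            assert d == pytest.approx(brute, abs=1e-9)

    def test_sign_follows_surface_normal(self):
        mesh = trimesh.creation.icosphere(2)
        sd, _, _ = SurfaceQuery(mesh).signed_distance(
            np.array([[0.0, 0.0, 1.5], [0.0, 0.0, 0.5]]))
        assert sd[0] == pytest.approx(0.5, abs=0.01)
        assert sd[1] == pytest.approx(-0.5, abs=0.01)


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

class TestRegistration:
    def test_identical_meshes_give_identity(self, coarse_specimen):
        mesh, _, _ = coarse_specimen
        reg = best_fit_register(mesh, mesh)
        assert reg.rotation_angle_deg() < 1e-6
        assert np.linalg.norm(reg.translation) < 1e-6

    def test_known_perturbation_recovered(self, coarse_specimen):
        mesh, _, _ = coarse_specimen
        t = RigidTransform.about_axis([10, 0, -100], [0.2, 1.0, 0.5], 2.0)
        t = t.compose(RigidTransform(np.eye(3), [3.0, -1.0, 2.0]))
        moved = apply_transform(mesh, t)
        reg = best_fit_register(moved, mesh)
        resid = reg.compose(t)
        assert resid.rotation_angle_deg() < 0.05
        probe = mesh.vertices[::997]
        assert np.linalg.norm(resid.apply(probe) - probe, axis=1).max() < 0.05

    def test_partial_overlap_recovery(self, coarse_specimen):
        """Proximal crop registered against the full bone still recovers."""
        mesh, landmarks, _ = coarse_specimen
        from hto3d import build_frame
        frame = build_frame(landmarks)
        crop = crop_by_level(mesh, frame, -DEFAULT_CROP_BELOW_PLATEAU_MM)
        t = RigidTransform.about_axis([0, 0, -30], [1.0, 0.3, 0.2], 2.0)
        t = t.compose(RigidTransform(np.eye(3), [2.0, 3.0, -1.0]))
        moved = apply_transform(crop, t)
        reg = best_fit_register(moved, mesh)
        resid = reg.compose(t)
        assert resid.rotation_angle_deg() < 0.1
        probe = crop.vertices[::97]
        assert np.linalg.norm(resid.apply(probe) - probe, axis=1).max() < 0.1


# ---------------------------------------------------------------------------
# deviation maps
# ---------------------------------------------------------------------------

class TestSurfaceDeviation:
    def test_identical_surfaces_have_zero_deviation(self):
        mesh = trimesh.creation.icosphere(2)
        dev = surface_deviation(mesh, mesh, RigidTransform.identity())
        assert np.abs(dev.distances).max() < 1e-6

    def test_outward_offset_slab(self):
        slab = trimesh.creation.box(extents=[40.0, 40.0, 1.0])
        offset = slab.copy()
        offset = trimesh.Trimesh(vertices=slab.vertices + slab.vertex_normals,
                                 faces=slab.faces)
        dev = surface_deviation(offset, slab, RigidTransform.identity())
        assert np.allclose(dev.distances, 1.0, atol=1e-3)

    def test_deviation_matches_signed_query(self):
        planned = trimesh.creation.icosphere(2)
        realized = trimesh.creation.icosphere(2, radius=1.02)
        dev = surface_deviation(realized, planned, RigidTransform.identity())
        assert np.allclose(dev.distances, 0.02, atol=1e-6)


class TestBandsAndGrades:
    def _map(self, values):
        values = np.asarray(values, dtype=float)
        n = len(values)
        mesh = trimesh.Trimesh(
            vertices=np.column_stack([np.arange(n), np.zeros(n), np.zeros(n)]),
            faces=np.array([[i, (i + 1) % n, (i + 2) % n] for i in range(n)]),
            process=False)
        return DeviationMap(distances=values, mesh=mesh)

    def test_all_zero_map_is_very_good(self):
        summ = classify_bands(self._map(np.zeros(10)))
        assert summ.fractions["very_good"] == 1.0
        assert grade_specimen(summ) == "very_good"

    def test_one_value_per_band(self):
        summ = classify_bands(self._map([0.5, 0.9, 1.5, 2.0]))
        assert [summ.fractions[k] for k in BAND_LABELS] == [0.25, 0.25, 0.25, 0.25]
        assert summ.worst_band == "unacceptable"

    def test_uniform_mass_in_first_band(self):
        rng = np.random.default_rng(42)
        summ = classify_bands(self._map(rng.uniform(0.0, 2.0, 100_000)))
        assert summ.fractions["very_good"] == pytest.approx(0.3, abs=0.01)

    def test_p95_in_good_band(self):
        values = np.full(100, 1.0)
        summ = classify_bands(self._map(values))
        assert grade_specimen(summ) == "good"

    def test_under_correction_grades_worse_than_ideal(self, default_result,
                                                      default_frame, planned_state):
        planned_mesh, _, _ = planned_state
        fixed = crop_by_level(planned_mesh, default_frame, -DEFAULT_CROP_BELOW_PLATEAU_MM)

        def grade_for(model):
            mesh, _ = simulate_surgical_error(default_result, model)
            moving = crop_by_level(mesh, default_frame, -DEFAULT_CROP_BELOW_PLATEAU_MM)
            reg = best_fit_register(moving, fixed)
            return grade_specimen(classify_bands(
                surface_deviation(mesh, planned_mesh, reg)))

        g_ideal = grade_for(ErrorModel())
        g_under = grade_for(ErrorModel(opening_angle_scale=0.7))
        assert BAND_LABELS.index(g_under) > BAND_LABELS.index(g_ideal)
        assert g_ideal == "very_good"


# ---------------------------------------------------------------------------
# angle deviation statistics
# ---------------------------------------------------------------------------

class TestAngleDeviationStats:
    def test_identical_angles_give_zero_row(self):
        a = TibialAngles(87.0, 8.0, 7.0, 35.0)
        row = angle_deviation_row(a, a, "x")
        assert (row.mpta, row.medial_slope, row.lateral_slope, row.torsion) == (0, 0, 0, 0)

    def test_quarter_degree_mpta_difference(self):
        a = TibialAngles(87.0, 8.0, 7.0, 35.0)
        b = TibialAngles(87.25, 8.0, 7.0, 35.0)
        assert angle_deviation_row(a, b, "1").mpta == 0.25

    def test_row_symmetric_in_arguments(self):
        a = TibialAngles(87.0, 8.0, 7.0, 35.0)
        b = TibialAngles(88.3, 7.1, 9.2, 30.0)
        r1, r2 = angle_deviation_row(a, b, "s"), angle_deviation_row(b, a, "s")
        assert r1 == r2

    def test_reference_cohort_statistics(self):
        """Cohort abs-mean/SD of the reference 13-specimen deviation table."""
        df = load_reference_cohort()
        rows = [angle_deviation_row(
            TibialAngles(87 + r.mpta, 8 + r.medial_slope, 7 + r.lateral_slope,
                         35 + r.torsion),
            TibialAngles(87.0, 8.0, 7.0, 35.0), str(r.specimen_id))
            for r in df.itertuples()]
        summary = summarize_deviations(rows)
        assert summary.loc["abs_mean", "medial_slope"] == 0.98
        assert summary.loc["sd", "medial_slope"] == 0.53
        assert summary.loc["abs_mean", "torsion"] == 5.74
        assert summary.loc["sd", "torsion"] == 3.24

    def test_constant_rows_have_zero_sd(self):
        a = TibialAngles(87.0, 8.0, 7.0, 35.0)
        b = TibialAngles(87.5, 8.5, 7.5, 35.5)
        rows = [angle_deviation_row(a, b, str(i)) for i in range(3)]
        summary = summarize_deviations(rows)
        assert (summary.loc["sd"] == 0.0).all()

    def test_single_row_insufficient_for_sd(self):
        a = TibialAngles(87.0, 8.0, 7.0, 35.0)
        with pytest.raises(InsufficientDataError):
            summarize_deviations([angle_deviation_row(a, a, "only")])


# ---------------------------------------------------------------------------
# end-to-end null test
# ---------------------------------------------------------------------------

def test_perfect_execution_yields_null_deviation(default_result, default_frame,
                                                 planned_state, ideal_execution):
    """A perfectly executed osteotomy deviates from its own plan by nothing."""
    planned_mesh, _, planned_angles = planned_state
    realized_mesh, realized_landmarks = ideal_execution
    from hto3d import measure_angles
    moving = crop_by_level(realized_mesh, default_frame, -DEFAULT_CROP_BELOW_PLATEAU_MM)
    fixed = crop_by_level(planned_mesh, default_frame, -DEFAULT_CROP_BELOW_PLATEAU_MM)
    reg = best_fit_register(moving, fixed)
    dev = surface_deviation(realized_mesh, planned_mesh, reg)
    assert np.abs(dev.distances).max() < 0.05
    assert grade_specimen(classify_bands(dev)) == "very_good"
    realized_angles = measure_angles(realized_mesh, realized_landmarks)
    row = angle_deviation_row(planned_angles, realized_angles, "null")
    assert (row.mpta, row.medial_slope, row.lateral_slope, row.torsion) == (0, 0, 0, 0)
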