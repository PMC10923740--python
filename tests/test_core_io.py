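"""Mesh/landmark I/O, rigid transforms and the anatomic frame."""

import json

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from hto3d import (
    LANDMARK_VOCABULARY,
    LandmarkSet,
    RigidTransform,
    Side,
    apply_transform,
    build_frame,
    read_landmarks,
    read_surface_mesh,
    write_landmarks,
    write_surface_mesh,
)
from hto3d.errors import (
    DegenerateFrameError,
    LandmarkError,
    MeshFormatError,
    ValidationError,
)
from .conftest import random_rigid

TET = trimesh.Trimesh(
    vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
    faces=[[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]],
)


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

class TestMeshIO:
    def test_binary_stl_tetrahedron_merges_soup(self, tmp_path):
        path = tmp_path / "tet.stl"
        write_surface_mesh(TET, path, format="stl-binary")
        assert path.stat().st_size == 84 + 4 * 50
        mesh = read_surface_mesh(path)
        assert len(mesh.vertices) == 4
        assert len(mesh.faces) == 4

    def test_ascii_and_binary_dialects_agree(self, tmp_path):
        pb, pa = tmp_path / "b.stl", tmp_path / "a.stl"
        write_surface_mesh(TET, pb, format="stl-binary")
        write_surface_mesh(TET, pa, format="stl-ascii")
        mb, ma = read_surface_mesh(pb), read_surface_mesh(pa)
        # same geometry irrespective of vertex ordering
        assert np.allclose(sorted(map(tuple, mb.vertices)),
                           sorted(map(tuple, ma.vertices)), atol=1e-6)
        assert mb.area == pytest.approx(ma.area, abs=1e-9)

    def test_synthetic_tibia_stl_round_trip(self, coarse_specimen, tmp_path):
        mesh, _, _ = coarse_specimen
        path = tmp_path / "tibia.stl"
        write_surface_mesh(mesh, path, format="stl-binary")
        back = read_surface_mesh(path)
        # vertex sets equal within float32 STL precision at ~360 mm coordinates
        from scipy.spatial import cKDTree
        d, _ = cKDTree(mesh.vertices).query(back.vertices)
        assert d.max() < 5e-5

    def test_ply_scalar_channel_round_trip(self, tmp_path):
        mesh = TET.copy()
        scalar = np.array([0.0, -1.25, 0.5, 2.0])
        mesh.vertex_attributes["quality"] = scalar
        path = tmp_path / "m.ply"
        write_surface_mesh(mesh, path, format="ply")
        back = read_surface_mesh(path)
        assert np.allclose(back.vertex_attributes["quality"], scalar, atol=1e-6)
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-6)

    def test_empty_mesh_rejected(self, tmp_path):
        empty = trimesh.Trimesh(vertices=np.zeros((4, 3)), faces=np.zeros((0, 3), int),
                                process=False)
        with pytest.raises(ValidationError):
            write_surface_mesh(empty, tmp_path / "x.stl")

    def test_truncated_binary_stl_reports_byte_offset(self, tmp_path):
        path = tmp_path / "trunc.stl"
        write_surface_mesh(TET, path, format="stl-binary")
        data = path.read_bytes()
        path.write_bytes(data[:-60])
        with pytest.raises(MeshFormatError, match=r"byte"):
            read_surface_mesh(path)


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def _full_landmark_set():
    rng = np.random.default_rng(0)
    return LandmarkSet(Side.LEFT, {n: rng.uniform(-40, 40, 3) for n in LANDMARK_VOCABULARY})


class TestLandmarkIO:
    def test_round_trip_identical_positions(self, tmp_path):
        lms = _full_landmark_set()
        path = tmp_path / "lm.json"
        write_landmarks(lms, path)
        back = read_landmarks(path)
        assert back.side is Side.LEFT
        assert not back.warnings
        for name in LANDMARK_VOCABULARY:
            assert np.allclose(back[name], lms[name])

    def test_unknown_names_preserved_with_warning(self, tmp_path):
        payload = {"side": "RIGHT", "landmarks": {"TKC": [0, 0, 0], "EXTRA": [1, 2, 3]}}
        path = tmp_path / "lm.json"
        path.write_text(json.dumps(payload))
        back = read_landmarks(path)
        assert "EXTRA" in back
        assert any("EXTRA" in w for w in back.warnings)

    def test_missing_required_name_raised_when_requested(self):
        lms = _full_landmark_set()
        del lms.points["IFT"]
        with pytest.raises(LandmarkError, match="IFT"):
            lms.require(("PMC", "PLC", "IFT", "MMAL"))

    def test_malformed_json_is_format_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(MeshFormatError):
            read_landmarks(path)


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

class TestRigidTransform:
    def test_identity_leaves_objects_unchanged(self):
        t = RigidTransform.identity()
        p = np.array([1.0, -2.0, 3.0])
        assert np.allclose(apply_transform(p, t), p)
        out = apply_transform(TET, t)
        assert np.allclose(out.vertices, TET.vertices)

    def test_inverse_composition_is_identity(self):
        rng = np.random.default_rng(1)
        t = random_rigid(rng)
        both = t.inverse().compose(t)
        assert np.allclose(both.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(both.translation, 0, atol=1e-9)

    def test_improper_rotation_rejected(self):
        M = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(ValidationError):
            RigidTransform(M, np.zeros(3))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_isometry_preserves_pairwise_distances(self, seed):
        rng = np.random.default_rng(seed)
        t = random_rigid(rng)
        pts = rng.uniform(-100, 100, (20, 3))
        moved = apply_transform(pts, t)
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None], axis=-1)
        assert np.allclose(d0, d1, rtol=1e-9, atol=1e-9)


# ---------------------------------------------------------------------------
# anatomic frame
# ---------------------------------------------------------------------------

def _axis_aligned_landmarks(side=Side.LEFT, with_distal=True):
    pts = {
        "TMCA": [0.0, 30.0, 0.0], "TMCP": [0.0, -30.0, 0.0],
        "MMPP": [-40.0, 0.0, 0.0], "MLPP": [40.0, 0.0, 0.0],
        "TKC": [0.0, 0.0, 0.0],
    }
    if with_distal:
        pts["MMAL"] = [-10.0, 0.0, -300.0]
    return LandmarkSet(side, pts)


class TestAnatomicFrame:
    def test_axis_aligned_construction(self):
        frame = build_frame(_axis_aligned_landmarks())
        assert np.allclose(frame.y_axis, [0, 1, 0], atol=1e-12)
        assert np.allclose(frame.z_axis, [0, 0, 1], atol=1e-12)
        assert np.allclose(np.abs(frame.x_axis), [1, 0, 0], atol=1e-12)
        assert np.allclose(frame.origin, 0)

    def test_side_fallback_without_distal_landmark(self):
        frame = build_frame(_axis_aligned_landmarks(side=Side.LEFT, with_distal=False))
        assert np.allclose(frame.z_axis, [0, 0, 1], atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_equivariance_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        t = random_rigid(rng)
        lms = _axis_aligned_landmarks()
        f0 = build_frame(lms)
        f1 = build_frame(apply_transform(lms, t))
        assert np.allclose(f1.origin, t.apply(f0.origin), atol=1e-9)
        for ax in ("x_axis", "y_axis", "z_axis"):
            assert np.allclose(getattr(f1, ax), t.rotation @ getattr(f0, ax), atol=1e-9)

    def test_coincident_points_degenerate(self):
        lms = _axis_aligned_landmarks()
        lms.points["TMCA"] = lms.points["TMCP"].copy()
        with pytest.raises(DegenerateFrameError):
            build_frame(lms)

    def test_collinear_points_degenerate(self):
        lms = _axis_aligned_landmarks()
        lms.points["MMPP"] = np.array([0.0, -20.0, 0.0])
        lms.points["MLPP"] = np.array([0.0, 20.0, 0.0])
        with pytest.raises(DegenerateFrameError):
            build_frame(lms)

    def test_landmark_outside_inflated_bbox_rejected(self, coarse_specimen):
        mesh, landmarks, _ = coarse_specimen
        bad = landmarks.copy()
        bad.points["TKC"] = bad.points["TKC"] + np.array([500.0, 0.0, 0.0])
        with pytest.raises(ValidationError, match="TKC"):
            bad.validate_against_mesh(mesh)


def test_generated_landmarks_lie_on_written_and_reread_surface(coarse_specimen, tmp_path):
    """Round-trip through STL keeps landmarks on the surface (ground-truth consistency)."""
    mesh, landmarks, _ = coarse_specimen
    path = tmp_path / "t.stl"
    write_surface_mesh(mesh, path)
    back = read_surface_mesh(path)
    from hto3d.meshquery import SurfaceQuery
    pts = np.array([landmarks[n] for n in LANDMARK_VOCABULARY])
    _, d, _ = SurfaceQuery(back).closest(pts)
    assert d.max() < 0.5
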