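"""Parametric proximal-tibia phantoms with analytically known landmarks.

The phantom is a stylized, watertight tibia: a tapered elliptical shaft, a
flared metaphysis widening into the plateau, a plateau surface tilted to
realize prescribed MPTA and medial/lateral slopes, an anterior tuberosity
bump, a distal twist realizing a prescribed torsion, and a mild distal flare
carrying the malleolus/incisura features.  Landmarks are emitted from the
same closed-form surface function that builds the mesh, so every landmark is
exactly a mesh vertex.

Because the measured angles are defined through the landmark-based frame
(whose axes are themselves tilted by the plateau inclination), the raw tilt
parameters are solved numerically so that the *measured* angle definitions
hit the requested targets exactly; the returned ground truth therefore equals
the targets by construction, independent of the mesh.

The module also simulates surgical execution error (under-correction, hinge
obliquity, anterior sag) and observer landmark jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import trimesh
from scipy.optimize import root

from .angle_analysis import (
    AxisLine,
    TibialAngles,
    compute_mpta,
    compute_slope,
    compute_torsion,
)
from .core_io import (
    LandmarkSet,
    RigidTransform,
    Side,
    apply_transform,
    build_frame,
    warn,
)
from .errors import ValidationError
from .osteotomy import OsteotomyResult, transform_landmarks


@dataclass
class SyntheticTibiaParams:
    """Parameters of one phantom; lengths in mm, angles in degrees."""

    side: Side = Side.LEFT
    total_length: float = 360.0
    plateau_width: float = 75.0       # MMPP-MLPP distance
    plateau_depth: float = 50.0       # anterior-posterior plateau extent
    shaft_radius: float = 13.0        # shaft half-width (depth is 0.8 of this)
    target_mpta: float = 87.0
    target_medial_slope: float = 8.0
    target_lateral_slope: float = 7.0
    target_torsion: float = 35.0
    tuberosity_offset: float = 12.0   # apex protrusion beyond the plateau rim
    malleolus_offset: float = 4.0     # distal flare amplitude
    mesh_resolution: Tuple[int, int] = (48, 180)  # circumferential x longitudinal
    seed: int = 0

    # fixed shape constants (not study conditions; see docs)
    metaphysis_length: float = 115.0
    tuberosity_level: float = -35.0   # z of the tuberosity apex
    twist_start: float = 110.0        # twist begins this far below the plateau
    twist_end_offset: float = 40.0    # twist completes this far above the distal end
    feature_offset: float = 18.0      # malleolus/incisura level above the distal end

    def __post_init__(self):
        if isinstance(self.side, str):
            self.side = Side(self.side)
        for name in ("total_length", "plateau_width", "plateau_depth", "shaft_radius"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        n_circ, n_long = self.mesh_resolution
        if n_circ < 24 or n_long < 60:
            raise ValidationError("mesh_resolution must be at least 24 x 60")
        if n_circ % 24 != 0:
            raise ValidationError("circumferential resolution must be a multiple of 24 "
                                  "so landmark meridians fall on mesh vertices")


@dataclass
class ErrorModel:
    """Execution-error knobs for the simulated surgery.

    ``opening_angle_scale`` < 1 emulates general under-correction (e.g. gap
    closing after wedge removal); ``hinge_tilt_axial`` tilts the hinge axis in
    the axial plane (degrees, posterolateral positive); ``anterior_sag``
    closes the anterior part of the gap by the given millimeters, emulating
    wedges supported posteriorly only; ``landmark_sigma`` adds isotropic
    observer noise to the realized landmarks.
    """

    opening_angle_scale: float = 1.0
    hinge_tilt_axial: float = 0.0
    anterior_sag: float = 0.0
    landmark_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.opening_angle_scale < 2.0:
            raise ValidationError("opening_angle_scale must lie in (0, 2)")
        if self.landmark_sigma < 0 or self.anterior_sag < 0:
            raise ValidationError("landmark_sigma and anterior_sag must be >= 0")


# ---------------------------------------------------------------------------
# closed-form geometry (canonical LEFT tibia: medial -x, anterior +y, proximal +z)
# ---------------------------------------------------------------------------

def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


class _Shape:
    """Closed-form surface of one phantom for a given raw tilt/twist vector."""

    def __init__(self, p: SyntheticTibiaParams, gamma: float, s_med: float,
                 s_lat: float, tau: float):
        # gamma: coronal joint-line tilt; s_med/s_lat: sagittal plateau tilts;
        # tau: distal external twist -- all in radians, canonical LEFT side.
        self.p = p
        self.gamma = gamma
        self.s_med = s_med
        self.s_lat = s_lat
        self.tau = tau
        self.w0 = p.plateau_width / 2.0
        self.d0 = p.plateau_depth / 2.0
        self.a_s = p.shaft_radius
        self.b_s = 0.8 * p.shaft_radius
        self.z_feat = -p.total_length + p.feature_offset
        self.z_ift = None  # solved lazily by _ift_level
        # tuberosity bump amplitude so the apex protrudes tuberosity_offset
        # beyond the plateau rim depth
        d_ttv = self._half_depth(p.tuberosity_level)
        self.bump_amp = (self.d0 + p.tuberosity_offset) / d_ttv - 1.0

    # -- longitudinal profiles ------------------------------------------------
    def _meta(self, z):
        return _smoothstep(-np.asarray(z, float) / self.p.metaphysis_length)

    def _flare(self, z):
        v = (-np.asarray(z, float) - (self.p.total_length - 30.0)) / 30.0
        return _smoothstep(v)

    def _half_width(self, z):
        return self.w0 + (self.a_s - self.w0) * self._meta(z) \
            + self.p.malleolus_offset * self._flare(z)

    def _half_depth(self, z):
        return self.d0 + (self.b_s - self.d0) * self._meta(z) \
            + self.p.malleolus_offset * self._flare(z)

    def _twist(self, z):
        span = self.p.total_length - self.p.twist_end_offset - self.p.twist_start
        u = (-np.asarray(z, float) - self.p.twist_start) / span
        return -self.tau * _smoothstep(u)  # external rotation, LEFT convention

    def _bump(self, phi, z):
        dphi = np.arctan2(np.sin(phi - np.pi / 2), np.cos(phi - np.pi / 2))
        g = np.exp(-(dphi ** 2) / (2 * 0.5 ** 2)
                   - ((np.asarray(z, float) - self.p.tuberosity_level) ** 2) / (2 * 10.0 ** 2))
        return 1.0 + self.bump_amp * g

    # -- plateau --------------------------------------------------------------
    def plateau_height(self, x, y):
        """Plateau surface height: coronal tilt plus x-interpolated sagittal slope."""
        s_mid = 0.5 * (self.s_med + self.s_lat)
        s_grad = (self.s_lat - self.s_med) / self.w0  # per unit x over half width
        s_local = s_mid + s_grad * np.asarray(x, float) / 2.0
        return -np.asarray(x, float) * math.tan(self.gamma) + np.asarray(y, float) * np.tan(s_local)

    def _blend(self, z):
        return np.clip(1.0 + np.asarray(z, float) / 25.0, 0.0, 1.0)

    # -- surface points -------------------------------------------------------
    def ring_point(self, phi, z):
        """Point on the side wall at meridian ``phi`` and nominal level ``z``."""
        phi = np.asarray(phi, float)
        z = np.asarray(z, float)
        w, d = self._half_width(z), self._half_depth(z)
        f = self._bump(phi, z)
        x0, y0 = w * np.cos(phi) * f, d * np.sin(phi) * f
        beta = self._twist(z)
        x = x0 * np.cos(beta) - y0 * np.sin(beta)
        y = x0 * np.sin(beta) + y0 * np.cos(beta)
        zz = z + self._blend(z) * self.plateau_height(x, y)
        return np.stack(np.broadcast_arrays(x, y, zz), axis=-1)

    def cap_point(self, rho, phi):
        """Point on the plateau cap: rim ring scaled by ``rho`` toward the center."""
        rim = self.ring_point(phi, 0.0)
        x, y = rho * rim[..., 0], rho * rim[..., 1]
        return np.stack(np.broadcast_arrays(x, y, self.plateau_height(x, y)), axis=-1)

    # -- landmarks ------------------------------------------------------------
    def landmarks(self) -> dict:
        deg = np.radians
        pts = {
            "TKC": np.zeros(3),
            "MMPP": self.ring_point(deg(180.0), 0.0),
            "MLPP": self.ring_point(deg(0.0), 0.0),
            "PMC": self.ring_point(deg(240.0), 0.0),
            "PLC": self.ring_point(deg(300.0), 0.0),
            "TMCA": self.cap_point(0.75, deg(120.0)),
            "TMCP": self.cap_point(0.75, deg(240.0)),
            "TLCA": self.cap_point(0.75, deg(60.0)),
            "TLCP": self.cap_point(0.75, deg(300.0)),
            "TTV": self.ring_point(deg(90.0), self.p.tuberosity_level),
            "MMAL": self.ring_point(deg(180.0), self.z_feat),
        }
        pts = {k: np.asarray(v, float).reshape(3) for k, v in pts.items()}
        pts["IFT"] = self.ring_point(0.0, self._ift_level(pts))
        self.z_ift = self._ift_level(pts)
        return pts

    def _ift_level(self, pts: dict) -> float:
        """Incisura level chosen so the malleolar line lies in the frame's
        axial plane (torsion then decouples from coronal hinge rotations)."""
        if getattr(self, "z_ift", None) is not None:
            return self.z_ift
        from scipy.optimize import brentq

        frame = build_frame(LandmarkSet(Side.LEFT, pts))
        mmal = pts["MMAL"]

        def resid(z):
            return float((self.ring_point(0.0, z) - mmal) @ frame.z_axis)

        lo = max(self.z_feat - 16.0, -self.p.total_length + 2.0)
        hi = self.z_feat + 16.0
        try:
            self.z_ift = float(brentq(resid, lo, hi, xtol=1e-10))
        except ValueError:
            self.z_ift = self.z_feat
        return self.z_ift


def _analytic_angles(shape: _Shape) -> np.ndarray:
    """Measured angle definitions evaluated on the analytic landmarks.

    The shaft axis of the canonical phantom is the world z-axis by symmetry,
    so the closed form needs no mesh.
    """
    lms = LandmarkSet(Side.LEFT, shape.landmarks())
    frame = build_frame(lms)
    axis = AxisLine(point=np.array([0.0, 0.0, -100.0]), direction=np.array([0.0, 0.0, 1.0]))
    return np.array([
        compute_mpta(lms, axis, frame),
        compute_slope(lms, axis, "MEDIAL"),
        compute_slope(lms, axis, "LATERAL"),
        compute_torsion(lms, frame),
    ])


def _solve_shape(params: SyntheticTibiaParams) -> _Shape:
    """Find raw tilt/twist parameters so the measured angles hit the targets."""
    targets = np.array([params.target_mpta, params.target_medial_slope,
                        params.target_lateral_slope, params.target_torsion])

    def residual(x):
        return _analytic_angles(_Shape(params, *x)) - targets

    x0 = np.radians([90.0 - params.target_mpta, params.target_medial_slope,
                     params.target_lateral_slope, params.target_torsion])
    sol = root(residual, x0, method="hybr", tol=1e-12)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-8:
        raise ValidationError(
            f"infeasible angle combination {targets.tolist()} (solver residual "
            f"{np.max(np.abs(sol.fun)):.2e})")
    if np.max(np.abs(sol.x[:3])) > np.radians(45.0):
        raise ValidationError("plateau tilt exceeds 45 degrees; parameters infeasible")
    return _Shape(params, *sol.x)


# ---------------------------------------------------------------------------
# mesh assembly
# ---------------------------------------------------------------------------

_CAP_RHOS = (0.75, 0.5, 0.25)


def _levels(params: SyntheticTibiaParams, shape: _Shape) -> np.ndarray:
    n_long = params.mesh_resolution[1]
    z = np.linspace(0.0, -params.total_length, n_long)
    feats = [params.tuberosity_level, shape.z_feat]
    if shape.z_ift is not None and abs(shape.z_ift - shape.z_feat) > 1e-9:
        feats.append(shape.z_ift)
    used = set()
    for feat in feats:  # snap the nearest free regular level onto each feature
        order = np.argsort(np.abs(z - feat))
        idx = next(int(i) for i in order if int(i) not in used)
        z[idx] = feat
        used.add(idx)
    return np.sort(z)[::-1]


def generate_tibia(params: Optional[SyntheticTibiaParams] = None):
    """Build one phantom: ``(mesh, landmarks, ground_truth_angles)``.

    The mesh is watertight; landmark coordinates are exact mesh vertices;
    the ground truth equals the target angles (realized by construction).
    Fully deterministic for fixed parameters.
    """
    if params is None:
        params = SyntheticTibiaParams()
    truth = TibialAngles(params.target_mpta, params.target_medial_slope,
                         params.target_lateral_slope, params.target_torsion)
    shape = _solve_shape(params)
    landmark_points = shape.landmarks()  # also fixes the incisura level

    n_circ = params.mesh_resolution[0]
    phis = 2.0 * np.pi * np.arange(n_circ) / n_circ
    levels = _levels(params, shape)
    n_lev = len(levels)

    rings = shape.ring_point(phis[None, :], levels[:, None])          # (n_lev, C, 3)
    caps = np.stack([shape.cap_point(rho, phis) for rho in _CAP_RHOS])  # (3, C, 3)
    top_center = np.array([[0.0, 0.0, 0.0]])
    bottom_center = np.array([[0.0, 0.0, float(levels[-1])]])

    verts = np.concatenate([rings.reshape(-1, 3), caps.reshape(-1, 3),
                            top_center, bottom_center])
    B = n_lev * n_circ
    i_top = B + 3 * n_circ
    i_bot = i_top + 1

    faces = []
    cols = np.arange(n_circ)
    nxt = (cols + 1) % n_circ

    def quad_band(upper, lower):
        # upper/lower: vertex index arrays of two stacked rings
        faces.append(np.column_stack([upper[cols], lower[cols], lower[nxt]]))
        faces.append(np.column_stack([upper[cols], lower[nxt], upper[nxt]]))

    ring_idx = lambda r: r * n_circ + np.arange(n_circ)  # noqa: E731
    cap_idx = lambda c: B + c * n_circ + np.arange(n_circ)  # noqa: E731

    for r in range(n_lev - 1):
        quad_band(ring_idx(r), ring_idx(r + 1))
    quad_band(cap_idx(0), ring_idx(0))      # rim to first interior cap ring
    quad_band(cap_idx(1), cap_idx(0))
    quad_band(cap_idx(2), cap_idx(1))
    faces.append(np.column_stack([np.full(n_circ, i_top), cap_idx(2)[cols], cap_idx(2)[nxt]]))
    faces.append(np.column_stack([np.full(n_circ, i_bot), ring_idx(n_lev - 1)[nxt],
                                  ring_idx(n_lev - 1)[cols]]))

    mesh = trimesh.Trimesh(vertices=verts, faces=np.concatenate(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()

    landmarks = LandmarkSet(Side.LEFT, landmark_points)
    if params.side is Side.RIGHT:
        v = mesh.vertices.copy()
        v[:, 0] = -v[:, 0]
        mesh = trimesh.Trimesh(vertices=v, faces=mesh.faces[:, ::-1], process=False)
        pts = {k: np.array([-p[0], p[1], p[2]]) for k, p in landmarks.points.items()}
        landmarks = LandmarkSet(Side.RIGHT, pts)
    return mesh, landmarks, truth


# ---------------------------------------------------------------------------
# error injection
# ---------------------------------------------------------------------------

def _solve_sag_angle(plan, point, target_mm: float) -> float:
    """Rotation about the in-cut medial-lateral axis lifting ``point`` by ``target_mm``."""
    z = plan.frame.z_axis

    def lift(theta_deg, sign):
        t = RigidTransform.about_axis(plan.cut_end * 0.5 + plan.medial_point * 0.5,
                                      plan.lateral_in_plane, sign * theta_deg)
        return float((t.apply(point) - point) @ z)

    sign = 1.0 if lift(1.0, 1.0) >= lift(1.0, -1.0) else -1.0
    lo, hi = 0.0, 30.0
    theta = 0.0
    for _ in range(80):
        theta = 0.5 * (lo + hi)
        if lift(theta, sign) < target_mm:
            lo = theta
        else:
            hi = theta
    return sign * theta


def simulate_surgical_error(result: OsteotomyResult, model: ErrorModel):
    """Re-execute the fragment motion with imperfections.

    Returns ``(realized_mesh, realized_landmarks)``: the distal fragment moved
    by a scaled opening about a (possibly tilted) hinge, with an optional
    extra anterior closure, and landmarks optionally jittered.  Deterministic
    per model seed.
    """
    plan = result.plan
    frame = plan.frame
    tilt = RigidTransform.about_axis(plan.hinge_point, frame.z_axis, model.hinge_tilt_axial)
    hinge_dir = tilt.rotation @ plan.hinge_direction
    theta = plan.opening_angle * model.opening_angle_scale
    t_open = RigidTransform.about_axis(plan.hinge_point, hinge_dir,
                                       plan.rotation_sign * theta)
    t_err = t_open
    if model.anterior_sag > 0.0:
        anterior_ref = plan.ascending_cut.point - \
            plan.main_cut.signed_distance(plan.ascending_cut.point) * plan.main_cut.normal
        sag = _solve_sag_angle(plan, t_open.apply(anterior_ref), model.anterior_sag)
        t_err = RigidTransform.about_axis(
            0.5 * (plan.cut_end + plan.medial_point), plan.lateral_in_plane, sag,
        ).compose(t_open)

    undo = result.fragment_transform.inverse()
    distal0 = apply_transform(result.distal_fragment, undo)
    realized_distal = apply_transform(distal0, t_err)
    realized_mesh = trimesh.util.concatenate([result.proximal_fragment, realized_distal])

    source = result.source_landmarks
    realized_landmarks, _ = transform_landmarks(source, plan, t_err)
    if model.landmark_sigma > 0.0:
        realized_landmarks = jitter_landmarks(realized_landmarks,
                                              model.landmark_sigma, model.seed)

    # deep self-intersection check at the cut
    contour = distal0.vertices[np.abs(plan.main_cut.signed_distance(distal0.vertices)) < 1e-6]
    if len(contour):
        penetration = plan.main_cut.signed_distance(t_err.apply(contour)).max()
        if penetration > 2.0:
            warn(f"error model drives fragments {penetration:.1f} mm into each other")
    return realized_mesh, realized_landmarks


def jitter_landmarks(landmarks: LandmarkSet, sigma_mm: float, seed: int) -> LandmarkSet:
    """Isotropic zero-mean Gaussian perturbation of each landmark (one observer)."""
    if sigma_mm < 0:
        raise ValidationError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    pts = {}
    for name in sorted(landmarks.points):
        pts[name] = landmarks.points[name] + rng.normal(0.0, sigma_mm, 3)
    return LandmarkSet(landmarks.side, pts, list(landmarks.warnings))
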