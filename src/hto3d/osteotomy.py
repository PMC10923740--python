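"""Virtual medial open-wedge high tibial osteotomy: planning and execution.

The plan uses the standard biplanar technique.  An ascending frontal cut is
placed 10 mm posterior of the tuberosity apex (TTV); the main cut enters the
medial cortex half a plateau-width below the medial plateau, runs parallel to
the medial slope line, aims at a point 15 mm distal to the lateral plateau,
and terminates 15 mm medial of the lateral cortex, leaving the usual lateral
bone bridge.  The hinge axis runs along the frame's y-axis through the
lateral edge of the bone at the cut level.

Execution splits the bone into a proximal fragment (plateau side, holding the
lateral bridge) and a distal fragment (shaft plus the tuberosity flange
anterior of the ascending cut), then rotates the distal fragment about the
hinge until the gap at the most medial point of the cut, measured along the
frame z-axis, reaches the prescribed opening.  In the virtual model the
lateral bridge is cut through rather than plastically deformed; it stays with
the undeformed proximal fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh

from .angle_analysis import AxisLine
from .core_io import (
    LANDMARK_VOCABULARY,
    AnatomicFrame,
    LandmarkSet,
    RigidTransform,
    apply_transform,
)
from .errors import GeometryError, PlanningError, TopologyError, ValidationError
from .meshquery import ray_hits

#: Intact lateral bridge length in mm (distance from cut end to lateral cortex).
LATERAL_BRIDGE_MM = 15.0
#: Distal offset of the lateral aim point below the lateral plateau, mm.
LATERAL_AIM_DROP_MM = 15.0
#: Ascending (frontal) cut offset posterior of the tuberosity apex, mm.
ASCENDING_OFFSET_MM = 10.0

_PLANE_TOL = 1e-6  # mm; vertices closer than this to a cut plane sit on its contour


@dataclass(frozen=True)
class CutPlane:
    """An (optionally bounded) cutting plane with unit normal."""

    point: np.ndarray
    normal: np.ndarray
    bounded_extent: Optional[np.ndarray] = None

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ValidationError("cut plane normal is zero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.point) @ self.normal


@dataclass
class OsteotomyPlan:
    """Fully determined biplanar opening-wedge plan for one specimen."""

    ascending_cut: CutPlane
    main_cut: CutPlane
    hinge_point: np.ndarray
    hinge_direction: np.ndarray
    medial_entry: np.ndarray
    gap_target: float
    opening_angle: float            # degrees, solved
    frame: AnatomicFrame
    lateral_bridge: float = LATERAL_BRIDGE_MM
    cut_end: np.ndarray = None      # lateral termination of the main cut
    medial_point: np.ndarray = None  # most medial point of the cut contour
    lateral_in_plane: np.ndarray = None  # unit medial->lateral direction inside main cut
    rotation_sign: float = 1.0      # sense of hinge rotation that opens medially

    def __post_init__(self):
        if not self.gap_target > 0:
            raise ValidationError("gap_target must be positive")
        if self.opening_angle is not None and not 0.0 < self.opening_angle < 30.0:
            raise ValidationError(
                f"opening angle {self.opening_angle:.2f} deg outside (0, 30)")


@dataclass
class OsteotomyResult:
    """Executed virtual osteotomy: fragments, motion and realized landmarks."""

    proximal_fragment: trimesh.Trimesh
    distal_fragment: trimesh.Trimesh          # already moved by fragment_transform
    fragment_transform: RigidTransform
    realized_landmarks: LandmarkSet
    plan: OsteotomyPlan
    medial_gap_mm: float = float("nan")       # realized gap, measured on cut contours
    ambiguous_landmarks: list = field(default_factory=list)
    source_landmarks: Optional[LandmarkSet] = None  # pre-osteotomy landmark set


# ---------------------------------------------------------------------------
# planning
# ---------------------------------------------------------------------------

def _horizontal(v: np.ndarray, frame: AnatomicFrame) -> np.ndarray:
    """Component of v perpendicular to the frame z-axis, normalized."""
    h = v - (v @ frame.z_axis) * frame.z_axis
    n = np.linalg.norm(h)
    if n < 1e-9:
        raise PlanningError("direction is parallel to the frame z-axis")
    return h / n


def plan_hto(mesh: trimesh.Trimesh, landmarks: LandmarkSet, frame: AnatomicFrame,
             axis: AxisLine, gap_target: float = 8.0) -> OsteotomyPlan:
    """Construct the biplanar opening-wedge plan from landmarks and the frame."""
    if not 1.0 < gap_target < 20.0:
        raise ValidationError(f"gap_target {gap_target} mm outside (1, 20)")
    landmarks.require(LANDMARK_VOCABULARY)
    y, z = frame.y_axis, frame.z_axis
    mmpp, mlpp = landmarks["MMPP"], landmarks["MLPP"]
    lateral = _horizontal(mlpp - mmpp, frame)

    # ascending frontal cut, 10 mm posterior of the tuberosity apex
    ascending = CutPlane(point=landmarks["TTV"] - ASCENDING_OFFSET_MM * y, normal=y)

    # medial entry: on the medial cortex, half a plateau width below the medial plateau
    width = float(np.linalg.norm(mlpp - mmpp))
    entry_level = frame.z_of(mmpp) - width / 2.0
    probe = frame.origin + entry_level * z
    hits, _ = ray_hits(mesh, probe, -lateral)
    if len(hits) == 0:
        raise PlanningError("no medial cortex found at the entry level")
    medial_entry = hits[-1]  # outermost crossing = medial cortex

    # main cut: contains the medial slope direction, runs from the entry toward
    # the aim point 15 mm distal of the lateral plateau
    aim = mlpp - LATERAL_AIM_DROP_MM * z
    slope_dir = landmarks["TMCP"] - landmarks["TMCA"]
    normal = np.cross(slope_dir, aim - medial_entry)
    if np.linalg.norm(normal) < 1e-9:
        raise PlanningError("main cut is degenerate (slope line parallel to entry-aim line)")
    normal = normal / np.linalg.norm(normal)
    if normal @ z < 0:
        normal = -normal
    main = CutPlane(point=medial_entry, normal=normal)

    section = mesh.section(plane_origin=main.point, plane_normal=main.normal)
    if section is None:
        raise PlanningError("main cut plane does not intersect the bone")
    contour = section.vertices.view(np.ndarray)
    lat_in_plane = lateral - (lateral @ main.normal) * main.normal
    lat_in_plane = lat_in_plane / np.linalg.norm(lat_in_plane)
    s = (contour - main.point) @ lat_in_plane
    hinge_point = contour[int(np.argmax(s))]
    medial_point = contour[int(np.argmin(s))]
    cut_end = hinge_point - LATERAL_BRIDGE_MM * lat_in_plane

    plan = OsteotomyPlan(
        ascending_cut=ascending, main_cut=main,
        hinge_point=hinge_point, hinge_direction=y.copy(),
        medial_entry=medial_entry, gap_target=float(gap_target),
        opening_angle=None, frame=frame,
        cut_end=cut_end, medial_point=medial_point, lateral_in_plane=lat_in_plane,
    )
    plan.opening_angle = solve_opening_angle(plan, medial_point, gap_target)
    return plan


def solve_opening_angle(plan: OsteotomyPlan, medial_point, gap_target: float,
                        tol_mm: float = 1e-6) -> float:
    """Opening angle (deg) whose hinge rotation drops the most medial cut point
    by ``gap_target`` along the frame z-axis; solved by bisection on (0, 30)."""
    medial_point = np.asarray(medial_point, dtype=float)
    z = plan.frame.z_axis

    def drop(theta_deg: float, sign: float) -> float:
        t = RigidTransform.about_axis(plan.hinge_point, plan.hinge_direction,
                                      sign * theta_deg)
        return float((medial_point - t.apply(medial_point)) @ z)

    sign = 1.0 if drop(1.0, 1.0) >= drop(1.0, -1.0) else -1.0
    plan.rotation_sign = sign
    lo, hi = 0.0, 30.0
    if drop(hi, sign) < gap_target:
        raise GeometryError(
            "no opening angle below 30 deg reaches the requested gap "
            "(hinge too close to the medial point)")
    theta = None
    for _ in range(100):
        theta = 0.5 * (lo + hi)
        err = drop(theta, sign) - gap_target
        if abs(err) < tol_mm:
            break
        if err < 0:
            lo = theta
        else:
            hi = theta
    return float(theta)


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

def _slice(mesh: trimesh.Trimesh, normal, point) -> trimesh.Trimesh:
    """Open (uncapped) half-space slice keeping the side the normal points to."""
    return trimesh.intersections.slice_mesh_plane(mesh, np.asarray(normal, float),
                                                  np.asarray(point, float), cap=False)


def _contour_points(fragment: trimesh.Trimesh, plane: CutPlane) -> np.ndarray:
    verts = fragment.vertices.view(np.ndarray)
    on = np.abs(plane.signed_distance(verts)) < _PLANE_TOL
    return verts[on]


def execute_hto(mesh: trimesh.Trimesh, landmarks: LandmarkSet,
                plan: OsteotomyPlan) -> OsteotomyResult:
    """Split the bone by the planned biplanar cuts and open the wedge.

    The plateau-side fragment (with the lateral bridge) stays fixed; the
    distal fragment (shaft plus tuberosity flange) rotates about the hinge by
    the solved opening angle.  The realized gap is re-measured from matching
    cut-contour points of the two fragments.
    """
    main, asc = plan.main_cut, plan.ascending_cut
    bridge_normal = np.cross(plan.hinge_direction, main.normal)
    bridge_normal /= np.linalg.norm(bridge_normal)
    if bridge_normal @ plan.lateral_in_plane < 0:
        bridge_normal = -bridge_normal

    above = _slice(mesh, main.normal, main.point)
    below = _slice(mesh, -main.normal, main.point)
    prox_main = _slice(above, -asc.normal, asc.point)
    flange = _slice(above, asc.normal, asc.point)
    bridge = _slice(below, bridge_normal, plan.cut_end)
    distal_core = _slice(below, -bridge_normal, plan.cut_end)

    n_pieces = sum(len(m.faces) > 0 for m in (prox_main, distal_core))
    if n_pieces != 2:
        raise TopologyError(n_pieces, "cuts did not produce both a proximal and a distal fragment")

    proximal = prox_main if len(bridge.faces) == 0 else \
        trimesh.util.concatenate([prox_main, bridge])
    distal_rest = distal_core if len(flange.faces) == 0 else \
        trimesh.util.concatenate([distal_core, flange])

    # matching contour points on either side of the main cut, before motion
    dist_contour = _contour_points(distal_core, main)
    prox_contour = _contour_points(proximal, main)
    if len(dist_contour) == 0 or len(prox_contour) == 0:
        raise TopologyError(n_pieces, "no cut contour found on a fragment")
    s = (dist_contour - main.point) @ plan.lateral_in_plane
    p_dist = dist_contour[int(np.argmin(s))]
    p_prox = prox_contour[int(np.argmin(np.linalg.norm(prox_contour - p_dist, axis=1)))]

    transform = RigidTransform.about_axis(plan.hinge_point, plan.hinge_direction,
                                          plan.rotation_sign * plan.opening_angle)
    moved = apply_transform(distal_rest, transform)
    gap = float((p_prox - transform.apply(p_dist)) @ plan.frame.z_axis)

    realized, ambiguous = transform_landmarks(landmarks, plan, transform)
    return OsteotomyResult(
        proximal_fragment=proximal, distal_fragment=moved,
        fragment_transform=transform, realized_landmarks=realized, plan=plan,
        medial_gap_mm=gap, ambiguous_landmarks=ambiguous,
        source_landmarks=landmarks.copy(),
    )


def transform_landmarks(landmarks: LandmarkSet, plan: OsteotomyPlan,
                        fragment_transform: RigidTransform):
    """Move distal-side landmarks by the fragment transform.

    Classification is by signed distance to the main cut with the tuberosity
    flange rule: points proximal of the main cut but anterior of the ascending
    cut travel with the distal fragment.  Landmarks within 0.5 mm of the main
    cut are assigned by sign and reported as ambiguous.
    """
    realized = {}
    ambiguous = []
    for name, p in landmarks.points.items():
        d_main = float(plan.main_cut.signed_distance(p))
        anterior = float(plan.ascending_cut.signed_distance(p)) > 0.0
        is_distal = d_main < 0.0 or anterior
        if abs(d_main) < 0.5:
            ambiguous.append(name)
        realized[name] = fragment_transform.apply(p) if is_distal else p.copy()
    out = LandmarkSet(landmarks.side, realized, list(landmarks.warnings))
    for name in ambiguous:
        out.warnings.append(f"landmark {name} within 0.5 mm of the main cut; assigned by sign")
    return out, ambiguous
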