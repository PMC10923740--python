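"""Tibial joint-angle measurement from a surface mesh plus anatomical landmarks.

Four angles characterize the proximal tibia:

* **MPTA** (medial proximal tibial angle) — coronal-plane angle between the
  joint line (MLPP to MMPP, pointing medially) and the anatomical axis
  (pointing proximally), measured on the medial side; ~87 deg in normal knees.
* **medial / lateral slope** — sagittal inclination of each plateau's
  anterior-posterior line against the anatomical axis; positive when the
  plateau dips posteriorly-distally.
* **torsion** — axial-plane angle between the dorsal plateau tangent and the
  distal incisura-to-malleolus line; external rotation positive.

The anatomical axis joins the cross-section centroids of the shaft at one and
two thirds of the shaft length below the plateau.  All angles are reported
side-normalized: mirror-image left/right specimens yield equal values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .core_io import (
    LANDMARK_VOCABULARY,
    AnatomicFrame,
    LandmarkSet,
    Side,
    build_frame,
    warn,
)
from .errors import DegeneracyError, RangeError, ValidationError

#: Minimum surviving length of a projected direction, relative to the original.
_PROJ_TOL = 1e-6


@dataclass(frozen=True)
class AxisLine:
    """A 3D line with a unit direction oriented proximally."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            if n < 1e-12:
                raise ValidationError("axis direction is zero")
            d = d / n
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class TibialAngles:
    """The four tibial angles of one specimen, in degrees."""

    mpta: float
    medial_slope: float
    lateral_slope: float
    torsion: float

    def __post_init__(self):
        if not 45.0 < self.mpta < 135.0:
            raise ValidationError(f"MPTA {self.mpta:.2f} outside (45, 135) deg")
        for name in ("medial_slope", "lateral_slope"):
            v = getattr(self, name)
            if not -45.0 < v < 45.0:
                raise ValidationError(f"{name} {v:.2f} outside (-45, 45) deg")
        if not -90.0 < self.torsion < 90.0:
            raise ValidationError(f"torsion {self.torsion:.2f} outside (-90, 90) deg")

    def as_dict(self) -> dict:
        return {"mpta": self.mpta, "medial_slope": self.medial_slope,
                "lateral_slope": self.lateral_slope, "torsion": self.torsion}


# ---------------------------------------------------------------------------
# shaft axis
# ---------------------------------------------------------------------------

def cross_section_centroid(mesh: trimesh.Trimesh, frame: AnatomicFrame, level: float) -> np.ndarray:
    """Area centroid of the largest closed contour of the mesh at frame-z ``level``.

    Distal slices can intersect more than one contour (e.g. a malleolus bump);
    the largest-area contour wins.  An open contour falls back to the polyline
    vertex centroid with a warning.
    """
    origin = frame.origin + level * frame.z_axis
    section = mesh.section(plane_origin=origin, plane_normal=frame.z_axis)
    if section is None:
        raise RangeError(f"plane z={level:.2f} mm does not intersect the mesh")
    planar, to_3d = section.to_2D()
    polygons = planar.polygons_full
    if len(polygons) == 0:
        warn(f"open contour at z={level:.2f} mm; using polyline vertex centroid")
        c2 = planar.vertices.mean(axis=0)
    else:
        poly = max(polygons, key=lambda p: p.area)
        c2 = np.array([poly.centroid.x, poly.centroid.y])
    return trimesh.transform_points(np.array([[c2[0], c2[1], 0.0]]), to_3d)[0]


def anatomical_axis(mesh: trimesh.Trimesh, frame: AnatomicFrame) -> AxisLine:
    """Anatomical axis from shaft midpoints at one and two thirds of shaft length.

    Shaft length runs from the plateau plane (frame-z = 0) to the distal-most
    vertex; the direction is oriented proximally.
    """
    z = frame.z_of(mesh.vertices)
    z_min = float(z.min())
    if z_min >= 0.0:
        raise RangeError("mesh has no extent distal to the plateau plane")
    length = -z_min
    c_upper = cross_section_centroid(mesh, frame, -length / 3.0)
    c_lower = cross_section_centroid(mesh, frame, -2.0 * length / 3.0)
    direction = c_upper - c_lower
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        raise RangeError("degenerate shaft: centroid slices coincide")
    return AxisLine(point=c_lower, direction=direction / norm)


# ---------------------------------------------------------------------------
# individual angles
# ---------------------------------------------------------------------------

def _project_out(v: np.ndarray, axis: np.ndarray, what: str) -> np.ndarray:
    """Remove the ``axis`` component of ``v``; error out if almost nothing is left."""
    p = v - (v @ axis) * axis
    if np.linalg.norm(p) < _PROJ_TOL * max(np.linalg.norm(v), 1e-300):
        raise DegeneracyError(f"{what} collapses when projected")
    return p


def compute_mpta(landmarks: LandmarkSet, axis: AxisLine, frame: AnatomicFrame) -> float:
    """Medial proximal tibial angle in the frame's coronal (x-z) plane.

    The angle between the joint line running medial-to-lateral and the
    proximally oriented axis equals the clinically reported medial-side angle
    (identical to the angle between the medially pointing joint vector and the
    distal axis direction); a varus joint line gives values below 90 deg and a
    medial opening wedge increases it.
    """
    landmarks.require(("MMPP", "MLPP"))
    joint = landmarks["MLPP"] - landmarks["MMPP"]  # medial -> lateral
    j = _project_out(joint, frame.y_axis, "joint line")
    a = _project_out(axis.direction, frame.y_axis, "anatomical axis")
    cosang = (j @ a) / (np.linalg.norm(j) * np.linalg.norm(a))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


_SLOPE_LANDMARKS = {"MEDIAL": ("TMCA", "TMCP"), "LATERAL": ("TLCA", "TLCP")}


def compute_slope(landmarks: LandmarkSet, axis: AxisLine, side: str) -> float:
    """Sagittal plateau slope: 90 deg minus the angle between the plateau's
    posterior-to-anterior line and the axis direction.

    Positive when the plateau dips posteriorly-distally (anterior point more
    proximal), the usual orthopedic sign.
    """
    try:
        ant_name, post_name = _SLOPE_LANDMARKS[side.upper()]
    except KeyError:
        raise ValueError(f"side must be MEDIAL or LATERAL, got {side!r}") from None
    landmarks.require((ant_name, post_name))
    v = landmarks[ant_name] - landmarks[post_name]
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise DegeneracyError(f"{ant_name} and {post_name} coincide")
    return float(np.degrees(np.arcsin(np.clip((v / n) @ axis.direction, -1.0, 1.0))))


def compute_torsion(landmarks: LandmarkSet, frame: AnatomicFrame) -> float:
    """Tibial torsion: signed axial-plane angle between the dorsal plateau
    tangent (PMC to PLC) and the distal malleolus-to-incisura line, both
    running medial-to-lateral; external rotation positive."""
    landmarks.require(("PMC", "PLC", "IFT", "MMAL"))
    proximal = landmarks["PLC"] - landmarks["PMC"]   # medial -> lateral
    distal = landmarks["IFT"] - landmarks["MMAL"]    # medial -> lateral
    p = _project_out(proximal, frame.z_axis, "dorsal tangent")
    d = _project_out(distal, frame.z_axis, "distal malleolar line")
    p2 = np.array([p @ frame.x_axis, p @ frame.y_axis])
    d2 = np.array([d @ frame.x_axis, d @ frame.y_axis])
    raw = np.degrees(np.arctan2(p2[0] * d2[1] - p2[1] * d2[0], p2 @ d2))
    sign = 1.0 if landmarks.side is Side.RIGHT else -1.0
    return float(sign * raw)


def measure_angles(mesh: trimesh.Trimesh, landmarks: LandmarkSet) -> TibialAngles:
    """Full specimen measurement: frame, anatomical axis, and all four angles."""
    landmarks.require(LANDMARK_VOCABULARY)
    # gross-error guard only; laxer than the I/O-level 5 mm bound so that
    # observer-noise studies on valid sets do not trip it
    landmarks.validate_against_mesh(mesh, inflate_mm=15.0)
    frame = build_frame(landmarks)
    axis = anatomical_axis(mesh, frame)
    return TibialAngles(
        mpta=compute_mpta(landmarks, axis, frame),
        medial_slope=compute_slope(landmarks, axis, "MEDIAL"),
        lateral_slope=compute_slope(landmarks, axis, "LATERAL"),
        torsion=compute_torsion(landmarks, frame),
    )

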