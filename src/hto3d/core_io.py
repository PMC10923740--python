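"""Mesh and landmark I/O, the tibial anatomic coordinate frame, and rigid-transform plumbing.

All geometry is in millimeters.  Meshes are carried as :class:`trimesh.Trimesh`
objects; an optional per-vertex scalar channel (used by the deviation export)
lives in ``mesh.vertex_attributes[SCALAR_CHANNEL]``.

The anatomic frame follows the landmark-based convention used for proximal
tibia analysis: the plateau defines the xy-plane, y runs posterior-to-anterior
along the medial plateau (TMCP to TMCA), the z-axis is the plateau normal
oriented proximally, and x completes a right-handed system.  The origin is the
tibial knee center (TKC).
"""

from __future__ import annotations

import enum
import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import (
    DegenerateFrameError,
    LandmarkError,
    MeshFormatError,
    ValidationError,
)

#: Name of the per-vertex scalar channel carried through PLY export.
SCALAR_CHANNEL = "quality"

#: Controlled vocabulary of the anatomical landmarks required for a full analysis.
LANDMARK_VOCABULARY = (
    "TMCA",  # medial plateau, most proximal anterior point
    "TMCP",  # medial plateau, most proximal posterior point
    "TLCA",  # lateral plateau, most proximal anterior point
    "TLCP",  # lateral plateau, most proximal posterior point
    "MMPP",  # most medial proximal point of the plateau
    "MLPP",  # most lateral proximal point of the plateau
    "TKC",   # tibial knee center
    "PMC",   # most posterior medial plateau point (dorsal tangent)
    "PLC",   # most posterior lateral plateau point (dorsal tangent)
    "TTV",   # most ventral point of the tibial tuberosity
    "IFT",   # deepest point of the incisura fibularis tibiae
    "MMAL",  # outermost point of the medial malleolus
)


class Side(enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


def _unit(v, err_msg="zero-length vector"):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateFrameError(err_msg)
    return v / n


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` in mm.

    ``rotation`` must be orthonormal with determinant +1 (checked on
    construction to 1e-9).  Composition and inversion are closed.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValidationError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValidationError("rotation determinant is not +1 (improper rotation)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix) -> "RigidTransform":
        M = np.asarray(matrix, dtype=float).reshape(4, 4)
        return cls(M[:3, :3], M[:3, 3])

    @classmethod
    def about_axis(cls, point, direction, angle_deg) -> "RigidTransform":
        """Rotation by ``angle_deg`` about the line through ``point`` along ``direction``."""
        from scipy.spatial.transform import Rotation

        d = _unit(direction, "axis direction must be nonzero")
        p = np.asarray(point, dtype=float)
        R = Rotation.from_rotvec(np.radians(angle_deg) * d).as_matrix()
        return cls(R, p - R @ p)

    def to_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation component in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Named anatomical points on (or near) a bone surface, with laterality."""

    side: Side
    points: dict  # name -> np.ndarray shape (3,)
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.points = {str(k): np.asarray(v, dtype=float).reshape(3)
                       for k, v in self.points.items()}
        if isinstance(self.side, str):
            self.side = Side(self.side)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise LandmarkError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def require(self, names) -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise LandmarkError(missing)

    def unknown_names(self) -> list:
        return [n for n in self.points if n not in LANDMARK_VOCABULARY]

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(self.side, {k: v.copy() for k, v in self.points.items()},
                           list(self.warnings))

    def validate_against_mesh(self, mesh: trimesh.Trimesh, inflate_mm: float = 5.0) -> None:
        """Every landmark must lie inside the mesh bounding box inflated by ``inflate_mm``."""
        lo = mesh.bounds[0] - inflate_mm
        hi = mesh.bounds[1] + inflate_mm
        for name, p in self.points.items():
            if np.any(p < lo) or np.any(p > hi):
                raise ValidationError(
                    f"landmark {name} at {np.round(p, 2)} lies outside the mesh "
                    f"bounding box inflated by {inflate_mm} mm")


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark JSON file: ``{"side": "LEFT", "landmarks": {name: [x,y,z]}}``.

    Unknown names are preserved and reported in ``LandmarkSet.warnings``; a
    missing *required* name only raises once an analysis actually asks for it.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise MeshFormatError(f"malformed landmark JSON in {path}: {exc}") from exc
    try:
        side = Side(payload["side"])
        raw = payload["landmarks"]
    except (KeyError, ValueError) as exc:
        raise MeshFormatError(f"landmark file {path} lacks a valid 'side'/'landmarks' entry") from exc
    points = {}
    for name, xyz in raw.items():
        arr = np.asarray(xyz, dtype=float)
        if arr.shape != (3,) or not np.all(np.isfinite(arr)):
            raise MeshFormatError(f"landmark {name} in {path} is not a finite 3-vector")
        points[name] = arr
    lms = LandmarkSet(side, points)
    for name in lms.unknown_names():
        lms.warnings.append(f"unknown landmark name preserved: {name}")
    return lms


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    payload = {
        "side": landmarks.side.value,
        "landmarks": {k: [float(x) for x in v] for k, v in sorted(landmarks.points.items())},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def _validate_mesh(mesh: trimesh.Trimesh, source="mesh") -> trimesh.Trimesh:
    if len(mesh.vertices) < 4:
        raise ValidationError(f"{source}: fewer than 4 vertices")
    if len(mesh.faces) == 0:
        raise ValidationError(f"{source}: no faces")
    if not np.all(mesh.faces < len(mesh.vertices)):
        raise ValidationError(f"{source}: face index out of range")
    areas = mesh.area_faces
    if np.any(areas <= 0):
        mesh.update_faces(areas > 0)
        if len(mesh.faces) == 0:
            raise ValidationError(f"{source}: all faces degenerate")
    return mesh


def _check_binary_stl(path: Path) -> None:
    """Raise :class:`MeshFormatError` naming the byte offset for truncated binary STL."""
    size = path.stat().st_size
    with open(path, "rb") as fh:
        head = fh.read(84)
    if len(head) < 84:
        raise MeshFormatError(f"{path}: truncated STL header, file ends at byte {size} (< 84)")
    if head[:5].lower() == b"solid" and b"facet" in path.read_bytes()[:512]:
        return  # ASCII dialect; leave to the parser
    (n_tri,) = struct.unpack("<I", head[80:84])
    expected = 84 + 50 * n_tri
    if size < expected:
        raise MeshFormatError(
            f"{path}: binary STL declares {n_tri} triangles "
            f"(expected {expected} bytes) but file ends at byte {size}")


def read_surface_mesh(path) -> trimesh.Trimesh:
    """Read a surface mesh (binary/ASCII STL or PLY) and validate it.

    Duplicate vertices within 1e-6 mm are merged (STL stores a triangle soup).
    A PLY per-vertex ``quality`` scalar, when present, is restored into
    ``mesh.vertex_attributes[SCALAR_CHANNEL]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        _check_binary_stl(path)
    try:
        if suffix == ".ply":
            mesh = trimesh.load(str(path), file_type="ply", process=False)
            raw = mesh.metadata.get("_ply_raw", {}).get("vertex", {}).get("data", {})
            if isinstance(raw, dict) and SCALAR_CHANNEL in raw:
                mesh.vertex_attributes[SCALAR_CHANNEL] = \
                    np.asarray(raw[SCALAR_CHANNEL], dtype=float).ravel()
        else:
            mesh = trimesh.load(str(path), file_type="stl")
    except MeshFormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise MeshFormatError(f"unreadable mesh file {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.vertices) == 0:
        raise ValidationError(f"{path}: empty mesh")
    if suffix != ".ply":
        mesh.merge_vertices(digits_vertex=6)
    return _validate_mesh(mesh, source=str(path))


def write_surface_mesh(mesh: trimesh.Trimesh, path, format: str = "stl-binary") -> None:
    """Write a mesh as ``stl-binary``, ``stl-ascii`` or ``ply`` (ASCII).

    The PLY variant carries the per-vertex scalar channel when present.
    """
    _validate_mesh(mesh, source="mesh to write")
    path = Path(path)
    if format == "stl-binary":
        data = trimesh.exchange.stl.export_stl(mesh)
    elif format == "stl-ascii":
        data = trimesh.exchange.stl.export_stl_ascii(mesh).encode()
    elif format == "ply":
        data = mesh.export(file_type="ply", encoding="ascii")
        if isinstance(data, str):
            data = data.encode()
    else:
        raise ValueError(f"unsupported mesh format: {format!r}")
    try:
        path.write_bytes(data)
    except OSError as exc:
        raise IOError(f"cannot write mesh to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# anatomic frame
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnatomicFrame:
    """Right-handed orthonormal tibial frame with origin at the knee center."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        R = self.basis
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValidationError("frame axes are not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValidationError("frame is not right-handed")

    @property
    def basis(self) -> np.ndarray:
        """Columns are the x, y, z axes in world coordinates."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def to_local(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (p - self.origin) @ self.basis

    def to_world(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.basis.T + self.origin

    def z_of(self, points) -> np.ndarray:
        """Signed frame-z coordinate (proximal positive) of world points."""
        return (np.asarray(points, dtype=float) - self.origin) @ self.z_axis


_FRAME_LANDMARKS = ("TMCA", "TMCP", "MMPP", "MLPP", "TKC")


def build_frame(landmarks: LandmarkSet) -> AnatomicFrame:
    """Construct the anatomic frame from the plateau landmarks.

    y is the unit vector from TMCP to TMCA (posterior to anterior along the
    medial plateau); the plateau plane is spanned by y and the MMPP-to-MLPP
    line, and z is its normal oriented proximally; x = y (cross) z completes a
    right-handed frame.  The proximal orientation cue is the knee-center-to-
    malleolus direction when a distal landmark (MMAL, else IFT) is present,
    otherwise the declared side disambiguates the normal.
    """
    landmarks.require(_FRAME_LANDMARKS)
    tmca, tmcp = landmarks["TMCA"], landmarks["TMCP"]
    mmpp, mlpp = landmarks["MMPP"], landmarks["MLPP"]
    if np.linalg.norm(tmca - tmcp) < 1e-9:
        raise DegenerateFrameError("TMCA and TMCP coincide")
    if np.linalg.norm(mlpp - mmpp) < 1e-9:
        raise DegenerateFrameError("MMPP and MLPP coincide")
    y = _unit(tmca - tmcp)
    u = _unit(mlpp - mmpp)  # medial -> lateral
    cross = np.cross(y, u)
    if np.linalg.norm(cross) < np.sin(np.radians(1.0)):
        raise DegenerateFrameError("plateau landmarks are collinear within 1 degree")
    n = _unit(cross)
    tkc = landmarks["TKC"]
    if "MMAL" in landmarks:
        cue = tkc - landmarks["MMAL"]
    elif "IFT" in landmarks:
        cue = tkc - landmarks["IFT"]
    else:
        # side convention: for a LEFT tibia (lateral along +u with anterior y)
        # the raw normal y x u points distally and must be flipped.
        cue = n if landmarks.side is Side.RIGHT else -n
    z = n if float(n @ cue) > 0 else -n
    z = _unit(z - (z @ y) * y)  # re-orthonormalize against y (guards rounding)
    x = np.cross(y, z)
    return AnatomicFrame(origin=tkc, x_axis=x, y_axis=y, z_axis=z)


# ---------------------------------------------------------------------------
# transform application
# ---------------------------------------------------------------------------

def apply_transform(obj, t: RigidTransform):
    """Apply a rigid transform to a mesh, a landmark set, or raw point(s).

    Returns a new object of the same type; the input is not modified.
    """
    if isinstance(obj, trimesh.Trimesh):
        out = obj.copy()
        out.apply_transform(t.to_matrix())
        return out
    if isinstance(obj, LandmarkSet):
        return LandmarkSet(obj.side, {k: t.apply(v) for k, v in obj.points.items()},
                           list(obj.warnings))
    arr = np.asarray(obj, dtype=float)
    if arr.shape[-1] != 3:
        raise TypeError(f"cannot transform object of type {type(obj).__name__}")
    return t.apply(arr)


def warn(message: str) -> None:
    warnings.warn(message, stacklevel=2)
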