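"""Plan-versus-result evaluation: registration, deviation maps and statistics.

The realized bone is rigidly registered onto its plan by a best-fit (ICP)
alignment of the proximal region — the part unchanged by the osteotomy — and
the resulting transform is applied to the entire realized anatomy.  Every
realized vertex then gets a signed perpendicular distance to the planned
surface (positive above/outside the plan).  Absolute deviations are binned
into the inspection bands

* very good:    |d| < 0.6 mm
* good:         0.6 <= |d| < 1.2 mm
* acceptable:   1.2 <= |d| < 1.7 mm
* unacceptable: |d| >= 1.7 mm

and a specimen is graded by the band containing the 95th percentile of |d|.
Per-angle plan-vs-result deviations are tabulated as absolute differences
with per-cohort absolute mean and sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh

from .angle_analysis import TibialAngles
from .core_io import SCALAR_CHANNEL, AnatomicFrame, RigidTransform, apply_transform
from .errors import InsufficientDataError, RangeError, ValidationError
from .meshquery import SurfaceQuery

#: Default band edges in mm.
BAND_EDGES = (0.6, 1.2, 1.7)
#: Band labels from best to worst.
BAND_LABELS = ("very_good", "good", "acceptable", "unacceptable")
#: Default proximal crop level for registration: 60 mm below the plateau.
DEFAULT_CROP_BELOW_PLATEAU_MM = 60.0


@dataclass
class DeviationMap:
    """Per-vertex signed distances (mm) of a realized surface to its plan."""

    distances: np.ndarray
    mesh: trimesh.Trimesh  # the registered realized mesh the distances refer to

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float).ravel()
        if len(self.distances) != len(self.mesh.vertices):
            raise ValidationError("one distance per realized vertex required")
        if not np.all(np.isfinite(self.distances)):
            raise ValidationError("deviation map contains non-finite values")
        self.mesh.vertex_attributes[SCALAR_CHANNEL] = self.distances

    def to_frame(self) -> pd.DataFrame:
        d = self.distances
        band = np.digitize(np.abs(d), BAND_EDGES)
        return pd.DataFrame({
            "vertex_id": np.arange(len(d)),
            "d_mm": d,
            "band": [BAND_LABELS[b] for b in band],
        })


@dataclass
class BandSummary:
    """Fractions of vertices per inspection band plus |d| percentiles."""

    edges: tuple
    fractions: dict      # label -> fraction in [0, 1]
    worst_band: str
    percentiles: dict    # {"p50": mm, "p95": mm, "max": mm}

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"band fractions sum to {total}, expected 1")


@dataclass(frozen=True)
class DeviationSummaryRow:
    """Absolute plan-vs-result angle deviations (deg) for one specimen."""

    specimen_id: str
    mpta: float
    medial_slope: float
    lateral_slope: float
    torsion: float

    def __post_init__(self):
        for name in ("mpta", "medial_slope", "lateral_slope", "torsion"):
            if getattr(self, name) < 0:
                raise ValidationError(f"absolute deviation {name} must be >= 0")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def crop_by_level(mesh: trimesh.Trimesh, frame: AnatomicFrame, z_min: float) -> trimesh.Trimesh:
    """Submesh of faces whose vertices all lie at frame-z >= ``z_min``."""
    z = frame.z_of(mesh.vertices)
    keep = np.all(z[mesh.faces] >= z_min, axis=1)
    if not keep.any():
        raise RangeError(f"crop level {z_min:.1f} mm leaves no faces")
    out = mesh.copy()
    out.update_faces(keep)
    out.remove_unreferenced_vertices()
    return out


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform taking src points onto dst points."""
    c_src, c_dst = src.mean(axis=0), dst.mean(axis=0)
    H = (src - c_src).T @ (dst - c_dst)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, c_dst - R @ c_src)


def _principal_axes(points: np.ndarray) -> np.ndarray:
    cov = np.cov((points - points.mean(axis=0)).T)
    _, vecs = np.linalg.eigh(cov)
    axes = vecs[:, ::-1]  # descending variance
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return axes


def best_fit_register(moving: trimesh.Trimesh, fixed: trimesh.Trimesh,
                      max_iter: int = 100, tol: float = 1e-6,
                      sample: int = 2000) -> RigidTransform:
    """Best-fit rigid registration of ``moving`` onto ``fixed``.

    A centroid (and, if it helps, principal-axes) pre-alignment is refined by
    iterative closest-point minimization of the mean squared point-to-surface
    distance.  Convergence: RMS improvement below ``tol`` (mm) or ``max_iter``
    iterations; non-convergence returns the best transform found, with a
    warning.
    """
    query = SurfaceQuery(fixed)
    pts = moving.vertices.view(np.ndarray)
    if len(pts) > sample:
        stride = len(pts) // sample
        pts = pts[::stride]

    def rms(points):
        _, d, _ = query.closest(points)
        return float(np.sqrt(np.mean(d ** 2)))

    # candidate pre-alignments: keep pose (partial overlap), centroid shift,
    # or centroid + principal axes; the lowest-RMS start wins
    t_identity = RigidTransform.identity()
    t_centroid = RigidTransform(np.eye(3),
                                fixed.vertices.mean(axis=0) - moving.vertices.mean(axis=0))
    axes_m = _principal_axes(moving.vertices)
    axes_f = _principal_axes(fixed.vertices)
    R_pca = axes_f @ axes_m.T
    c_m, c_f = moving.vertices.mean(axis=0), fixed.vertices.mean(axis=0)
    t_pca = RigidTransform(R_pca, c_f - R_pca @ c_m)
    current = min((t_identity, t_centroid, t_pca), key=lambda t: rms(t.apply(pts)))

    last = rms(current.apply(pts))
    converged = False
    for _ in range(max_iter):
        warped = current.apply(pts)
        closest, _, _ = query.closest(warped)
        step = _kabsch(warped, closest)
        current = step.compose(current)
        now = rms(current.apply(pts))
        if abs(last - now) < tol:
            converged = True
            break
        last = now
    if not converged:
        from .core_io import warn
        warn(f"ICP did not converge within {max_iter} iterations (RMS {last:.4f} mm)")
    return current


def surface_deviation(realized: trimesh.Trimesh, planned: trimesh.Trimesh,
                      registration: RigidTransform) -> DeviationMap:
    """Signed perpendicular distance of every realized vertex to the plan.

    The registration (estimated on the common proximal region) is applied to
    the entire realized mesh; the sign comes from the planned surface normal
    at the closest point.
    """
    registered = apply_transform(realized, registration)
    signed, _, _ = SurfaceQuery(planned).signed_distance(registered.vertices)
    return DeviationMap(distances=signed, mesh=registered)


# ---------------------------------------------------------------------------
# banding, grading, statistics
# ---------------------------------------------------------------------------

def classify_bands(dev_map: DeviationMap, edges: Sequence[float] = BAND_EDGES) -> BandSummary:
    """Band fractions over |d| with half-open bins, plus a percentile table."""
    d = np.abs(dev_map.distances)
    if len(d) == 0:
        raise ValidationError("empty deviation map")
    bins = np.concatenate([[0.0], np.asarray(edges, dtype=float), [np.inf]])
    counts, _ = np.histogram(d, bins=bins)
    fractions = dict(zip(BAND_LABELS, counts / len(d)))
    worst = max((lab for lab, f in fractions.items() if f > 0),
                key=BAND_LABELS.index)
    percentiles = {
        "p50": float(np.percentile(d, 50)),
        "p95": float(np.percentile(d, 95)),
        "max": float(d.max()),
    }
    return BandSummary(edges=tuple(edges), fractions=fractions,
                       worst_band=worst, percentiles=percentiles)


def grade_specimen(summary: BandSummary) -> str:
    """Specimen grade: the band containing the 95th percentile of |d|."""
    p95 = summary.percentiles["p95"]
    band = int(np.digitize([p95], summary.edges)[0])
    return BAND_LABELS[band]


def angle_deviation_row(planned: TibialAngles, realized: TibialAngles,
                        specimen_id: str) -> DeviationSummaryRow:
    """Absolute per-angle plan-vs-result differences, reported to 2 decimals."""
    def diff(a, b):
        return round(abs(a - b), 2)
    return DeviationSummaryRow(
        specimen_id=str(specimen_id),
        mpta=diff(planned.mpta, realized.mpta),
        medial_slope=diff(planned.medial_slope, realized.medial_slope),
        lateral_slope=diff(planned.lateral_slope, realized.lateral_slope),
        torsion=diff(planned.torsion, realized.torsion),
    )


_ANGLE_COLUMNS = ("mpta", "medial_slope", "lateral_slope", "torsion")


def rows_to_frame(rows: Sequence[DeviationSummaryRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "specimen_id": r.specimen_id,
        **{c: getattr(r, c) for c in _ANGLE_COLUMNS},
    } for r in rows])


def summarize_deviations(rows: Sequence[DeviationSummaryRow]) -> pd.DataFrame:
    """Per-angle absolute mean and sample SD (n-1), rounded to 2 decimals.

    Returns a two-row frame indexed ``abs_mean`` / ``sd``.
    """
    if len(rows) < 2:
        raise InsufficientDataError("at least 2 specimens required for a sample SD")
    df = rows_to_frame(rows)[list(_ANGLE_COLUMNS)]
    out = pd.DataFrame({
        c: [round(float(df[c].mean()), 2), round(float(df[c].std(ddof=1)), 2)]
        for c in _ANGLE_COLUMNS
    }, index=["abs_mean", "sd"])
    return out


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_deviation_map(dev_map: DeviationMap, ply_path=None, csv_path=None) -> None:
    """Write the deviation map as PLY (per-vertex scalar) and/or CSV."""
    from .core_io import write_surface_mesh
    if ply_path is not None:
        write_surface_mesh(dev_map.mesh, ply_path, format="ply")
    if csv_path is not None:
        dev_map.to_frame().to_csv(csv_path, index=False, float_format="%.6f")
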