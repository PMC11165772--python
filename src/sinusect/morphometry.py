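"""Cross-sectional morphometry of an aligned cavity mesh.

The cavity length ``L`` is the anteroposterior extent of the mesh; the 0%
plane passes through the frontmost vertex and the 100% plane through the
rearmost, both perpendicular to the AP (+Y) axis. Cutting planes at fixed
fractions of ``L`` intersect the mesh in one or more polyline loops whose
vertices — the cutting points — are fitted with a single closed periodic
cubic B-spline. Per section, the width ``W`` is the mediolateral (X)
extent of the fitted curve, the height ``H`` the superoinferior (Z)
extent, and the aspect ratio ``AR = W / H``.

When a section intersects several loops (internal air-cell partitions),
the points of all loops are pooled and one envelope curve is fitted; a
``largest_loop_only`` flag restricts fitting to the biggest loop instead.
The 0% and 100% planes are tangent to the mesh and yield degenerate
single-point sections, flagged with ``W = H = 0`` and undefined AR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon

from .core import TriangleMesh

__all__ = [
    "SectionContour",
    "SectionMetrics",
    "SinusProfile",
    "measure_length",
    "cut_section",
    "fit_closed_bspline",
    "section_dims",
    "profile_sinus",
]

AP_AXIS = 1  # +Y anteroposterior
ML_AXIS = 0  # +X mediolateral (width)
SI_AXIS = 2  # +Z superoinferior (height)

#: sample density used for extent queries on the fitted curve
CURVE_SAMPLES = 720

_DEGENERATE_TOL_MM = 1e-6


@dataclass
class SectionContour:
    """Plane-mesh intersection at one length fraction."""

    fraction: int
    plane_position: float
    cutting_points: np.ndarray
    tck: tuple | None = None
    degenerate: bool = False
    n_loops: int = 1

    def curve_points(self, n: int = CURVE_SAMPLES) -> np.ndarray:
        """Sample the fitted closed curve; (n, 3) points in mm."""
        if self.tck is None:
            raise ValueError("no fitted curve on this contour")
        u = np.linspace(0.0, 1.0, n, endpoint=False)
        x, z = interpolate.splev(u, self.tck)
        pts = np.empty((n, 3))
        pts[:, ML_AXIS] = x
        pts[:, AP_AXIS] = self.plane_position
        pts[:, SI_AXIS] = z
        return pts


@dataclass
class SectionMetrics:
    fraction: int
    width_mm: float
    height_mm: float
    aspect_ratio: float  # NaN when degenerate / H == 0
    degenerate: bool = False


@dataclass
class SinusProfile:
    """Length plus the per-fraction metric profile of one sinus."""

    subject: str
    sex: str
    side: str
    length_mm: float
    metrics: list[SectionMetrics] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject,
                "sex": self.sex,
                "side": self.side,
                "fraction": [m.fraction for m in self.metrics],
                "W_mm": [m.width_mm for m in self.metrics],
                "H_mm": [m.height_mm for m in self.metrics],
                "AR": [m.aspect_ratio for m in self.metrics],
                "length_mm": self.length_mm,
            }
        )


def measure_length(mesh: TriangleMesh) -> tuple[float, float, float]:
    """AP length and the 0% / 100% plane positions (mm).

    The 0% plane passes through the minimum-AP vertex (ties broken by
    minimum SI then minimum ML coordinate), the 100% plane through the
    maximum-AP vertex.
    """
    if mesh.n_vertices == 0:
        raise ValueError("empty mesh")
    y = mesh.vertices[:, AP_AXIS]
    y0, y1 = float(y.min()), float(y.max())
    if y1 - y0 <= _DEGENERATE_TOL_MM:
        raise ValueError("mesh has zero anteroposterior extent")
    return y1 - y0, y0, y1


def _loop_split(points: np.ndarray, segments: np.ndarray) -> list[np.ndarray]:
    """Group intersection points into connected loops via segment adjacency."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    n = len(points)
    adj = coo_matrix(
        (np.ones(len(segments)), (segments[:, 0], segments[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    return [np.flatnonzero(labels == i) for i in range(n_comp)]


def cut_section(
    mesh: TriangleMesh,
    fraction: int,
    length_info: tuple[float, float, float] | None = None,
    largest_loop_only: bool = False,
) -> SectionContour:
    """Intersect the cutting plane at ``fraction`` percent with the mesh.

    Cutting points are the plane-edge intersection vertices, ordered by
    polar angle about their centroid in the cutting plane. At tangent
    planes (0%, 100%) a degenerate single-point contour is returned.
    """
    if fraction < 0 or fraction > 100:
        raise ValueError("fraction must be in [0, 100]")
    length, y0, y1 = length_info if length_info is not None else measure_length(mesh)
    y_cut = y0 + length * fraction / 100.0

    verts = mesh.vertices
    d = verts[:, AP_AXIS] - y_cut
    # nudge vertices lying exactly on the plane so every face edge either
    # crosses cleanly or not at all
    d = np.where(np.abs(d) < 1e-9, 1e-9, d)
    if fraction in (0, 100) or np.all(d >= -_DEGENERATE_TOL_MM) or np.all(
        d <= _DEGENERATE_TOL_MM
    ):
        # tangent plane: single extreme point, ties broken (AP, SI, ML)
        sign = 1.0 if fraction <= 50 else -1.0
        keys = np.lexsort(
            (verts[:, ML_AXIS], verts[:, SI_AXIS], sign * verts[:, AP_AXIS])
        )
        apex = verts[keys[0]]
        return SectionContour(
            fraction, y_cut, apex[None, :].copy(), degenerate=True, n_loops=0
        )

    tri_d = d[mesh.faces]
    crossing = (tri_d.min(axis=1) < 0) & (tri_d.max(axis=1) > 0)
    if not crossing.any():
        raise ValueError(
            f"mesh not contiguous along AP axis: empty section at {fraction}%"
        )

    # unique crossing edges -> one intersection point each
    faces = mesh.faces[crossing]
    edges = faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    edges = np.sort(edges, axis=1)
    cross_edge = d[edges[:, 0]] * d[edges[:, 1]] < 0
    face_ids = np.repeat(np.arange(len(faces)), 3)[cross_edge]
    edges = edges[cross_edge]
    uniq_edges, inverse = np.unique(edges, axis=0, return_inverse=True)
    a, b = uniq_edges[:, 0], uniq_edges[:, 1]
    t = d[a] / (d[a] - d[b])
    points = verts[a] + t[:, None] * (verts[b] - verts[a])
    points[:, AP_AXIS] = y_cut  # exact by construction; pin for tolerance

    # per-face segments connect the two crossing-edge points of each face
    segs: list[tuple[int, int]] = []
    order = np.argsort(face_ids, kind="stable")
    fi, pi = face_ids[order], inverse[order]
    start = 0
    while start < len(fi):
        stop = start
        while stop < len(fi) and fi[stop] == fi[start]:
            stop += 1
        ids = np.unique(pi[start:stop])
        if len(ids) == 2:
            segs.append((ids[0], ids[1]))
        start = stop
    segments = np.asarray(segs, dtype=np.int64).reshape(-1, 2)

    n_loops = 1
    if len(segments):
        loops = _loop_split(points, segments)
        loops = [lp for lp in loops if len(lp) >= 3]
        n_loops = max(len(loops), 1)
        if largest_loop_only and len(loops) > 1:
            areas = []
            for lp in loops:
                xz = points[np.ix_(lp, [ML_AXIS, SI_AXIS])]
                areas.append(ConvexHull(xz).volume if len(lp) >= 3 else 0.0)
            points = points[loops[int(np.argmax(areas))]]

    # order pooled points by polar angle about the in-plane centroid
    xz = points[:, [ML_AXIS, SI_AXIS]]
    centroid = xz.mean(axis=0)
    angles = np.arctan2(xz[:, 1] - centroid[1], xz[:, 0] - centroid[0])
    points = points[np.argsort(angles, kind="stable")]
    return SectionContour(fraction, y_cut, points, n_loops=n_loops)


def _dedupe_ring(xz: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    """Drop consecutive (cyclically) duplicate points."""
    keep = np.ones(len(xz), dtype=bool)
    diff = np.linalg.norm(xz - np.roll(xz, 1, axis=0), axis=1)
    keep[diff <= tol] = False
    if not keep.any():
        keep[0] = True
    return xz[keep]


def _bridge_gaps(xz: np.ndarray, factor: float = 3.0) -> np.ndarray:
    """Insert chord points into unusually large gaps of the ordered ring.

    Open cut loops (from boundary clipping) leave a long straight span the
    closed curve must cross; without support points an interpolating
    periodic cubic bulges far outside the section there. Gaps longer than
    ``factor`` times the mean spacing are subdivided along their chord.
    """
    nxt = np.roll(xz, -1, axis=0)
    gaps = np.linalg.norm(nxt - xz, axis=1)
    mean_gap = gaps.mean()
    if not np.any(gaps > factor * mean_gap):
        return xz
    pieces = []
    for i in range(len(xz)):
        pieces.append(xz[i : i + 1])
        if gaps[i] > factor * mean_gap:
            n_sub = min(int(np.ceil(gaps[i] / mean_gap)), 64)
            t = np.linspace(0.0, 1.0, n_sub + 1)[1:-1, None]
            pieces.append(xz[i] + t * (nxt[i] - xz[i]))
    return np.vstack(pieces)


def fit_closed_bspline(
    contour: SectionContour, smoothing: float = 0.0
) -> SectionContour:
    """Fit a periodic cubic B-spline through the ordered cutting points.

    ``smoothing = 0`` interpolates the points exactly; larger values
    smooth (scipy ``splprep`` ``s`` parameter). If the angular ordering
    produces a self-intersecting polygon, the fit falls back to the convex
    hull of the points with a warning.
    """
    if contour.degenerate:
        return contour
    xz = contour.cutting_points[:, [ML_AXIS, SI_AXIS]]
    xz = _dedupe_ring(xz)
    if len(xz) < 4:
        return SectionContour(
            contour.fraction,
            contour.plane_position,
            contour.cutting_points,
            degenerate=True,
            n_loops=contour.n_loops,
        )
    if not Polygon(xz).is_valid:
        warnings.warn(
            f"section at {contour.fraction}%: angular ordering self-intersects; "
            "falling back to convex-hull ordering",
            stacklevel=2,
        )
        hull = ConvexHull(xz)
        xz = xz[hull.vertices]
        if len(xz) < 4:
            return SectionContour(
                contour.fraction,
                contour.plane_position,
                contour.cutting_points,
                degenerate=True,
                n_loops=contour.n_loops,
            )
    xz = _bridge_gaps(xz)
    ring = np.vstack([xz, xz[:1]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # splprep chatters about knot counts
        tck, _ = interpolate.splprep(
            [ring[:, 0], ring[:, 1]], per=True, k=3, s=smoothing
        )
    return SectionContour(
        contour.fraction,
        contour.plane_position,
        contour.cutting_points,
        tck=tck,
        n_loops=contour.n_loops,
    )


def section_dims(contour: SectionContour) -> SectionMetrics:
    """Width / height / aspect ratio of a fitted section curve.

    Degenerate sections report ``W = H = 0`` with ``AR = NaN``.
    """
    if contour.degenerate or contour.tck is None:
        return SectionMetrics(contour.fraction, 0.0, 0.0, float("nan"), True)
    pts = contour.curve_points()
    width = float(pts[:, ML_AXIS].max() - pts[:, ML_AXIS].min())
    height = float(pts[:, SI_AXIS].max() - pts[:, SI_AXIS].min())
    ar = width / height if height > 0 else float("nan")
    return SectionMetrics(contour.fraction, width, height, ar)


def profile_sinus(
    mesh: TriangleMesh,
    subject: str = "",
    sex: str = "",
    side: str = "",
    fraction_step: int = 10,
    smoothing: float = 0.0,
    largest_loop_only: bool = False,
) -> SinusProfile:
    """Full length + per-fraction metric profile of an aligned cavity mesh."""
    if fraction_step <= 0 or 100 % fraction_step:
        raise ValueError("fraction step must divide 100")
    length_info = measure_length(mesh)
    metrics = []
    for fraction in range(0, 101, fraction_step):
        contour = cut_section(
            mesh, fraction, length_info, largest_loop_only=largest_loop_only
        )
        contour = fit_closed_bspline(contour, smoothing=smoothing)
        metrics.append(section_dims(contour))
    return SinusProfile(subject, sex, side, length_info[0], metrics)
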