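"""Planar contour handling and ventricular volume primitives.

A traced echocardiographic border is an ordered polygon of points in
centimetres in a view-local 2D frame.  Apical (AP4CH/AP2CH) contours carry
two base landmarks marking the mitral-annulus endpoints; the ventricular
long axis runs from the midpoint of that base segment to the contour vertex
farthest from it.  Volumes follow the biplane method of disks: the cavity is
cut into ``n_disks`` slabs of equal height along the long axis and each slab
is treated as an elliptical disk whose two diameters are the chord widths of
the two orthogonal apical contours at the slab midpoint,

    V = (pi/4) * sum_i a_i * b_i * h      [ml, with lengths in cm]

The parasternal short-axis (PSAX) view contributes the mean wall thickness
``t = sqrt(A1/pi) - sqrt(A2/pi)``, the difference of the equivalent-circle
radii of the epicardial (A1) and endocardial (A2) areas.

Chord widths are measured as the total length of the slicing line's
intersection with the polygon interior (even-odd rule over edge crossings),
which is exact for simple polygons and tolerates mild non-convexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import ContourError, GeometryError, TracingError

VIEWS = ("AP4CH", "AP2CH", "PSAX", "PLAX")
BOUNDARIES = ("endocardium", "epicardium")
PHASES = ("end-diastole", "end-systole")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlanarContour:
    """Ordered polygon of tracing points (cm) in one echo view.

    Parameters
    ----------
    points
        (N, 2) array-like of x, y coordinates in cm, N >= 3.  The polygon is
        closed implicitly from the last point back to the first.
    view
        One of ``AP4CH``, ``AP2CH``, ``PSAX``, ``PLAX``.
    boundary
        ``endocardium`` or ``epicardium``.
    phase
        ``end-diastole`` (default) or ``end-systole``.
    base_indices
        Optional pair of vertex indices marking the mitral-annulus (base)
        endpoints; required by apical long-axis operations.
    """

    points: np.ndarray
    view: str
    boundary: str
    phase: str = "end-diastole"
    base_indices: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContourError(f"points must be (N, 2), got shape {pts.shape}")
        if len(pts) < 3:
            raise ContourError(f"contour needs >= 3 points, got {len(pts)}")
        if not np.all(np.isfinite(pts)):
            raise ContourError("contour contains non-finite coordinates")
        if self.view not in VIEWS:
            raise ContourError(f"unknown view {self.view!r}; expected one of {VIEWS}")
        if self.boundary not in BOUNDARIES:
            raise ContourError(
                f"unknown boundary {self.boundary!r}; expected one of {BOUNDARIES}")
        if self.phase not in PHASES:
            raise ContourError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        object.__setattr__(self, "points", pts)
        poly = _ShapelyPolygon(pts)
        if not poly.is_valid or poly.area <= 0.0:
            raise ContourError(
                f"{self.view} {self.boundary} contour is not a simple polygon "
                "(self-intersecting or degenerate)")
        if self.base_indices is not None:
            i, j = self.base_indices
            n = len(pts)
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ContourError(
                    f"base_indices {self.base_indices} invalid for contour of {n} points")
            object.__setattr__(self, "base_indices", (int(i), int(j)))

    def scaled(self, k: float) -> "PlanarContour":
        """Contour with all coordinates multiplied by ``k``."""
        return replace(self, points=self.points * float(k))


@dataclass(frozen=True)
class BiplaneTracing:
    """Apical biplane tracing set: endocardium in AP4CH + AP2CH, optionally
    the epicardium in both views as well."""

    ap4ch_endo: PlanarContour
    ap2ch_endo: PlanarContour
    ap4ch_epi: Optional[PlanarContour] = None
    ap2ch_epi: Optional[PlanarContour] = None

    def __post_init__(self) -> None:
        for c, view in ((self.ap4ch_endo, "AP4CH"), (self.ap2ch_endo, "AP2CH")):
            if c.view != view or c.boundary != "endocardium":
                raise ContourError(f"expected {view} endocardium, got {c.view} {c.boundary}")
            if c.base_indices is None:
                raise ContourError(f"{view} endocardial contour is missing base landmarks")
        for endo, epi, view in ((self.ap4ch_endo, self.ap4ch_epi, "AP4CH"),
                                (self.ap2ch_endo, self.ap2ch_epi, "AP2CH")):
            if epi is not None:
                if epi.view != view or epi.boundary != "epicardium":
                    raise ContourError(
                        f"expected {view} epicardium, got {epi.view} {epi.boundary}")
                if polygon_area(epi) <= polygon_area(endo):
                    raise TracingError(
                        f"{view} epicardial area does not exceed endocardial area")

    @property
    def has_epicardium(self) -> bool:
        return self.ap4ch_epi is not None and self.ap2ch_epi is not None


@dataclass(frozen=True)
class PsaxTracing:
    """Parasternal short-axis tracing pair: endocardium (A2) inside the
    epicardium (A1)."""

    endo: PlanarContour
    epi: PlanarContour

    def __post_init__(self) -> None:
        if self.endo.boundary != "endocardium" or self.epi.boundary != "epicardium":
            raise ContourError("PsaxTracing requires an endocardium and an epicardium")
        a1, a2 = polygon_area(self.epi), polygon_area(self.endo)
        if not (a1 > a2 > 0.0):
            raise TracingError(
                f"PSAX areas must satisfy epi > endo > 0, got A1={a1:.4g}, A2={a2:.4g}")

    @property
    def a1(self) -> float:
        """Epicardial area A1 (cm^2)."""
        return polygon_area(self.epi)

    @property
    def a2(self) -> float:
        """Endocardial area A2 (cm^2)."""
        return polygon_area(self.endo)


@dataclass(frozen=True)
class LinearMeasures:
    """1D end-diastolic calipers (cm): septal wall (IVSd), internal diameter
    (LVIDd), posterior wall (PWTd), optionally the systolic diameter LVIDs."""

    ivsd: float
    lvidd: float
    pwtd: float
    lvids: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("ivsd", "lvidd", "pwtd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise GeometryError(f"{name} must be positive and finite, got {v}")
        if self.lvids is not None:
            if not np.isfinite(self.lvids) or self.lvids <= 0:
                raise GeometryError(f"lvids must be positive and finite, got {self.lvids}")
            if self.lvids >= self.lvidd:
                raise GeometryError(
                    f"lvids ({self.lvids}) must be smaller than lvidd ({self.lvidd})")


@dataclass(frozen=True)
class DiskStack:
    """Paired disk diameters from the two apical views plus the common slab
    geometry; the input of :func:`biplane_disk_volume`."""

    diam_a: np.ndarray
    diam_b: np.ndarray
    disk_height: float
    n_disks: int
    long_axis_length: float

    def __post_init__(self) -> None:
        a = np.asarray(self.diam_a, dtype=float)
        b = np.asarray(self.diam_b, dtype=float)
        if len(a) != self.n_disks or len(b) != self.n_disks:
            raise GeometryError(
                f"diameter lists ({len(a)}, {len(b)}) must both have n_disks={self.n_disks}")
        if np.any(a < 0) or np.any(b < 0):
            raise GeometryError("disk diameters must be >= 0")
        if self.long_axis_length <= 0 or self.n_disks < 1:
            raise GeometryError("long_axis_length must be > 0 and n_disks >= 1")
        if not np.isclose(self.disk_height, self.long_axis_length / self.n_disks):
            raise GeometryError("disk_height must equal long_axis_length / n_disks")
        object.__setattr__(self, "diam_a", a)
        object.__setattr__(self, "diam_b", b)


@dataclass(frozen=True)
class LongAxis:
    """Ventricular long axis: from the mitral base-segment midpoint to the
    apex (the contour vertex farthest from that midpoint)."""

    base_mid: np.ndarray
    apex: np.ndarray
    length: float
    direction: np.ndarray = field(init=False)  # unit vector base -> apex

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise GeometryError("long axis has zero length")
        object.__setattr__(self, "direction",
                           (np.asarray(self.apex) - np.asarray(self.base_mid)) / self.length)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def polygon_area(contour: PlanarContour) -> float:
    """Absolute shoelace area of the traced polygon in cm^2.

    Orientation-independent.  Raises :class:`ContourError` for degenerate
    (collinear) contours, which the :class:`PlanarContour` constructor
    already rejects.
    """
    pts = contour.points
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area <= 0.0:
        raise ContourError("degenerate contour with zero area")
    return float(area)


def long_axis(contour: PlanarContour) -> LongAxis:
    """Long axis of an apical contour.

    The axis runs from the midpoint of the base (mitral-annulus) segment to
    the vertex farthest from that midpoint.  Requires ``base_indices``.
    """
    if contour.base_indices is None:
        raise ContourError(
            f"{contour.view} {contour.boundary} contour has no base landmarks; "
            "long axis undefined")
    i, j = contour.base_indices
    base_mid = 0.5 * (contour.points[i] + contour.points[j])
    d = np.linalg.norm(contour.points - base_mid, axis=1)
    dmax = float(np.max(d))
    if dmax <= 0.0:
        raise GeometryError("long axis has zero length")
    # ties in distance (e.g. a semicircular cavity, where every vertex is
    # equidistant from the base midpoint) break towards the vertex farthest
    # from the base line itself
    cand = np.flatnonzero(d >= dmax * (1.0 - 1e-9))
    if len(cand) > 1:
        bvec = contour.points[j] - contour.points[i]
        nrm = np.linalg.norm(bvec)
        if nrm > 0:
            n = np.array([-bvec[1], bvec[0]]) / nrm
            perp = np.abs((contour.points[cand] - base_mid) @ n)
            k = int(cand[np.argmax(perp)])
        else:
            k = int(cand[0])
    else:
        k = int(cand[0])
    return LongAxis(base_mid=base_mid, apex=contour.points[k], length=float(d[k]))


def _chords_at_depths(contour: PlanarContour, axis: LongAxis,
                      depths: np.ndarray) -> np.ndarray:
    """Total in-polygon chord width perpendicular to ``axis`` at each depth
    (cm from the base midpoint towards the apex).

    Even-odd crossing rule on the closed polygon, vectorised over depths.
    Depths outside the contour yield 0.
    """
    u = axis.direction
    # axis frame: xi along the axis (depth), eta transverse
    rel = contour.points - axis.base_mid
    xi = rel @ u
    eta = rel @ np.array([-u[1], u[0]])
    xi2, eta2 = np.roll(xi, -1), np.roll(eta, -1)

    s = np.asarray(depths, dtype=float)[:, None]            # (S, 1)
    # half-open convention: a vertex exactly on the slicing line is counted
    # on exactly one of its two edges, so crossings always pair up
    crosses = (xi[None, :] <= s) != (xi2[None, :] <= s)     # (S, E)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (s - xi[None, :]) / (xi2 - xi)[None, :]
    eta_cross = eta[None, :] + frac * (eta2 - eta)[None, :]

    widths = np.zeros(len(s))
    for r in range(len(s)):
        e = np.sort(eta_cross[r, crosses[r]])
        if len(e) >= 2:
            widths[r] = float(np.sum(e[1::2] - e[0::2]))
    return widths


def disk_diameters(contour: PlanarContour, axis: LongAxis, n_disks: int,
                   fractions: Optional[Sequence[float]] = None) -> np.ndarray:
    """Chord widths (cm) of ``contour`` perpendicular to the long axis.

    By default the axis is divided into ``n_disks`` equal slabs from base to
    apex and the chord is evaluated at each slab midpoint.  ``fractions``
    overrides the sampling positions (as fractions of the axis length, used
    when two views of different lengths share common slab fractions).
    """
    if n_disks < 1:
        raise GeometryError(f"n_disks must be >= 1, got {n_disks}")
    if axis.length <= 0:
        raise GeometryError("axis length is zero")
    if fractions is None:
        fractions = (np.arange(n_disks) + 0.5) / n_disks
    fr = np.asarray(fractions, dtype=float)
    if len(fr) != n_disks:
        raise GeometryError("fractions must have length n_disks")
    return _chords_at_depths(contour, axis, fr * axis.length)


def biplane_stack(view_a: PlanarContour, view_b: PlanarContour,
                  n_disks: int = 20) -> DiskStack:
    """Build the biplane disk stack from two orthogonal apical contours.

    When the two long-axis lengths differ, the common axis length is the
    longer of the two and each view's chords are sampled at the common slab
    fractions of its own axis.
    """
    ax_a, ax_b = long_axis(view_a), long_axis(view_b)
    length = max(ax_a.length, ax_b.length)
    fr = (np.arange(n_disks) + 0.5) / n_disks
    da = disk_diameters(view_a, ax_a, n_disks, fractions=fr)
    db = disk_diameters(view_b, ax_b, n_disks, fractions=fr)
    return DiskStack(diam_a=da, diam_b=db, disk_height=length / n_disks,
                     n_disks=n_disks, long_axis_length=length)


def biplane_disk_volume(stack: DiskStack) -> float:
    """Biplane method-of-disks volume in ml: ``V = (pi/4) * sum a_i b_i * h``."""
    return float(np.pi / 4.0 * np.sum(stack.diam_a * stack.diam_b) * stack.disk_height)


def mean_wall_thickness_psax(psax: PsaxTracing) -> float:
    """Mean wall thickness ``t`` (cm) from the PSAX tracing pair.

    ``t = sqrt(A1/pi) - sqrt(A2/pi)`` — the difference of the
    equivalent-circle radii of the epicardial and endocardial areas.
    """
    return mean_wall_thickness_from_areas(psax.a1, psax.a2)


def mean_wall_thickness_from_areas(a1: float, a2: float) -> float:
    """Mean wall thickness from explicit PSAX areas (cm^2)."""
    if not (a1 > a2 > 0.0):
        raise TracingError(
            f"inverted or degenerate PSAX tracing: A1={a1:.4g} must exceed A2={a2:.4g} > 0")
    return float(np.sqrt(a1 / np.pi) - np.sqrt(a2 / np.pi))


def teichholz_volume(d: float) -> float:
    """Teichholz 1D left-ventricular volume (ml) from the internal diameter
    ``d`` (cm): ``V = 7.0 d^3 / (2.4 + d)``."""
    if not np.isfinite(d) or d <= 0.0:
        raise GeometryError(f"internal diameter must be positive, got {d}")
    return float(7.0 * d**3 / (2.4 + d))


def ejection_fraction(edv: float, esv: float) -> float:
    """Ejection fraction in percent: ``100 (EDV - ESV) / EDV``."""
    if edv <= 0:
        raise GeometryError(f"EDV must be positive, got {edv}")
    if esv < 0 or esv > edv:
        raise GeometryError(f"ESV must lie in [0, EDV], got ESV={esv}, EDV={edv}")
    return float(100.0 * (edv - esv) / edv)
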