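"""Cell-shape parameter Psi and outline tangent geometry.

A cell outline is a simple closed polygon of ~150 nodes.  Shape
irregularity is quantified by comparing the outline with an area-matched
ellipse: construct the largest ellipse inside the outline and the
smallest ellipse outside it, interpolate between them until the cell
area outside the ellipse (``O``) balances the ellipse area outside the
cell (``I``), and report

    Psi = (O + I) / T

where ``T`` is the cell area.  ``Psi`` is 0 for a perfect ellipse and
approaches 2 for extreme shapes; it is invariant under translation,
rotation and uniform scaling.  The balancing condition ``O = I`` implies
the intermediate ellipse has the same area as the cell.

Implementation notes: the inner/outer ellipses share the orientation and
axis ratio of an algebraic least-squares ellipse fit to the outline
vertices, scaled about its centre; the inner scale is found by bisection
on polygon containment, the outer scale directly from the largest
normalised vertex radius (ellipses are convex, so covering the vertices
covers the polygon).  Boolean areas use polygon clipping with the
ellipse discretised at 256 vertices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.prepared import prep
from skimage.measure import EllipseModel

from .circular import normalize_angle

__all__ = [
    "CellOutline",
    "EllipseParams",
    "ShapeResult",
    "tangent_at_node",
    "outward_normal_at_node",
    "fit_base_ellipse",
    "inner_outer_ellipses",
    "interpolated_ellipse",
    "overlap_areas",
    "shape_psi",
]

ELLIPSE_VERTICES = 256  # discretisation used for boolean area operations


class GeometryError(ValueError):
    """Raised for degenerate or invalid outline geometry."""


@dataclass(frozen=True)
class CellOutline:
    """Simple closed polygon of outline nodes, counter-clockwise."""

    vertices: np.ndarray  # (n, 2), not repeating the first vertex

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise GeometryError("vertices must have shape (n, 2)")
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 8:
            raise GeometryError("outline needs at least 8 vertices")
        poly = Polygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError("outline must be a simple polygon with positive area")
        # enforce counter-clockwise orientation
        if not poly.exterior.is_ccw:
            v = v[::-1].copy()
        object.__setattr__(self, "vertices", v)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclass(frozen=True)
class EllipseParams:
    """Centre, semi-axes (major >= minor) and major-axis orientation (degrees)."""

    center: Tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float  # degrees, axis orientation is 180-periodic

    def __post_init__(self):
        if not self.semi_major >= self.semi_minor > 0:
            raise GeometryError("require semi_major >= semi_minor > 0")

    @property
    def area(self) -> float:
        return math.pi * self.semi_major * self.semi_minor

    def boundary_points(self, n: int = ELLIPSE_VERTICES) -> np.ndarray:
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        th = math.radians(self.orientation)
        ct, st = math.cos(th), math.sin(th)
        x = self.semi_major * np.cos(t)
        y = self.semi_minor * np.sin(t)
        return np.column_stack(
            (self.center[0] + ct * x - st * y, self.center[1] + st * x + ct * y)
        )

    def polygon(self, n: int = ELLIPSE_VERTICES) -> Polygon:
        return Polygon(self.boundary_points(n))

    def normalized_radius(self, points: np.ndarray) -> np.ndarray:
        """r <= 1 for points inside the ellipse, 1 on it, > 1 outside."""
        p = np.asarray(points, dtype=float) - np.asarray(self.center)
        th = math.radians(self.orientation)
        ct, st = math.cos(th), math.sin(th)
        u = ct * p[..., 0] + st * p[..., 1]
        v = -st * p[..., 0] + ct * p[..., 1]
        return np.hypot(u / self.semi_major, v / self.semi_minor)

    def scaled(self, factor: float) -> "EllipseParams":
        return EllipseParams(
            center=self.center,
            semi_major=self.semi_major * factor,
            semi_minor=self.semi_minor * factor,
            orientation=self.orientation,
        )


@dataclass(frozen=True)
class ShapeResult:
    """Psi with its constituent areas and the three ellipses."""

    psi: float
    O: float
    I: float
    T: float
    inner: EllipseParams
    outer: EllipseParams
    intermediate: EllipseParams
    t_interp: float
    warnings: Tuple[str, ...] = ()


def tangent_at_node(outline: CellOutline, node_index: int) -> float:
    """Tangent direction (degrees) at a node: the chord through its neighbours."""
    v = outline.vertices
    n = v.shape[0]
    i = node_index % n
    prev_v, next_v = v[(i - 1) % n], v[(i + 1) % n]
    chord = next_v - prev_v
    if np.hypot(*chord) < 1e-12:
        raise GeometryError(f"duplicate adjacent vertices around node {node_index}")
    return normalize_angle(math.degrees(math.atan2(chord[1], chord[0])))


def outward_normal_at_node(outline: CellOutline, node_index: int) -> float:
    """Outward normal direction (degrees): tangent - 90 for a CCW outline."""
    return normalize_angle(tangent_at_node(outline, node_index) - 90.0)


def fit_base_ellipse(outline: CellOutline) -> EllipseParams:
    """Algebraic least-squares ellipse through the outline vertices."""
    model = EllipseModel.from_estimate(outline.vertices)
    if not model:
        raise GeometryError("ellipse fit to outline vertices failed")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if b > a:
        a, b = b, a
        theta += math.pi / 2.0
    theta_deg = math.degrees(theta) % 180.0
    return EllipseParams(center=(xc, yc), semi_major=a, semi_minor=b, orientation=theta_deg)


def _verify_containment(outline: CellOutline, inner: EllipseParams, outer: EllipseParams):
    tol = 1e-6
    r_out = outer.normalized_radius(outline.vertices)
    if np.any(r_out > 1.0 + 1e-9):
        raise GeometryError("outer ellipse does not cover all outline vertices")
    pts = inner.boundary_points(512)
    poly = outline.polygon.buffer(tol * math.sqrt(outline.area))
    if not Polygon(pts).within(poly):
        raise GeometryError("inner ellipse escapes the outline")


def inner_outer_ellipses(
    outline: CellOutline, verify: bool = True
) -> Tuple[EllipseParams, EllipseParams]:
    """Largest inside / smallest outside ellipse of the base-fit family.

    Both ellipses are scalings of the least-squares base ellipse about
    its centre.  The outer factor is the largest normalised vertex
    radius; the inner factor is found by ~50 bisection steps on
    containment of the discretised ellipse in the polygon.
    """
    base = fit_base_ellipse(outline)
    poly = outline.polygon
    radii = base.normalized_radius(outline.vertices)
    outer_factor = float(np.max(radii))

    prepared = prep(poly)
    if not prepared.contains(Point(base.center)):
        raise GeometryError("base ellipse centre lies outside the outline")
    lo, hi = 0.0, float(np.min(radii))
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if prepared.contains(base.scaled(mid).polygon()):
            lo = mid
        else:
            hi = mid
    inner = base.scaled(lo if lo > 0 else hi * 0.5)
    outer = base.scaled(outer_factor)
    if verify:
        _verify_containment(outline, inner, outer)
    return inner, outer


def interpolated_ellipse(
    inner: EllipseParams, outer: EllipseParams, t: float
) -> EllipseParams:
    """Parameter-wise linear interpolation between two ellipses.

    ``t = 0`` gives the inner ellipse, ``t = 1`` the outer.  Orientation
    is interpolated along the shortest angular path of the 180-periodic
    axis direction.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must be in [0, 1]")
    d_orient = (outer.orientation - inner.orientation + 90.0) % 180.0 - 90.0
    return EllipseParams(
        center=(
            (1 - t) * inner.center[0] + t * outer.center[0],
            (1 - t) * inner.center[1] + t * outer.center[1],
        ),
        semi_major=(1 - t) * inner.semi_major + t * outer.semi_major,
        semi_minor=(1 - t) * inner.semi_minor + t * outer.semi_minor,
        orientation=inner.orientation + t * d_orient,
    )


def overlap_areas(
    outline: CellOutline, ellipse: EllipseParams
) -> Tuple[float, float, float]:
    """Mismatch areas between a cell outline and an ellipse.

    Returns ``(O, I, T)``: cell area outside the ellipse, ellipse area
    outside the cell, and total cell area.
    """
    cell = outline.polygon
    if cell.area <= 0:
        raise GeometryError("degenerate polygon")
    ell = ellipse.polygon()
    O = cell.difference(ell).area
    I = ell.difference(cell).area
    return O, I, cell.area


def shape_psi(outline: CellOutline, tol_factor: float = 1e-3, max_iter: int = 60) -> ShapeResult:
    """Compute the shape parameter Psi of an outline.

    Bisects the interpolation coordinate ``t`` until ``|O - I|`` is below
    ``tol_factor * T`` (the area-matching condition), then reports
    ``Psi = (O + I)/T``.  If the residual never changes sign the result
    minimising ``|O - I|`` is returned with a warning flag.
    """
    inner, outer = inner_outer_ellipses(outline)
    T = outline.area
    warnings: List[str] = []

    def residual(t):
        O, I, _ = overlap_areas(outline, interpolated_ellipse(inner, outer, t))
        return O, I, O - I

    lo_t, hi_t = 0.0, 1.0
    O_lo, I_lo, g_lo = residual(lo_t)
    O_hi, I_hi, g_hi = residual(hi_t)
    best = min(
        [(abs(g_lo), lo_t, O_lo, I_lo), (abs(g_hi), hi_t, O_hi, I_hi)]
    )
    if g_lo < 0 or g_hi > 0:
        # no bracketing: fall back to a scan minimising |O - I|
        warnings.append("no sign change of O - I on [0, 1]; reporting minimiser")
        for t in np.linspace(0.0, 1.0, 41):
            O, I, g = residual(t)
            if abs(g) < best[0]:
                best = (abs(g), t, O, I)
    else:
        t_mid, O_mid, I_mid = lo_t, O_lo, I_lo
        for _ in range(max_iter):
            t_mid = 0.5 * (lo_t + hi_t)
            O_mid, I_mid, g_mid = residual(t_mid)
            if abs(g_mid) < best[0]:
                best = (abs(g_mid), t_mid, O_mid, I_mid)
            if abs(g_mid) <= tol_factor * T:
                break
            if g_mid > 0:
                lo_t = t_mid
            else:
                hi_t = t_mid
        if best[0] > tol_factor * T:
            warnings.append("O = I balancing did not reach tolerance")

    _, t_star, O, I = best
    return ShapeResult(
        psi=(O + I) / T,
        O=O,
        I=I,
        T=T,
        inner=inner,
        outer=outer,
        intermediate=interpolated_ellipse(inner, outer, t_star),
        t_interp=t_star,
        warnings=tuple(warnings),
    )
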