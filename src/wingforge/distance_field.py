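"""Signed distance and sizing fields derived from a region partition.

The mesh generator needs callable geometry: a signed distance
``d(x, y)`` that is negative inside the meshable domain, a relative
sizing field ``h(x, y)``, the bounding box, and the fixed points pinned
on subdomain interfaces.  All of these are built from the region labels:
the "inside" set is the union of all subdomain pixels, all hole pixels
(discontinuities are meshed through and excised element-wise afterwards)
and the internal border walls; only the outer wall is the zero level
set.  ``d`` at pixel centres is the exact Euclidean distance transform,
extended to arbitrary points by bilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .errors import ValidationError
from .image_io import GridPoint
from .region_detect import BORDER, OUTSIDE, RegionMap, interface_pixels

__all__ = [
    "DistanceField",
    "FixedPointSet",
    "build_signed_distance",
    "build_sizing",
    "select_fixed_points",
    "select_boundary_fixed_points",
    "combine_fixed_points",
    "inside_mask",
]


def inside_mask(region: RegionMap) -> np.ndarray:
    """Boolean mask of the meshable union: subdomains, holes, and
    internal border pixels (walls between regions that are not the
    outer outline)."""
    labels = region.labels
    interior = (labels >= 1) | (labels <= -2)  # subdomains + holes
    border = labels == BORDER
    outside = labels == OUTSIDE
    # outer wall = border pixels 4-adjacent to an OUTSIDE pixel (or on
    # the image frame); everything else on the border net is internal
    adj_out = np.zeros_like(outside)
    adj_out[:-1, :] |= outside[1:, :]
    adj_out[1:, :] |= outside[:-1, :]
    adj_out[:, :-1] |= outside[:, 1:]
    adj_out[:, 1:] |= outside[:, :-1]
    frame = np.zeros_like(outside)
    frame[0, :] = frame[-1, :] = frame[:, 0] = frame[:, -1] = True
    outer_wall = border & (adj_out | frame)
    return interior | (border & ~outer_wall)


@dataclass
class DistanceField:
    """Signed distance + sizing callables over the image frame.

    ``d(points)`` takes an (n, 2) array of (x, y) and returns signed
    distances in pixel units, negative inside; ``h(points)`` returns
    the relative local edge length (dimensionless multiplier of h0).
    ``bbox`` is ``((xmin, ymin), (xmax, ymax))`` — the frame extents.
    """

    d: object
    h: object
    bbox: tuple[tuple[float, float], tuple[float, float]]
    grid: np.ndarray = field(repr=False, default=None)  # pixel-centre d values

    def with_sizing(self, h) -> "DistanceField":
        return DistanceField(d=self.d, h=h, bbox=self.bbox, grid=self.grid)


@dataclass(frozen=True)
class FixedPointSet:
    """Planar points pinned as mesh nodes (interface tracery)."""

    points: np.ndarray  # (n, 2) float

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


class _GridInterp:
    """Bilinear interpolation of a pixel-centre grid in (x, y) plane
    coordinates, clamped to the frame with Euclidean growth outside it
    so points that stray past the bounding box still see a positive,
    increasing distance."""

    def __init__(self, grid: np.ndarray, n_rows: int, n_cols: int):
        # grid indexed [row, col]; x = col, y = (n_rows-1) - row
        self._interp = RegularGridInterpolator(
            (np.arange(n_rows), np.arange(n_cols)),
            grid,
            method="linear",
            bounds_error=False,
            fill_value=None,
        )
        self.n_rows = n_rows
        self.n_cols = n_cols

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x, y = pts[:, 0], pts[:, 1]
        cx = np.clip(x, 0.0, self.n_cols - 1.0)
        cy = np.clip(y, 0.0, self.n_rows - 1.0)
        rows = (self.n_rows - 1.0) - cy
        cols = cx
        vals = self._interp(np.column_stack([rows, cols]))
        overshoot = np.hypot(x - cx, y - cy)
        return vals + overshoot


def build_signed_distance(region: RegionMap) -> DistanceField:
    """Exact-EDT signed distance for the meshable union of a RegionMap.

    At pixel centres ``d`` equals +(distance to the nearest inside
    pixel) outside and −(distance to the nearest outside pixel) inside;
    between centres it is bilinear.  Sizing defaults to uniform.
    """
    if region.n_subdomains < 1:
        raise ValidationError("region map has no subdomains")
    inside = inside_mask(region)
    # EDT(mask) = per-pixel distance to the nearest zero of the mask
    d_inside = ndimage.distance_transform_edt(inside)
    d_outside = ndimage.distance_transform_edt(~inside)
    grid = np.where(inside, -d_inside, d_outside)
    n_rows, n_cols = region.shape
    d = _GridInterp(grid, n_rows, n_cols)
    bbox = ((0.0, 0.0), (float(n_cols - 1), float(n_rows - 1)))
    uniform = lambda pts: np.ones(len(np.atleast_2d(pts)))  # noqa: E731
    return DistanceField(d=d, h=uniform, bbox=bbox, grid=grid)


def build_sizing(
    region: RegionMap,
    mode: str = "uniform",
    h0: float = 8.0,
    grading: float = 0.3,
    dfield: DistanceField | None = None,
):
    """Relative sizing field h(x, y).

    ``uniform`` → 1 everywhere (absolute scale set by h0 alone);
    ``graded`` → ``1 + grading * |d(x,y)|`` so elements shrink toward
    the borders.  h0 below 1 px is rejected: the pixel grid cannot
    support sub-pixel geometry.
    """
    if h0 < 1:
        raise ValidationError(f"h0 must be >= 1 pixel, got {h0}")
    if mode == "uniform":
        return lambda pts: np.ones(len(np.atleast_2d(pts)))
    if mode == "graded":
        if dfield is None:
            dfield = build_signed_distance(region)
        d = dfield.d
        return lambda pts: 1.0 + grading * np.abs(d(pts))
    raise ValidationError(f"unknown sizing mode {mode!r}")


def _junction_pixels(region: RegionMap, candidates: set[GridPoint]) -> set[GridPoint]:
    """Interface pixels whose 8-neighbourhood touches >= 3 distinct
    regions, where "regions" are subdomains, holes, the exterior, and
    the outer wall treated as one pseudo-region.  Captures both triple
    points of the wall network and interface endpoints abutting the
    domain outline."""
    labels = region.labels
    inside = inside_mask(region)
    outer_wall = (labels == BORDER) & ~inside
    n_rows, n_cols = labels.shape
    out = set()
    for r, c in candidates:
        neigh = set()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    lab = int(labels[rr, cc])
                    if lab != BORDER:
                        neigh.add(lab)
                    elif outer_wall[rr, cc]:
                        neigh.add("wall")
        if len(neigh) >= 3:
            out.add(GridPoint(int(r), int(c)))
    return out


def _resample_polyline(poly: np.ndarray, spacing: float, closed: bool) -> np.ndarray:
    seg = np.diff(poly, axis=0)
    L = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(L)])
    total = cum[-1]
    if total < spacing:
        return poly[:1]
    n = max(3, int(round(total / spacing)))
    targets = np.linspace(0.0, total, n, endpoint=not closed)
    return np.column_stack(
        [np.interp(targets, cum, poly[:, 0]), np.interp(targets, cum, poly[:, 1])]
    )


def _corner_points(poly: np.ndarray, closed: bool, turn_deg: float = 60.0) -> np.ndarray:
    """Sharp corners of a contour: locations where the tangent turns by
    more than ``turn_deg`` within a ~4 px window (staircase noise on
    rasterized curves stays below that).  Each corner is refined as the
    intersection of the tangent lines flanking the turn, so the apex is
    recovered even where the discrete level set chamfers it."""
    dense = _resample_polyline(poly, 1.0, closed)
    n = len(dense)
    if n < 12:
        return np.empty((0, 2))
    w = 4
    if not closed:
        return np.empty((0, 2))  # open contours (frame-clipped) carry no corners here

    def at(i):
        return dense[i % n]

    ang = np.array(
        [np.arctan2(*(at(i + 1) - at(i))[::-1]) for i in range(n)]
    )
    # turn across a 2w window centred on vertex i
    turns = np.array(
        [
            np.abs(np.angle(np.exp(1j * (ang[(i + w - 1) % n] - ang[(i - w) % n]))))
            for i in range(n)
        ]
    )
    thresh = np.deg2rad(turn_deg)
    corners = []
    visited = np.zeros(n, dtype=bool)
    order = np.argsort(-turns)
    for k in order:
        if turns[k] < thresh or visited[k]:
            continue
        for j in range(k - 2 * w, k + 2 * w + 1):
            visited[j % n] = True
        # tangent lines fitted just outside the turn window
        before = np.array([at(j) for j in range(k - 2 * w, k - w + 1)])
        after = np.array([at(j) for j in range(k + w, k + 2 * w + 1)])
        apex = _intersect_lines(before, after)
        if apex is None or np.hypot(*(apex - at(k))) > 2.0 * w:
            apex = at(k)
        corners.append(apex)
    return np.array(corners).reshape(-1, 2)


def _intersect_lines(a_pts: np.ndarray, b_pts: np.ndarray):
    """Intersection of the least-squares lines through two point sets;
    None when nearly parallel."""

    def fit(pts):
        c = pts.mean(axis=0)
        u, s, vt = np.linalg.svd(pts - c)
        return c, vt[0]

    c1, u1 = fit(a_pts)
    c2, u2 = fit(b_pts)
    A = np.column_stack([u1, -u2])
    det = np.linalg.det(A)
    if abs(det) < 1e-6:
        return None
    t = np.linalg.solve(A, c2 - c1)
    return c1 + t[0] * u1


def _lipschitz_interp(region: RegionMap) -> _GridInterp:
    """Bilinear interpolant of the half-pixel-contracted signed EDT
    (1-Lipschitz, same sign pattern as the exact field)."""
    inside = inside_mask(region)
    din = ndimage.distance_transform_edt(inside)
    dout = ndimage.distance_transform_edt(~inside)
    g = np.where(inside, -(din - 0.5), dout - 0.5)
    return _GridInterp(g, *region.shape)


def _project_to_zero(pts: np.ndarray, fd, steps: int = 5) -> np.ndarray:
    """Newton-project points onto the zero level set of fd."""
    pts = pts.copy()
    deps = 1e-4
    for _ in range(steps):
        d = fd(pts)
        if np.abs(d).max() < 1e-9:
            break
        gx = (fd(pts + [deps, 0.0]) - d) / deps
        gy = (fd(pts + [0.0, deps]) - d) / deps
        n2 = np.maximum(gx**2 + gy**2, 1e-12)
        pts = pts - (d / n2)[:, None] * np.column_stack([gx, gy])
    return pts


def select_boundary_fixed_points(
    region: RegionMap,
    spacing: float = 8.0,
    avoid: FixedPointSet | None = None,
) -> FixedPointSet:
    """Fixed nodes pinned along the domain's outer boundary.

    The zero level set of the signed distance is traced by marching
    squares.  Sharp outline corners (tangent turn > 60 degrees over a
    few pixels) are located by intersecting the tangent lines flanking
    the turn and kept first; the rest of each contour is then covered
    by a greedy walk that pins a point wherever the arc runs farther
    than 0.8 spacing from every already-pinned point (including the
    ``avoid`` set, normally the subdomain-interface fixed points), so
    coverage has no gaps and no two pins crowd each other.  All points
    are projected onto the zero level set.  Pinning the outline
    alongside the interfaces treats every boundary pixel found by the
    burn as a fixed point, thinned to the mesh density; it keeps
    boundary nodes well spaced on rasterized curves and holds outline
    corners that force equilibrium alone cannot."""
    if spacing < 1:
        raise ValidationError(f"spacing must be >= 1 pixel, got {spacing}")
    from skimage.measure import find_contours

    fd = _lipschitz_interp(region)
    n_rows = region.shape[0]
    # only avoid points that themselves sit on (or hug) the boundary
    # compete with boundary pins; interface points a few px inside must
    # not suppress boundary coverage above them
    held: list[np.ndarray] = []
    if avoid is not None and len(avoid):
        near = np.abs(fd(avoid.points)) <= 1.5
        held = [np.asarray(p) for p in avoid.points[near]]
    kept: list[np.ndarray] = []

    def _xy(rc: np.ndarray) -> np.ndarray:
        return np.column_stack([rc[:, 1], (n_rows - 1) - rc[:, 0]])

    def _min_d2(p) -> float:
        pts = held + kept
        if not pts:
            return np.inf
        arr = np.asarray(pts)
        return float(((arr - p) ** 2).sum(axis=1).min())

    for contour in find_contours(fd._interp.values, 0.0):
        closed = bool(np.allclose(contour[0], contour[-1]))
        corners = _corner_points(contour, closed)
        if len(corners):
            for p in _project_to_zero(_xy(corners), fd):
                if _min_d2(p) >= (0.8 * spacing) ** 2:
                    kept.append(p)
        dense = _resample_polyline(contour, 1.0, closed)
        if len(dense) < 3:
            continue
        for p in _project_to_zero(_xy(dense), fd):
            if _min_d2(p) >= (0.8 * spacing) ** 2:
                kept.append(p)
    return FixedPointSet(points=np.array(kept, dtype=float).reshape(-1, 2))


def combine_fixed_points(
    interfaces: FixedPointSet, boundary: FixedPointSet, spacing: float
) -> FixedPointSet:
    """Merge interface and outline fixed points; interface points take
    precedence.  The dedupe radius is kept just above the minimum node
    separation (0.35 spacing) so dropping a boundary sample near an
    interface junction cannot open a gap much wider than the spacing
    itself."""
    pts = list(interfaces.points)
    for p in boundary.points:
        if all(((p - q) ** 2).sum() >= (0.35 * spacing) ** 2 for q in pts):
            pts.append(p)
    return FixedPointSet(points=np.array(pts, dtype=float).reshape(-1, 2))


def select_fixed_points(region: RegionMap, spacing: float = 8.0) -> FixedPointSet:
    """Fixed mesh nodes along every subdomain-subdomain interface.

    All interface pixels are collected, converted to plane coordinates,
    then greedily thinned in row-major order keeping a point iff it is
    at least ``spacing`` px from every already-kept point.  Junction
    pixels (interface endpoints at the outline, walls meeting >= 3
    regions) are placed first and thinned only at ``spacing / 2``, so
    the wall topology survives thinning.
    """
    if spacing < 1:
        raise ValidationError(f"spacing must be >= 1 pixel, got {spacing}")
    K = region.n_subdomains
    pixels: set[GridPoint] = set()
    for a in range(1, K + 1):
        for b in range(a + 1, K + 1):
            pixels |= interface_pixels(region, a, b)
    if not pixels:
        return FixedPointSet(points=np.empty((0, 2)))
    junctions = _junction_pixels(region, pixels)
    n_rows = region.shape[0]
    kept: list[tuple[float, float]] = []

    def _try_keep(p: GridPoint, min_d: float):
        x, y = float(p.col), float(n_rows - 1 - p.row)
        if all((x - kx) ** 2 + (y - ky) ** 2 >= min_d**2 for kx, ky in kept):
            kept.append((x, y))

    for p in sorted(junctions):
        _try_keep(p, spacing / 2.0)
    for p in sorted(pixels - junctions):
        _try_keep(p, spacing)
    return FixedPointSet(points=np.array(kept, dtype=float).reshape(-1, 2))
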