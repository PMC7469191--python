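"""Force-equilibrium Delaunay mesh generation on image-derived geometry.

The generator follows the classic Distmesh scheme: nodes start on an
equilateral lattice inside the signed-distance zero level set, are
re-triangulated by Delaunay whenever they drift, and relax under
repulsive bar forces until the largest interior displacement per pseudo
time step falls below tolerance.  Nodes that leave the domain are
projected back along the numerical gradient of the distance field.
Fixed points (subdomain interfaces) never move, so section boundaries
are traced by element edges.

After generation each triangle is assigned the label of the region its
centroid falls in; triangles inside discontinuities are excised last,
mirroring the mesh-then-remove order of operations for holes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay

from .distance_field import DistanceField, FixedPointSet
from .errors import DegenerateDomainError, ValidationError, WingforgeError
from .region_detect import BORDER, OUTSIDE, RegionMap

__all__ = [
    "MeshParams",
    "TriMesh",
    "generate_mesh",
    "assign_sections",
    "remove_hole_elements",
    "triangle_quality",
]


@dataclass(frozen=True)
class MeshParams:
    """Solver parameters.

    h0 is the target node spacing in pixels; the remaining constants
    are the standard internals of the force-equilibrium iteration
    (force scale, pseudo time step, convergence / re-triangulation /
    geometry tolerances).
    """

    h0: float = 8.0
    Fscale: float = 1.2
    dt: float = 0.2
    dptol: float = 0.001
    ttol: float = 0.1
    geps_rel: float = 0.001  # geps = geps_rel * h0
    max_iter: int = 2000
    rng_seed: int = 0

    def __post_init__(self):
        if self.h0 <= 0 or self.dptol <= 0 or self.ttol <= 0 or self.geps_rel <= 0:
            raise ValidationError("h0 and tolerances must be positive")
        if self.Fscale <= 1:
            raise ValidationError("Fscale must exceed 1")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")

    @property
    def geps(self) -> float:
        return self.geps_rel * self.h0


@dataclass
class TriMesh:
    """Triangular surface mesh.

    nodes: (n, 2) or (n, 3) coordinates; triangles: (m, 3) node ids,
    counter-clockwise in the xy-plane; section_of: per-triangle region
    label (subdomain id 1..K, or a negative hole marker before
    excision); fixed_nodes: ids pinned during generation.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    section_of: np.ndarray | None = None
    fixed_nodes: frozenset[int] = frozenset()
    converged: bool = True
    n_iterations: int = 0
    node_map: dict[int, int] | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def is_3d(self) -> bool:
        return self.nodes.shape[1] == 3

    def xy(self) -> np.ndarray:
        return self.nodes[:, :2]

    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a sorted (k, 2) id array."""
        e = np.vstack(
            [
                self.triangles[:, [0, 1]],
                self.triangles[:, [1, 2]],
                self.triangles[:, [2, 0]],
            ]
        )
        return np.unique(np.sort(e, axis=1), axis=0)


def _signed_areas(nodes_xy: np.ndarray, tris: np.ndarray) -> np.ndarray:
    a = nodes_xy[tris[:, 0]]
    b = nodes_xy[tris[:, 1]]
    c = nodes_xy[tris[:, 2]]
    return 0.5 * (
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )


def _orient_ccw(nodes_xy: np.ndarray, tris: np.ndarray) -> np.ndarray:
    tris = tris.copy()
    flip = _signed_areas(nodes_xy, tris) < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return tris


def _initial_points(
    fd, fh, h0: float, bbox, geps: float, rng: np.random.Generator
) -> np.ndarray:
    (xmin, ymin), (xmax, ymax) = [(float(b[0]), float(b[1])) for b in bbox]
    xs = np.arange(xmin, xmax + h0, h0)
    ys = np.arange(ymin, ymax + h0 * np.sqrt(3) / 2, h0 * np.sqrt(3) / 2)
    xg, yg = np.meshgrid(xs, ys)
    xg[1::2] += h0 / 2  # shift every other row: equilateral lattice
    pts = np.column_stack([xg.ravel(), yg.ravel()])
    pts = pts[fd(pts) < geps]
    if len(pts) == 0:
        return pts
    # density-proportional rejection: keep with probability ~ 1/h^2
    r0 = 1.0 / fh(pts) ** 2
    keep = rng.random(len(pts)) < r0 / r0.max()
    return pts[keep]


def _mesh_field(dfield: DistanceField):
    """The mesher's internal distance oracle.

    The exact signed EDT jumps by 2 px across the in/out pixel
    interface (+1 on a wall pixel, -1 on its interior neighbour), which
    makes bilinear gradients near the boundary twice the true slope and
    destabilises node projection.  Shrinking every pixel-centre value
    by half a pixel toward zero restores a 1-Lipschitz field with the
    same sign pattern and (to within a fraction of a pixel) the same
    zero level set, so it is used for all meshing decisions while the
    exposed field keeps the exact-EDT contract.
    """
    if dfield.grid is None:
        return dfield.d
    from .distance_field import _GridInterp

    g = dfield.grid
    n_rows, n_cols = g.shape
    return _GridInterp(g - 0.5 * np.sign(g), n_rows, n_cols)


def generate_mesh(
    dfield: DistanceField,
    pfix: FixedPointSet | None = None,
    params: MeshParams | None = None,
) -> TriMesh:
    """Run the force-equilibrium Delaunay iteration.

    Returns an unsectioned 2-D mesh whose triangles all have centroids
    strictly inside the domain.  Non-convergence within ``max_iter``
    issues a warning and returns the best mesh with
    ``converged=False``; fewer than 3 surviving points raises
    :class:`DegenerateDomainError`.
    """
    params = params or MeshParams()
    fd, fh = _mesh_field(dfield), dfield.h
    h0, geps = params.h0, params.geps
    deps = np.sqrt(np.finfo(float).eps) * h0
    rng = np.random.default_rng(params.rng_seed)

    fix = (
        np.array(pfix.points, dtype=float, copy=True).reshape(-1, 2)
        if pfix is not None and len(pfix)
        else np.empty((0, 2))
    )
    if len(fix) and (fd(fix) > geps).any():
        raise ValidationError("a fixed point lies outside the domain")
    if len(fix):
        # fixed points hugging the outer boundary (interface endpoints
        # sit half a pixel inside it) are snapped onto the zero level
        # set, else they trap near-degenerate boundary triangles
        for _ in range(3):
            d = fd(fix)
            near = d > -1.0
            if not near.any():
                break
            po = fix[near]
            gx = (fd(po + [deps, 0.0]) - d[near]) / deps
            gy = (fd(po + [0.0, deps]) - d[near]) / deps
            n2 = np.maximum(gx**2 + gy**2, 1e-12)
            fix[near] = po - (d[near] / n2)[:, None] * np.column_stack([gx, gy])

    p = _initial_points(fd, fh, h0, dfield.bbox, geps, rng)
    if len(fix):
        # drop lattice points that collide with a fixed point
        if len(p):
            d2 = ((p[:, None, :] - fix[None, :, :]) ** 2).sum(-1)
            p = p[(d2 > (0.5 * h0) ** 2).all(axis=1)]
        p = np.vstack([fix, p])
    nfix = len(fix)
    if len(p) < 3:
        raise DegenerateDomainError(
            f"only {len(p)} points survive at h0={h0}; domain too small or thin"
        )

    pold = np.full_like(p, np.inf)
    tris = None
    converged = False
    it = 0
    dt = params.dt
    best_disp = np.inf
    stall = 0
    dmove = np.inf
    for it in range(1, params.max_iter + 1):
        if np.max(np.hypot(*(p - pold).T)) / h0 > params.ttol:
            pold = p.copy()
            tris = Delaunay(p).simplices
            cent = p[tris].mean(axis=1)
            tris = tris[fd(cent) < -geps]
            bars = np.unique(
                np.sort(
                    np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]),
                    axis=1,
                ),
                axis=0,
            )
        pprev = p.copy()
        barvec = p[bars[:, 0]] - p[bars[:, 1]]
        L = np.hypot(barvec[:, 0], barvec[:, 1])
        hbars = fh((p[bars[:, 0]] + p[bars[:, 1]]) / 2)
        L0 = hbars * params.Fscale * np.sqrt((L**2).sum() / (hbars**2).sum())
        # density control: points crammed to less than half their target
        # spacing cannot escape tangentially under repulsive-only forces;
        # delete them and re-triangulate
        if it % 30 == 0 and (L0 > 2 * L).any():
            drop = np.unique(bars[L0 > 2 * L].ravel())
            drop = drop[drop >= nfix]
            if len(drop):
                p = np.delete(p, drop, axis=0)
                pold = np.full_like(p, np.inf)
                dt = params.dt
                best_disp = np.inf
                stall = 0
                continue
        F = np.maximum(L0 - L, 0.0)
        Fvec = (F / np.maximum(L, 1e-12))[:, None] * barvec
        Ftot = np.zeros_like(p)
        np.add.at(Ftot, bars[:, 0], Fvec)
        np.add.at(Ftot, bars[:, 1], -Fvec)
        Ftot[:nfix] = 0.0
        p = p + dt * Ftot

        # project escapees back onto the zero level set
        d = fd(p)
        out = d > 0
        if out.any():
            po = p[out]
            dgradx = (fd(po + [deps, 0.0]) - d[out]) / deps
            dgrady = (fd(po + [0.0, deps]) - d[out]) / deps
            norm2 = np.maximum(dgradx**2 + dgrady**2, 1e-12)
            p[out] = po - (d[out] / norm2)[:, None] * np.column_stack(
                [dgradx, dgrady]
            )

        # convergence on the net per-iteration displacement (movement
        # after boundary projection): a node pushed out and projected
        # straight back has reached its constrained equilibrium
        dmove = np.max(np.hypot(*(p - pprev).T))
        if dmove / h0 < params.dptol:
            converged = True
            break
        # small-amplitude limit cycles at staircase boundary pixels are
        # damped by cooling the pseudo time step when progress stalls
        if dmove < 0.99 * best_disp:
            best_disp = dmove
            stall = 0
        else:
            stall += 1
            if stall >= 50:
                dt = max(dt * 0.7, 0.01 * params.dt)
                stall = 0

    if not converged:
        warnings.warn(
            f"mesh did not converge in {params.max_iter} iterations "
            f"(last displacement {dmove / h0:.2e} h0)",
            stacklevel=2,
        )

    tris = Delaunay(p).simplices
    cent = p[tris].mean(axis=1)
    tris = tris[fd(cent) < -geps]
    if len(tris) == 0:
        raise DegenerateDomainError("no triangles survive inside the domain")
    tris = _fix_boundary_slivers(p, tris, fd, nfix)
    p = _smooth_improve(p, tris, nfix, fd, geps)
    tris = _orient_ccw(p, tris)
    # compact: drop orphan nodes, keep fixed points identifiable
    used = np.unique(tris)
    remap = -np.ones(len(p), dtype=int)
    remap[used] = np.arange(len(used))
    nodes = p[used]
    tris = remap[tris]
    fixed = frozenset(int(remap[i]) for i in range(nfix) if remap[i] >= 0)
    return TriMesh(
        nodes=nodes,
        triangles=tris,
        fixed_nodes=fixed,
        converged=converged,
        n_iterations=it,
    )


def _tri_quality(p: np.ndarray, tris: np.ndarray) -> np.ndarray:
    a = np.linalg.norm(p[tris[:, 1]] - p[tris[:, 2]], axis=1)
    b = np.linalg.norm(p[tris[:, 2]] - p[tris[:, 0]], axis=1)
    c = np.linalg.norm(p[tris[:, 0]] - p[tris[:, 1]], axis=1)
    denom = a * b * c
    q = (b + c - a) * (c + a - b) * (a + b - c) / np.where(denom > 0, denom, 1.0)
    return np.clip(np.where(denom > 0, q, 0.0), 0.0, 1.0)


def _fix_boundary_slivers(
    p: np.ndarray, tris: np.ndarray, fd, nfix: int, qtol: float = 0.3
) -> np.ndarray:
    """Repair flat boundary artifacts in the final triangulation.

    On rasterized outlines three adjacent boundary nodes can be almost
    collinear; Delaunay then emits near-zero-area caps hugging the
    boundary (all vertices and the centroid within about a pixel of the
    zero level set).  Each cap is first attacked by flipping its shared
    edge with the inner neighbour — which absorbs the sliver while
    keeping every (possibly pinned) node connected — and dropped
    outright only when no flip helps and no fixed node would be
    orphaned.  Interior slivers are never touched."""
    for _ in range(20):
        q = _tri_quality(p, tris)
        cent_d = fd(p[tris].mean(axis=1))
        vert_d = fd(p[tris.ravel()]).reshape(tris.shape)
        caps = np.nonzero((q < qtol) & (cent_d > -1.0) & (vert_d > -1.0).all(axis=1))[0]
        if not len(caps):
            return tris
        edges = np.sort(
            np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]), axis=1
        )
        edge_count: dict[tuple, list[int]] = {}
        for ti, t in enumerate(tris):
            for i in range(3):
                e = tuple(sorted((t[i], t[(i + 1) % 3])))
                edge_count.setdefault(e, []).append(ti)
        all_edges = set(edge_count)
        changed = False
        drop: set[int] = set()
        for ci in caps:
            if ci in drop:
                continue
            t = tris[ci]
            shared = [
                tuple(sorted((t[i], t[(i + 1) % 3])))
                for i in range(3)
                if len(edge_count[tuple(sorted((t[i], t[(i + 1) % 3])))]) == 2
            ]
            flipped = False
            for e in shared:
                nb = next(x for x in edge_count[e] if x != ci)
                if nb in drop:
                    continue
                b = next(v for v in t if v not in e)
                d = next(v for v in tris[nb] if v not in e)
                if tuple(sorted((b, d))) in all_edges:
                    continue
                new1 = np.array([e[0], b, d])
                new2 = np.array([e[1], b, d])
                areas = _signed_areas(p, np.array([new1, new2]))
                if np.abs(areas).min() < 1e-9 or np.sign(areas[0]) != np.sign(areas[1]):
                    continue
                old_q = _tri_quality(p, tris[[ci, nb]]).min()
                new_q = _tri_quality(p, np.array([new1, new2])).min()
                if new_q <= old_q:
                    continue
                tris[ci], tris[nb] = new1, new2
                flipped = changed = True
                break
            if flipped:
                break  # edge bookkeeping is stale; rebuild next round
            # fall back to dropping, unless that would orphan a pinned node
            orphans_fixed = any(
                v < nfix and all(ti == ci for ti in _incident(edge_count, tris, v))
                for v in t
            )
            if not orphans_fixed:
                drop.add(ci)
                changed = True
        if drop:
            tris = np.delete(tris, sorted(drop), axis=0)
        if not changed:
            return tris
    return tris


def _incident(edge_count, tris, v):
    out = []
    for e, tids in edge_count.items():
        if v in e:
            out.extend(tids)
    return set(out)


def _smooth_improve(
    p: np.ndarray,
    tris: np.ndarray,
    nfix: int,
    fd,
    geps: float,
    passes: int = 10,
    qtol: float = 0.6,
) -> np.ndarray:
    """Local Laplacian improvement of low-quality patches.

    Free vertices of triangles below ``qtol`` are moved to the average
    of their neighbours; a move is kept only when it strictly raises
    the minimum quality of the incident triangles, keeps every incident
    orientation, and stays inside the domain.  Connectivity is frozen,
    so the pass can only improve the final triangulation."""
    for _ in range(passes):
        q = _tri_quality(p, tris)
        bad = np.unique(tris[q < qtol])
        bad = bad[bad >= nfix]
        moved = False
        for v in bad:
            inc = np.nonzero((tris == v).any(axis=1))[0]
            nbrs = np.unique(tris[inc])
            nbrs = nbrs[nbrs != v]
            if len(nbrs) < 3:
                continue
            cand = p[nbrs].mean(axis=0)
            if fd(cand[None])[0] > -geps:
                continue
            old = p[v].copy()
            q_old = _tri_quality(p, tris[inc]).min()
            a_old = np.sign(_signed_areas(p, tris[inc]))
            p[v] = cand
            q_new = _tri_quality(p, tris[inc]).min()
            a_new = np.sign(_signed_areas(p, tris[inc]))
            if q_new > q_old and (a_new == a_old).all():
                moved = True
            else:
                p[v] = old
        if not moved:
            break
    return p


def _round_half_down(v: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties toward negative infinity, so
    centroid-pixel lookup at exact half coordinates is reproducible."""
    return np.ceil(np.asarray(v) - 0.5).astype(int)


def _centroid_pixels(mesh: TriMesh, region: RegionMap) -> tuple[np.ndarray, np.ndarray]:
    n_rows, n_cols = region.shape
    cent = mesh.centroids()[:, :2]
    rows = np.clip(_round_half_down((n_rows - 1) - cent[:, 1]), 0, n_rows - 1)
    cols = np.clip(_round_half_down(cent[:, 0]), 0, n_cols - 1)
    return rows, cols


def assign_sections(mesh: TriMesh, region: RegionMap) -> TriMesh:
    """Label each triangle with the region containing its centroid.

    Centroids landing on a BORDER pixel take the label of the nearest
    non-border pixel (by Euclidean distance transform).  A centroid
    resolving to OUTSIDE indicates a triangle the generator should have
    dropped and raises an internal-consistency error.
    """
    labels = region.labels
    border = labels == BORDER
    # per-pixel index of the nearest non-border pixel
    _, (ir, ic) = ndimage.distance_transform_edt(border, return_indices=True)
    resolved = labels[ir, ic]
    rows, cols = _centroid_pixels(mesh, region)
    sec = np.where(border[rows, cols], resolved[rows, cols], labels[rows, cols])
    if (sec == OUTSIDE).any():
        raise WingforgeError(
            "triangle centroid resolved to OUTSIDE: mesh and region map "
            "are inconsistent"
        )
    return replace(mesh, section_of=sec.astype(int))


def remove_hole_elements(mesh: TriMesh, region: RegionMap) -> TriMesh:
    """Excise triangles whose centroid lies in a discontinuity.

    Orphan nodes are compacted; the old→new node id map is attached to
    the result as ``node_map`` for traceability.
    """
    if mesh.section_of is None:
        raise ValidationError("assign sections before removing hole elements")
    keep = mesh.section_of >= 1
    tris = mesh.triangles[keep]
    sec = mesh.section_of[keep]
    used = np.unique(tris)
    remap = -np.ones(mesh.n_nodes, dtype=int)
    remap[used] = np.arange(len(used))
    node_map = {int(i): int(remap[i]) for i in used}
    fixed = frozenset(
        int(remap[i]) for i in mesh.fixed_nodes if remap[i] >= 0
    )
    return TriMesh(
        nodes=mesh.nodes[used],
        triangles=remap[tris],
        section_of=sec,
        fixed_nodes=fixed,
        converged=mesh.converged,
        n_iterations=mesh.n_iterations,
        node_map=node_map,
    )


def triangle_quality(mesh: TriMesh) -> np.ndarray:
    """Radius-ratio quality q = 2 r_in / r_circ per triangle.

    q = 1 for an equilateral triangle, 0 for a degenerate one; zero
    area never raises.  Uses the side-length identity
    q = (b+c-a)(c+a-b)(a+b-c) / (abc).
    """
    return _tri_quality(mesh.xy(), mesh.triangles)
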