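"""Programmatic generation of test images.

Every image the test-suite and examples need is generated here, from
simple rectangle outlines through partitioned and holey variants up to
wing-like venation patterns (an elliptical outline crossed by curved
longitudinal veins and short crossveins) and ridge heightmaps for
corrugation.  All generators are pure functions of their arguments —
identical calls yield identical images — and each one declares seed
pixels guaranteed to pass region detection.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.draw import circle_perimeter, line, polygon_perimeter

from .errors import ValidationError, WingforgeError
from .image_io import GridPoint, PixelImage
from .region_detect import SeedSpec

__all__ = [
    "make_rectangle",
    "make_partitioned_rectangle",
    "make_holey_rectangle",
    "make_irregular_domain",
    "make_wing_like",
    "make_ridge_heightmap",
    "make_random_blobs",
]

_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _blank(frame: tuple[int, int]) -> np.ndarray:
    return np.ones(frame, dtype=float)


def make_rectangle(
    frame: tuple[int, int] = (100, 100), margin: int = 10
) -> tuple[PixelImage, SeedSpec]:
    """Black rectangle outline inset by ``margin``, seeded at its centre."""
    n_rows, n_cols = frame
    if margin < 1:
        raise ValidationError("margin must be >= 1 px")
    if n_rows - 2 * margin < 3 or n_cols - 2 * margin < 3:
        raise ValidationError(f"margin {margin} too large for frame {frame}")
    v = _blank(frame)
    r0, r1 = margin, n_rows - margin - 1
    c0, c1 = margin, n_cols - margin - 1
    v[r0, c0 : c1 + 1] = 0
    v[r1, c0 : c1 + 1] = 0
    v[r0 : r1 + 1, c0] = 0
    v[r0 : r1 + 1, c1] = 0
    seed = GridPoint((r0 + r1) // 2, (c0 + c1) // 2)
    return PixelImage(v, kind="binary"), SeedSpec(subdomain_seeds=(seed,))


def make_partitioned_rectangle(
    frame: tuple[int, int] = (100, 200),
    margin: int = 10,
    n_cells: int = 2,
) -> tuple[PixelImage, SeedSpec]:
    """Rectangle outline plus ``n_cells - 1`` vertical 1-px dividers,
    one seed per cell."""
    if n_cells < 2:
        raise ValidationError("n_cells must be >= 2")
    image, _ = make_rectangle(frame, margin)
    v = image.values.copy()
    n_rows, n_cols = frame
    r0, r1 = margin, n_rows - margin - 1
    c0, c1 = margin, n_cols - margin - 1
    divider_cols = [
        c0 + round(i * (c1 - c0) / n_cells) for i in range(1, n_cells)
    ]
    edges = [c0] + divider_cols + [c1]
    if min(b - a for a, b in zip(edges, edges[1:])) < 3:
        raise ValidationError("cells narrower than 3 px")
    for c in divider_cols:
        v[r0 : r1 + 1, c] = 0
    mid_row = (r0 + r1) // 2
    seeds = tuple(
        GridPoint(mid_row, (a + b) // 2) for a, b in zip(edges, edges[1:])
    )
    return PixelImage(v, kind="binary"), SeedSpec(subdomain_seeds=seeds)


def make_holey_rectangle(
    frame: tuple[int, int] = (100, 200),
    margin: int = 10,
    hole_center: tuple[int, int] | None = None,
    hole_radius: int = 10,
    n_cells: int = 2,
) -> tuple[PixelImage, SeedSpec]:
    """Partitioned rectangle with a circular discontinuity inside one
    cell; the circle interior is declared as a hole seed."""
    image, seeds = make_partitioned_rectangle(frame, margin, n_cells)
    v = image.values.copy()
    if hole_center is None:
        first = seeds.subdomain_seeds[0]
        hole_center = (first.row, first.col)
    hr, hc = hole_center
    rr, cc = circle_perimeter(hr, hc, hole_radius, shape=frame)
    if v[rr, cc].min() == 0:
        raise ValidationError("hole outline intersects a wall")
    # the circle must be fully inside one cell: no other black pixel
    # within its bounding disc
    yy, xx = np.mgrid[0 : frame[0], 0 : frame[1]]
    disc = (yy - hr) ** 2 + (xx - hc) ** 2 <= (hole_radius + 1) ** 2
    if (v[disc] == 0).any():
        raise ValidationError("hole overlaps domain walls")
    v[rr, cc] = 0
    # re-derive any cell seed the circle swallowed: walk down the cell's
    # centre column to the first white pixel clear of the hole disc
    sub_seeds = []
    for s in seeds.subdomain_seeds:
        if (s.row - hr) ** 2 + (s.col - hc) ** 2 <= (hole_radius + 1) ** 2:
            for r in range(margin + 1, frame[0] - margin - 1):
                if (
                    v[r, s.col] == 1.0
                    and (r - hr) ** 2 + (s.col - hc) ** 2 > (hole_radius + 1) ** 2
                ):
                    s = GridPoint(r, s.col)
                    break
        sub_seeds.append(s)
    return (
        PixelImage(v, kind="binary"),
        SeedSpec(
            subdomain_seeds=tuple(sub_seeds),
            hole_seeds=(GridPoint(hr, hc),),
        ),
    )


def _closed_outline(v: np.ndarray, rows: np.ndarray, cols: np.ndarray):
    rr, cc = polygon_perimeter(rows, cols, shape=v.shape, clip=True)
    v[rr, cc] = 0


def make_irregular_domain(
    frame: tuple[int, int] = (100, 120),
    rng_seed: int = 0,
    n_holes: int = 2,
) -> tuple[PixelImage, SeedSpec]:
    """Smooth irregular blob outline (Fourier-perturbed polar curve)
    with circular discontinuities scattered inside."""
    rng = np.random.default_rng(rng_seed)
    n_rows, n_cols = frame
    cy, cx = (n_rows - 1) / 2, (n_cols - 1) / 2
    base = 0.38 * min(n_rows, n_cols)
    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    r = base * (
        1.0
        + 0.12 * np.cos(2 * theta + rng.uniform(0, 2 * np.pi))
        + 0.08 * np.cos(3 * theta + rng.uniform(0, 2 * np.pi))
    )
    rows = cy + r * np.sin(theta)
    cols = cx + r * np.cos(theta)
    v = _blank(frame)
    _closed_outline(v, rows, cols)

    # interior = the white component containing the centre
    lab, _ = ndimage.label(v == 1, structure=_FOUR)
    centre_lab = lab[int(cy), int(cx)]
    interior = lab == centre_lab

    hole_seeds = []
    attempts = 0
    while len(hole_seeds) < n_holes and attempts < 200:
        attempts += 1
        hr = int(rng.integers(5, n_rows - 5))
        hc = int(rng.integers(5, n_cols - 5))
        radius = int(rng.integers(4, 8))
        yy, xx = np.mgrid[0:n_rows, 0:n_cols]
        disc = (yy - hr) ** 2 + (xx - hc) ** 2 <= (radius + 2) ** 2
        if not interior[disc].all() or (v[disc] == 0).any():
            continue
        if disc[int(cy), int(cx)]:  # never swallow the subdomain seed
            continue
        rr, cc = circle_perimeter(hr, hc, radius, shape=frame)
        v[rr, cc] = 0
        hole_seeds.append(GridPoint(hr, hc))
    if len(hole_seeds) < n_holes:
        raise WingforgeError("could not place all holes inside the blob")
    return (
        PixelImage(v, kind="binary"),
        SeedSpec(
            subdomain_seeds=(GridPoint(int(cy), int(cx)),),
            hole_seeds=tuple(hole_seeds),
        ),
    )


def _draw_polyline(v: np.ndarray, pts: np.ndarray, value: float = 0.0):
    pts = np.asarray(pts)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
        ok = (rr >= 0) & (rr < v.shape[0]) & (cc >= 0) & (cc < v.shape[1])
        v[rr[ok], cc[ok]] = value


def make_wing_like(
    frame: tuple[int, int] = (120, 240),
    n_longitudinal_veins: int = 5,
    n_crossveins: int = 4,
    rng_seed: int = 0,
) -> tuple[PixelImage, SeedSpec]:
    """Synthetic wing venation: an elliptical outline crossed by curved
    longitudinal vein polylines and short vertical crossveins.

    The interior is partitioned into at least ``n_longitudinal_veins``
    cells; a seed is auto-derived for every interior cell by flood
    fill, so the declared seeds always pass region detection.
    Deterministic in ``rng_seed``; control points are perturbed and the
    pattern regenerated (up to 10 attempts) if the partition is too
    coarse.
    """
    if n_longitudinal_veins < 2:
        raise ValidationError("need at least 2 longitudinal veins")
    n_rows, n_cols = frame
    cy, cx = (n_rows - 1) / 2, (n_cols - 1) / 2
    ry, rx = 0.42 * n_rows, 0.46 * n_cols
    half = rx - ry  # straight-span half-length of the stadium outline

    for attempt in range(10):
        rng = np.random.default_rng(rng_seed + 1009 * attempt)
        v = _blank(frame)
        # wing silhouette: a stadium (straight leading/trailing edges,
        # rounded tips) so longitudinal veins meet the margin steeply
        phi = np.linspace(-np.pi / 2, np.pi / 2, 360)
        right = np.column_stack(
            [cy + ry * np.sin(phi), cx + half + ry * np.cos(phi)]
        )
        left = np.column_stack(
            [cy - ry * np.sin(phi), cx - half - ry * np.cos(phi)]
        )
        outline = np.vstack([right, left])
        _closed_outline(v, outline[:, 0], outline[:, 1])

        # signed "inside" test: within ry of the central spine segment
        yy = np.arange(n_rows)[:, None] - cy
        xx = np.arange(n_cols)[None, :] - cx
        xc = np.clip(xx, -half, half)
        inside_outline = yy**2 + (xx - xc) ** 2 <= ry**2

        # longitudinal veins: gently bowed arcs spanning the full frame,
        # later clipped to the silhouette so they join the outline
        # vein fan compressed to +-0.62 ry so veins cross the rounded
        # tips steeply (shallow crossings breed acute mesh wedges); a
        # shared bow with small per-vein jitter keeps the membrane
        # strips between veins nearly parallel
        veins = _blank(frame)
        ts = np.linspace(0.0, 1.0, 64)
        band = 1.24 * ry / (n_longitudinal_veins - 1)
        shared_bow = rng.uniform(-0.15, 0.15)
        vein_rows = []
        for i in range(n_longitudinal_veins):
            r_base = cy - 0.62 * ry + i * band
            bow = (shared_bow + rng.uniform(-0.05, 0.05)) * band
            rows = r_base + bow * 4 * ts * (1 - ts)  # quadratic bump
            cols = -1 + (n_cols + 1) * ts
            pts = np.column_stack([rows, cols])
            _draw_polyline(veins, pts)
            vein_rows.append(rows)
        # crossveins: short vertical links between adjacent veins
        for j in range(n_crossveins):
            i = int(rng.integers(0, n_longitudinal_veins - 1))
            t_idx = int(rng.integers(12, 52))
            c = -1 + (n_cols + 1) * ts[t_idx]
            r_top = vein_rows[i][t_idx]
            r_bot = vein_rows[i + 1][t_idx]
            _draw_polyline(veins, [(r_top, c), (r_bot, c)])
        # clip veins to the silhouette interior (dilated 2 px so every
        # vein overlaps the rasterized outline), then merge
        clip = ndimage.binary_dilation(inside_outline, iterations=2)
        vein_black = (veins == 0) & clip
        v[vein_black] = 0

        lab, n_lab = ndimage.label(v == 1, structure=_FOUR)
        frame_labels = set(lab[0, :]) | set(lab[-1, :]) | set(lab[:, 0]) | set(lab[:, -1])
        frame_labels.discard(0)
        seeds = []
        for k in range(1, n_lab + 1):
            if k in frame_labels:
                continue
            rs, cs = np.nonzero(lab == k)
            seeds.append(GridPoint(int(rs[0]), int(cs[0])))
        if len(seeds) >= n_longitudinal_veins:
            return (
                PixelImage(v, kind="binary"),
                SeedSpec(subdomain_seeds=tuple(sorted(seeds))),
            )
    raise WingforgeError(
        "wing pattern generation failed to partition the interior after 10 attempts"
    )


def make_ridge_heightmap(
    frame: tuple[int, int] = (100, 100),
    ridge_path=None,
    ridge_value: float = 0.0,
    background_value: float = 1.0,
    base: PixelImage | None = None,
) -> PixelImage:
    """1-px polyline at ``ridge_value`` on a constant background.

    ``ridge_path`` is a sequence of (row, col) vertices; by default a
    vertical centreline.  Pass a previous result as ``base`` to
    compose several extrema (e.g. a black maximum plus grey
    intermediates) in one map.
    """
    n_rows, n_cols = frame
    if base is not None:
        if base.shape != tuple(frame):
            raise ValidationError("base frame differs")
        v = base.values.copy()
    else:
        v = np.full(frame, float(background_value))
    if ridge_path is None:
        mid = n_cols // 2
        ridge_path = [(0, mid), (n_rows - 1, mid)]
    _draw_polyline(v, np.asarray(ridge_path, dtype=float), value=float(ridge_value))
    kind = "binary" if np.isin(v, (0.0, 1.0)).all() else "continuous"
    return PixelImage(v, kind=kind)


def make_random_blobs(
    frame: tuple[int, int] = (64, 64), rng_seed: int = 0
) -> PixelImage:
    """Random smooth binary blob image (for stress-testing the burning
    algorithm against a reference flood fill; no declared seeds)."""
    rng = np.random.default_rng(rng_seed)
    noise = rng.standard_normal(frame)
    smooth = ndimage.gaussian_filter(noise, sigma=4.0)
    v = (smooth > np.median(smooth)).astype(float)
    return PixelImage(v, kind="binary")
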