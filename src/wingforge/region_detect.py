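"""Burning-algorithm region detection.

The burning algorithm (BA) is a frontier-based flood fill on a binary
image: starting from a user-selected white pixel it repeatedly inspects
the four orthogonal neighbours of the white pixels found in the previous
pass, collecting adjacent black pixels as the region's boundary, until no
new white pixel is found.  Run once per user seed it partitions the image
into the exterior, the border network, numbered subdomains (the
vein-bounded cells of a wing), and discontinuities (holes/cracks to be
excised from the final model).

Labels in the partition matrix:

* ``OUTSIDE = -1`` — white pixels connected to the image frame
* ``BORDER  =  0`` — black pixels
* ``1..K``        — subdomains, in seed order
* ``-2, -3, ...`` — holes, in seed order
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DuplicateSeedError,
    OpenBoundaryError,
    SeedOnBorderError,
    UnseededRegionError,
    ValidationError,
)
from .image_io import GridPoint, PixelImage

__all__ = [
    "OUTSIDE",
    "BORDER",
    "RegionMap",
    "SeedSpec",
    "burn",
    "detect_regions",
    "interface_pixels",
]

OUTSIDE = -1
BORDER = 0

# 4-orthogonal neighbour offsets (the BA never looks diagonally)
_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass(frozen=True)
class SeedSpec:
    """Ordered user seeds: one white pixel per subdomain and per hole."""

    subdomain_seeds: tuple[GridPoint, ...] = ()
    hole_seeds: tuple[GridPoint, ...] = ()

    def __post_init__(self):
        object.__setattr__(
            self,
            "subdomain_seeds",
            tuple(GridPoint(*s) for s in self.subdomain_seeds),
        )
        object.__setattr__(
            self, "hole_seeds", tuple(GridPoint(*s) for s in self.hole_seeds)
        )


@dataclass
class RegionMap:
    """Total partition of an image into outside/border/subdomains/holes.

    Attributes
    ----------
    labels
        Integer matrix, image-shaped; see module docstring for codes.
    boundary_pixels
        Per region label, the set of BORDER grid points the burn found
        4-adjacent to that region.
    """

    labels: np.ndarray
    boundary_pixels: dict[int, frozenset[GridPoint]] = field(default_factory=dict)

    @property
    def n_subdomains(self) -> int:
        return int(max(0, self.labels.max(initial=0)))

    @property
    def n_holes(self) -> int:
        m = int(self.labels.min(initial=0))
        return -m - 1 if m < -1 else 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def subdomain_mask(self, k: int) -> np.ndarray:
        if not 1 <= k <= self.n_subdomains:
            raise ValidationError(f"invalid subdomain id {k}")
        return self.labels == k

    def hole_mask(self, m: int) -> np.ndarray:
        lab = -1 - m
        if not -1 - self.n_holes <= lab <= -2:
            raise ValidationError(f"invalid hole id {m}")
        return self.labels == lab

    def hole_label(self, m: int) -> int:
        """Label value of the m-th hole (1-based m → -2, -3, ...)."""
        return -1 - m


def _check_seed(image: PixelImage, seed: GridPoint) -> GridPoint:
    row, col = seed
    if not (0 <= row < image.n_rows and 0 <= col < image.n_cols):
        raise ValidationError(f"seed ({row},{col}) outside image frame")
    if image.values[row, col] == 0.0:
        raise SeedOnBorderError(f"seed ({row},{col}) lies on a black pixel")
    return GridPoint(row, col)


def _burn_masks(white: np.ndarray, seeds: list[GridPoint]):
    """Frontier-by-frontier burn over the boolean ``white`` mask.

    Returns (interior mask, boundary mask).  Each pass expands only from
    white pixels reached in the previous pass, exactly the BA iteration.
    """
    interior = np.zeros_like(white, dtype=bool)
    boundary = np.zeros_like(white, dtype=bool)
    frontier = np.zeros_like(white, dtype=bool)
    for r, c in seeds:
        frontier[r, c] = True
    interior |= frontier
    while frontier.any():
        nxt = np.zeros_like(frontier)
        for dr, dc in _OFFSETS:
            shifted = np.zeros_like(frontier)
            src = frontier[
                max(0, -dr) : frontier.shape[0] - max(0, dr),
                max(0, -dc) : frontier.shape[1] - max(0, dc),
            ]
            shifted[
                max(0, dr) : frontier.shape[0] - max(0, -dr),
                max(0, dc) : frontier.shape[1] - max(0, -dc),
            ] = src
            nxt |= shifted
        boundary |= nxt & ~white
        frontier = nxt & white & ~interior
        interior |= frontier
    return interior, boundary


def burn(
    image: PixelImage, seed: GridPoint | tuple[int, int]
) -> tuple[set[GridPoint], set[GridPoint]]:
    """Burn from one seed: the maximal 4-connected white component
    containing it, plus all black pixels 4-adjacent to that component.

    Raises :class:`SeedOnBorderError` if the seed is black and
    :class:`ValidationError` if it is out of range.
    """
    if image.kind != "binary":
        raise ValidationError("burn requires a binary image")
    seed = _check_seed(image, GridPoint(*seed))
    white = image.values == 1.0
    interior, boundary = _burn_masks(white, [seed])
    return (
        {GridPoint(int(r), int(c)) for r, c in zip(*np.nonzero(interior))},
        {GridPoint(int(r), int(c)) for r, c in zip(*np.nonzero(boundary))},
    )


def detect_regions(image: PixelImage, seeds: SeedSpec) -> RegionMap:
    """Partition the image from user seeds.

    The exterior is burned first from every white pixel on the image
    frame edge (no user seed needed); then each subdomain seed and each
    hole seed burns its component; remaining black pixels become BORDER.
    A subdomain seed whose component touches the frame means the domain
    outline is not closed; a white component no burn reached means a
    cavity the user forgot to seed.  Both abort with a specific error.
    """
    if image.kind != "binary":
        raise ValidationError("detect_regions requires a binary image")
    white = image.values == 1.0
    labels = np.full(image.shape, BORDER, dtype=np.int32)
    boundary_sets: dict[int, frozenset[GridPoint]] = {}

    # exterior burn, seeded from all white frame-edge pixels
    edge = np.zeros_like(white)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    edge_seeds = [
        GridPoint(int(r), int(c)) for r, c in zip(*np.nonzero(edge & white))
    ]
    outside = np.zeros_like(white)
    if edge_seeds:
        outside, out_bnd = _burn_masks(white, edge_seeds)
        boundary_sets[OUTSIDE] = frozenset(
            GridPoint(int(r), int(c)) for r, c in zip(*np.nonzero(out_bnd))
        )
    labels[outside] = OUTSIDE

    claimed = outside.copy()

    def _burn_seed(seed: GridPoint, label: int, what: str):
        seed = _check_seed(image, seed)
        if outside[seed.row, seed.col]:
            raise OpenBoundaryError(
                f"{what} seed ({seed.row},{seed.col}) is connected to the "
                "image frame: the domain border is not closed"
            )
        if claimed[seed.row, seed.col]:
            raise DuplicateSeedError(
                f"{what} seed ({seed.row},{seed.col}) lies in an already "
                "seeded component"
            )
        interior, bnd = _burn_masks(white, [seed])
        labels[interior] = label
        claimed[:] |= interior
        boundary_sets[label] = frozenset(
            GridPoint(int(r), int(c)) for r, c in zip(*np.nonzero(bnd))
        )

    for k, seed in enumerate(seeds.subdomain_seeds, start=1):
        _burn_seed(seed, k, "subdomain")
    for m, seed in enumerate(seeds.hole_seeds, start=1):
        _burn_seed(seed, -1 - m, "hole")

    unreached = white & ~claimed
    if unreached.any():
        r, c = (int(i[0]) for i in np.nonzero(unreached))
        raise UnseededRegionError(
            f"white pixel ({r},{c}) was reached by no burn; seed its "
            "component as a subdomain or hole"
        )
    return RegionMap(labels=labels, boundary_pixels=boundary_sets)


def interface_pixels(region: RegionMap, a: int, b: int) -> set[GridPoint]:
    """BORDER pixels 4-adjacent to both subdomain ``a`` and subdomain
    ``b`` — the shared internal wall, empty when they share none."""
    if a == b:
        raise ValidationError("interface requires two distinct subdomains")
    mask_a = region.subdomain_mask(a)
    mask_b = region.subdomain_mask(b)
    border = region.labels == BORDER

    def _adjacent(mask):
        adj = np.zeros_like(mask)
        adj[:-1, :] |= mask[1:, :]
        adj[1:, :] |= mask[:-1, :]
        adj[:, :-1] |= mask[:, 1:]
        adj[:, 1:] |= mask[:, :-1]
        return adj

    shared = border & _adjacent(mask_a) & _adjacent(mask_b)
    return {GridPoint(int(r), int(c)) for r, c in zip(*np.nonzero(shared))}
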