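"""Out-of-plane corrugation from a secondary heightmap image.

The secondary image encodes relief: black pixels (value 0) mark the
maximum height, white pixels (value 1) the minimum, and grey values
mark intermediate local extrema in proportion to their intensity.  The
map is smoothed by synchronous passes of a 3x3 neighbourhood mean —
each pass replaces every pixel by the average of its (edge-truncated)
neighbourhood — and the iteration count controls how sharp the
resulting corrugations are.

Pure neighbourhood averaging relaxes any image toward a constant,
which would erase the encoded extrema; by default the extremum pixels
are therefore re-imposed after every pass (``constrain=True``), turning
the iteration into relaxation toward a smooth interpolation of held
boundary values.  ``constrain=False`` gives the literal unconstrained
diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import convolve2d

from .errors import FrameMismatchError, ValidationError
from .image_io import PixelImage
from .mesher import TriMesh

__all__ = ["HeightMap", "smooth_heightmap", "apply_heights", "default_amplitude"]


@dataclass
class HeightMap:
    """Smoothed per-pixel height field.

    v holds values in [0, 1] on the primary image frame; constrained
    marks extremum pixels held fixed during smoothing; amplitude is the
    physical height A assigned to v = 0 (z = A * (1 - v)).
    """

    v: np.ndarray
    constrained: np.ndarray
    iterations: int
    amplitude: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.v.shape

    def with_amplitude(self, amplitude: float) -> "HeightMap":
        if amplitude <= 0:
            raise ValidationError("amplitude must be positive")
        return _dc_replace(self, amplitude=amplitude)


def default_amplitude(shape: tuple[int, int]) -> float:
    """Default corrugation amplitude: 5% of the larger frame dimension."""
    return 0.05 * max(shape)


def _modal_value(v: np.ndarray) -> float:
    vals, counts = np.unique(v, return_counts=True)
    return float(vals[np.argmax(counts)])


def detect_constraint_mask(v: np.ndarray, tol: float = 0.05) -> np.ndarray:
    """Extremum pixels: those deviating from the modal background value
    by more than ``tol``."""
    return np.abs(v - _modal_value(v)) > tol


_KERNEL = np.ones((3, 3))


def _mean_pass(v: np.ndarray) -> np.ndarray:
    # truncated windows: corners average 4 values, edges 6, interior 9
    num = convolve2d(v, _KERNEL, mode="same")
    den = convolve2d(np.ones_like(v), _KERNEL, mode="same")
    return num / den


def smooth_heightmap(
    height_image: PixelImage,
    iterations: int = 100,
    constrain: bool = True,
    constraint_mask: np.ndarray | None = None,
    amplitude: float | None = None,
) -> HeightMap:
    """Run synchronous 3x3-mean smoothing passes on the height image.

    With ``constrain=True`` (default) extremum pixels — auto-detected
    as deviating > 0.05 from the modal background, or given explicitly
    via ``constraint_mask`` — are reset to their initial values after
    every pass, so the encoded maximum/minimum heights survive any
    number of iterations.
    """
    if iterations < 0:
        raise ValidationError("iterations must be >= 0")
    v0 = height_image.values.astype(float)
    if constraint_mask is not None:
        mask = np.asarray(constraint_mask, dtype=bool)
        if mask.shape != v0.shape:
            raise FrameMismatchError("constraint mask frame differs from image")
    else:
        mask = detect_constraint_mask(v0)
    v = v0.copy()
    for _ in range(iterations):
        v = _mean_pass(v)
        if constrain:
            v[mask] = v0[mask]
    if amplitude is None:
        amplitude = default_amplitude(v0.shape)
    return HeightMap(
        v=v, constrained=mask, iterations=iterations, amplitude=float(amplitude)
    )


def apply_heights(mesh: TriMesh, hmap: HeightMap) -> TriMesh:
    """Lift a 2-D mesh out of plane: z = A * (1 - v) at each node.

    Black (v=0) pixels reach the full amplitude A, white (v=1) stay in
    plane, grey values interpolate linearly; between pixel centres v is
    bilinear.  Nodes outside the heightmap frame are an error.
    """
    if mesh.is_3d:
        raise ValidationError("mesh already has z coordinates")
    n_rows, n_cols = hmap.shape
    xy = mesh.xy()
    x, y = xy[:, 0], xy[:, 1]
    eps = 1e-9
    if (
        (x < -eps).any()
        or (x > n_cols - 1 + eps).any()
        or (y < -eps).any()
        or (y > n_rows - 1 + eps).any()
    ):
        raise ValidationError("mesh node outside the heightmap frame")
    interp = RegularGridInterpolator(
        (np.arange(n_rows), np.arange(n_cols)), hmap.v, method="linear"
    )
    rows = np.clip((n_rows - 1.0) - y, 0, n_rows - 1)
    cols = np.clip(x, 0, n_cols - 1)
    v = interp(np.column_stack([rows, cols]))
    z = hmap.amplitude * (1.0 - v)
    return _dc_replace(mesh, nodes=np.column_stack([xy, z]))
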