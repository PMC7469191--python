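"""Raster image loading, binarization, and the pixel→plane coordinate
convention shared by every downstream stage.

The pipeline works on black-and-white images in which black pixels
(value 0) are domain borders and white pixels (value 1) are interior or
exterior regions.  All geometry downstream (distance fields, meshing,
export) lives in a right-handed planar frame where a pixel at
``(row, col)`` sits at ``x = col``, ``y = (n_rows - 1) - row`` — i.e. the
top image row maps to the top of the y-axis and exported models appear
upright in FE viewers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import ValidationError

__all__ = [
    "PixelImage",
    "GridPoint",
    "load_image",
    "from_array",
    "check_same_frame",
    "pixel_to_xy",
    "xy_to_pixel",
]


class GridPoint(NamedTuple):
    """0-based pixel index; ``row`` counts down from the top row."""

    row: int
    col: int


@dataclass(frozen=True)
class PixelImage:
    """A raster grid of intensities in [0, 1].

    Parameters
    ----------
    values
        Array of shape ``(n_rows, n_cols)`` with entries in [0, 1].
    kind
        ``"binary"`` if every value is exactly 0 or 1, else
        ``"continuous"``.
    """

    values: np.ndarray
    kind: str = "continuous"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValidationError(f"image must be 2-D, got shape {v.shape}")
        if v.shape[0] < 3 or v.shape[1] < 3:
            raise ValidationError(
                f"image must be at least 3x3, got {v.shape[0]}x{v.shape[1]}"
            )
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValidationError("pixel values must lie in [0, 1]")
        if self.kind == "binary" and not np.isin(v, (0.0, 1.0)).all():
            raise ValidationError("binary image contains non-{0,1} values")
        if self.kind not in ("binary", "continuous"):
            raise ValidationError(f"unknown image kind {self.kind!r}")
        object.__setattr__(self, "values", v)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def from_array(
    values: np.ndarray, mode: str = "binary", threshold: float = 0.5
) -> PixelImage:
    """Build a :class:`PixelImage` from an in-memory array.

    Arrays of integer dtype are rescaled by their dtype maximum; float
    arrays are taken to already lie in [0, 1].  ``mode="binary"``
    thresholds at ``threshold`` (values strictly below map to 0).
    """
    arr = np.asarray(values)
    if arr.ndim == 3:  # colour → luminance (Rec. 601 weights)
        arr = arr[..., :3].astype(float) @ np.array([0.2989, 0.5870, 0.1140])
        if np.issubdtype(np.asarray(values).dtype, np.integer):
            arr = arr / np.iinfo(np.asarray(values).dtype).max
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    arr = np.clip(arr, 0.0, 1.0)
    if mode == "binary":
        if not 0.0 < threshold < 1.0:
            raise ValidationError(f"threshold must be in (0,1), got {threshold}")
        arr = np.where(arr < threshold, 0.0, 1.0)
        return PixelImage(arr, kind="binary")
    elif mode == "continuous":
        return PixelImage(arr, kind="continuous")
    raise ValidationError(f"unknown mode {mode!r}")


def load_image(path, mode: str = "binary", threshold: float = 0.5) -> PixelImage:
    """Load a PNG/BMP/TIFF raster and normalise it to [0, 1].

    Colour images are converted to luminance before thresholding.
    ``mode="binary"`` maps values below ``threshold`` to 0 (border) and
    the rest to 1; ``mode="continuous"`` keeps the grayscale values
    (used for corrugation heightmaps).
    """
    import imageio.v3 as iio

    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by backend
        raise OSError(f"cannot read image {path!r}: {exc}") from exc
    return from_array(raw, mode=mode, threshold=threshold)


def check_same_frame(a: PixelImage, b: PixelImage) -> bool:
    """True iff the two images have identical frame sizes."""
    return a.shape == b.shape


def pixel_to_xy(p: GridPoint, image: PixelImage) -> tuple[float, float]:
    """Map a grid point to planar coordinates (pixel centres at integers).

    ``x = col``; ``y = (n_rows - 1) - row`` so y increases upward.
    """
    row, col = p
    if not (0 <= row < image.n_rows and 0 <= col < image.n_cols):
        raise ValidationError(
            f"pixel ({row},{col}) outside {image.n_rows}x{image.n_cols} image"
        )
    return float(col), float(image.n_rows - 1 - row)


def xy_to_pixel(x: float, y: float, image: PixelImage) -> GridPoint:
    """Inverse of :func:`pixel_to_xy` for integer-coordinate points."""
    row = int(round(image.n_rows - 1 - y))
    col = int(round(x))
    if not (0 <= row < image.n_rows and 0 <= col < image.n_cols):
        raise ValidationError(f"point ({x},{y}) outside image frame")
    return GridPoint(row, col)
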