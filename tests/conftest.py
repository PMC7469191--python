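"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own implementations:
region equivalence is checked against scipy.ndimage connected-component
labelling, distances against a brute-force minimum over pixel centres.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from wingforge import fixtures as fx
from wingforge.distance_field import (
    build_signed_distance,
    combine_fixed_points,
    select_boundary_fixed_points,
    select_fixed_points,
)
from wingforge.region_detect import detect_regions

FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def flood_fill_oracle(values: np.ndarray, seed: tuple[int, int]):
    """Reference 4-connected flood fill: returns (interior, boundary)
    boolean masks via scipy connected-component labelling."""
    white = values == 1.0
    labels, _ = ndimage.label(white, structure=FOUR)
    comp = labels == labels[seed]
    dilated = ndimage.binary_dilation(comp, structure=FOUR)
    return comp, dilated & ~white


def brute_force_min_distance(mask: np.ndarray) -> np.ndarray:
    """|signed distance| oracle: per-pixel minimum Euclidean distance to
    the opposite set, by explicit all-pairs minimisation over opposite
    pixel centres (chunked to bound memory)."""
    from scipy.spatial.distance import cdist

    n_rows, n_cols = mask.shape
    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    flat = mask.ravel()
    out = np.empty(mask.size)
    for side in (True, False):
        src = pts[flat == side]
        opp = pts[flat != side]
        mins = np.empty(len(src))
        for start in range(0, len(src), 1024):
            mins[start : start + 1024] = cdist(
                src[start : start + 1024], opp
            ).min(axis=1)
        out[flat == side] = mins
    return out.reshape(mask.shape)


def standard_pfix(region, spacing=8.0):
    """Interface + outline fixed points, as the pipeline builds them."""
    ip = select_fixed_points(region, spacing)
    bp = select_boundary_fixed_points(region, spacing, avoid=ip)
    return combine_fixed_points(ip, bp, spacing)


@pytest.fixture(scope="session")
def rectangle_fixture():
    return fx.make_rectangle()


@pytest.fixture(scope="session")
def partitioned_fixture():
    return fx.make_partitioned_rectangle()


@pytest.fixture(scope="session")
def holey_fixture():
    return fx.make_holey_rectangle()


@pytest.fixture(scope="session")
def rectangle_region(rectangle_fixture):
    image, seeds = rectangle_fixture
    return detect_regions(image, seeds)


@pytest.fixture(scope="session")
def partitioned_region(partitioned_fixture):
    image, seeds = partitioned_fixture
    return detect_regions(image, seeds)


@pytest.fixture(scope="session")
def holey_region(holey_fixture):
    image, seeds = holey_fixture
    return detect_regions(image, seeds)


@pytest.fixture(scope="session")
def rectangle_field(rectangle_region):
    return build_signed_distance(rectangle_region)
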