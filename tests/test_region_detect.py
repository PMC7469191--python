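import numpy as np
import pytest

from wingforge import fixtures as fx
from wingforge.errors import (
    DuplicateSeedError,
    OpenBoundaryError,
    SeedOnBorderError,
    UnseededRegionError,
    ValidationError,
)
from wingforge.image_io import GridPoint, PixelImage
from wingforge.region_detect import (
    BORDER,
    OUTSIDE,
    SeedSpec,
    burn,
    detect_regions,
    interface_pixels,
)

from conftest import flood_fill_oracle


def ring_image(n=5):
    v = np.ones((n, n))
    v[0, :] = v[-1, :] = v[:, 0] = v[:, -1] = 0.0
    return PixelImage(v, kind="binary")


class TestBurn:
    def test_ring_interior_and_boundary(self):
        img = ring_image(5)
        interior, boundary = burn(img, (2, 2))
        assert interior == {GridPoint(r, c) for r in (1, 2, 3) for c in (1, 2, 3)}
        # all 16 ring pixels are 4-adjacent to the 3x3 interior? only
        # those sharing an edge with it: the 12 non-corner ring pixels
        expected = {
            GridPoint(r, c)
            for r in range(5)
            for c in range(5)
            if (r in (0, 4) or c in (0, 4))
            and any(
                (abs(r - ir) + abs(c - ic)) == 1
                for ir in (1, 2, 3)
                for ic in (1, 2, 3)
            )
        }
        assert boundary == expected

    def test_seed_on_black_rejected(self):
        with pytest.raises(SeedOnBorderError):
            burn(ring_image(5), (0, 0))

    def test_seed_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            burn(ring_image(5), (9, 9))

    def test_all_white_image(self):
        img = PixelImage(np.ones((5, 5)), kind="binary")
        interior, boundary = burn(img, (2, 2))
        assert len(interior) == 25
        assert boundary == set()

    @pytest.mark.parametrize("seed_idx", range(25))
    def test_matches_flood_fill_oracle_on_random_blobs(self, seed_idx):
        img = fx.make_random_blobs(rng_seed=seed_idx)
        white = np.argwhere(img.values == 1.0)
        pick = white[seed_idx % len(white)]
        interior, boundary = burn(img, tuple(pick))
        ref_int, ref_bnd = flood_fill_oracle(img.values, tuple(pick))
        got_int = np.zeros(img.shape, dtype=bool)
        got_bnd = np.zeros(img.shape, dtype=bool)
        for r, c in interior:
            got_int[r, c] = True
        for r, c in boundary:
            got_bnd[r, c] = True
        np.testing.assert_array_equal(got_int, ref_int)
        np.testing.assert_array_equal(got_bnd, ref_bnd)

    def test_seed_position_invariant(self):
        img = fx.make_random_blobs(rng_seed=3)
        white = np.argwhere(img.values == 1.0)
        a, _ = burn(img, tuple(white[0]))
        other = next(tuple(w) for w in white[1:] if GridPoint(*w) in a)
        b, _ = burn(img, other)
        assert a == b


class TestDetectRegions:
    def test_rectangle_partition(self, rectangle_fixture):
        image, seeds = rectangle_fixture
        region = detect_regions(image, seeds)
        assert region.n_subdomains == 1
        assert region.n_holes == 0
        labels = region.labels
        total = (
            (labels == OUTSIDE).sum()
            + (labels == BORDER).sum()
            + (labels == 1).sum()
        )
        assert total == image.n_rows * image.n_cols

    def test_partitioned_with_hole(self, holey_fixture):
        image, seeds = holey_fixture
        region = detect_regions(image, seeds)
        assert region.n_subdomains == 2
        assert region.n_holes == 1
        hole = region.hole_mask(1)
        for k in (1, 2):
            assert not (hole & region.subdomain_mask(k)).any()

    def test_label_counts_partition_the_image(self, partitioned_region):
        labels = partitioned_region.labels
        counts = sum(
            (labels == lab).sum()
            for lab in (OUTSIDE, BORDER, 1, 2)
        )
        assert counts == labels.size

    def test_broken_outline_raises_open_boundary(self):
        image, seeds = fx.make_rectangle((50, 50), margin=5)
        v = image.values.copy()
        v[5, 20] = 1.0  # knock one pixel out of the outline
        broken = PixelImage(v, kind="binary")
        with pytest.raises(OpenBoundaryError):
            detect_regions(broken, seeds)

    def test_duplicate_seeds_rejected(self, rectangle_fixture):
        image, seeds = rectangle_fixture
        double = SeedSpec(
            subdomain_seeds=seeds.subdomain_seeds + seeds.subdomain_seeds
        )
        with pytest.raises(DuplicateSeedError):
            detect_regions(image, double)

    def test_unseeded_cavity_reported(self, holey_fixture):
        image, seeds = holey_fixture
        missing = SeedSpec(subdomain_seeds=seeds.subdomain_seeds)  # no hole seed
        with pytest.raises(UnseededRegionError):
            detect_regions(image, missing)

    def test_seed_order_permutes_labels_not_partition(self, partitioned_fixture):
        image, seeds = partitioned_fixture
        fwd = detect_regions(image, seeds)
        rev = detect_regions(
            image, SeedSpec(subdomain_seeds=seeds.subdomain_seeds[::-1])
        )
        np.testing.assert_array_equal(
            fwd.subdomain_mask(1), rev.subdomain_mask(2)
        )
        np.testing.assert_array_equal(
            fwd.labels == BORDER, rev.labels == BORDER
        )


@pytest.fixture(scope="module")
def divided():
    # 26-row frame, margin 2: outline rows 2..23, divider rows 3..22
    image, seeds = fx.make_partitioned_rectangle((26, 41), margin=2, n_cells=2)
    return detect_regions(image, seeds)


class TestInterfacePixels:

    def test_divider_line_pixels(self, divided):
        pix = interface_pixels(divided, 1, 2)
        assert len(pix) == 20
        cols = {p.col for p in pix}
        assert len(cols) == 1  # a single vertical line
        assert {p.row for p in pix} == set(range(3, 23))

    def test_same_subdomain_rejected(self, divided):
        with pytest.raises(ValidationError):
            interface_pixels(divided, 1, 1)

    def test_disjoint_outlines_share_no_wall(self):
        v = np.ones((20, 40))
        for c0 in (2, 22):
            v[2, c0 : c0 + 16] = 0
            v[17, c0 : c0 + 16] = 0
            v[2:18, c0] = 0
            v[2:18, c0 + 15] = 0
        image = PixelImage(v, kind="binary")
        region = detect_regions(
            image, SeedSpec(subdomain_seeds=((9, 9), (9, 29)))
        )
        assert interface_pixels(region, 1, 2) == set()
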