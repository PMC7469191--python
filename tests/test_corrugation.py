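import numpy as np
import pytest

from wingforge import fixtures as fx
from wingforge.corrugation import (
    HeightMap,
    apply_heights,
    default_amplitude,
    smooth_heightmap,
)
from wingforge.errors import FrameMismatchError, ValidationError
from wingforge.image_io import PixelImage
from wingforge.mesher import TriMesh


def delta3():
    v = np.ones((3, 3))
    v[1, 1] = 0.0
    return PixelImage(v, kind="binary")


class TestSmoothing:
    @pytest.mark.parametrize("n", [0, 1, 10, 100])
    def test_uniform_image_is_fixed_point(self, n):
        img = PixelImage(np.full((6, 6), 0.5))
        out = smooth_heightmap(img, iterations=n, constrain=False)
        np.testing.assert_allclose(out.v, 0.5)

    def test_single_pass_truncated_window_means(self):
        out = smooth_heightmap(delta3(), iterations=1, constrain=False)
        assert out.v[1, 1] == pytest.approx(8 / 9)
        assert out.v[0, 0] == pytest.approx(3 / 4)
        assert out.v[0, 1] == pytest.approx(5 / 6)  # edge: 6-px window

    @pytest.mark.parametrize("n", [1, 5, 50])
    def test_constrained_extrema_held(self, n):
        out = smooth_heightmap(delta3(), iterations=n, constrain=True)
        assert out.v[1, 1] == 0.0

    def test_maximum_principle(self):
        ridge = fx.make_ridge_heightmap((40, 40))
        for n in (1, 20, 300):
            out = smooth_heightmap(ridge, iterations=n, constrain=False)
            assert out.v.min() >= ridge.values.min() - 1e-12
            assert out.v.max() <= ridge.values.max() + 1e-12

    def test_total_variation_non_increasing(self):
        def tv(v):
            return np.abs(np.diff(v, axis=0)).sum() + np.abs(np.diff(v, axis=1)).sum()

        ridge = fx.make_ridge_heightmap((40, 40))
        prev = tv(ridge.values)
        v = ridge
        for _ in range(5):
            out = smooth_heightmap(v, iterations=1, constrain=False)
            cur = tv(out.v)
            assert cur <= prev + 1e-12
            prev = cur
            v = PixelImage(out.v)

    def test_constrained_mode_converges_on_ridge(self):
        from wingforge.corrugation import _mean_pass, detect_constraint_mask

        ridge = fx.make_ridge_heightmap((40, 40))
        v0 = ridge.values
        mask = detect_constraint_mask(v0)
        v = v0.copy()
        for n in range(20000):
            nxt = _mean_pass(v)
            nxt[mask] = v0[mask]
            delta = np.abs(nxt - v).max()
            v = nxt
            if delta < 1e-6:
                break
        assert delta < 1e-6
        # the relaxed field peaks (max height = min v) right beside the
        # held ridge line
        peak = np.unravel_index(np.argmin(np.where(mask, np.inf, v)), v.shape)
        ridge_cols = np.nonzero(mask.any(axis=0))[0]
        assert min(abs(peak[1] - c) for c in ridge_cols) <= 1

    def test_sharpness_decreases_with_iterations(self):
        ridge = fx.make_ridge_heightmap((60, 60))
        grads = []
        for n in (20, 100, 150, 200, 300):
            v = smooth_heightmap(ridge, iterations=n, constrain=True).v
            z = 1.0 - v  # height profile
            grads.append(np.abs(np.diff(z, axis=1)).max())
        assert all(a > b for a, b in zip(grads, grads[1:]))

    def test_negative_iterations_rejected(self):
        with pytest.raises(ValidationError):
            smooth_heightmap(delta3(), iterations=-1)

    def test_explicit_constraint_mask(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 0] = True
        out = smooth_heightmap(delta3(), iterations=3, constraint_mask=mask)
        assert out.v[0, 0] == 1.0  # held at its initial value
        assert out.v[1, 1] != 0.0  # centre no longer constrained

    def test_mask_frame_mismatch(self):
        with pytest.raises(FrameMismatchError):
            smooth_heightmap(delta3(), constraint_mask=np.zeros((4, 4), dtype=bool))


class TestApplyHeights:
    def _flat_mesh(self, pts):
        n = len(pts)
        tris = [[i, i + 1, i + 2] for i in range(n - 2)]
        return TriMesh(nodes=np.asarray(pts, float), triangles=np.asarray(tris))

    def test_extremes_and_interpolation(self):
        # 3-col map: v = 0, 0.2, 0.4 in columns 0..2
        v = np.tile(np.array([0.0, 0.2, 0.4]), (3, 1))
        hmap = HeightMap(v=v, constrained=np.zeros_like(v, bool), iterations=0, amplitude=10.0)
        mesh = self._flat_mesh([[0.0, 1.0], [2.0, 1.0], [1.5, 1.0], [0.5, 2.0]])
        out = apply_heights(mesh, hmap)
        z = out.nodes[:, 2]
        assert z[0] == pytest.approx(10.0)  # v=0 -> maximum height A
        assert z[1] == pytest.approx(6.0)  # v=0.4
        assert z[3] == pytest.approx(9.0)  # midway between 0 and 0.2 -> v=0.1
        # node midway between v=0.2 and v=0.4 -> z = 10*(1-0.3) = 7
        assert z[2] == pytest.approx(7.0)

    def test_z_range_bounded_by_amplitude(self):
        rng = np.random.default_rng(0)
        v = rng.random((8, 8))
        hmap = HeightMap(v=v, constrained=np.zeros_like(v, bool), iterations=0, amplitude=5.0)
        pts = np.column_stack([rng.uniform(0, 7, 30), rng.uniform(0, 7, 30)])
        out = apply_heights(self._flat_mesh(pts), hmap)
        assert out.nodes[:, 2].min() >= 0.0
        assert out.nodes[:, 2].max() <= 5.0

    def test_node_outside_frame_rejected(self):
        v = np.ones((5, 5))
        hmap = HeightMap(v=v, constrained=np.zeros_like(v, bool), iterations=0, amplitude=1.0)
        with pytest.raises(ValidationError):
            apply_heights(self._flat_mesh([[0, 0], [9, 0], [1, 1]]), hmap)

    def test_already_3d_rejected(self):
        v = np.ones((5, 5))
        hmap = HeightMap(v=v, constrained=np.zeros_like(v, bool), iterations=0, amplitude=1.0)
        mesh = TriMesh(
            nodes=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
            triangles=np.array([[0, 1, 2]]),
        )
        with pytest.raises(ValidationError):
            apply_heights(mesh, hmap)

    def test_default_amplitude_is_five_percent_of_frame(self):
        assert default_amplitude((120, 240)) == pytest.approx(12.0)
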