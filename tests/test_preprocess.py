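"""Preprocessing chain: crop, block-mean downscale, pad, min-max."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import spottune3d as st


def _vol(arr, spacing=(1.0, 1.0, 1.0)):
    return st.MRVolume(np.asarray(arr, dtype=float), spacing)


def _mask_with_blob(shape, center, r=2):
    m = np.zeros(shape, dtype=np.int16)
    sl = tuple(slice(max(c - r, 0), min(c + r + 1, s))
               for c, s in zip(center, shape))
    m[sl] = 2
    return st.SegmentationMask(m)


class TestCrop:
    def test_identity_crop(self, rng):
        v = _vol(rng.random((10, 10, 10)))
        m = _mask_with_blob((10, 10, 10), (5, 5, 5))
        out = st.crop_to_tumor(v, m, (10, 10, 10))
        assert np.array_equal(out.voxels, v.voxels)

    def test_centroid_near_face_window_flush(self, rng):
        v = _vol(rng.random((20, 20, 20)))
        m = _mask_with_blob((20, 20, 20), (3, 10, 10), r=1)
        out = st.crop_to_tumor(v, m, (12, 12, 12))
        assert out.shape == (12, 12, 12)
        # exhaustive check: retained block must equal the flush window
        assert np.array_equal(out.voxels, v.voxels[0:12, 4:16, 4:16])

    def test_empty_mask_rejected(self, rng):
        v = _vol(rng.random((8, 8, 8)))
        empty = st.SegmentationMask(np.zeros((8, 8, 8), dtype=np.int16))
        with pytest.raises(ValueError, match="empty"):
            st.crop_to_tumor(v, empty, (4, 4, 4))

    def test_oversized_crop_rejected(self, rng):
        v = _vol(rng.random((8, 8, 8)))
        m = _mask_with_blob((8, 8, 8), (4, 4, 4))
        with pytest.raises(ValueError, match="crop_shape"):
            st.crop_to_tumor(v, m, (9, 8, 8))


class TestDownscale:
    def test_block_mean_oracle(self):
        v = _vol(np.arange(64, dtype=float).reshape(4, 4, 4))
        out = st.downscale(v, 2)
        expected = np.empty((2, 2, 2))
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    expected[i, j, k] = v.voxels[2 * i:2 * i + 2,
                                                 2 * j:2 * j + 2,
                                                 2 * k:2 * k + 2].mean()
        assert np.allclose(out.voxels, expected)
        assert out.spacing_mm == (2.0, 2.0, 2.0)

    def test_factor_one_identity(self, rng):
        v = _vol(rng.random((5, 5, 5)))
        assert np.array_equal(st.downscale(v, 1).voxels, v.voxels)

    def test_odd_axis_floor(self, rng):
        v = _vol(rng.random((5, 6, 7)))
        assert st.downscale(v, 2).shape == (2, 3, 3)

    def test_factor_too_large(self, rng):
        with pytest.raises(ValueError):
            st.downscale(_vol(rng.random((3, 3, 3))), 4)


class TestPad:
    def test_even_deficit_symmetric(self, rng):
        v = _vol(rng.random((7, 8, 4)))
        out = st.pad_square_slices(v, 8)
        assert out.shape == (7, 8, 8)
        assert np.array_equal(out.voxels[:, :, 2:6], v.voxels)

    def test_odd_deficit_extra_high_side(self, rng):
        v = _vol(rng.random((7, 8, 5)))
        out = st.pad_square_slices(v, 8)
        # deficit 3 -> 1 low, 2 high; locate the original subarray
        assert np.array_equal(out.voxels[:, :, 1:6], v.voxels)
        assert np.all(out.voxels[:, :, 0] == 0)
        assert np.all(out.voxels[:, :, 6:] == 0)

    def test_already_target_unchanged(self, rng):
        v = _vol(rng.random((7, 8, 8)))
        assert np.array_equal(st.pad_square_slices(v, 8).voxels, v.voxels)

    def test_overlong_axis_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            st.pad_square_slices(_vol(rng.random((7, 8, 9))), 8)


class TestMinMax:
    def test_affine_endpoints(self):
        v = _vol(np.array([2.0, 4.0, 6.0]).reshape(1, 1, 3))
        out = st.minmax_normalize(v)
        assert np.allclose(out.voxels.ravel(), [0.0, 0.5, 1.0])

    def test_idempotent_on_unit_range(self, rng):
        x = rng.random((4, 4, 4))
        x.flat[0], x.flat[-1] = 0.0, 1.0
        v = _vol(x)
        assert np.allclose(st.minmax_normalize(v).voxels, x)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(hst.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_range_and_perfect_correlation(self, seed):
        x = np.random.default_rng(seed).normal(size=(4, 5, 6))
        out = st.minmax_normalize(_vol(x)).voxels
        assert out.min() == 0.0 and out.max() == 1.0
        r = np.corrcoef(out.ravel(), x.ravel())[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            st.minmax_normalize(_vol(np.full((3, 3, 3), 2.0)))


class TestFullChain:
    def test_study_geometry(self, rng):
        # 155×240×240 -> crop 140×172×164 -> downscale 70×86×82 -> pad 86
        v = _vol(rng.random((155, 240, 240)))
        m = _mask_with_blob((155, 240, 240), (80, 120, 120), r=6)
        out = st.preprocess_volume(v, m)
        assert out.shape == (70, 86, 86)
        assert out.voxels.min() == 0.0 and out.voxels.max() == 1.0
        assert out.spacing_mm == (2.0, 2.0, 2.0)

    def test_chain_deterministic(self, rng):
        x = rng.random((32, 32, 32))
        m = _mask_with_blob((32, 32, 32), (16, 16, 16), r=4)
        cfg = st.PreprocessConfig((28, 28, 28), 2, 14)
        a = st.preprocess_volume(_vol(x), m, cfg).voxels
        b = st.preprocess_volume(_vol(x.copy()), m, cfg).voxels
        assert np.array_equal(a, b)
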