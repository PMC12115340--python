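import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage

from vitrophen import segment
from vitrophen.errors import (
    ConfigurationError,
    DimensionMismatchError,
    EmptyMaskWarning,
)
from vitrophen.segment import (
    CRUCIFORM,
    SegmentationConfig,
    binarize,
    clean_mask,
    crop,
    fill_small,
    or_masks,
    segment_plant,
)
from vitrophen.synthgen import SceneSpec, generate_scene

masks = hnp.arrays(dtype=bool, shape=st.tuples(st.integers(1, 16), st.integers(1, 16)))


class TestConfig:
    def test_defaults_match_published_pipeline(self):
        cfg = SegmentationConfig()
        assert (cfg.crop_width, cfg.crop_height) == (2800, 2600)
        assert cfg.y_threshold == 45
        assert cfg.a_threshold == 124
        assert cfg.close_kernel == 5

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"y_threshold": 300},
            {"a_threshold": -1},
            {"close_kernel": 4},
            {"close_kernel": 1},
            {"fill_min_size": 0},
            {"crop_width": 0},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SegmentationConfig(**kwargs)

    def test_from_file_json_and_yaml(self, tmp_path):
        (tmp_path / "c.json").write_text('{"y_threshold": 50, "crop_width": 100}')
        (tmp_path / "c.yaml").write_text("y_threshold: 50\ncrop_width: 100\n")
        for name in ("c.json", "c.yaml"):
            cfg = SegmentationConfig.from_file(tmp_path / name)
            assert cfg.y_threshold == 50 and cfg.crop_width == 100

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown"):
            SegmentationConfig.from_mapping({"treshold": 45})


class TestCrop:
    def test_full_resolution_default_crop(self):
        img = np.zeros((4000, 6000, 3), dtype=np.uint8)
        out = crop(img, SegmentationConfig())
        assert out.shape == (2600, 2800, 3)

    def test_identity_crop(self):
        img = np.arange(4 * 5 * 3, dtype=np.uint8).reshape(4, 5, 3)
        out = crop(img, SegmentationConfig(crop_width=5, crop_height=4))
        np.testing.assert_array_equal(out, img)

    def test_oversized_crop_names_dimension(self):
        img = np.zeros((4, 5, 3), dtype=np.uint8)
        with pytest.raises(ConfigurationError, match="crop_width"):
            crop(img, SegmentationConfig(crop_width=6, crop_height=4))
        with pytest.raises(ConfigurationError, match="crop_height"):
            crop(img, SegmentationConfig(crop_width=5, crop_height=5))

    def test_anchor_out_of_bounds(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        cfg = SegmentationConfig(crop_width=5, crop_height=5, crop_anchor=(7, 0))
        with pytest.raises(ConfigurationError):
            crop(img, cfg)

    def test_centred_anchor(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        img[3:8, 2:7] = 9
        cfg = SegmentationConfig(crop_width=6, crop_height=4)
        out = crop(img, cfg)  # anchor (3, 2)
        np.testing.assert_array_equal(out, img[3:7, 2:8])


class TestBinarize:
    def test_strictly_above(self):
        ch = np.array([[44, 46]], dtype=np.uint8)
        np.testing.assert_array_equal(binarize(ch, 45, "above"), [[False, True]])

    def test_boundary_empty(self):
        ch = np.full((3, 3), 45, dtype=np.uint8)
        assert not binarize(ch, 45, "above").any()

    def test_at_or_below_realises_inversion(self):
        ch = np.array([[120, 124, 130]], dtype=np.uint8)
        np.testing.assert_array_equal(
            binarize(ch, 124, "at_or_below"), [[True, True, False]]
        )

    def test_bad_keep_mode(self):
        with pytest.raises(ConfigurationError):
            binarize(np.zeros((2, 2), dtype=np.uint8), 10, "below")


class TestCleanMask:
    def test_isolated_pixel_removed(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        assert not clean_mask(m).any()

    def test_square_loses_corners(self):
        m = np.zeros((14, 14), bool)
        m[2:12, 2:12] = True
        out = clean_mask(m)
        expected = m.copy()
        for r, c in [(2, 2), (2, 11), (11, 2), (11, 11)]:
            expected[r, c] = False
        np.testing.assert_array_equal(out, expected)

    def test_closing_bridges_small_gap(self):
        m = np.zeros((11, 11), bool)
        m[5, 4] = m[5, 6] = True  # two pixels 2 apart
        square = np.ones((5, 5), bool)
        closed = ndimage.binary_erosion(
            ndimage.binary_dilation(m, structure=square), structure=square
        )
        _, n = ndimage.label(closed, structure=np.ones((3, 3)))
        assert n == 1

    def test_opening_contained_in_closing(self, rng):
        for _ in range(20):
            m = rng.random((20, 20)) < 0.4
            square = np.ones((5, 5), bool)
            closed = ndimage.binary_erosion(
                ndimage.binary_dilation(m, structure=square), structure=square
            )
            assert not (clean_mask(m) & ~closed).any()


class TestFillSmall:
    def test_drops_small_components(self):
        m = np.zeros((20, 20), bool)
        m[0, 0:3] = True  # size 3
        m[5:13, 5:15] = True  # size 80
        out = fill_small(m, 50)
        assert out.sum() == 80
        assert not out[0].any()

    def test_min_size_one_is_identity(self, rng):
        m = rng.random((15, 15)) < 0.3
        np.testing.assert_array_equal(fill_small(m, 1), m)

    def test_empty_mask(self):
        assert not fill_small(np.zeros((5, 5), bool), 10).any()

    def test_anti_extensive(self, rng):
        for _ in range(20):
            m = rng.random((20, 20)) < 0.3
            assert not (fill_small(m, 5) & ~m).any()

    def test_exact_threshold_kept(self):
        m = np.zeros((5, 5), bool)
        m[1:3, 1:3] = True  # size 4
        assert fill_small(m, 4).sum() == 4
        assert fill_small(m, 5).sum() == 0


class TestOrMasks:
    def test_identity_and_idempotence(self, rng):
        m = rng.random((8, 8)) < 0.5
        empty = np.zeros((8, 8), bool)
        np.testing.assert_array_equal(or_masks(m, empty), m)
        np.testing.assert_array_equal(or_masks(m, m), m)

    def test_disjoint_additivity(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0, :] = True  # 10 px
        b[5:7, :] = True  # 20 px
        assert or_masks(a, b).sum() == 30

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionMismatchError):
            or_masks(np.zeros((2, 2), bool), np.zeros((3, 2), bool))

    @settings(max_examples=50, deadline=None)
    @given(data=st.data(), shape=st.tuples(st.integers(1, 12), st.integers(1, 12)))
    def test_commutative_associative(self, data, shape):
        strat = hnp.arrays(dtype=bool, shape=shape)
        a, b, c = (data.draw(strat) for _ in range(3))
        np.testing.assert_array_equal(or_masks(a, b), or_masks(b, a))
        np.testing.assert_array_equal(
            or_masks(or_masks(a, b), c), or_masks(a, or_masks(b, c))
        )


class TestSegmentPlant:
    def test_all_background_warns_empty(self, scene_cfg):
        img = np.zeros((360, 480, 3), dtype=np.uint8)
        img[:] = (40, 70, 160)
        with pytest.warns(EmptyMaskWarning):
            mask, masked = segment_plant(img, scene_cfg)
        assert not mask.any()
        assert not masked.any()

    def test_synthetic_iou(self, scene_cfg):
        img, truth = generate_scene(SceneSpec(seed=3))
        mask, _ = segment_plant(img, scene_cfg)
        inter = (mask & truth.truth_mask).sum()
        union = (mask | truth.truth_mask).sum()
        assert inter / union >= 0.90

    def test_truth_recovered_away_from_borders(self, scene_cfg):
        img, truth = generate_scene(SceneSpec(seed=11))
        mask, _ = segment_plant(img, scene_cfg)
        interior = ndimage.binary_erosion(
            truth.truth_mask, structure=np.ones((3, 3)), iterations=2
        )
        assert not (interior & ~mask).any()

    def test_deterministic(self, scene_cfg):
        img, _ = generate_scene(SceneSpec(seed=5))
        m1, r1 = segment_plant(img, scene_cfg)
        m2, r2 = segment_plant(img, scene_cfg)
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_array_equal(r1, r2)

    def test_masked_background_is_zero(self, scene_cfg):
        img, _ = generate_scene(SceneSpec(seed=5))
        mask, masked = segment_plant(img, scene_cfg)
        assert not masked[~mask].any()


def test_cruciform_is_the_four_connected_cross():
    np.testing.assert_array_equal(
        CRUCIFORM, np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
    )
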