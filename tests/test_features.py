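import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from cytoiex.features import (
    FEATURE_COLUMNS,
    FeatureError,
    ShapiroNormalizer,
    _glcm_mask_restricted,
    apply_normalization,
    chromatin_entropy,
    extract_features,
    fit_normalization,
    nc_ratio,
    shape_features,
    texture_features,
)


def _disk_mask(radius, pad=5):
    mask = np.zeros((2 * (radius + pad),) * 2, dtype=bool)
    rr, cc = draw_disk((radius + pad, radius + pad), radius)
    mask[rr, cc] = True
    return mask


class TestShapeFeatures:
    def test_disk_matches_analytic_geometry(self):
        feats = shape_features(_disk_mask(50))
        assert abs(feats["area"] - np.pi * 50**2) / (np.pi * 50**2) < 0.01
        assert feats["eccentricity"] <= 0.1
        assert 0.95 <= feats["circularity"] <= 1.05

    def test_filled_square_has_unit_extent(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:50, 10:50] = True
        assert shape_features(mask)["extent"] == 1.0

    def test_ellipse_elongation(self):
        mask = np.zeros((160, 160), dtype=bool)
        rr, cc = draw_ellipse(80, 80, 30, 60)
        mask[rr, cc] = True
        assert abs(shape_features(mask)["elongation"] - 2.0) / 2.0 < 0.05

    def test_rejects_empty_and_multicomponent(self):
        with pytest.raises(FeatureError):
            shape_features(np.zeros((10, 10), dtype=bool))
        two = np.zeros((20, 20), dtype=bool)
        two[2:5, 2:5] = True
        two[12:15, 12:15] = True
        with pytest.raises(FeatureError):
            shape_features(two)

    def test_scale_equivariance(self):
        small = _disk_mask(25)
        big = _disk_mask(50)
        fs, fb = shape_features(small), shape_features(big)
        assert abs(fb["area"] / fs["area"] - 4.0) < 0.2
        assert abs(fb["perimeter"] / fs["perimeter"] - 2.0) < 0.1
        for key in ("circularity", "eccentricity", "solidity", "extent"):
            assert abs(fb[key] - fs[key]) <= 0.05 * max(abs(fs[key]), 1e-6)


class TestTextureFeatures:
    def test_constant_patch_degenerate_limits(self):
        mask = _disk_mask(20)
        gray = np.full(mask.shape, 128, dtype=np.uint8)
        feats = texture_features(mask, gray)
        assert feats["contrast"] == 0.0
        assert feats["dissimilarity"] == 0.0
        assert feats["homogeneity"] == 1.0
        assert feats["asm"] == 1.0
        assert feats["energy"] == 1.0
        assert feats["correlation"] == 1.0
        assert feats["std_dev"] == 0.0
        assert feats["hist_peaks"] == 1.0
        assert feats["hist_valleys"] == 0.0

    def test_checkerboard_contrast_at_angle_zero(self):
        # quantized levels {0, 31}: every horizontal pair differs by 31
        gray = np.zeros((32, 32), dtype=np.uint8)
        gray[::2, 1::2] = 255
        gray[1::2, ::2] = 255
        mask = np.ones((32, 32), dtype=bool)
        quant = (gray.astype(np.uint16) // 8).astype(np.uint8)
        glcm = _glcm_mask_restricted(quant, mask)
        p0 = glcm[:, :, 0, 0]  # angle 0
        i, j = np.meshgrid(np.arange(32), np.arange(32), indexing="ij")
        assert ((i - j) ** 2 * p0).sum() == pytest.approx(31**2)

    def test_energy_is_sqrt_asm(self, rng):
        mask = _disk_mask(15)
        gray = rng.integers(0, 256, size=mask.shape).astype(np.uint8)
        feats = texture_features(mask, gray)
        assert feats["energy"] == pytest.approx(np.sqrt(feats["asm"]))

    def test_rotation_robustness_of_angle_averaged_glcm(self, rng):
        mask = np.ones((64, 64), dtype=bool)
        gray = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
        f0 = texture_features(mask, gray)
        f90 = texture_features(mask, np.rot90(gray).copy())
        for key in ("contrast", "dissimilarity", "homogeneity", "asm"):
            assert abs(f90[key] - f0[key]) <= 0.10 * abs(f0[key])

    def test_bimodal_histogram_has_two_peaks_one_valley(self, rng):
        mask = np.ones((80, 80), dtype=bool)
        gray = np.where(rng.random((80, 80)) < 0.5,
                        rng.normal(60, 8, (80, 80)), rng.normal(190, 8, (80, 80)))
        feats = texture_features(mask, np.clip(gray, 0, 255).astype(np.uint8))
        assert feats["hist_peaks"] == 2.0
        assert feats["hist_valleys"] == 1.0


class TestEntropyAndNC:
    @pytest.mark.parametrize(
        "levels,expected",
        [(np.zeros(1024), 0.0), (np.tile([10, 200], 512), 1.0), (np.arange(1024) % 256, 8.0)],
    )
    def test_entropy_reference_points(self, levels, expected):
        mask = np.ones((32, 32), dtype=bool)
        gray = np.asarray(levels, dtype=np.uint8).reshape(32, 32)
        assert chromatin_entropy(mask, gray) == pytest.approx(expected)

    def test_nc_ratio_values(self):
        assert nc_ratio(100, 200) == pytest.approx(1.0)
        assert nc_ratio(3737.5, 3737.5 * (1 + 1 / 0.7075)) == pytest.approx(0.7075)
        assert nc_ratio(2093.3, 2093.3 * (1 + 1 / 0.4833)) == pytest.approx(0.4833)

    def test_nc_ratio_rejects_nonpositive_cytoplasm(self):
        with pytest.raises(FeatureError, match="cytoplasm"):
            nc_ratio(100, 100)


class TestFeatureTable:
    def test_column_order_and_completeness(self, rng):
        masks = [_disk_mask(15), _disk_mask(20)]
        shape = masks[1].shape
        masks[0] = np.pad(masks[0], ((0, shape[0] - masks[0].shape[0]), (0, shape[1] - masks[0].shape[1])))
        gray = rng.integers(0, 256, size=shape).astype(np.uint8)
        table = extract_features(masks, gray, labels=["normal", "malignant"])
        assert list(table.columns[1 : 1 + len(FEATURE_COLUMNS)]) == list(FEATURE_COLUMNS)
        assert not table[list(FEATURE_COLUMNS)].isna().any().any()


class TestNormalization:
    def test_gaussian_column_takes_zscore_branch(self, rng):
        table = pd.DataFrame({"area": rng.normal(100, 10, 200)})
        norm = ShapiroNormalizer().fit(table)
        assert norm.kinds_ == ["zscore"]
        z = norm.transform(table)[:, 0]
        assert abs(z.mean()) <= 0.1
        assert 0.9 <= z.std(ddof=1) <= 1.1

    def test_heavy_tailed_column_takes_rank_branch(self, rng):
        table = pd.DataFrame({"x": np.exp(rng.normal(0, 1.5, 200))})
        norm = ShapiroNormalizer().fit(table)
        assert norm.kinds_ == ["rank"]
        r = norm.transform(table)[:, 0]
        assert r.min() >= 0.0 and r.max() <= 1.0

    def test_constant_column_flagged_and_zeroed(self):
        table = pd.DataFrame({"c": np.ones(50)})
        norm = ShapiroNormalizer().fit(table)
        assert norm.kinds_ == ["constant"]
        assert np.all(norm.transform(table) == 0.0)

    def test_new_rows_use_training_statistics(self, rng):
        train = pd.DataFrame({"x": np.exp(rng.normal(0, 1.5, 200))})
        # rank transform of a value beyond the training range clamps to [0, 1]
        norm = ShapiroNormalizer().fit(train)
        out = norm.transform(pd.DataFrame({"x": [train["x"].max() * 10]}))
        assert out[0, 0] == pytest.approx(1.0, abs=0.01)

    def test_roundtrip_serialization(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=100), "b": np.exp(rng.normal(0, 2, 100))})
        norm = ShapiroNormalizer().fit(table)
        clone = ShapiroNormalizer.from_dict(norm.to_dict())
        np.testing.assert_allclose(clone.transform(table), norm.transform(table))

    def test_requires_eight_rows(self):
        with pytest.raises(ValueError):
            ShapiroNormalizer().fit(pd.DataFrame({"a": np.arange(5.0)}))

    def test_table_wrappers_only_touch_core_columns(self, rng):
        table = pd.DataFrame(
            {"cell_id": range(30), "area": rng.normal(3000, 200, 30),
             "circularity": rng.normal(0.8, 0.05, 30), "class": ["normal"] * 30}
        )
        model = fit_normalization(table)
        out = apply_normalization(model, table)
        assert set(model.columns) == {"area", "circularity"}
        assert (out["cell_id"] == table["cell_id"]).all()
        assert (out["class"] == "normal").all()
        assert abs(out["area"].mean()) < 0.2
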