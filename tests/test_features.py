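"""Shape, color-moment, and GLCM texture extraction against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from notoroot import (
    ALL_FEATURE_NAMES,
    COLOR_NAMES,
    FUSION_SUBSETS,
    SHAPE_NAMES,
    TEXTURE_NAMES,
    ExtractionConfig,
    PreprocessConfig,
    TextureConfig,
    color_moments,
    compute_glcm,
    extract_all,
    extract_color_features,
    extract_shape_features,
    extract_texture_features,
    generate_root_image,
    glcm_features,
    read_feature_csv,
    write_feature_csv,
)
from notoroot.exceptions import DegenerateTextureError, InputError
from notoroot.features import Glcm

from _oracles import oracle_glcm, oracle_moments, oracle_texture

NATIVE = ExtractionConfig(preprocess=PreprocessConfig(resize_to=None))


# ---------------------------------------------------------------------------
# shape

def _square_mask(size=100, canvas=160):
    mask = np.zeros((canvas, canvas), dtype=bool)
    o = (canvas - size) // 2
    mask[o : o + size, o : o + size] = True
    return mask


class TestShape:
    def test_axis_aligned_square(self):
        sf = extract_shape_features(_square_mask())
        assert sf.elongation == pytest.approx(1.0, rel=0.02)
        assert sf.duty_cycle == pytest.approx(1.0, rel=0.02)
        assert sf.rect_w == pytest.approx(100, rel=0.02)
        assert sf.rect_h == pytest.approx(100, rel=0.02)
        assert sf.min_w == pytest.approx(100, rel=0.02)
        assert sf.min_h == pytest.approx(100, rel=0.02)

    def test_elongated_rectangle(self):
        mask = np.zeros((260, 120), dtype=bool)
        mask[30:230, 35:85] = True  # 200 x 50
        sf = extract_shape_features(mask)
        assert sf.elongation == pytest.approx(4.0, rel=0.02)
        assert sf.radius == pytest.approx(np.hypot(100, 25), rel=0.02)

    def test_rotated_square(self):
        from skimage.transform import rotate

        base = _square_mask(100, 200).astype(float)
        rot = rotate(base, 45, order=0).astype(bool)
        sf = extract_shape_features(rot)
        assert sf.min_w == pytest.approx(100, rel=0.03)
        assert sf.min_h == pytest.approx(100, rel=0.03)
        assert sf.rect_w == pytest.approx(100 * np.sqrt(2), rel=0.03)
        assert sf.rect_h == pytest.approx(100 * np.sqrt(2), rel=0.03)

    def test_translation_invariance(self):
        a = extract_shape_features(_square_mask(60, 160))
        mask = np.zeros((160, 160), dtype=bool)
        mask[5:65, 90:150] = True
        b = extract_shape_features(mask)
        for name in ("area", "perimeter", "elongation", "duty_cycle", "radius"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-6)

    def test_scale_invariance_of_dimensionless_features(self):
        from skimage.transform import rescale

        from notoroot import SyntheticImageSpec

        _, mask, _ = generate_root_image(SyntheticImageSpec(), "I", seed=6)
        base = extract_shape_features(mask)
        for factor in (0.5, 2.0):
            scaled = rescale(mask.astype(float), factor, order=0).astype(bool)
            sf = extract_shape_features(scaled)
            assert sf.elongation == pytest.approx(base.elongation, rel=0.02)
            assert sf.duty_cycle == pytest.approx(base.duty_cycle, rel=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(InputError):
            extract_shape_features(np.zeros((32, 32), dtype=bool))


# ---------------------------------------------------------------------------
# color

class TestColorMoments:
    def test_constant_sample(self):
        assert color_moments([100.0] * 4) == pytest.approx((100.0, 0.0, 0.0, -3.0))

    def test_two_point_sample_matches_formula_oracle(self):
        got = color_moments([0.0, 2.0])
        assert got == pytest.approx(oracle_moments([0.0, 2.0]), abs=1e-12)
        assert got[:3] == pytest.approx((1.0, 1.0, 0.0))

    def test_matches_oracle_on_random_samples(self, rng):
        for _ in range(20):
            vals = rng.uniform(0, 255, size=rng.integers(2, 50))
            assert color_moments(vals) == pytest.approx(
                oracle_moments(list(vals)), abs=1e-9
            )

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 255), min_size=1, max_size=20))
    def test_permutation_invariance(self, values):
        assert color_moments(values) == pytest.approx(
            color_moments(values[::-1]), nan_ok=True
        )

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            color_moments([])


class TestColorFeatures:
    def test_pure_red_foreground(self):
        img = np.zeros((40, 40, 3), dtype=np.uint8)
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 10:30] = True
        img[mask] = (255, 0, 0)
        cm = extract_color_features(img, mask).as_dict()
        assert cm["Rmean"] == pytest.approx(255.0)
        assert cm["Gmean"] == pytest.approx(0.0)
        assert cm["Bmean"] == pytest.approx(0.0)
        for ch in "RGB":
            assert cm[f"{ch}var"] == pytest.approx(0.0)

    def test_background_independence(self, rng):
        img = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        mask = np.zeros((32, 32), dtype=bool)
        mask[8:24, 8:24] = True
        a = extract_color_features(img, mask).as_dict()
        img2 = img.copy()
        img2[~mask] = 255
        b = extract_color_features(img2, mask).as_dict()
        assert a == pytest.approx(b)

    def test_matches_per_pixel_oracle(self, rng):
        from skimage.color import rgb2hsv

        for _ in range(20):
            img = rng.integers(0, 256, (24, 24, 3), dtype=np.uint8)
            mask = rng.random((24, 24)) < 0.5
            mask[12, 12] = True
            got = extract_color_features(img, mask).as_dict()
            hsv = rgb2hsv(img) * 255.0
            planes = dict(
                R=img[..., 0].astype(float), G=img[..., 1].astype(float),
                B=img[..., 2].astype(float), H=hsv[..., 0], S=hsv[..., 1],
                V=hsv[..., 2],
            )
            for ch, plane in planes.items():
                vals = [plane[r, c] for r in range(24) for c in range(24) if mask[r, c]]
                mu, var, s, k = oracle_moments(vals)
                assert got[f"{ch}mean"] == pytest.approx(mu, abs=1e-9)
                assert got[f"{ch}var"] == pytest.approx(var, abs=1e-9)
                assert got[f"{ch}s"] == pytest.approx(s, abs=1e-9)
                assert got[f"{ch}k"] == pytest.approx(k, abs=1e-9)


# ---------------------------------------------------------------------------
# texture

class TestGlcm:
    def test_hand_enumerated_row(self):
        gray = np.array([[0, 0, 255, 255]], dtype=np.uint8)
        g = compute_glcm(gray, d=1, theta=0, levels=2)
        # unordered pair counts (0,0):2, (0,1):2, (1,1):2 over 6 ordered slots
        expected = np.array([[2, 1], [1, 2]]) / 6.0
        assert np.allclose(g.matrix, expected)

    def test_constant_image_single_diagonal(self):
        gray = np.full((8, 8), 100, dtype=np.uint8)
        g = compute_glcm(gray, d=1, theta=0, levels=64)
        q = (100 * 64) // 256
        assert g.matrix[q, q] == pytest.approx(1.0)
        assert g.matrix.sum() == pytest.approx(1.0)

    def test_symmetric_and_normalized(self, rng):
        for _ in range(10):
            gray = rng.integers(0, 256, (16, 16), dtype=np.uint8)
            for theta in (0, 45, 90, 135):
                g = compute_glcm(gray, d=2, theta=theta, levels=16)
                assert np.allclose(g.matrix, g.matrix.T)
                assert g.matrix.sum() == pytest.approx(1.0)

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(20):
            gray = rng.integers(0, 256, (12, 12), dtype=np.uint8)
            mask = rng.random((12, 12)) < 0.8
            mask[4:8, 4:8] = True
            for theta in (0, 45, 90, 135):
                g = compute_glcm(gray, mask, d=2, theta=theta, levels=8)
                assert np.allclose(
                    g.matrix, oracle_glcm(gray, mask, 2, theta, 8), atol=1e-12
                )

    def test_no_valid_pair_rejected(self):
        gray = np.zeros((8, 8), dtype=np.uint8)
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, 0] = True
        with pytest.raises(DegenerateTextureError):
            compute_glcm(gray, mask, d=2, theta=0, levels=8)


class TestGlcmFeatures:
    def test_two_by_two_diagonal_matrix(self):
        g = Glcm(np.array([[0.5, 0.0], [0.0, 0.5]]), d=1, theta=0, levels=2)
        tf = glcm_features(g)
        assert tf.homogeneity == pytest.approx(1.0)
        assert tf.contrast == pytest.approx(0.0)
        assert tf.dissimilarity == pytest.approx(0.0)
        assert tf.energy == pytest.approx(0.5)
        assert tf.entropy == pytest.approx(np.log10(2))
        assert tf.auto_correlation == pytest.approx(0.5)

    def test_single_entry_matrix(self):
        m = np.zeros((4, 4))
        m[2, 2] = 1.0
        tf = glcm_features(Glcm(m, 1, 0, 4))
        assert tf.energy == pytest.approx(1.0)
        assert tf.entropy == pytest.approx(0.0)
        assert tf.contrast == pytest.approx(0.0)
        assert tf.homogeneity == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            m = rng.random((8, 8))
            m = m + m.T
            m /= m.sum()
            tf = glcm_features(Glcm(m, 2, 0, 8))
            hom, con, dis, ent, ene, cor, auto = oracle_texture(m)
            assert tf.homogeneity == pytest.approx(hom, abs=1e-9)
            assert tf.contrast == pytest.approx(con, abs=1e-9)
            assert tf.dissimilarity == pytest.approx(dis, abs=1e-9)
            assert tf.entropy == pytest.approx(ent, abs=1e-9)
            assert tf.energy == pytest.approx(ene, abs=1e-9)
            assert tf.correlation == pytest.approx(cor, abs=1e-9)
            assert tf.auto_correlation == pytest.approx(auto, abs=1e-9)


class TestTextureFeatures:
    def test_constant_foreground(self):
        gray = np.full((32, 32), 90, dtype=np.uint8)
        mask = np.ones((32, 32), dtype=bool)
        tf = extract_texture_features(gray, mask)
        assert tf.energy == pytest.approx(1.0)
        assert tf.contrast == pytest.approx(0.0)

    def test_isotropic_noise_direction_balance(self, rng):
        gray = rng.integers(0, 256, (96, 96), dtype=np.uint8)
        mask = np.ones((96, 96), dtype=bool)
        contrasts = [
            glcm_features(compute_glcm(gray, mask, d=2, theta=t, levels=64)).contrast
            for t in (0, 45, 90, 135)
        ]
        mean = np.mean(contrasts)
        assert all(abs(c - mean) / mean < 0.2 for c in contrasts)

    def test_rotation_by_90_leaves_average_unchanged(self, rng):
        gray = rng.integers(0, 256, (48, 48), dtype=np.uint8)
        mask = np.ones((48, 48), dtype=bool)
        a = extract_texture_features(gray, mask).as_dict()
        b = extract_texture_features(np.rot90(gray).copy(), np.rot90(mask).copy()).as_dict()
        for name in TEXTURE_NAMES:
            assert a[name] == pytest.approx(b[name], abs=1e-6)

    def test_windowed_mode_runs(self, rng):
        gray = rng.integers(0, 256, (64, 64), dtype=np.uint8)
        mask = np.ones((64, 64), dtype=bool)
        tf = extract_texture_features(gray, mask, TextureConfig(window=7))
        assert np.isfinite(list(tf.as_dict().values())).all()


# ---------------------------------------------------------------------------
# fused vector

class TestExtractAll:
    def test_canonical_order_and_finiteness(self, small_image_spec):
        img, _, _ = generate_root_image(small_image_spec, "II", seed=11)
        vec = extract_all(img, NATIVE)
        assert list(vec.index) == ALL_FEATURE_NAMES
        assert len(vec) == 40
        assert np.isfinite(vec.to_numpy()).all()

    def test_block_sizes(self):
        assert len(SHAPE_NAMES) == 9
        assert len(COLOR_NAMES) == 24
        assert len(TEXTURE_NAMES) == 7
        assert len(FUSION_SUBSETS["shape+texture"]) == 16
        assert len(FUSION_SUBSETS["shape+color"]) == 33
        assert len(FUSION_SUBSETS["all"]) == 40

    def test_deterministic(self, small_image_spec):
        img, _, _ = generate_root_image(small_image_spec, "III", seed=12)
        assert extract_all(img, NATIVE).equals(extract_all(img, NATIVE))

    def test_csv_round_trip(self, small_image_spec, tmp_path):
        img, _, _ = generate_root_image(small_image_spec, "I", seed=13)
        vec = extract_all(img, NATIVE)
        df = pd.DataFrame([vec])
        df["grade"] = ["I"]
        path = tmp_path / "features.csv"
        write_feature_csv(df, path)
        back = read_feature_csv(path)
        assert list(back.columns) == ALL_FEATURE_NAMES + ["grade"]
        np.testing.assert_allclose(
            back[ALL_FEATURE_NAMES].to_numpy(), df[ALL_FEATURE_NAMES].to_numpy(),
            rtol=1e-9,
        )
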