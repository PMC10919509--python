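import itertools

import numpy as np
import pytest

from nodulecad import features as ft
from nodulecad.candidate_detection import label_candidates
from nodulecad.errors import ValidationError
from nodulecad.preprocessing import ImageSlice
from oracles import brute_force_glcm


def hist(values):
    return ft.GrayHistogram(H=np.asarray(values, float), L=len(values))


class TestGrayHistogram:
    def test_constant_region_single_bin(self):
        h = ft.gray_histogram(np.full(40, 0.5), L=8)
        assert h.H.max() == 1.0 and h.H.sum() == 1.0

    def test_two_level_region(self):
        v = np.array([0.1] * 5 + [0.9] * 5)
        h = ft.gray_histogram(v, L=2)
        assert np.allclose(h.H, [0.5, 0.5])

    def test_normalized(self, rng):
        h = ft.gray_histogram(rng.uniform(size=100), L=16)
        assert h.H.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            ft.gray_histogram(np.array([]), L=8)

    def test_invalid_histogram_rejected(self):
        with pytest.raises(ValidationError):
            ft.GrayHistogram(H=np.array([0.5, 0.4]), L=2)


class TestEnergyEntropy:
    def test_single_bin_energy_one(self):
        assert ft.energy(hist([1.0, 0.0, 0.0])) == 1.0

    def test_uniform_energy(self):
        assert ft.energy(hist([1 / 16] * 16)) == pytest.approx(0.0625)

    def test_hand_summed_energy(self):
        # 0.25 + 0.09 + 0.04
        assert ft.energy(hist([0.5, 0.3, 0.2])) == pytest.approx(0.38)

    def test_single_bin_entropy_zero(self):
        assert ft.entropy(hist([1.0, 0.0])) == 0.0

    def test_uniform_entropy_log2(self):
        assert ft.entropy(hist([1 / 16] * 16)) == pytest.approx(4.0)

    def test_half_half_one_bit(self):
        assert ft.entropy(hist([0.5, 0.5])) == pytest.approx(1.0)

    def test_natural_log_base(self):
        assert ft.entropy(hist([0.5, 0.5]), base=np.e) == pytest.approx(np.log(2))

    def test_energy_entropy_inverse_ordering(self, rng):
        # if p majorizes q, energy(p) >= energy(q) and entropy(p) <= entropy(q)
        for _ in range(20):
            p = rng.dirichlet(np.ones(8))
            mix = 0.5 * p + 0.5 * np.full(8, 1 / 8)  # p majorizes mix
            hp, hm = hist(p), hist(mix / mix.sum())
            assert ft.energy(hp) >= ft.energy(hm) - 1e-12
            assert ft.entropy(hp) <= ft.entropy(hm) + 1e-12


class TestCalcification:
    def test_none_above_threshold(self):
        assert ft.calcification(np.full(10, 0.5), T=0.9) == 0.0

    def test_all_above_threshold(self):
        assert ft.calcification(np.full(10, 0.95), T=0.9) == 1.0

    def test_hand_built_patch(self):
        patch = np.full((3, 4), 0.5)
        patch[0, :3] = 0.95  # 3 of 12 pixels above
        assert ft.calcification(patch, T=0.9) == pytest.approx(0.25)

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            ft.calcification(np.full(4, 0.5), T=1.5)


class TestGLCM:
    def test_constant_region_diagonal_mass(self):
        img = np.full((6, 6), 0.5)
        mask = np.ones((6, 6), bool)
        g = ft.glcm(img, mask, L=16, d=1, theta=0)
        k = ft.quantize(np.array([0.5]), 16)[0]
        assert g.S[k, k] == 1.0

    def test_vertical_stripes_off_diagonal(self):
        img = np.zeros((4, 4))
        img[:, 1::2] = 1.0  # alternating level-0 / level-1 columns
        mask = np.ones((4, 4), bool)
        g = ft.glcm(img, mask, L=2, d=1, theta=0, symmetric=True)
        assert g.S[0, 1] == pytest.approx(0.5)
        assert g.S[1, 0] == pytest.approx(0.5)
        assert g.S[0, 0] == g.S[1, 1] == 0.0

    @pytest.mark.parametrize(
        "d,theta,symmetric",
        list(itertools.product([1, 2], [0, 45, 90, 135], [True, False])),
    )
    def test_matches_brute_force_oracle(self, d, theta, symmetric, rng):
        img = rng.uniform(size=(12, 12))
        mask = rng.uniform(size=(12, 12)) < 0.7
        mask[5:8, 5:8] = True
        g = ft.glcm(img, mask, L=4, d=d, theta=theta, symmetric=symmetric)
        expected = brute_force_glcm(img, mask, 4, d, theta, symmetric)
        assert np.allclose(g.S, expected, atol=1e-12)

    def test_pairs_leaving_mask_skipped(self):
        img = np.array([[0.0, 0.9], [0.9, 0.0]])
        mask = np.array([[True, False], [False, True]])
        with pytest.raises(ValidationError):
            ft.glcm(img, mask, L=2, d=1, theta=0)

    def test_contrast_closed_forms(self):
        idx = np.arange(2)
        stripe = ft.GLCM(
            S=np.array([[0.0, 0.5], [0.5, 0.0]]), d=1, theta=0, L=2
        )
        assert ft.glcm_contrast(stripe) == pytest.approx(1.0)
        assert ft.glcm_homogeneity(stripe) == pytest.approx(0.5)

    def test_checkerboard_contrast_one(self):
        img = np.indices((6, 6)).sum(axis=0) % 2 * 1.0
        g = ft.glcm(img, np.ones((6, 6), bool), L=2, d=1, theta=0)
        assert ft.glcm_contrast(g) == pytest.approx(1.0)

    def test_constant_region_contrast_zero_homogeneity_one(self):
        img = np.full((5, 5), 0.3)
        g = ft.glcm(img, np.ones((5, 5), bool), L=16, d=1, theta=90)
        assert ft.glcm_contrast(g) == 0.0
        assert ft.glcm_homogeneity(g) == pytest.approx(1.0)

    def test_homogeneity_bounded(self, rng):
        for _ in range(10):
            img = rng.uniform(size=(8, 8))
            g = ft.glcm(img, np.ones((8, 8), bool), L=8, d=1, theta=45)
            assert 0.0 < ft.glcm_homogeneity(g) <= 1.0


class TestShape3D:
    def test_single_voxel(self):
        out = ft.shape3d_features(np.ones((1, 1, 1), bool))
        assert out["volume"] == 1.0
        assert out["surface_area"] == 6.0
        assert out["equivalent_diameter"] == pytest.approx((6 / np.pi) ** (1 / 3))
        assert out["sphericity"] == pytest.approx(
            np.pi ** (1 / 3) * 6 ** (2 / 3) / 6
        )  # ~0.806

    def test_cube(self):
        out = ft.shape3d_features(np.ones((10, 10, 10), bool))
        assert out["volume"] == 1000.0
        assert out["surface_area"] == 600.0
        assert out["compactness"] == pytest.approx(600**3 / (36 * np.pi * 1e6))

    def test_ball_more_spherical_than_spiculated(self):
        zz, yy, xx = np.mgrid[0:24, 0:24, 0:24]
        r2 = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2
        ball = r2 <= 8**2
        theta = np.arctan2(yy - 12, xx - 12)
        spiky = r2 <= (8 * (1 + 0.3 * np.sin(6 * theta))) ** 2
        s_ball = ft.shape3d_features(ball)["sphericity"]
        s_spiky = ft.shape3d_features(spiky)["sphericity"]
        assert s_ball > s_spiky

    def test_anisotropic_spacing(self):
        out = ft.shape3d_features(np.ones((2, 2, 2), bool), spacing=(2.0, 1.0, 1.0))
        assert out["volume"] == pytest.approx(16.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            ft.shape3d_features(np.zeros((3, 3, 3), bool))


class TestExtractFeatures:
    def test_default_config_yields_17_named_features(self, disk_image):
        img, mask = disk_image
        (cand,) = label_candidates(mask, img)
        vec = ft.extract_features(cand, img)
        assert len(vec.names) == 17
        assert len(vec.values) == 17
        assert vec.names == ft.FeatureConfig().feature_names()

    def test_translation_invariance(self):
        from conftest import disk_mask

        px = np.full((64, 64), 0.2)
        vecs = []
        for center in [(20, 20), (40, 38)]:
            mask = disk_mask((64, 64), center, 9)
            frame = px.copy()
            frame[mask] = 0.8
            img = ImageSlice(pixels=frame)
            (cand,) = label_candidates(mask, img)
            vecs.append(ft.extract_features(cand, img).values)
        assert np.allclose(vecs[0], vecs[1], atol=1e-9)

    def test_equal_intensity_shapes_share_gray_block(self, disk_image, bar_image):
        gray = slice(0, 5)
        blocks = []
        for img, mask in (disk_image, bar_image):
            (cand,) = label_candidates(mask, img)
            blocks.append(ft.extract_features(cand, img).values[gray])
        assert np.allclose(blocks[0], blocks[1], atol=1e-9)
        # ... while the shape block differs
        shapes = []
        for img, mask in (disk_image, bar_image):
            (cand,) = label_candidates(mask, img)
            shapes.append(ft.extract_features(cand, img).values[5:11])
        assert not np.allclose(shapes[0], shapes[1])

    def test_all_features_finite_on_detector_output(self):
        from nodulecad import fixtures as fx
        from nodulecad import preprocessing as pp

        out = fx.generate_phantom(fx.PhantomSpec(seed=17, noise_sigma=0.1))
        mask = pp.segment_foreground(out.image)
        for cand in label_candidates(mask, out.image, min_area=5):
            vec = ft.extract_features(cand, out.image)
            assert np.isfinite(vec.values).all()


@pytest.mark.slow
class TestTextureStructure:
    def test_nodules_vs_textured_distractors(self):
        """Nodules: higher energy, lower entropy, higher homogeneity, lower
        contrast than textured distractors — over 20 patch-set seeds."""
        from scipy import stats

        from nodulecad.benchmark import patch_feature_table

        rows = {"nod": [], "dis": []}
        for seed in range(20):
            X, labels, names = patch_feature_table(8, seed)
            nod = np.isin(labels, ["benign", "malignant"])
            idx = {k: names.index(k) for k in ("energy", "entropy", "homogeneity_d1", "contrast_d1")}
            rows["nod"].append([X[nod, idx[k]].mean() for k in idx])
            rows["dis"].append([X[~nod, idx[k]].mean() for k in idx])
        nod = np.array(rows["nod"])
        dis = np.array(rows["dis"])
        # energy, homogeneity: nodule > distractor; entropy, contrast: <
        for col, sign in ((0, 1), (1, -1), (2, 1), (3, -1)):
            diff = sign * (nod[:, col] - dis[:, col])
            t = stats.ttest_1samp(diff, 0.0, alternative="greater")
            assert t.pvalue < 1e-6
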