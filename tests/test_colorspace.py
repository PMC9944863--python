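"""Color-space conversions checked against independent references.

sRGB/XYZ/CIELAB are cross-checked against scikit-image's independently
coded converters; CIECAM02 against the published CIE worked example; and
S-CIELAB against a brute-force 2-D convolution oracle coded directly in
this file.
"""

import numpy as np
import pytest
import skimage.color as skc

from relcolors import colorspace as cs


class TestSrgbXyz:
    def test_white_is_d65(self):
        xyz = cs.srgb_to_xyz(np.array([255, 255, 255])).values
        np.testing.assert_allclose(xyz, cs.D65_WHITE, atol=5e-4)

    def test_black_is_zero(self):
        np.testing.assert_allclose(cs.srgb_to_xyz(np.zeros(3)).values, 0.0, atol=1e-12)

    def test_matches_skimage_on_arbitrary_color(self):
        rgb = np.array([[[128, 64, 200]]], dtype=np.uint8)
        mine = cs.srgb_to_xyz(rgb).values
        ref = skc.rgb2xyz(rgb.astype(np.float64) / 255.0) * 100.0
        np.testing.assert_allclose(mine, ref, rtol=2e-4, atol=5e-3)

    def test_rejects_non_three_channel(self):
        with pytest.raises(ValueError):
            cs.srgb_to_xyz(np.zeros((4, 4, 4)))

    def test_gray_roundtrip_exact_all_levels(self):
        grays = np.arange(256, dtype=np.uint8).reshape(-1, 1).repeat(3, axis=1)
        back = cs.xyz_to_srgb(cs.srgb_to_xyz(grays))
        assert np.array_equal(back, grays)


class TestLab:
    def test_whitepoint_maps_to_L100(self):
        lab = cs.xyz_to_lab(cs.TristimulusImage(values=cs.D65_WHITE.copy())).values
        np.testing.assert_allclose(lab, [100.0, 0.0, 0.0], atol=1e-9)

    def test_zero_maps_to_zero(self):
        lab = cs.xyz_to_lab(cs.TristimulusImage(values=np.zeros(3))).values
        np.testing.assert_allclose(lab, 0.0, atol=1e-9)

    def test_mid_gray_lightness_formula(self):
        # Y = 18.4: L* = 116 (Y/Yn)^(1/3) - 16, hand-evaluated
        xyz = cs.D65_WHITE * 18.4 / 100.0
        L = cs.xyz_to_lab(cs.TristimulusImage(values=xyz)).values[0]
        expected = 116.0 * (18.4 / 100.0) ** (1.0 / 3.0) - 16.0
        assert L == pytest.approx(expected, abs=1e-9)

    def test_matches_skimage(self):
        rgb = np.array([[[128, 64, 200]], [[17, 230, 99]]], dtype=np.uint8)
        mine = cs.srgb_to_lab(rgb).values
        ref = skc.rgb2lab(rgb.astype(np.float64) / 255.0)
        np.testing.assert_allclose(mine, ref, atol=2e-2)

    def test_missing_whitepoint_rejected(self):
        with pytest.raises((ValueError, AttributeError, TypeError)):
            cs.xyz_to_lab(cs.TristimulusImage(values=np.ones(3), whitepoint=None))


class TestCiecam02Ucs:
    def test_cie_worked_example(self):
        """The published CIECAM02 verification case: XYZ (19.01, 20, 21.78)
        under white (95.05, 100, 108.88), L_A = 318.31, average surround
        gives J = 41.731, h = 219.049 deg, M = 0.1088."""
        vc = cs.ViewingConditions(
            whitepoint=np.array([95.05, 100.0, 108.88]), adapting_luminance=318.31
        )
        got = cs.xyz_to_ciecam02ucs(
            cs.TristimulusImage(values=np.array([19.01, 20.0, 21.78])), vc
        ).values
        J, M, h = 41.73109, 0.108842, 219.04848
        J_p = 1.7 * J / (1.0 + 0.007 * J)
        M_p = np.log1p(0.0228 * M) / 0.0228
        expected = [J_p, M_p * np.cos(np.radians(h)), M_p * np.sin(np.radians(h))]
        np.testing.assert_allclose(got, expected, atol=1e-4)

    def test_white_maps_to_top_of_lightness_scale(self):
        vc = cs.ViewingConditions()
        got = cs.xyz_to_ciecam02ucs(
            cs.TristimulusImage(values=vc.whitepoint.copy()), vc
        ).values
        assert got[0] == pytest.approx(100.0, abs=1e-9)
        # incomplete adaptation (D < 1 at L_A = 64) leaves the white a small
        # residual chroma; near-zero on the 100-unit UCS scale
        assert abs(got[1]) < 2.0 and abs(got[2]) < 2.0

    def test_deterministic(self):
        rgb = np.array([[[10, 200, 30]]], dtype=np.uint8)
        a = cs.xyz_to_ciecam02ucs(cs.srgb_to_xyz(rgb)).values
        b = cs.xyz_to_ciecam02ucs(cs.srgb_to_xyz(rgb)).values
        np.testing.assert_array_equal(a, b)

    def test_invalid_adapting_luminance_rejected(self):
        with pytest.raises(ValueError):
            cs.ViewingConditions(adapting_luminance=-5.0)


class TestDeltaE:
    def test_identical_images_zero_both_spaces(self, noisy_image):
        img, _ = noisy_image
        assert cs.mean_delta_e_ucs(img, img).mean_delta_e == 0.0
        assert cs.mean_delta_e_scielab(img, img).mean_delta_e == pytest.approx(0, abs=1e-12)

    def test_symmetry(self, noisy_image):
        img, _ = noisy_image
        other = img[::-1].copy()
        for fn in (cs.mean_delta_e_ucs, cs.mean_delta_e_scielab):
            d1 = fn(img, other).mean_delta_e
            d2 = fn(other, img).mean_delta_e
            assert d1 == pytest.approx(d2, rel=1e-12)
            assert d1 >= 0

    def test_constant_pair_equals_single_pair_distance(self):
        a = np.full((8, 8, 3), (200, 40, 40), dtype=np.uint8)
        b = np.full((8, 8, 3), (40, 170, 60), dtype=np.uint8)
        ucs_a = cs.xyz_to_ciecam02ucs(cs.srgb_to_xyz(a[0, 0])).values
        ucs_b = cs.xyz_to_ciecam02ucs(cs.srgb_to_xyz(b[0, 0])).values
        expected = float(np.linalg.norm(ucs_a - ucs_b))
        assert cs.mean_delta_e_ucs(a, b).mean_delta_e == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cs.mean_delta_e_ucs(np.zeros((4, 4, 3)), np.zeros((5, 5, 3)))


class TestScielab:
    def test_uniform_pair_equals_plain_cielab(self):
        a = np.full((16, 16, 3), (100, 50, 30), dtype=np.uint8)
        b = np.full((16, 16, 3), (110, 60, 20), dtype=np.uint8)
        got = cs.mean_delta_e_scielab(a, b).mean_delta_e
        lab_a = cs.srgb_to_lab(a).values
        lab_b = cs.srgb_to_lab(b).values
        plain = float(np.linalg.norm(lab_a - lab_b, axis=-1).mean())
        assert got == pytest.approx(plain, abs=1e-6)

    def test_nonpositive_sampling_rejected(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            cs.mean_delta_e_scielab(img, img, samples_per_degree=0)

    def test_matches_bruteforce_2d_convolution(self):
        """Independent oracle: direct (non-separable) 2-D convolution with
        the same opponent transform and kernels, coded from scratch here."""
        rng = np.random.default_rng(5)
        a = rng.integers(0, 256, size=(24, 24, 3), dtype=np.uint8)
        b = a.copy()
        b[8:16, 8:16] = [200, 30, 30]
        sppd = 24.0

        def oracle(img):
            xyz = cs.srgb_to_xyz(img).values
            opp = np.einsum("ij,hwj->hwi", cs._XYZ_TO_OPP, xyz)
            out = np.empty_like(opp)
            for ch, name in enumerate(("lum", "rg", "by")):
                comps = cs._scielab_kernels(cs._SCIELAB_FILTERS[name], sppd)
                k2 = sum(w * np.outer(g, g) for w, g in comps)  # 2-D Gaussian mixture
                half = len(comps[0][1]) // 2
                padded = np.pad(opp[..., ch], half, mode="symmetric")
                h, w = opp.shape[:2]
                res = np.empty((h, w))
                for i in range(h):
                    for j in range(w):
                        res[i, j] = (padded[i : i + 2 * half + 1, j : j + 2 * half + 1] * k2).sum()
                out[..., ch] = res
            xyz_f = np.einsum("ij,hwj->hwi", cs._OPP_TO_XYZ, out)
            lab = cs.xyz_to_lab(cs.TristimulusImage(values=xyz_f)).values
            return lab

        expected = float(np.linalg.norm(oracle(a) - oracle(b), axis=-1).mean())
        got = cs.mean_delta_e_scielab(a, b, samples_per_degree=sppd).mean_delta_e
        assert got == pytest.approx(expected, rel=1e-6)


def test_nested_palettes_non_increasing_delta_e(four_mode_image):
    """Refining a palette (nested palettes) cannot worsen mean Delta E."""
    from relcolors.quantize import Quantization, apply_palette

    img, gt = four_mode_image
    palette = np.array([[200, 40, 40], [40, 170, 60], [50, 60, 200], [220, 200, 50]], float)
    prev_ucs, prev_s = np.inf, np.inf
    for n in (1, 2, 4):
        pal = palette[:n]
        flat = img.reshape(-1, 3).astype(float)
        d = ((flat[:, None] - pal[None]) ** 2).sum(-1)
        labels = d.argmin(1).reshape(img.shape[:2])
        out = apply_palette(img, Quantization(palette=pal, labels=labels, n=n))
        de_ucs = cs.mean_delta_e_ucs(img, out).mean_delta_e
        de_s = cs.mean_delta_e_scielab(img, out).mean_delta_e
        assert de_ucs <= prev_ucs + 1e-9 and de_s <= prev_s + 1e-9
        prev_ucs, prev_s = de_ucs, de_s
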