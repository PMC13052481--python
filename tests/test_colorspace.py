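"""Unit and property tests for the RGB -> Lab conversion chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itakit import ConversionConfig, UnsupportedOperationError, ValidationError
from itakit.colorspace import (
    D65_WHITE_MATRIX,
    SRGB_XYZ_MATRIX,
    lab_to_rgb,
    linearize,
    normalize_rgb,
    read_image,
    rgb_to_lab,
    rgb_to_xyz,
    xyz_to_lab,
)


def px(r, g, b, dtype=np.uint8):
    return np.array([[[r, g, b]]], dtype=dtype)


class TestNormalize:
    @pytest.mark.parametrize("value,expected", [(255, 1.0), (0, 0.0), (51, 0.2)])
    def test_exact_division(self, value, expected):
        assert normalize_rgb(px(value, value, value))[0, 0, 0] == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            normalize_rgb(np.array([[[0, 0, 300]]]))
        with pytest.raises(ValidationError):
            normalize_rgb(np.array([[[-1, 0, 0]]]))

    def test_rejects_fractional_values(self):
        with pytest.raises(ValidationError):
            normalize_rgb(np.array([[[0.5, 1.0, 2.0]]]))


class TestLinearize:
    @pytest.mark.parametrize("mode", ["standard", "paper_literal"])
    def test_fixed_points(self, mode, std_cfg, literal_cfg):
        cfg = std_cfg if mode == "standard" else literal_cfg
        out = linearize(np.array([0.0, 1.0]), cfg)
        assert out[0] == pytest.approx(0.0)
        assert out[1] == pytest.approx(1.0)  # a*1^g + b = 1.055 - 0.055

    def test_standard_branch_continuity(self, std_cfg):
        # 0.04045 / 12.92 = 0.0031308; power branch agrees at the knee
        lo = linearize(np.array([0.04045]), std_cfg)[0]
        hi = linearize(np.array([0.04045 + 1e-9]), std_cfg)[0]
        assert lo == pytest.approx(0.0031308, abs=1e-7)
        assert hi == pytest.approx(lo, abs=1e-5)

    def test_paper_literal_is_encoding_curve(self, literal_cfg):
        # printed function applies the 1/2.4 exponent: brightens mid-tones
        mid = linearize(np.array([0.5]), literal_cfg)[0]
        assert mid == pytest.approx(1.055 * 0.5 ** (1 / 2.4) - 0.055)
        assert mid > 0.5  # encoding, not linearization

    def test_paper_literal_odd_extension(self, literal_cfg):
        u = np.array([0.3])
        assert linearize(-u, literal_cfg)[0] == pytest.approx(
            -linearize(u, literal_cfg)[0]
        )

    def test_standard_monotone(self, std_cfg):
        u = np.linspace(0, 1, 500)
        assert np.all(np.diff(linearize(u, std_cfg)) > 0)


class TestRgbToXyz:
    def test_black_and_basis(self, std_cfg):
        assert np.allclose(rgb_to_xyz(px(0, 0, 0, float)), 0.0)
        red = rgb_to_xyz(np.array([[[1.0, 0.0, 0.0]]]), std_cfg)[0, 0]
        assert np.allclose(red, SRGB_XYZ_MATRIX[:, 0])

    def test_white_gives_row_sums(self, std_cfg):
        white = rgb_to_xyz(np.array([[[1.0, 1.0, 1.0]]]), std_cfg)[0, 0]
        assert white == pytest.approx(
            [0.9504700, 1.0000001, 1.0888300], abs=1e-7
        )


class TestXyzToLab:
    def test_white_point_maps_to_L100(self, std_cfg):
        lab = xyz_to_lab(D65_WHITE_MATRIX.reshape(1, 1, 3), std_cfg)[0, 0]
        assert lab == pytest.approx([100.0, 0.0, 0.0], abs=1e-9)

    def test_black_maps_to_L0(self, std_cfg):
        lab = xyz_to_lab(np.zeros((1, 1, 3)), std_cfg)[0, 0]
        assert lab[0] == pytest.approx(0.0, abs=1e-12)  # 116*(4/29) - 16 = 0

    def test_rejects_negative_tristimulus(self, std_cfg):
        with pytest.raises(ValidationError):
            xyz_to_lab(np.array([[[-0.1, 0.5, 0.5]]]), std_cfg)

    def test_mid_gray_is_neutral(self, std_cfg):
        lab = rgb_to_lab(px(128, 128, 128), std_cfg)[0, 0]
        assert abs(lab[1]) < 0.2 and abs(lab[2]) < 0.2


class TestFullChain:
    def test_white_and_black(self, std_cfg):
        white = rgb_to_lab(px(255, 255, 255), std_cfg)[0, 0]
        assert white == pytest.approx([100.0, 0.0, 0.0], abs=1e-6)
        black = rgb_to_lab(px(0, 0, 0), std_cfg)[0, 0]
        assert black == pytest.approx([0.0, 0.0, 0.0], abs=1e-9)

    def test_gray_axis_neutrality(self, std_cfg):
        grays = np.arange(256, dtype=np.uint8).reshape(-1, 1, 1).repeat(3, axis=2)
        lab = rgb_to_lab(grays, std_cfg)
        assert np.abs(lab[..., 1]).max() < 0.25
        assert np.abs(lab[..., 2]).max() < 0.25

    def test_L_strictly_increasing_on_gray_axis(self, std_cfg):
        grays = np.arange(256, dtype=np.uint8).reshape(-1, 1, 1).repeat(3, axis=2)
        L = rgb_to_lab(grays, std_cfg)[..., 0].ravel()
        assert np.all(np.diff(L) > 0)

    def test_agrees_with_skimage_oracle(self, std_cfg, rng):
        from skimage.color import rgb2lab

        rgb8 = rng.integers(0, 256, (1, 1000, 3), dtype=np.uint8)
        ours = rgb_to_lab(rgb8, std_cfg)
        oracle = rgb2lab(rgb8 / 255.0)
        d_e = np.linalg.norm(ours - oracle, axis=-1)
        assert d_e.max() < 0.02


class TestInverse:
    def test_white_black_round_trip(self, std_cfg):
        rgb, mask = lab_to_rgb(np.array([[[100.0, 0.0, 0.0]]]), std_cfg)
        assert tuple(rgb[0, 0]) == (255, 255, 255) and not mask.any()
        rgb, _ = lab_to_rgb(np.zeros((1, 1, 3)), std_cfg)
        assert tuple(rgb[0, 0]) == (0, 0, 0)

    def test_identity_on_8bit_within_one_step(self, std_cfg, rng):
        rgb8 = rng.integers(0, 256, (100, 100, 3), dtype=np.uint8)
        back, mask = lab_to_rgb(rgb_to_lab(rgb8, std_cfg), std_cfg)
        assert not mask.any()
        assert np.abs(back.astype(int) - rgb8.astype(int)).max() <= 1

    def test_round_trip_delta_e_bounded(self, std_cfg, rng):
        # random in-gamut Lab triples survive Lab->RGB8->Lab within dE 1
        rgb8 = rng.integers(0, 256, (1, 10000, 3), dtype=np.uint8)
        lab = rgb_to_lab(rgb8, std_cfg)
        back8, _ = lab_to_rgb(lab, std_cfg)
        lab2 = rgb_to_lab(back8, std_cfg)
        assert np.linalg.norm(lab - lab2, axis=-1).max() <= 1.0

    def test_out_of_gamut_flagged_and_clipped(self, std_cfg):
        # saturated green far outside sRGB
        rgb, mask = lab_to_rgb(np.array([[[60.0, -200.0, 0.0]]]), std_cfg)
        assert mask.all()
        assert rgb.min() >= 0 and rgb.max() <= 255

    def test_paper_literal_not_invertible(self, literal_cfg):
        with pytest.raises(UnsupportedOperationError):
            lab_to_rgb(np.zeros((1, 1, 3)), literal_cfg)


class TestPaperLiteralMode:
    def test_delta_offset_applied(self, literal_cfg):
        lab = rgb_to_lab(px(200, 150, 120), literal_cfg)[0, 0]
        # a*, b* carry the +128 storage offset
        assert lab[1] > 100 and lab[2] > 100

    def test_deterministic_to_the_bit(self, literal_cfg, rng):
        rgb8 = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        a = rgb_to_lab(rgb8, literal_cfg)
        b = rgb_to_lab(rgb8.copy(), literal_cfg)
        assert a.tobytes() == b.tobytes()

    def test_rounded_white_point_selectable(self):
        cfg = ConversionConfig.standard(white_point="rounded")
        assert np.allclose(cfg.white_point, [0.95, 1.0, 1.09])


class TestConfigSerialization:
    @pytest.mark.parametrize(
        "cfg", [ConversionConfig.standard(), ConversionConfig.paper_literal()]
    )
    def test_round_trip(self, cfg):
        restored = ConversionConfig.from_dict(cfg.to_dict())
        assert restored.mode == cfg.mode
        assert restored.delta_offset == cfg.delta_offset
        assert np.allclose(restored.xyz_matrix, cfg.xyz_matrix)
        assert np.allclose(restored.white_point, cfg.white_point)


class TestReadImage:
    def test_reads_png_and_jpeg(self, tmp_path, patch_factory):
        from PIL import Image

        rgb, _ = patch_factory(20.0)
        for name in ("p.png", "p.jpg"):
            Image.fromarray(rgb, mode="RGB").save(tmp_path / name)
            arr = read_image(tmp_path / name)
            assert arr.dtype == np.uint8 and arr.shape == rgb.shape
        # PNG is lossless
        assert np.array_equal(read_image(tmp_path / "p.png"), rgb)

    def test_alpha_dropped_with_warning(self, tmp_path):
        from PIL import Image

        rgba = np.zeros((4, 4, 4), dtype=np.uint8)
        rgba[..., 3] = 255
        Image.fromarray(rgba, mode="RGBA").save(tmp_path / "a.png")
        with pytest.warns(UserWarning, match="alpha"):
            arr = read_image(tmp_path / "a.png")
        assert arr.shape == (4, 4, 3)

    def test_rejects_16bit(self, tmp_path):
        from PIL import Image

        im16 = Image.fromarray(np.zeros((4, 4), dtype=np.int32)).convert("I;16")
        im16.save(tmp_path / "deep.png")
        with pytest.raises(ValidationError):
            read_image(tmp_path / "deep.png")


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255))
def test_lab_within_expected_ranges(r, g, b):
    """L* stays in [0, 100] and chroma stays bounded for any 8-bit pixel."""
    lab = rgb_to_lab(px(r, g, b), ConversionConfig.standard())[0, 0]
    assert -1e-9 <= lab[0] <= 100 + 1e-9
    assert abs(lab[1]) < 130 and abs(lab[2]) < 130
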