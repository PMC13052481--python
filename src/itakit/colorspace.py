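"""Per-pixel conversion chain from 8-bit sRGB photographs to CIE L*a*b*.

Two conversion modes are provided:

``standard``
    The CIE-correct chain: sRGB decoding gamma (EOTF), the D65 sRGB
    3x3 matrix to CIE 1931 XYZ, single white-point normalization, and
    the CIELAB f(t) nonlinearity.  This is the mode every downstream
    ITA computation should use.

``paper_literal``
    Reproduces, verbatim, a published variant of the chain in which the
    gamma step applies the sRGB *encoding* curve (exponent 1/2.4), the
    XYZ values are divided by the white point twice before f(t), and a
    fixed offset of 128 is added to a* and b* (an 8-bit storage
    convention).  The mode exists for traceability: it is pure and
    deterministic, but its Lab output is not CIELAB and the chain is
    not invertible.

All operations are element-wise over H x W x 3 float64 arrays; images
are plain numpy arrays, as in scikit-image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from PIL import Image

from .errors import UnsupportedOperationError, ValidationError

__all__ = [
    "ConversionConfig",
    "SRGB_XYZ_MATRIX",
    "D65_WHITE_MATRIX",
    "D65_WHITE_ROUNDED",
    "normalize_rgb",
    "linearize",
    "rgb_to_xyz",
    "xyz_to_lab",
    "rgb_to_lab",
    "lab_to_rgb",
    "read_image",
]

#: sRGB (D65) linear-RGB -> CIE 1931 XYZ matrix, IEC 61966-2-1 coefficients.
SRGB_XYZ_MATRIX = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

#: D65 white point consistent with the matrix above (its row sums), so that
#: RGB white maps exactly to L*=100, a*=b*=0.
D65_WHITE_MATRIX = SRGB_XYZ_MATRIX.sum(axis=1)

#: The rounded two/three-digit white point (0.95, 1, 1.09) sometimes quoted
#: alongside the matrix; selectable for traceability.
D65_WHITE_ROUNDED = np.array([0.95, 1.0, 1.09])

# CIELAB nonlinearity constants
_DELTA = 6.0 / 29.0
_F_THRESHOLD = _DELTA**3  # t threshold in f(t)


@dataclass(frozen=True)
class ConversionConfig:
    """Constants of the RGB -> Lab chain.

    Parameters
    ----------
    mode
        ``"standard"`` (CIE-correct) or ``"paper_literal"`` (see module
        docstring).
    gamma_a, gamma_b, gamma_c, gamma_exponent
        Constants of the piecewise gamma function: a=1.055, b=-0.055,
        c=12.92.  ``gamma_exponent`` is the exponent of the power branch
        *as applied*: 2.4 when decoding (standard), 1/2.4 when the
        printed encoding curve is reproduced literally.
    xyz_matrix
        3x3 linear-RGB -> XYZ matrix.
    white_point
        (Xref, Yref, Zref) D65 normalization.
    delta_offset
        Constant added to a* and b* (0 in standard mode, 128 in
        paper-literal mode).
    """

    mode: Literal["standard", "paper_literal"] = "standard"
    gamma_a: float = 1.055
    gamma_b: float = -0.055
    gamma_c: float = 12.92
    gamma_exponent: float = 2.4
    xyz_matrix: np.ndarray = field(default_factory=lambda: SRGB_XYZ_MATRIX.copy())
    white_point: np.ndarray = field(default_factory=lambda: D65_WHITE_MATRIX.copy())
    delta_offset: float = 0.0

    @classmethod
    def standard(cls, white_point: str = "matrix") -> "ConversionConfig":
        """CIE-correct configuration (the default for all analysis)."""
        return cls(mode="standard", white_point=_resolve_white(white_point))

    @classmethod
    def paper_literal(cls, white_point: str = "rounded") -> "ConversionConfig":
        """Verbatim reproduction of the printed equation chain."""
        return cls(
            mode="paper_literal",
            gamma_exponent=1.0 / 2.4,
            white_point=_resolve_white(white_point),
            delta_offset=128.0,
        )

    def with_white_point(self, white_point: str) -> "ConversionConfig":
        return replace(self, white_point=_resolve_white(white_point))

    # -- flat key-value serialization -------------------------------------
    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "gamma_a": self.gamma_a,
            "gamma_b": self.gamma_b,
            "gamma_c": self.gamma_c,
            "gamma_exponent": self.gamma_exponent,
            "delta_offset": self.delta_offset,
        }
        for i in range(3):
            for j in range(3):
                d[f"xyz_matrix_{i}{j}"] = float(self.xyz_matrix[i, j])
        for k, name in enumerate("xyz"):
            d[f"white_{name}"] = float(self.white_point[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ConversionConfig":
        matrix = np.array(
            [[d[f"xyz_matrix_{i}{j}"] for j in range(3)] for i in range(3)]
        )
        white = np.array([d[f"white_{name}"] for name in "xyz"])
        return cls(
            mode=d["mode"],
            gamma_a=d["gamma_a"],
            gamma_b=d["gamma_b"],
            gamma_c=d["gamma_c"],
            gamma_exponent=d["gamma_exponent"],
            xyz_matrix=matrix,
            white_point=white,
            delta_offset=d["delta_offset"],
        )


def _resolve_white(white_point: str) -> np.ndarray:
    if white_point == "matrix":
        return D65_WHITE_MATRIX.copy()
    if white_point == "rounded":
        return D65_WHITE_ROUNDED.copy()
    raise ValidationError(
        f"white_point must be 'matrix' or 'rounded', got {white_point!r}"
    )


def _as_pixel_array(img: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim < 1 or arr.shape[-1] != 3:
        raise ValidationError(
            f"{name} must have 3 channels on the last axis, got shape {arr.shape}"
        )
    return arr


def normalize_rgb(img: np.ndarray) -> np.ndarray:
    """Scale 8-bit RGB channel values to [0, 1].

    Raises :class:`ValidationError` if any channel value falls outside
    [0, 255] or is non-integral.
    """
    arr = _as_pixel_array(img, "RGB image")
    if np.issubdtype(arr.dtype, np.floating) and not np.all(arr == np.floor(arr)):
        raise ValidationError("8-bit RGB image must contain integer channel values")
    if arr.min() < 0 or arr.max() > 255:
        raise ValidationError(
            f"channel values must lie in [0, 255]; found range "
            f"[{arr.min()}, {arr.max()}]"
        )
    return arr.astype(np.float64) / 255.0


def linearize(img: np.ndarray, cfg: ConversionConfig | None = None) -> np.ndarray:
    """Apply the piecewise gamma function channel-wise.

    Standard mode decodes display-referred sRGB to linear light
    (u <= 0.04045 -> u/12.92, else ((u + 0.055)/1.055)^2.4).
    Paper-literal mode applies the printed piecewise function with the
    encoding exponent 1/2.4 and a linear segment on [0, 0.0031), with
    odd extension C(-u) = -C(u) for negative inputs.
    """
    cfg = cfg or ConversionConfig.standard()
    arr = np.asarray(img, dtype=np.float64)
    if cfg.mode == "standard":
        if arr.min() < 0 or arr.max() > 1:
            raise ValidationError("normalized RGB values must lie in [0, 1]")
        return np.where(
            arr <= 0.04045,
            arr / cfg.gamma_c,
            ((arr - cfg.gamma_b) / cfg.gamma_a) ** cfg.gamma_exponent,
        )
    # paper-literal: printed C(u), odd-extended
    u = np.abs(arr)
    out = np.where(
        u < 0.0031,
        cfg.gamma_c * u,
        cfg.gamma_a * u**cfg.gamma_exponent + cfg.gamma_b,
    )
    return np.sign(arr) * out


def rgb_to_xyz(img: np.ndarray, cfg: ConversionConfig | None = None) -> np.ndarray:
    """Left-multiply each linear-RGB pixel by the 3x3 matrix."""
    cfg = cfg or ConversionConfig.standard()
    arr = _as_pixel_array(img, "linear RGB image").astype(np.float64)
    return arr @ cfg.xyz_matrix.T


def xyz_to_lab(img: np.ndarray, cfg: ConversionConfig | None = None) -> np.ndarray:
    """CIELAB nonlinearity: XYZ -> (L*, a*, b*).

    Standard mode normalizes each tristimulus value by the white point
    once and applies f(t) with threshold (6/29)^3.  Paper-literal mode
    reproduces the printed double normalization (t = X / Xref^2) and
    adds the delta offset to a* and b*.
    """
    cfg = cfg or ConversionConfig.standard()
    arr = _as_pixel_array(img, "XYZ image").astype(np.float64)
    if arr.min() < 0:
        raise ValidationError("tristimulus values must be non-negative")
    t = arr / cfg.white_point
    if cfg.mode == "paper_literal":
        t = t / cfg.white_point  # printed chain divides by the white point twice
    f = np.where(t > _F_THRESHOLD, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy) + cfg.delta_offset
    b = 200.0 * (fy - fz) + cfg.delta_offset
    return np.stack([L, a, b], axis=-1)


def rgb_to_lab(img: np.ndarray, cfg: ConversionConfig | None = None) -> np.ndarray:
    """Full chain: 8-bit RGB -> normalized -> linear -> XYZ -> L*a*b*."""
    cfg = cfg or ConversionConfig.standard()
    return xyz_to_lab(rgb_to_xyz(linearize(normalize_rgb(img), cfg), cfg), cfg)


def lab_to_rgb(
    lab: np.ndarray, cfg: ConversionConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the standard chain back to quantized 8-bit RGB.

    Returns ``(rgb8, out_of_gamut)`` where ``out_of_gamut`` flags pixels
    whose linear RGB fell outside [0, 1] and was clipped.

    Raises
    ------
    UnsupportedOperationError
        In paper-literal mode: the printed forward chain (encoding gamma
        labelled as linearization, double white-point division) is not
        algebraically invertible as written.
    """
    cfg = cfg or ConversionConfig.standard()
    if cfg.mode != "standard":
        raise UnsupportedOperationError(
            "lab_to_rgb is defined for standard mode only; the paper-literal "
            "forward chain is not invertible"
        )
    arr = _as_pixel_array(lab, "Lab image").astype(np.float64)
    L, a, b = arr[..., 0], arr[..., 1], arr[..., 2]
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - b / 200.0
    f = np.stack([fx, fy, fz], axis=-1)
    t = np.where(f > _DELTA, f**3, 3 * _DELTA**2 * (f - 4.0 / 29.0))
    xyz = t * cfg.white_point
    lin = xyz @ np.linalg.inv(cfg.xyz_matrix).T
    # tolerance absorbs float round-off at the gamut boundary (exact 0/1)
    out_of_gamut = np.any((lin < -1e-9) | (lin > 1 + 1e-9), axis=-1)
    lin = np.clip(lin, 0.0, 1.0)
    encoded = np.where(
        lin <= 0.04045 / cfg.gamma_c,
        cfg.gamma_c * lin,
        cfg.gamma_a * lin ** (1.0 / cfg.gamma_exponent) + cfg.gamma_b,
    )
    rgb8 = np.round(encoded * 255.0).astype(np.uint8)
    return rgb8, out_of_gamut


def read_image(path) -> np.ndarray:
    """Read an 8-bit RGB JPEG/PNG as an H x W x 3 uint8 array.

    Pixels are assumed sRGB-encoded; embedded ICC profiles are ignored.
    An alpha channel, if present, is dropped with a warning.  16-bit,
    CMYK and other exotic modes are rejected.
    """
    try:
        im = Image.open(path)
        im.load()
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise ValidationError(f"cannot decode {path}: {exc}") from exc
    if im.mode in ("RGBA", "LA", "PA"):
        warnings.warn(
            f"{path}: alpha channel dropped; pixels treated as sRGB",
            stacklevel=2,
        )
        im = im.convert("RGB")
    elif im.mode == "L":
        im = im.convert("RGB")
    elif im.mode != "RGB":
        raise ValidationError(
            f"{path}: unsupported image mode {im.mode!r}; expected 8-bit RGB "
            "(16-bit and CMYK inputs are not supported)"
        )
    arr = np.asarray(im, dtype=np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"{path}: decoded shape {arr.shape} is not H x W x 3")
    return arr
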