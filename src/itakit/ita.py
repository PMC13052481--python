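"""Individual typology angle (ITA) mapping, summary and classification.

ITA is the angle in the CIELAB L*-b* plane about the pivot (L*=50, b*=0):

    ITA(deg) = (180/pi) * arctan((L* - 50) / b*)

It is the dermatology-standard proxy for constitutive skin pigmentation:
light skin sits high on L* and low on b* (large positive ITA), heavily
pigmented skin sits below L*=50 (negative ITA).  Six half-open intervals
partition [-90, 90] into the uniformly distributed phenotype scale used
here.

The angle is computed with atan2(L*-50, b*) so pixels with b* < 0 (a
non-physiological blue cast for skin) land outside [-90, 90] and are
masked invalid rather than folded back into the scale; the degenerate
pixel (L*=50, b*=0) is likewise masked, not zero-filled, because a zero
would silently bias the mean toward the "brown" bin.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .errors import ValidationError

__all__ = [
    "RoiSpec",
    "ItaMap",
    "ItaSummary",
    "ItaHistogram",
    "SkinToneCategory",
    "crop_roi",
    "default_roi",
    "ita_from_lab",
    "ita_map",
    "summarize_ita",
    "classify_ita",
    "ita_histogram",
]


@dataclass(frozen=True)
class RoiSpec:
    """Square n x n region of interest, 0-based top-left origin."""

    row_offset: int
    col_offset: int
    size_n: int

    def __post_init__(self):
        if self.size_n < 1:
            raise ValidationError(f"ROI size must be >= 1, got {self.size_n}")
        if self.row_offset < 0 or self.col_offset < 0:
            raise ValidationError(
                f"ROI offsets must be non-negative, got "
                f"({self.row_offset}, {self.col_offset})"
            )

    def validate_within(self, height: int, width: int) -> None:
        if self.row_offset + self.size_n > height or self.col_offset + self.size_n > width:
            raise ValidationError(
                f"ROI rows [{self.row_offset}, {self.row_offset + self.size_n}) x "
                f"cols [{self.col_offset}, {self.col_offset + self.size_n}) exceeds "
                f"image bounds {height} x {width}"
            )


def default_roi(height: int, width: int) -> RoiSpec:
    """Centered square of side floor(min(H, W)/4) used when no ROI is given."""
    n = max(1, min(height, width) // 4)
    return RoiSpec((height - n) // 2, (width - n) // 2, n)


def crop_roi(img: np.ndarray, roi: RoiSpec) -> np.ndarray:
    """Extract the ROI sub-image; no resampling."""
    arr = np.asarray(img)
    roi.validate_within(arr.shape[0], arr.shape[1])
    return arr[
        roi.row_offset : roi.row_offset + roi.size_n,
        roi.col_offset : roi.col_offset + roi.size_n,
    ]


class SkinToneCategory(enum.Enum):
    """Six-bin phenotype scale over ITA; intervals are (lower, upper],
    except the lowest which is closed at -90."""

    VERY_LIGHT = ("very_light", 50.0, 90.0)
    LIGHT = ("light", 25.0, 50.0)
    FAIR = ("fair", 0.0, 25.0)
    BROWN = ("brown", -25.0, 0.0)
    DARK = ("dark", -50.0, -25.0)
    VERY_DARK = ("very_dark", -90.0, -50.0)

    def __init__(self, label: str, lower: float, upper: float):
        self.label = label
        self.lower = lower
        self.upper = upper

    @property
    def interval(self) -> tuple[float, float]:
        return (self.lower, self.upper)


def classify_ita(ita: float) -> SkinToneCategory:
    """Map an ITA value in [-90, 90] to its unique phenotype bin.

    Boundary values belong to the interval whose upper edge they touch
    (0 -> brown, 25 -> fair, -50 -> very_dark); -90 belongs to very_dark.
    """
    x = float(ita)
    if not np.isfinite(x) or x < -90.0 or x > 90.0:
        raise ValidationError(f"ITA must lie in [-90, 90] degrees, got {ita}")
    for cat in SkinToneCategory:
        if cat.lower < x <= cat.upper:
            return cat
    return SkinToneCategory.VERY_DARK  # x == -90


def ita_from_lab(L_star, b_star):
    """Per-element ITA in degrees from L* and b*.

    Uses atan2(L*-50, b*): b*=0 with L* != 50 yields +/-90 exactly;
    the undefined point (50, 0) yields NaN.  Scalar in, scalar out.
    """
    L = np.asarray(L_star, dtype=np.float64)
    b = np.asarray(b_star, dtype=np.float64)
    with np.errstate(invalid="ignore"):
        angle = np.degrees(np.arctan2(L - 50.0, b))
    undefined = (L == 50.0) & (b == 0.0)
    angle = np.where(undefined, np.nan, angle)
    if angle.ndim == 0:
        return float(angle)
    return angle


@dataclass
class ItaMap:
    """Per-pixel ITA in degrees plus a validity mask.

    ``defined_mask`` is False at the degenerate pivot (50, 0) and at
    pixels whose angle falls outside [-90, 90] (negative b*).
    """

    values: np.ndarray
    defined_mask: np.ndarray

    @property
    def defined_values(self) -> np.ndarray:
        return self.values[self.defined_mask]

    @property
    def n_defined(self) -> int:
        return int(self.defined_mask.sum())

    @property
    def n_undefined(self) -> int:
        return int(self.defined_mask.size - self.defined_mask.sum())

    def to_png(self, path, sidecar_path=None) -> None:
        """Write the map as 8-bit grayscale, [-90, 90] -> [0, 255] linearly;
        undefined pixels are written as 0.  A JSON sidecar records the scale."""
        scaled = np.zeros(self.values.shape, dtype=np.uint8)
        v = np.clip(self.values[self.defined_mask], -90.0, 90.0)
        scaled[self.defined_mask] = np.round((v + 90.0) / 180.0 * 255.0).astype(np.uint8)
        Image.fromarray(scaled, mode="L").save(path)
        sidecar = sidecar_path or (str(path) + ".json")
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "scale": "ita_deg = value / 255 * 180 - 90",
                    "lo_deg": -90.0,
                    "hi_deg": 90.0,
                    "n_undefined": self.n_undefined,
                },
                fh,
                indent=2,
            )


def ita_map(lab: np.ndarray) -> ItaMap:
    """Element-wise ITA over a Lab image; populates the validity mask."""
    arr = np.asarray(lab, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValidationError(f"Lab image must be H x W x 3, got shape {arr.shape}")
    values = ita_from_lab(arr[..., 0], arr[..., 2])
    defined = np.isfinite(values) & (values >= -90.0) & (values <= 90.0)
    return ItaMap(values=values, defined_mask=defined)


@dataclass(frozen=True)
class ItaSummary:
    """Scalar reduction of an ITA map: the mean over defined pixels is the
    single representative skin-tone value."""

    mean_ita: float
    sd_ita: float
    n_pixels: int
    n_undefined: int
    category: SkinToneCategory
    mean_a_star: float | None = None

    def to_dict(self, ndigits: int | None = 2) -> dict:
        rnd = (lambda x: x) if ndigits is None else (lambda x: round(x, ndigits))
        d = {
            "mean_ita_deg": rnd(self.mean_ita),
            "sd_ita_deg": rnd(self.sd_ita),
            "n_pixels": self.n_pixels,
            "n_undefined": self.n_undefined,
            "category": self.category.label,
        }
        if self.mean_a_star is not None:
            d["mean_a_star"] = rnd(self.mean_a_star)
        return d


def summarize_ita(ita: ItaMap, mean_a_star: float | None = None) -> ItaSummary:
    """Mean and population SD over defined pixels; category from the mean.

    Raises :class:`ValidationError` if every pixel is masked.
    """
    vals = ita.defined_values
    if vals.size == 0:
        raise ValidationError("ITA map has no defined pixels to summarize")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    return ItaSummary(
        mean_ita=mean,
        sd_ita=sd,
        n_pixels=int(vals.size),
        n_undefined=ita.n_undefined,
        category=classify_ita(np.clip(mean, -90.0, 90.0)),
        mean_a_star=mean_a_star,
    )


@dataclass(frozen=True)
class ItaHistogram:
    """Counts of defined map pixels over [-90, 90] at a fixed bin width."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_lower_deg": self.bin_edges[:-1],
                "bin_upper_deg": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def ita_histogram(ita: ItaMap, bin_width: float = 1.0) -> ItaHistogram:
    """Histogram of defined pixels over [-90, 90]; counts sum to n_defined."""
    if bin_width <= 0:
        raise ValidationError(f"bin width must be positive, got {bin_width}")
    n_bins = int(np.ceil(180.0 / bin_width))
    edges = -90.0 + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(ita.defined_values, bins=edges)
    return ItaHistogram(bin_edges=edges, counts=counts)
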