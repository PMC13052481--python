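"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators:

* skin patches at a prescribed ITA — a uniform Lab color placed on the
  ray of angle ITA about the pivot (L*=50, b*=0), plus i.i.d. Gaussian
  Lab texture noise, encoded to quantized 8-bit sRGB;
* exposure sweeps drawn from a known Boltzmann curve with additive
  Gaussian noise on the default 5-point exposure grid;
* reference-colorimeter series as Gaussian draws about a mean Lab triple
  with prescribed per-channel SD (default 20 readings, the clinical
  protocol count).

All generators are deterministic under a fixed seed.  The texture model
is i.i.d. noise, not spatially correlated skin microstructure: adequate
for validating the color pipeline, not a skin reflectance simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colorspace import ConversionConfig, lab_to_rgb
from .errors import ValidationError
from .exposure import DEFAULT_EXPOSURE_GRID, ExposureSweep, boltzmann
from .reference import ReferenceSeries

__all__ = ["PatchSpec", "SweepSpec", "make_patch", "make_sweep", "make_reference"]


@dataclass(frozen=True)
class PatchSpec:
    """Recipe for a uniform skin patch of known ITA.

    ``radius`` is the distance from the pivot (L*=50, b*=0) in the L*b*
    plane: the patch color is (L*, b*) = (50 + r sin ITA, r cos ITA).
    The default radius 30 stays in-gamut across the whole phenotype
    scale except |ITA| > 80; ``a_star`` defaults to 12, a typical
    reddish skin chroma (ITA itself ignores a*).
    """

    target_ita: float
    radius: float = 30.0
    a_star: float = 12.0
    noise_sd: float = 0.0
    size_n: int = 64
    seed: int = 0

    def __post_init__(self):
        if not -90.0 < self.target_ita < 90.0:
            raise ValidationError(
                f"target ITA must lie in (-90, 90), got {self.target_ita}"
            )
        if self.radius <= 0:
            raise ValidationError(f"radius must be positive, got {self.radius}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise SD must be >= 0, got {self.noise_sd}")
        if self.size_n < 1:
            raise ValidationError(f"patch size must be >= 1, got {self.size_n}")

    @property
    def lab_center(self) -> np.ndarray:
        theta = np.radians(self.target_ita)
        return np.array(
            [50.0 + self.radius * np.sin(theta), self.a_star, self.radius * np.cos(theta)]
        )


def make_patch(spec: PatchSpec) -> tuple[np.ndarray, float]:
    """Generate an 8-bit RGB patch; returns (image, exact target ITA).

    The clean center color must be in-gamut; an out-of-gamut spec raises
    a :class:`ValidationError` naming the offending linear-RGB channel.
    Noisy pixels that individually leave the gamut are clipped (the
    standard encoder behavior).
    """
    cfg = ConversionConfig.standard()
    center = spec.lab_center
    _, oog = lab_to_rgb(center.reshape(1, 1, 3), cfg)
    if oog.any():
        channel = _offending_channel(center, cfg)
        raise ValidationError(
            f"patch spec (ITA={spec.target_ita}, radius={spec.radius}, "
            f"a*={spec.a_star}) is out of the sRGB gamut on the {channel} channel"
        )
    rng = np.random.default_rng(spec.seed)
    lab = np.broadcast_to(center, (spec.size_n, spec.size_n, 3)).copy()
    if spec.noise_sd > 0:
        lab += rng.normal(0.0, spec.noise_sd, lab.shape)
        lab[..., 0] = np.clip(lab[..., 0], 0.0, 100.0)
    rgb8, _ = lab_to_rgb(lab, cfg)
    return rgb8, float(spec.target_ita)


def _offending_channel(lab_center: np.ndarray, cfg: ConversionConfig) -> str:
    from .colorspace import _DELTA  # CIELAB constant

    L, a, b = lab_center
    fy = (L + 16.0) / 116.0
    f = np.array([fy + a / 500.0, fy, fy - b / 200.0])
    t = np.where(f > _DELTA, f**3, 3 * _DELTA**2 * (f - 4.0 / 29.0))
    lin = (t * cfg.white_point) @ np.linalg.inv(cfg.xyz_matrix).T
    bad = np.where((lin < 0) | (lin > 1))[0]
    return "RGB"[bad[0]] if bad.size else "none"


@dataclass(frozen=True)
class SweepSpec:
    """Recipe for replicated exposure sweeps from a known Boltzmann truth."""

    A1: float
    A2: float
    x0: float
    dx: float
    exposures: tuple = DEFAULT_EXPOSURE_GRID
    noise_sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0
    flash: bool | None = None
    ambient: bool | None = None

    def __post_init__(self):
        ex = np.asarray(self.exposures, dtype=np.float64)
        if not np.all(np.diff(ex) > 0):
            raise ValidationError("exposures must be strictly increasing")
        if self.noise_sd < 0:
            raise ValidationError(f"noise SD must be >= 0, got {self.noise_sd}")
        if self.dx == 0:
            raise ValidationError("truth slope dx must be nonzero")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


def make_sweep(spec: SweepSpec) -> list[ExposureSweep]:
    """Draw ``n_replicates`` sweeps: Boltzmann curve plus Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    x = np.asarray(spec.exposures, dtype=np.float64)
    clean = boltzmann(x, spec.A1, spec.A2, spec.x0, spec.dx)
    sweeps = []
    for i in range(spec.n_replicates):
        noise = rng.normal(0.0, spec.noise_sd, x.shape) if spec.noise_sd > 0 else 0.0
        sweeps.append(
            ExposureSweep(
                x,
                clean + noise,
                flash=spec.flash,
                ambient=spec.ambient,
                label=f"replicate_{i}",
            )
        )
    return sweeps


def make_reference(
    mean_lab,
    sd_lab,
    n: int = 20,
    seed: int = 0,
    site: str = "",
    subject_id: str = "",
) -> ReferenceSeries:
    """Gaussian reference series about ``mean_lab`` with per-channel SD.

    The default n=20 matches the clinical colorimeter protocol (twenty
    consecutive readings per site).
    """
    if n < 2:
        raise ValidationError(f"need n >= 2 readings, got {n}")
    mean = np.asarray(mean_lab, dtype=np.float64)
    sd = np.broadcast_to(np.asarray(sd_lab, dtype=np.float64), (3,))
    if (sd < 0).any():
        raise ValidationError("per-channel SDs must be >= 0")
    rng = np.random.default_rng(seed)
    readings = mean + rng.normal(0.0, 1.0, (n, 3)) * sd
    readings[:, 0] = np.clip(readings[:, 0], 0.0, 100.0)
    return ReferenceSeries(readings, site=site, subject_id=subject_id)
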