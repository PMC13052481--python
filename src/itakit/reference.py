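"""Reference-colorimeter series and agreement metrics.

A handheld tristimulus colorimeter pressed against the skin (light-tight,
D65 illumination) is the clinical gold standard for skin color.  Its
protocol here: 20 consecutive L*a*b* readings per anatomical site at
0.5 Hz, summarized as per-reading ITA mean and SD.  Agreement between a
camera-derived ITA and the reference is reported as a signed ITA error,
alongside the CIE76 color difference (Euclidean distance in Lab) for
completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.color import deltaE_cie76

from .errors import ValidationError
from .ita import ita_from_lab

__all__ = [
    "ReferenceSeries",
    "AgreementReport",
    "CohortStats",
    "SITES",
    "summarize_reference",
    "delta_e76",
    "ita_error",
    "cohort_stats",
    "read_reference_csv",
    "write_reference_csv",
]

#: Anatomical sites measured in the finger/wrist protocol.
SITES = ("finger_palmar", "finger_dorsal", "wrist_palmar", "wrist_dorsal")


@dataclass(frozen=True)
class ReferenceSeries:
    """Repeated colorimeter readings for one subject and site."""

    readings: np.ndarray  # (n, 3) L*, a*, b*
    site: str = ""
    subject_id: str = ""

    def __post_init__(self):
        arr = np.asarray(self.readings, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValidationError(
                f"readings must be an (n, 3) array of L*, a*, b*, got {arr.shape}"
            )
        L = arr[:, 0]
        if L.min() < 0 or L.max() > 100:
            raise ValidationError(
                f"L* readings must lie in [0, 100]; found range "
                f"[{L.min():.2f}, {L.max():.2f}]"
            )
        object.__setattr__(self, "readings", arr)

    def __len__(self) -> int:
        return self.readings.shape[0]

    @property
    def mean_lab(self) -> np.ndarray:
        return self.readings.mean(axis=0)

    @property
    def ita_per_reading(self) -> np.ndarray:
        return np.asarray(
            ita_from_lab(self.readings[:, 0], self.readings[:, 2])
        )


def summarize_reference(series: ReferenceSeries) -> tuple[float, float]:
    """Mean and sample SD of per-reading ITA.

    ITA is computed reading-by-reading and then averaged (matching how
    the instrument reports per-measurement ITA), not from the averaged
    Lab triple.  Requires at least 2 readings.
    """
    if len(series) < 2:
        raise ValidationError(
            f"need >= 2 readings for an SD, got {len(series)}"
        )
    ita = series.ita_per_reading
    if np.isnan(ita).any():
        raise ValidationError("series contains the undefined point (L*=50, b*=0)")
    return float(ita.mean()), float(ita.std(ddof=1))


def delta_e76(lab1, lab2) -> float:
    """CIE76 color difference: Euclidean distance between Lab triples."""
    return float(
        deltaE_cie76(
            np.asarray(lab1, dtype=np.float64), np.asarray(lab2, dtype=np.float64)
        )
    )


@dataclass(frozen=True)
class AgreementReport:
    """Camera-vs-reference agreement for one site."""

    ita_error: float  # measured minus reference mean, degrees
    delta_e76: float
    reference_mean_ita: float
    reference_sd_ita: float

    def to_dict(self, ndigits: int | None = 2) -> dict:
        rnd = (lambda x: x) if ndigits is None else (
            lambda x: None if x is None or not np.isfinite(x) else round(x, ndigits)
        )
        return {
            "ita_error_deg": rnd(self.ita_error),
            "delta_e76": rnd(self.delta_e76),
            "reference_mean_ita_deg": rnd(self.reference_mean_ita),
            "reference_sd_ita_deg": rnd(self.reference_sd_ita),
        }


def ita_error(
    measured_ita: float,
    series: ReferenceSeries,
    measured_mean_lab=None,
) -> AgreementReport:
    """Signed ITA error (measured - reference mean) plus CIE76 distance.

    ``measured_mean_lab`` is the mean Lab triple of the measurement ROI;
    if omitted, delta_e76 is reported as NaN.
    """
    ref_mean, ref_sd = summarize_reference(series)
    if measured_mean_lab is None:
        de = float("nan")
    else:
        de = delta_e76(measured_mean_lab, series.mean_lab)
    return AgreementReport(
        ita_error=float(measured_ita) - ref_mean,
        delta_e76=de,
        reference_mean_ita=ref_mean,
        reference_sd_ita=ref_sd,
    )


@dataclass(frozen=True)
class CohortStats:
    """Dispersion of per-site mean ITA values across sites or subjects."""

    span: float  # max - min, degrees
    mean: float
    sd: float  # sample SD (ddof=1)


def cohort_stats(mean_itas) -> CohortStats:
    """Span (max - min), mean and sample SD of a collection of mean ITAs."""
    vals = np.asarray(mean_itas, dtype=np.float64)
    if vals.size < 2:
        raise ValidationError(f"need >= 2 values, got {vals.size}")
    return CohortStats(
        span=float(vals.max() - vals.min()),
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
    )


def read_reference_csv(path) -> list[ReferenceSeries]:
    """Read series from CSV with header subject,site,L,a,b (one row per
    reading); rows sharing (subject, site) form one series."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"{path}: malformed CSV: {exc}") from exc
    required = {"subject", "site", "L", "a", "b"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    series = []
    for (subject, site), grp in df.groupby(["subject", "site"], sort=True):
        series.append(
            ReferenceSeries(
                grp[["L", "a", "b"]].to_numpy(),
                site=str(site),
                subject_id=str(subject),
            )
        )
    return series


def write_reference_csv(series_list: list[ReferenceSeries], path) -> None:
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "subject": s.subject_id,
                    "site": s.site,
                    "L": s.readings[:, 0],
                    "a": s.readings[:, 1],
                    "b": s.readings[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
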