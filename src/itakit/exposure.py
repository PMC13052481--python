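"""Exposure-dependent ITA response: Boltzmann sigmoid model and fit.

Mean ITA measured from photographs of the same site rises with camera
exposure along a characteristic sigmoid, from an under-exposed floor to
an over-exposed ceiling.  The four-parameter Boltzmann function

    ITA(x) = A2 + (A1 - A2) / (1 + exp((x - x0) / dx))

describes this curve: A1 is the initial (low-exposure) value, A2 the
final value, x0 the center, and dx the slope constant of the linear
regime.  Fitting it to a sweep of measured exposures lets one locate
the exposure whose ITA best matches a reference colorimeter reading,
and quantify hysteresis-like gaps between flash/ambient conditions.

The fit follows the statsmodels idiom: build a :class:`BoltzmannModel`
from the data, call :meth:`~BoltzmannModel.fit`, inspect the returned
:class:`BoltzmannResults` (params, bse, rmse, summary(), plot()).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ValidationError

__all__ = [
    "ExposureSweep",
    "BoltzmannModel",
    "BoltzmannResults",
    "boltzmann",
    "fit_boltzmann",
    "optimal_exposure",
    "hysteresis_gap",
    "read_sweeps_csv",
    "write_sweeps_csv",
]

#: Exposure settings acquired in the characteristic-curve protocol.
DEFAULT_EXPOSURE_GRID = (0.3, 0.7, 1.0, 1.3, 1.7)

_DX_BOUNDS = (1e-4, 10.0)


def boltzmann(x, A1: float, A2: float, x0: float, dx: float):
    """Evaluate the Boltzmann sigmoid; dx must be nonzero."""
    if dx == 0:
        raise ValidationError("Boltzmann slope constant dx must be nonzero")
    x = np.asarray(x, dtype=np.float64)
    with np.errstate(over="ignore"):  # exp overflow -> inf -> correct asymptote
        out = A2 + (A1 - A2) / (1.0 + np.exp((x - x0) / dx))
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class ExposureSweep:
    """Mean-ITA readings over a strictly increasing exposure grid."""

    exposures: np.ndarray
    mean_ita: np.ndarray
    flash: bool | None = None
    ambient: bool | None = None
    label: str = ""

    def __post_init__(self):
        ex = np.asarray(self.exposures, dtype=np.float64)
        it = np.asarray(self.mean_ita, dtype=np.float64)
        if ex.ndim != 1 or it.shape != ex.shape:
            raise ValidationError(
                f"exposures and mean_ita must be equal-length 1-D arrays, "
                f"got shapes {ex.shape} and {it.shape}"
            )
        if ex.size < 2:
            raise ValidationError("a sweep needs at least 2 points")
        if not np.all(np.diff(ex) > 0):
            raise ValidationError("exposures must be strictly increasing")
        object.__setattr__(self, "exposures", ex)
        object.__setattr__(self, "mean_ita", it)

    def __len__(self) -> int:
        return self.exposures.size

    @property
    def condition(self) -> str:
        def onoff(v):
            return "?" if v is None else ("on" if v else "off")

        return f"flash={onoff(self.flash)}, ambient={onoff(self.ambient)}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.exposures,
                "mean_ita": self.mean_ita,
                "flash": "" if self.flash is None else ("on" if self.flash else "off"),
                "ambient": ""
                if self.ambient is None
                else ("on" if self.ambient else "off"),
            }
        )


class BoltzmannModel:
    """Nonlinear least-squares Boltzmann fit of an exposure sweep.

    Parameters
    ----------
    exposures, mean_ita
        The sweep data; at least 4 points, strictly increasing exposures.

    Initialization is A1 = first reading, A2 = last reading, x0 = median
    exposure, dx = exposure range / 4, with dx bounded to (1e-4, 10];
    chosen for robustness on short 5-point sweeps.
    """

    param_names = ("A1", "A2", "x0", "dx")

    def __init__(self, exposures, mean_ita):
        sweep = ExposureSweep(exposures, mean_ita)
        if len(sweep) < 4:
            raise ValidationError(
                f"Boltzmann fit needs >= 4 points, got {len(sweep)}"
            )
        self.sweep = sweep

    @classmethod
    def from_sweep(cls, sweep: ExposureSweep) -> "BoltzmannModel":
        model = cls(sweep.exposures, sweep.mean_ita)
        model.sweep = sweep
        return model

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, x_col: str = "exposure", y_col: str = "mean_ita"
    ) -> "BoltzmannModel":
        return cls(df[x_col].to_numpy(), df[y_col].to_numpy())

    def start_params(self) -> np.ndarray:
        x, y = self.sweep.exposures, self.sweep.mean_ita
        return np.array([y[0], y[-1], float(np.median(x)), (x[-1] - x[0]) / 4.0])

    def fit(self) -> "BoltzmannResults":
        """Unweighted nonlinear least squares via scipy's trust-region solver.

        Never raises on non-convergence: the returned results carry
        ``converged=False`` and the start parameters instead.
        """
        x, y = self.sweep.exposures, self.sweep.mean_ita
        p0 = self.start_params()
        p0[3] = float(np.clip(p0[3], *_DX_BOUNDS))
        lower = [-np.inf, -np.inf, -np.inf, _DX_BOUNDS[0]]
        upper = [np.inf, np.inf, np.inf, _DX_BOUNDS[1]]
        try:
            popt, pcov = curve_fit(
                boltzmann, x, y, p0=p0, bounds=(lower, upper), maxfev=20000
            )
            converged = bool(np.all(np.isfinite(popt)))
        except (RuntimeError, ValueError):
            popt, pcov, converged = p0, np.full((4, 4), np.nan), False
        resid = y - boltzmann(x, *popt)
        rmse = float(np.sqrt(np.mean(resid**2)))
        degenerate = bool(np.ptp(y) < 1e-9 or abs(popt[0] - popt[1]) < 1e-9)
        return BoltzmannResults(
            model=self,
            params=pd.Series(popt, index=self.param_names),
            cov_params=pd.DataFrame(
                pcov, index=self.param_names, columns=self.param_names
            ),
            rmse=rmse,
            converged=converged,
            degenerate=degenerate,
        )


@dataclass
class BoltzmannResults:
    """Fitted Boltzmann parameters with diagnostics.

    ``degenerate`` flags flat sweeps (A1 == A2), where the slope constant
    dx is unidentifiable and retains its bounded initial value.
    """

    model: BoltzmannModel
    params: pd.Series
    cov_params: pd.DataFrame
    rmse: float
    converged: bool
    degenerate: bool = False

    @property
    def A1(self) -> float:
        return float(self.params["A1"])

    @property
    def A2(self) -> float:
        return float(self.params["A2"])

    @property
    def x0(self) -> float:
        return float(self.params["x0"])

    @property
    def dx(self) -> float:
        return float(self.params["dx"])

    @property
    def bse(self) -> pd.Series:
        """Asymptotic standard errors from the NLS covariance."""
        return pd.Series(
            np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index
        )

    def predict(self, x):
        return boltzmann(x, *self.params.to_numpy())

    def to_dict(self) -> dict:
        return {
            "A1": self.A1,
            "A2": self.A2,
            "x0": self.x0,
            "dx": self.dx,
            "rmse": self.rmse,
            "converged": self.converged,
            "degenerate": self.degenerate,
        }

    def summary(self) -> str:
        lines = [
            "Boltzmann exposure-response fit",
            "=" * 46,
            f"{'n points':<14}{len(self.model.sweep):>10}",
            f"{'rmse (deg)':<14}{self.rmse:>10.4f}",
            f"{'converged':<14}{str(self.converged):>10}",
            f"{'degenerate':<14}{str(self.degenerate):>10}",
            "-" * 46,
            f"{'param':<8}{'estimate':>12}{'std err':>12}",
        ]
        bse = self.bse
        for name in self.params.index:
            se = bse[name]
            se_str = f"{se:>12.4f}" if np.isfinite(se) else f"{'nan':>12}"
            lines.append(f"{name:<8}{self.params[name]:>12.4f}{se_str}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot(self, ax=None, n_curve: int = 200):
        """Scatter the sweep and overlay the fitted sigmoid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sw = self.model.sweep
        ax.plot(sw.exposures, sw.mean_ita, "o", label="measured")
        xs = np.linspace(sw.exposures[0], sw.exposures[-1], n_curve)
        ax.plot(xs, self.predict(xs), "-", label="Boltzmann fit")
        ax.set_xlabel("exposure setting")
        ax.set_ylabel("mean ITA (deg)")
        ax.legend()
        return ax


def fit_boltzmann(sweep: ExposureSweep) -> BoltzmannResults:
    """Convenience wrapper: ``BoltzmannModel.from_sweep(sweep).fit()``."""
    return BoltzmannModel.from_sweep(sweep).fit()


def optimal_exposure(sweep: ExposureSweep, reference_ita: float) -> float:
    """The measured exposure whose mean ITA is closest to the reference.

    Restricted to acquired settings (not the continuous fit); ties break
    toward the lower exposure.
    """
    dev = np.abs(sweep.mean_ita - reference_ita)
    return float(sweep.exposures[int(np.argmin(dev))])


def hysteresis_gap(sweep_a: ExposureSweep, sweep_b: ExposureSweep) -> float:
    """Mean absolute mean-ITA difference between two conditions sharing a grid."""
    if len(sweep_a) != len(sweep_b) or not np.allclose(
        sweep_a.exposures, sweep_b.exposures, rtol=0, atol=1e-12
    ):
        raise ValidationError(
            f"exposure grids differ: {sweep_a.exposures} vs {sweep_b.exposures}"
        )
    return float(np.mean(np.abs(sweep_a.mean_ita - sweep_b.mean_ita)))


def _parse_onoff(value, col: str, line: int) -> bool | None:
    s = str(value).strip().lower()
    if s in ("", "nan", "none"):
        return None
    if s in ("on", "true", "1"):
        return True
    if s in ("off", "false", "0"):
        return False
    raise ValidationError(f"line {line}: column {col!r} must be on/off, got {value!r}")


def read_sweeps_csv(path) -> list[ExposureSweep]:
    """Read sweeps from CSV with columns exposure, mean_ita[, flash, ambient].

    Rows sharing a (flash, ambient) condition form one sweep.  Parse
    failures report the offending line number.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"{path}: malformed CSV: {exc}") from exc
    for col in ("exposure", "mean_ita"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValidationError(
                f"{path}: line {line}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r}"
            )
        df[col] = pd.to_numeric(df[col])
    for col in ("flash", "ambient"):
        if col not in df.columns:
            df[col] = None
        else:
            df[col] = [
                _parse_onoff(v, col, i + 2) for i, v in enumerate(df[col])
            ]
    sweeps = []
    for (flash, amb), grp in df.groupby(["flash", "ambient"], dropna=False, sort=True):
        grp = grp.sort_values("exposure")
        sweeps.append(
            ExposureSweep(
                grp["exposure"].to_numpy(),
                grp["mean_ita"].to_numpy(),
                flash=None if pd.isna(flash) else bool(flash),
                ambient=None if pd.isna(amb) else bool(amb),
            )
        )
    return sweeps


def write_sweeps_csv(sweeps: list[ExposureSweep], path) -> None:
    pd.concat([s.to_frame() for s in sweeps], ignore_index=True).to_csv(
        path, index=False
    )
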