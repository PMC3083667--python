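"""Monthly climate forcing: synthetic generation, I/O, and recorded change.

The environment agents observe is a dense monthly grid of three variables —
temperature, precipitation and runoff — spanning a multi-decade window
(by default 1960–2090). Real forcing can be supplied as a CSV table; the
built-in generator emulates its structure (linear upward trend in the annual
mean, a single sinusoidal seasonal cycle, i.i.d. Gaussian month-to-month
noise) and is calibrated so that the noise-free five-year annual means of
the first and last five full years hit configured targets exactly.

``recorded_change`` computes q_x, the difference between the current month's
value and the long-run mean of that calendar month over a baseline year set —
the "community truth" against which perceived change is compared.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ClimateVariable",
    "FLUX_VARIABLES",
    "MonthlySeries",
    "VariableGenConfig",
    "ClimateGenConfig",
    "ClimateTableError",
    "NoHistoryError",
    "default_climate_config",
    "generate_synthetic_climate",
    "load_climate_table",
    "write_climate_table",
    "historical_monthly_mean",
    "recorded_change",
]


class ClimateVariable(str, enum.Enum):
    """The three environmental variables agents observe."""

    TEMPERATURE = "temperature"
    PRECIPITATION = "precipitation"
    RUNOFF = "runoff"


#: Depth-flux variables that cannot be negative (temperature can).
FLUX_VARIABLES = frozenset(
    {ClimateVariable.PRECIPITATION, ClimateVariable.RUNOFF}
)


class ClimateTableError(ValueError):
    """Raised when a climate CSV table is malformed or has gaps."""


class NoHistoryError(ValueError):
    """Raised when a historical mean is requested over an empty year set."""


class MonthlySeries:
    """Dense monthly values for every variable over [start_year, end_year].

    Parameters
    ----------
    start_year, end_year
        Inclusive calendar-year range.
    data
        Mapping from :class:`ClimateVariable` to a ``(n_years, 12)`` array,
        row ``k`` holding the twelve monthly values of ``start_year + k``.
    """

    def __init__(
        self,
        start_year: int,
        end_year: int,
        data: Mapping[ClimateVariable, np.ndarray],
    ) -> None:
        if end_year < start_year:
            raise ValueError("end_year must be >= start_year")
        n_years = end_year - start_year + 1
        self.start_year = int(start_year)
        self.end_year = int(end_year)
        self._data: dict[ClimateVariable, np.ndarray] = {}
        for var in ClimateVariable:
            if var not in data:
                raise ValueError(f"missing variable {var.value!r}")
            arr = np.asarray(data[var], dtype=float)
            if arr.shape != (n_years, 12):
                raise ValueError(
                    f"{var.value}: expected shape {(n_years, 12)}, got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{var.value}: non-finite values")
            if var in FLUX_VARIABLES and np.any(arr < 0):
                raise ValueError(f"{var.value}: flux variable has negative values")
            self._data[var] = arr

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    def matrix(self, var: ClimateVariable) -> np.ndarray:
        """Return the ``(n_years, 12)`` value array for ``var`` (do not mutate)."""
        return self._data[ClimateVariable(var)]

    def value(self, var: ClimateVariable, year: int, month: int) -> float:
        if not self.start_year <= year <= self.end_year:
            raise ValueError(f"year {year} outside series range")
        if not 1 <= month <= 12:
            raise ValueError(f"month must be in 1..12, got {month}")
        return float(self._data[ClimateVariable(var)][year - self.start_year, month - 1])

    def annual_means(self, var: ClimateVariable) -> np.ndarray:
        return self.matrix(var).mean(axis=1)

    def covers(self, start_year: int, end_year: int) -> bool:
        return self.start_year <= start_year and self.end_year >= end_year

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with columns year, month, temperature, precipitation, runoff."""
        years = np.repeat(self.years, 12)
        months = np.tile(np.arange(1, 13), self.n_years)
        cols = {"year": years, "month": months}
        for var in ClimateVariable:
            cols[var.value] = self._data[var].ravel()
        return pd.DataFrame(cols)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MonthlySeries):
            return NotImplemented
        return (
            self.start_year == other.start_year
            and self.end_year == other.end_year
            and all(
                np.array_equal(self._data[v], other._data[v])
                for v in ClimateVariable
            )
        )

    def __repr__(self) -> str:
        return (
            f"MonthlySeries({self.start_year}-{self.end_year}, "
            f"{self.n_years * 12} months x 3 variables)"
        )


@dataclass(frozen=True)
class VariableGenConfig:
    """Generator settings for one climate variable.

    ``start_mean`` / ``end_mean`` are calibration targets: the annual means of
    the first and last five full years of the noise-free series. The seasonal
    term is a cosine with period 12 peaking at ``peak_month``; ``noise_sd`` is
    the standard deviation of i.i.d. Gaussian monthly noise. ``nonnegative``
    clips the summed value at zero (for depth fluxes).
    """

    start_mean: float
    end_mean: float
    seasonal_amplitude: float = 0.0
    noise_sd: float = 0.0
    peak_month: int = 7
    nonnegative: bool = False

    def __post_init__(self) -> None:
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 1 <= self.peak_month <= 12:
            raise ValueError("peak_month must be in 1..12")


def _default_variables() -> dict[ClimateVariable, VariableGenConfig]:
    # Endpoint means are the published five-year averages for the study
    # region; amplitudes/noise reflect western-Alaska monthly climatology
    # (temperature peaks in July, precipitation in August, runoff at the
    # June snowmelt; both fluxes are clipped at zero).
    return {
        ClimateVariable.TEMPERATURE: VariableGenConfig(
            start_mean=-4.4, end_mean=3.9, seasonal_amplitude=13.0,
            noise_sd=2.5, peak_month=7, nonnegative=False,
        ),
        ClimateVariable.PRECIPITATION: VariableGenConfig(
            start_mean=23.9, end_mean=45.0, seasonal_amplitude=15.0,
            noise_sd=8.0, peak_month=8, nonnegative=True,
        ),
        ClimateVariable.RUNOFF: VariableGenConfig(
            start_mean=5.6, end_mean=13.0, seasonal_amplitude=5.0,
            noise_sd=2.5, peak_month=6, nonnegative=True,
        ),
    }


@dataclass(frozen=True)
class ClimateGenConfig:
    """Full configuration for :func:`generate_synthetic_climate`."""

    start_year: int = 1960
    end_year: int = 2090
    seed: int = 0
    variables: Mapping[ClimateVariable, VariableGenConfig] = field(
        default_factory=_default_variables
    )

    def __post_init__(self) -> None:
        if self.end_year < self.start_year + 9:
            raise ValueError(
                "end_year must be at least start_year + 9 "
                "(five-year endpoint means need ten distinct years)"
            )
        for var in ClimateVariable:
            if var not in self.variables:
                raise ValueError(f"missing generator config for {var.value!r}")


def default_climate_config(seed: int = 0) -> ClimateGenConfig:
    """Default generator configuration calibrated to the published endpoint means."""
    return ClimateGenConfig(seed=seed)


def generate_synthetic_climate(cfg: ClimateGenConfig) -> MonthlySeries:
    """Generate a dense monthly series: linear trend + seasonality + noise.

    The trend is linear in continuous time t = year_offset + (month − 0.5)/12,
    anchored so the noise-free annual means of the first and last five years
    average exactly ``start_mean`` and ``end_mean``. The cosine seasonal term
    sums to zero over any calendar year, so it does not disturb the
    calibration. Identical configuration (including seed) yields a
    bit-identical series.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.end_year - cfg.start_year + 1
    k = np.arange(n, dtype=float)[:, None]
    m = np.arange(1, 13, dtype=float)[None, :]
    t = k + (m - 0.5) / 12.0  # year-mean of t is k + 0.5; first-5 mean is 2.5
    data: dict[ClimateVariable, np.ndarray] = {}
    for var in ClimateVariable:  # fixed order keeps the noise stream stable
        vc = cfg.variables[var]
        slope = (vc.end_mean - vc.start_mean) / (n - 5)
        trend = vc.start_mean + slope * (t - 2.5)
        seasonal = vc.seasonal_amplitude * np.cos(
            2.0 * math.pi * (m - vc.peak_month) / 12.0
        )
        noise = rng.normal(0.0, vc.noise_sd, size=(n, 12)) if vc.noise_sd > 0 else 0.0
        values = trend + seasonal + noise
        if vc.nonnegative:
            values = np.clip(values, 0.0, None)
        data[var] = values
    return MonthlySeries(cfg.start_year, cfg.end_year, data)


_CSV_COLUMNS = ["year", "month"] + [v.value for v in ClimateVariable]


def load_climate_table(path: str | Path) -> MonthlySeries:
    """Load a dense monthly climate table from CSV.

    The file must have header columns ``year,month,temperature,precipitation,
    runoff`` and exactly one row for every (year, month) between the earliest
    and latest year present. The first gap or non-numeric cell found is
    reported in the error.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ClimateTableError(f"{path}: missing columns {missing_cols}")
    if len(df) == 0:
        raise ClimateTableError(f"{path}: empty table")
    for col in _CSV_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise ClimateTableError(
                f"{path}: non-numeric value in column {col!r} at data row {row}"
            )
        df[col] = coerced
    years = df["year"].astype(int)
    months = df["month"].astype(int)
    if ((months < 1) | (months > 12)).any():
        raise ClimateTableError(f"{path}: month values must be in 1..12")
    start_year, end_year = int(years.min()), int(years.max())
    seen: dict[tuple[int, int], int] = {}
    for idx, (y, mo) in enumerate(zip(years, months)):
        key = (int(y), int(mo))
        if key in seen:
            raise ClimateTableError(
                f"{path}: duplicate entry for {key[0]}-{key[1]:02d}"
            )
        seen[key] = idx
    for y in range(start_year, end_year + 1):
        for mo in range(1, 13):
            if (y, mo) not in seen:
                raise ClimateTableError(f"{path}: missing entry for {y}-{mo:02d}")
    n_years = end_year - start_year + 1
    data = {}
    order = np.lexsort((months.to_numpy(), years.to_numpy()))
    for var in ClimateVariable:
        data[var] = df[var.value].to_numpy(dtype=float)[order].reshape(n_years, 12)
    return MonthlySeries(start_year, end_year, data)


def write_climate_table(series: MonthlySeries, path: str | Path) -> None:
    """Write a series as CSV; values round-trip exactly through ``load_climate_table``."""
    # 17 significant digits round-trip IEEE doubles bit-exactly.
    series.to_frame().to_csv(path, index=False, float_format="%.17g")


def historical_monthly_mean(
    series: MonthlySeries,
    var: ClimateVariable,
    month: int,
    years: Iterable[int],
) -> float:
    """Arithmetic mean of ``var`` at calendar ``month`` over the given years.

    Raises :class:`NoHistoryError` when the year set is empty — callers use
    this to mark a perception as undefined rather than to abort.
    """
    year_list = sorted(set(int(y) for y in years))
    if not year_list:
        raise NoHistoryError("empty year set: no history to average over")
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    if year_list[0] < series.start_year or year_list[-1] > series.end_year:
        raise ValueError("requested years fall outside the series range")
    idx = np.asarray(year_list) - series.start_year
    return float(series.matrix(var)[idx, month - 1].mean())


def recorded_change(
    series: MonthlySeries,
    var: ClimateVariable,
    month: int,
    current_year: int,
    baseline_years: Iterable[int] | None = None,
) -> float:
    """Recorded change q_x: current value minus the baseline monthly mean.

    ``baseline_years`` defaults to every series year strictly before
    ``current_year`` — the full record available to the community.
    """
    if not series.start_year <= current_year <= series.end_year:
        raise ValueError(f"current_year {current_year} outside series range")
    if baseline_years is None:
        baseline_years = range(series.start_year, current_year)
    return series.value(var, current_year, month) - historical_monthly_mean(
        series, var, month, baseline_years
    )
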