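"""Hydroxyl-proton exchange kinetics from NMR observables.

Two estimators:

* :func:`exchange_rate_from_exsy` - the initial-rate EXSY estimator.  In a
  two-site exchange experiment (hydroxyl proton <-> water) the ratio of the
  exchange cross-peak volume to the diagonal-peak volume grows linearly at
  short mixing times, r(t_m) ~= k_ex * t_m, so a through-origin fit of the
  ratio over an initial window yields the exchange rate constant.

* :func:`temperature_coefficient` - ordinary least-squares slope of a
  hydroxyl proton's chemical shift against temperature, reported as a
  magnitude in ppb/K.  Small magnitudes indicate shielding from solvent
  exchange, e.g. by intramolecular hydrogen bonding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ExsyDataset",
    "ExchangeResult",
    "TempShiftSeries",
    "TempCoefficient",
    "exchange_rate_from_exsy",
    "temperature_coefficient",
]


@dataclass
class ExsyDataset:
    """EXSY peak volumes on a mixing-time grid for one exchange site."""

    site: str
    mixing_times: np.ndarray  # seconds, strictly increasing, positive
    diagonal: np.ndarray
    cross: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.mixing_times = np.asarray(self.mixing_times, dtype=float)
        self.diagonal = np.asarray(self.diagonal, dtype=float)
        self.cross = np.asarray(self.cross, dtype=float)
        n = len(self.mixing_times)
        if len(self.diagonal) != n or len(self.cross) != n:
            raise ValueError("mixing times and volumes must have equal length")
        if np.any(self.mixing_times <= 0) or np.any(np.diff(self.mixing_times) <= 0):
            raise ValueError("mixing times must be positive and strictly increasing")
        if np.any(self.diagonal < 0) or np.any(self.cross < 0):
            raise ValueError("peak volumes must be non-negative")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if len(self.sigma) != n or np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive and match the grid")


@dataclass
class ExchangeResult:
    """Initial-rate EXSY fit: k_ex (1/s) plus fit diagnostics."""

    k_ex: float
    slope: float
    intercept: float
    stderr: float
    n_points: int
    degenerate: bool = False

    def __post_init__(self):
        if self.k_ex < 0:
            raise ValueError("exchange rate must be non-negative")


@dataclass
class TempShiftSeries:
    """Chemical shift (ppm) of one OH site across temperatures (K)."""

    site: str
    temperatures: np.ndarray
    shifts_ppm: np.ndarray

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.shifts_ppm = np.asarray(self.shifts_ppm, dtype=float)
        if len(self.temperatures) != len(self.shifts_ppm):
            raise ValueError("temperatures and shifts must have equal length")
        if len(self.temperatures) < 3:
            raise ValueError("at least three temperature points are required")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class TempCoefficient:
    """|d(shift)/dT| in ppb/K with the raw slope sign kept separately."""

    magnitude_ppb_per_k: float
    slope_sign: int
    stderr_ppb_per_k: float

    def __post_init__(self):
        if self.magnitude_ppb_per_k < 0:
            raise ValueError("coefficient magnitude must be non-negative")


def exchange_rate_from_exsy(
    data: ExsyDataset,
    window: float = 0.009,
    ratio_convention: str = "cross_over_diagonal",
) -> ExchangeResult:
    """Exchange rate constant from the initial EXSY build-up.

    Points with mixing time <= `window` (seconds) enter a through-origin
    least-squares fit of cross/diagonal versus mixing time; the slope is
    k_ex.  The `diagonal_over_cross` convention instead fits the inverted
    ratio to 1/(k t_m); it is provided for comparison but is non-linear at
    short times and not recommended.
    """
    sel = data.mixing_times <= window + 1e-12
    t = data.mixing_times[sel]
    diag = data.diagonal[sel]
    cross = data.cross[sel]
    if len(t) < 2:
        raise ValueError("need at least two points inside the fitting window")
    if np.any(diag <= 0):
        raise ValueError("diagonal volumes must be positive inside the window")

    if np.all(cross == 0):
        return ExchangeResult(0.0, 0.0, 0.0, 0.0, len(t), degenerate=True)

    w = 1.0 / data.sigma[sel] ** 2 if data.sigma is not None else np.ones_like(t)
    if ratio_convention == "cross_over_diagonal":
        r = cross / diag
        slope = float(np.sum(w * t * r) / np.sum(w * t * t))
        resid = r - slope * t
        dof = max(len(t) - 1, 1)
        stderr = float(
            np.sqrt(np.sum(w * resid**2) / dof / np.sum(w * t * t))
        )
        k = max(slope, 0.0)
        return ExchangeResult(k, slope, 0.0, stderr, len(t))
    if ratio_convention == "diagonal_over_cross":
        y = diag / cross
        inv_t = 1.0 / t
        c = float(np.sum(w * y * inv_t) / np.sum(w * inv_t**2))
        k = 1.0 / c if c > 0 else 0.0
        resid = y - c * inv_t
        dof = max(len(t) - 1, 1)
        stderr_c = float(np.sqrt(np.sum(w * resid**2) / dof / np.sum(w * inv_t**2)))
        stderr_k = stderr_c / c**2 if c > 0 else float("inf")
        return ExchangeResult(k, 1.0 / c if c > 0 else float("inf"), 0.0, stderr_k, len(t))
    raise ValueError(f"unknown ratio convention {ratio_convention!r}")


def temperature_coefficient(series: TempShiftSeries) -> TempCoefficient:
    """OLS slope of chemical shift versus temperature, in ppb/K magnitude."""
    fit = stats.linregress(series.temperatures, series.shifts_ppm * 1000.0)
    slope = float(fit.slope)
    sign = 0 if slope == 0 else (1 if slope > 0 else -1)
    return TempCoefficient(abs(slope), sign, float(fit.stderr))
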