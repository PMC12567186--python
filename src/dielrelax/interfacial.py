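"""Maxwell-Wagner-Sillars interfacial polarization and dc-conductivity analysis.

For conductive inclusions (permittivity eps1', conductivity sigma1) dispersed
in a matrix (eps2', sigma2), interfacial charge build-up relaxes with

    tau_MWS = eps0 * (eps2' + A*phi*(eps1' - eps2')) / (sigma2 + A*phi*(sigma1 - sigma2))

where A is the inclusion depolarization factor (1/3 for spheres) and phi the
inclusion volume fraction.  When sigma1 << sigma2 the associated relaxation
frequency is proportional to the matrix dc conductivity, which shows up as a
slope of one in a log-log correlation of f0 against sigma0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import math

import numpy as np
from scipy import stats

from .models import EPS0
from .relaxation import ArrheniusFit, fit_arrhenius

__all__ = [
    "MWSParams",
    "ConductivitySeries",
    "CorrelationResult",
    "mws_relaxation_time",
    "mws_relaxation_frequency",
    "sigma_slow_correlation",
    "fit_conductivity_regimes",
    "conductivity_series_from_results",
]


@dataclass
class MWSParams:
    """Two-phase mixture parameters for interfacial polarization."""

    eps1: float
    eps2: float
    sigma1: float
    sigma2: float
    A: float = 1.0 / 3.0
    phi: float = 0.0

    def __post_init__(self):
        if self.eps1 < 1 or self.eps2 < 1:
            raise ValueError("relative permittivities must be >= 1")
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("conductivities must be >= 0")
        if not 0 < self.A <= 1:
            raise ValueError("depolarization factor A must be in (0, 1]")
        if not 0 <= self.phi < 1:
            raise ValueError("volume fraction phi must be in [0, 1)")


def mws_relaxation_time(p: MWSParams) -> float:
    """Interfacial-polarization relaxation time tau (s)."""
    num = p.eps2 + p.A * p.phi * (p.eps1 - p.eps2)
    den = p.sigma2 + p.A * p.phi * (p.sigma1 - p.sigma2)
    if den <= 0:
        raise ValueError("non-relaxing configuration: effective conductivity <= 0")
    if num <= 0:
        raise ValueError("non-relaxing configuration: effective permittivity <= 0")
    return EPS0 * num / den


def mws_relaxation_frequency(p: MWSParams) -> float:
    """Companion helper: f = 1 / (2 pi tau_MWS), in Hz."""
    return 1.0 / (2.0 * math.pi * mws_relaxation_time(p))


@dataclass
class ConductivitySeries:
    """Per-temperature dc conductivity and exponent from tan(delta) fits."""

    temperature: np.ndarray  # K
    sigma0: np.ndarray  # S/m
    n: Optional[np.ndarray] = None
    ta_label: str = ""

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.sigma0 = np.asarray(self.sigma0, dtype=float)
        if self.temperature.size != self.sigma0.size:
            raise ValueError("temperature and sigma0 must have equal length")
        if np.any(self.sigma0 < 0):
            raise ValueError("sigma0 must be >= 0")
        if self.n is not None:
            self.n = np.asarray(self.n, dtype=float)


def conductivity_series_from_results(results, ta_label: str = "") -> ConductivitySeries:
    """Extract (T, sigma0, n) from isotherm fit results that used a conductivity term."""
    T, sig, n = [], [], []
    for res in results:
        if res.model.conductivity is None or not res.success:
            continue
        T.append(res.temperature)
        sig.append(res.model.conductivity.sigma0)
        n.append(res.model.conductivity.n)
    return ConductivitySeries(np.array(T), np.array(sig), np.array(n), ta_label)


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    slope_stderr: float
    slope_ci95: tuple[float, float]
    n_points: int
    r_value: float


def sigma_slow_correlation(series: ConductivitySeries, slow_f0) -> CorrelationResult:
    """Log-log regression of the slow-process frequency on dc conductivity.

    ``slow_f0`` is a list of (temperature_K, f0_Hz).  Temperatures are
    matched between the two inputs (within 0.01 K); proportionality between
    f0 and sigma0 corresponds to a slope of one.
    """
    slow = {round(float(t), 2): float(f) for t, f in slow_f0}
    x, y = [], []
    for t, s in zip(series.temperature, series.sigma0):
        key = round(float(t), 2)
        if key in slow and s > 0 and slow[key] > 0:
            x.append(math.log10(s))
            y.append(math.log10(slow[key]))
    if len(x) < 3:
        raise ValueError(f"need >= 3 matched temperatures, got {len(x)}")
    reg = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, len(x) - 2)
    return CorrelationResult(
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        slope_stderr=float(reg.stderr),
        slope_ci95=(float(reg.slope - tcrit * reg.stderr), float(reg.slope + tcrit * reg.stderr)),
        n_points=len(x),
        r_value=float(reg.rvalue),
    )


def fit_conductivity_regimes(
    series: ConductivitySeries, breakpoint: float | str = "auto"
) -> tuple[ArrheniusFit, ArrheniusFit, float]:
    """Two-regime Arrhenius analysis of log10 sigma0 versus 1/T.

    Returns (low-T fit, high-T fit, breakpoint K).  In "auto" mode every
    midpoint of the temperature grid leaving at least 3 points per side is
    tried and the split with the lowest total squared residual wins.
    """
    order = np.argsort(series.temperature)
    T = series.temperature[order]
    sig = series.sigma0[order]
    if np.any(sig <= 0):
        raise ValueError("two-regime fit requires sigma0 > 0 everywhere")
    pts = np.column_stack([T, sig])

    def _split(tb):
        lo = pts[T < tb]
        hi = pts[T >= tb]
        if len(lo) < 3 or len(hi) < 3:
            return None
        flo = fit_arrhenius(lo)
        fhi = fit_arrhenius(hi)
        ssr = flo.rms_residual**2 * len(lo) + fhi.rms_residual**2 * len(hi)
        return flo, fhi, ssr

    if breakpoint == "auto":
        best = None
        for i in range(len(T) - 1):
            tb = 0.5 * (T[i] + T[i + 1])
            out = _split(tb)
            if out is None:
                continue
            if best is None or out[2] < best[1][2]:
                best = (tb, out)
        if best is None:
            raise ValueError("not enough points for two regimes (need >= 3 per side)")
        tb, (flo, fhi, _) = best
    else:
        tb = float(breakpoint)
        out = _split(tb)
        if out is None:
            raise ValueError("fewer than 3 points in one of the regimes")
        flo, fhi, _ = out
    return flo, fhi, float(tb)
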