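"""Relaxation maps and temperature laws: Arrhenius, VFT, Tg and fragility.

A relaxation map collects, per labelled process, the fitted relaxation
frequency f0 at each temperature.  Arrhenius groups give an activation
energy; VFT groups give (f_inf, B, T0) from which the dielectric glass
transition temperature (relaxation time = 100 s by convention) and the
dynamic fragility index m follow in closed form:

    log10 f = log10 f_inf - B / (ln(10) * (T - T0))            (VFT)
    Tg      = T0 + B / (ln(10) * (2 + log10(2*pi*f_inf)))
    m       = C * (1 + ln(10) * C * T0 / B),  C = 2 + log10(2*pi*f_inf)
            = B * Tg / (ln(10) * (Tg - T0)^2)

All temperatures are kelvin unless a name says otherwise; the gas constant
R = 8.314462618 J/(mol K) converts Arrhenius slopes to kJ/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

R_GAS = 8.314462618  # J/(mol K)
LN10 = math.log(10.0)
#: conventional glass-transition relaxation frequency, 1/(2*pi*100 s)
F_TG = 1.0 / (2.0 * math.pi * 100.0)
#: rounded log10 f0 level used to read Tg off a relaxation map
LOG_F_TG_ROUNDED = -2.8

__all__ = [
    "R_GAS",
    "F_TG",
    "MapEntry",
    "RelaxationMap",
    "ArrheniusFit",
    "VFTFit",
    "NoCrossingError",
    "build_relaxation_map",
    "fit_arrhenius",
    "fit_vft",
    "tg_from_vft",
    "tg_kelvin_from_vft",
    "fragility_from_vft",
    "dielectric_tg_crossing",
]


class NoCrossingError(RuntimeError):
    """The map group does not reach log10 f0 = -2.8 within the extrapolation guard."""


@dataclass
class MapEntry:
    label: str
    temperature: float  # K
    f0: float  # Hz
    provenance: str = "fit"

    def __post_init__(self):
        if not self.f0 > 0:
            raise ValueError("map entries require f0 > 0")


@dataclass
class RelaxationMap:
    entries: list[MapEntry] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        seen = []
        for e in self.entries:
            if e.label not in seen:
                seen.append(e.label)
        return seen

    def group(self, label: str, free_only: bool = True) -> list[tuple[float, float]]:
        """(T, f0) points of one process.

        With ``free_only`` (default) entries whose f0 was imposed (from an
        Arrhenius or VFT extrapolation, or by the user) are excluded, so
        refitting a temperature law to the map cannot be circular.
        """
        pts = []
        for e in self.entries:
            if e.label != label:
                continue
            if free_only and e.provenance.startswith("fixed:"):
                continue
            pts.append((e.temperature, e.f0))
        return pts


def build_relaxation_map(results: Sequence) -> RelaxationMap:
    """Collect (T, f0) per process label from isotherm fit results.

    Entries flagged "unresolved" in a result are skipped; the per-parameter
    provenance of f0 is carried on each entry.
    """
    entries = []
    for res in results:
        for p in res.model.processes:
            if res.flags.get(p.label) == "unresolved":
                continue
            prov = res.provenance.get(p.label, {}).get("f0", "fit")
            entries.append(MapEntry(p.label, res.temperature, p.f0, prov))
    return RelaxationMap(entries=entries)


@dataclass
class ArrheniusFit:
    """log10 f = log10_f_inf - Ea / (ln10 * R * T), Ea in kJ/mol."""

    log10_f_inf: float
    Ea: float
    n_points: int = 0
    rms_residual: float = 0.0

    def log10_frequency_at(self, T) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        return self.log10_f_inf - self.Ea * 1e3 / (LN10 * R_GAS * T)

    def frequency_at(self, T):
        return 10.0 ** self.log10_frequency_at(T)


@dataclass
class VFTFit:
    """Vogel-Fulcher-Tammann law f = f_inf * exp(-B / (T - T0))."""

    log10_f_inf: float
    B: float  # K
    T0: float  # K
    fixed_f_inf: bool = False
    n_points: int = 0
    rms_residual: float = 0.0
    ok: bool = True
    message: str = ""

    def __post_init__(self):
        if self.T0 < 0 or self.B <= 0:
            raise ValueError("VFT requires T0 >= 0 K and B > 0 K")

    def log10_frequency_at(self, T) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        return self.log10_f_inf - self.B / (LN10 * (T - self.T0))

    def frequency_at(self, T):
        return 10.0 ** self.log10_frequency_at(T)

    @property
    def tg_K(self) -> float:
        return tg_kelvin_from_vft(self)

    @property
    def tg_C(self) -> float:
        return tg_from_vft(self)

    @property
    def fragility(self) -> float:
        return fragility_from_vft(self)


def _as_tf_arrays(points):
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be a sequence of (temperature_K, f0_Hz) pairs")
    T, f0 = pts[:, 0], pts[:, 1]
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive kelvin")
    if np.any(f0 <= 0):
        raise ValueError("relaxation frequencies must be positive")
    return T, np.log10(f0)


def fit_arrhenius(points, robust: bool = False) -> ArrheniusFit:
    """Ordinary least squares of log10 f0 on 1/T.

    With ``robust`` one round of gross-outlier rejection is applied: points
    more than half a decade off the first-pass line are dropped and the
    line refitted (exact data are unaffected).
    """
    T, logf = _as_tf_arrays(points)
    if T.size < 2:
        raise ValueError("Arrhenius fit needs at least 2 points")
    x = 1.0 / T
    slope, intercept = np.polyfit(x, logf, 1)
    resid = logf - (intercept + slope * x)
    if robust and T.size >= 3:
        keep = np.abs(resid) <= 0.5
        if 2 <= keep.sum() < T.size:
            slope, intercept = np.polyfit(x[keep], logf[keep], 1)
            resid = logf[keep] - (intercept + slope * x[keep])
    return ArrheniusFit(
        log10_f_inf=float(intercept),
        Ea=float(-slope * LN10 * R_GAS / 1e3),
        n_points=int(resid.size),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


def _vft_linear_subfit(T, logf, T0, fixed_log10_f_inf=None):
    """Given T0, the VFT law is linear in (log10 f_inf, B); solve it exactly."""
    x = 1.0 / (LN10 * (T - T0))
    if fixed_log10_f_inf is None:
        A = np.column_stack([np.ones_like(x), -x])
        coef, *_ = np.linalg.lstsq(A, logf, rcond=None)
        lf, B = float(coef[0]), float(coef[1])
    else:
        lf = float(fixed_log10_f_inf)
        y = lf - logf
        B = float(y @ x / (x @ x))
    resid = logf - (lf - B * x)
    return lf, B, float(np.sum(resid**2))


def fit_vft(
    points,
    fixed_log10_f_inf: Optional[float] = None,
    robust: bool = False,
) -> VFTFit:
    """Nonlinear least squares of log10 f0 against the VFT law.

    T0 is profiled on a grid (the two remaining parameters are solved as a
    linear subproblem for each candidate T0), then all free parameters are
    polished with bounded trust-region least squares.  With ``robust`` the
    polish uses a soft-L1 loss (scale 0.1 decades), which tames isolated
    outlier map points without affecting exact data.  Deterministic.
    """
    T, logf = _as_tf_arrays(points)
    nmin = 2 if fixed_log10_f_inf is not None else 3
    if T.size < nmin:
        raise ValueError(f"VFT fit needs at least {nmin} points")
    t_lo = float(np.min(T))
    t0_max = t_lo - 1e-3

    # profile T0
    grid = np.linspace(0.0, max(t0_max - 1.0, 1e-3), 200)
    best = None
    for t0 in grid:
        lf, B, ssr = _vft_linear_subfit(T, logf, t0, fixed_log10_f_inf)
        if B <= 0:
            continue
        if best is None or ssr < best[3]:
            best = (lf, B, t0, ssr)
    if best is None:  # frequencies speeding up on cooling; not a VFT group
        return VFTFit(0.0, 1.0, 0.0, fixed_f_inf=fixed_log10_f_inf is not None,
                      n_points=int(T.size), rms_residual=float("nan"),
                      ok=False, message="no valid VFT profile (B <= 0 everywhere)")
    lf0, B0, t00, _ = best

    if fixed_log10_f_inf is None:
        def resid(p):
            lf, logB, t0 = p
            return logf - (lf - 10.0**logB / (LN10 * (T - t0)))

        sol = least_squares(
            resid, x0=[lf0, math.log10(max(B0, 1e-3)), t00],
            bounds=([-6.0, -3.0, 0.0], [25.0, 6.0, t0_max]), method="trf",
            loss="soft_l1" if robust else "linear", f_scale=0.1,
        )
        lf, B, t0 = float(sol.x[0]), float(10.0 ** sol.x[1]), float(sol.x[2])
    else:
        def resid(p):
            logB, t0 = p
            return logf - (fixed_log10_f_inf - 10.0**logB / (LN10 * (T - t0)))

        sol = least_squares(
            resid, x0=[math.log10(max(B0, 1e-3)), t00],
            bounds=([-3.0, 0.0], [6.0, t0_max]), method="trf",
            loss="soft_l1" if robust else "linear", f_scale=0.1,
        )
        lf, B, t0 = float(fixed_log10_f_inf), float(10.0 ** sol.x[0]), float(sol.x[1])

    rms = float(np.sqrt(np.mean(sol.fun**2)))
    # a Vogel temperature within half a kelvin of the coldest point means the
    # asymptote is effectively inside the data: not a trustworthy VFT group
    ok = bool(sol.success) and t0 < t_lo - 0.5
    msg = "" if ok else ("Vogel temperature at the data boundary (asymptote inside data)"
                         if t0 >= t_lo - 0.5 else sol.message)
    return VFTFit(lf, B, t0, fixed_f_inf=fixed_log10_f_inf is not None,
                  n_points=int(T.size), rms_residual=rms, ok=ok, message=msg)


def _tg_denominator(fit: VFTFit) -> float:
    c = 2.0 + math.log10(2.0 * math.pi) + fit.log10_f_inf
    if c <= 0:
        raise ValueError("2 + log10(2*pi*f_inf) <= 0: Tg undefined for this f_inf")
    return c


def tg_kelvin_from_vft(fit: VFTFit) -> float:
    """Temperature (K) where the VFT law reaches f = 1/(2*pi*100 s)."""
    return fit.T0 + fit.B / (LN10 * _tg_denominator(fit))


def tg_from_vft(fit: VFTFit) -> float:
    """Dielectric glass-transition temperature in degrees Celsius."""
    return tg_kelvin_from_vft(fit) - 273.15


def fragility_from_vft(fit: VFTFit) -> float:
    """Dynamic fragility index m (steepness of log tau vs Tg/T at Tg)."""
    c = _tg_denominator(fit)
    return c * (1.0 + LN10 * c * fit.T0 / fit.B)


def dielectric_tg_crossing(
    map_group,
    vft_fit: Optional[VFTFit] = None,
    max_extrapolation_K: float = 150.0,
) -> float:
    """Temperature (deg C) where a map group crosses log10 f0 = -2.8.

    If the points bracket the -2.8 level the crossing is read by linear
    interpolation of log10 f0 versus 1/T between the bracketing pair.
    Otherwise a VFT law (fitted here unless supplied) is extrapolated; the
    crossing is rejected when it falls outside (T0 + 1 K, max(T) + 100 K) or
    more than ``max_extrapolation_K`` below the coldest point.
    """
    T, logf = _as_tf_arrays(map_group)
    order = np.argsort(T)
    T, logf = T[order], logf[order]
    level = LOG_F_TG_ROUNDED

    below = logf < level
    if below.any() and (~below).any():
        # log f0 increases with T for slowing-on-cooling processes
        for i in range(T.size - 1):
            lo, hi = logf[i], logf[i + 1]
            if (lo - level) * (hi - level) <= 0:
                x1, x2 = 1.0 / T[i], 1.0 / T[i + 1]
                x = x1 + (level - lo) * (x2 - x1) / (hi - lo)
                return 1.0 / x - 273.15

    if vft_fit is None:
        if T.size < 3:
            raise NoCrossingError("no bracketing points and too few points for a VFT fit")
        vft_fit = fit_vft(np.column_stack([T, 10.0**logf]))
        if not vft_fit.ok:
            raise NoCrossingError(f"VFT fit failed: {vft_fit.message}")
    t_cross = vft_fit.T0 + vft_fit.B / (LN10 * (vft_fit.log10_f_inf - level))
    if not (vft_fit.T0 + 1.0 < t_cross < float(np.max(T)) + 100.0):
        raise NoCrossingError(f"crossing {t_cross:.1f} K outside the extrapolation guard")
    if t_cross < float(np.min(T)) - max_extrapolation_K:
        raise NoCrossingError(
            f"crossing {t_cross:.1f} K is more than {max_extrapolation_K:.0f} K below the data"
        )
    return t_cross - 273.15
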