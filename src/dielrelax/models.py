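"""Forward models for broadband dielectric spectra.

Complex permittivity is carried with the loss convention ``eps* = eps' - i*eps''``
with ``eps'' >= 0``; all public containers store the loss as a positive number.
Frequencies are in Hz throughout, temperatures in kelvin inside containers
(degrees Celsius only at the I/O boundary).
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: vacuum permittivity, F/m (CODATA)
EPS0 = 8.8541878128e-12

__all__ = [
    "EPS0",
    "HNProcess",
    "ConductivityTerm",
    "CompositeDielectricModel",
    "IsothermalSpectrum",
    "hn_term",
    "conductivity_term",
    "composite_eps",
    "tan_delta",
    "hn_loss_peak_frequency",
    "tan_delta_plateau",
]


def _check_frequency(f):
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0.0) or not np.all(np.isfinite(f)):
        raise ValueError("frequencies must be positive and finite")
    return f


@dataclass
class HNProcess:
    """One Havriliak-Negami relaxation term.

    Parameters
    ----------
    delta_eps
        Dielectric strength (relaxed minus unrelaxed permittivity), > 0.
    f0
        Relaxation frequency in Hz, > 0.
    a
        Width (symmetric-broadening) exponent, 0 < a <= 1.
    b
        Asymmetry exponent, 0 < b <= 1.  ``a = b = 1`` is the Debye limit,
        ``b = 1`` the Cole-Cole family.
    label
        Free-text tag for the process ("beta", "alpha_a", "slow", "EP", ...).
    """

    delta_eps: float
    f0: float
    a: float = 1.0
    b: float = 1.0
    label: str = ""

    def __post_init__(self):
        if not self.delta_eps > 0:
            raise ValueError(f"delta_eps must be > 0, got {self.delta_eps}")
        if not self.f0 > 0:
            raise ValueError(f"f0 must be > 0, got {self.f0}")
        if not 0 < self.a <= 1:
            raise ValueError(f"width exponent a must be in (0, 1], got {self.a}")
        if not 0 < self.b <= 1:
            raise ValueError(f"symmetry exponent b must be in (0, 1], got {self.b}")


@dataclass
class ConductivityTerm:
    """Fractional-exponent conductivity contribution sigma0 / (eps0 * (i*2*pi*f)^n).

    ``n = 1`` is ohmic (pure dc loss); fractional n describes dispersive
    (hopping) transport in disordered solids.  sigma0 is in S/m.
    """

    sigma0: float
    n: float = 1.0

    def __post_init__(self):
        if self.sigma0 < 0:
            raise ValueError(f"sigma0 must be >= 0, got {self.sigma0}")
        if not 0 < self.n <= 1:
            raise ValueError(f"conductivity exponent n must be in (0, 1], got {self.n}")


def hn_term(process: HNProcess, f):
    """Complex permittivity contribution of a single HN process at frequency f (Hz).

    Returns delta_eps / (1 + (i f/f0)^a)^b on the principal branch, i.e. a
    complex number with non-negative real part and non-positive imaginary part
    (the loss is ``-imag``).
    """
    f = _check_frequency(f)
    # (i x)^a on the principal branch = x^a * exp(i a pi / 2) for x > 0
    x = (f / process.f0) ** process.a * cmath.exp(1j * math.pi * process.a / 2.0)
    return process.delta_eps / (1.0 + x) ** process.b


def conductivity_term(c: ConductivityTerm, f):
    """Complex permittivity contribution of the conductivity term at f (Hz).

    sigma0 / (eps0 * (i 2 pi f)^n), principal branch: both the real part
    (proportional to cos(n*pi/2)) and the loss (sin(n*pi/2)) scale as f^-n.
    """
    f = _check_frequency(f)
    mag = c.sigma0 / (EPS0 * (2.0 * math.pi * f) ** c.n)
    return mag * cmath.exp(-1j * math.pi * c.n / 2.0)


def hn_loss_peak_frequency(process: HNProcess) -> float:
    """Frequency of the loss maximum of an isolated HN term (closed form)."""
    a, b = process.a, process.b
    num = math.sin(a * math.pi / (2.0 + 2.0 * b))
    den = math.sin(a * b * math.pi / (2.0 + 2.0 * b))
    return process.f0 * (num / den) ** (1.0 / a)


def tan_delta_plateau(c: ConductivityTerm) -> float:
    """Low-frequency limit of tan(delta) for any model containing this term.

    For 0 < n < 1 the conductivity term dominates both eps' and eps'' as
    f -> 0 and tan(delta) tends to the constant tan(n*pi/2).  For n = 1 the
    real part of the term vanishes and the limit diverges.
    """
    if c.n >= 1.0:
        raise ValueError("n = 1 (ohmic): tan(delta) diverges at low frequency, no plateau")
    return math.tan(c.n * math.pi / 2.0)


@dataclass
class CompositeDielectricModel:
    """Unrelaxed permittivity + HN processes + optional conductivity term.

    ``eps(f)`` evaluates the full complex permittivity; ``tan_delta(f)`` the
    loss tangent eps''/eps', which is *not* a bare sum of per-process terms
    because the composite real part sits in the denominator.
    """

    eps_inf: float
    processes: list[HNProcess] = field(default_factory=list)
    conductivity: Optional[ConductivityTerm] = None

    def __post_init__(self):
        if not self.eps_inf >= 1.0:
            raise ValueError(f"eps_inf must be >= 1, got {self.eps_inf}")
        labels = [p.label for p in self.processes]
        if len(set(labels)) != len(labels):
            raise ValueError(f"process labels must be unique, got {labels}")

    def eps(self, f):
        return composite_eps(self, f)

    def eps_real(self, f):
        return np.real(composite_eps(self, f))

    def eps_imag(self, f):
        """Positive loss eps''(f)."""
        return -np.imag(composite_eps(self, f))

    def tan_delta(self, f):
        return tan_delta(self, f)

    # -- JSON round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "eps_inf": self.eps_inf,
            "processes": {
                p.label: {"delta_eps": p.delta_eps, "f0": p.f0, "a": p.a, "b": p.b}
                for p in self.processes
            },
            "process_order": [p.label for p in self.processes],
        }
        if self.conductivity is not None:
            d["conductivity"] = {"sigma0": self.conductivity.sigma0, "n": self.conductivity.n}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CompositeDielectricModel":
        order = d.get("process_order", list(d.get("processes", {})))
        procs = [HNProcess(label=lab, **d["processes"][lab]) for lab in order]
        cond = d.get("conductivity")
        return cls(
            eps_inf=d["eps_inf"],
            processes=procs,
            conductivity=ConductivityTerm(**cond) if cond else None,
        )


def composite_eps(model: CompositeDielectricModel, f):
    """Full complex permittivity eps*(f) = eps_inf + sum_j HN_j + conductivity."""
    f = _check_frequency(f)
    out = np.full(f.shape, model.eps_inf, dtype=complex) if f.ndim else complex(model.eps_inf)
    for p in model.processes:
        out = out + hn_term(p, f)
    if model.conductivity is not None and model.conductivity.sigma0 > 0:
        out = out + conductivity_term(model.conductivity, f)
    return out


def tan_delta(model: CompositeDielectricModel, f):
    """Loss tangent eps''/eps' of the composite model.

    Invariant under rescaling all of (eps_inf, delta_eps_j, sigma0) by one
    positive factor, which is exactly the effect of a sample-thickness change
    on the apparent permittivity.
    """
    e = composite_eps(model, f)
    re = np.real(e)
    if np.any(np.asarray(re) <= 0):
        raise ValueError("composite eps'(f) <= 0: unphysical parameter set for tan(delta)")
    return -np.imag(e) / re


@dataclass
class IsothermalSpectrum:
    """One temperature's frequency sweep of measured permittivity.

    ``temperature`` is in kelvin, ``frequencies`` strictly increasing in Hz,
    ``eps_imag`` stored as a positive loss.  ``meta`` carries sample id,
    annealing temperature and ramp index.
    """

    temperature: float
    frequencies: np.ndarray
    eps_real: np.ndarray
    eps_imag: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.eps_real = np.asarray(self.eps_real, dtype=float)
        self.eps_imag = np.asarray(self.eps_imag, dtype=float)
        n = self.frequencies.size
        if self.eps_real.size != n or self.eps_imag.size != n:
            raise ValueError("frequency and permittivity arrays must have equal length")
        if n and np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(self.eps_real <= 0):
            raise ValueError("eps' must be positive everywhere")
        if np.any(self.eps_imag < 0):
            raise ValueError("eps'' is stored as a positive loss")

    @property
    def tan_delta(self) -> np.ndarray:
        return self.eps_imag / self.eps_real

    @property
    def temperature_C(self) -> float:
        return self.temperature - 273.15
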