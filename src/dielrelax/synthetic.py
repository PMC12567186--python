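"""Synthetic broadband dielectric datasets with known ground truth.

The generator emulates the structure of solution-cast polysaccharide-film
measurements: 0.1 Hz - 1 MHz log-frequency sweeps at 5 or 10 K steps from
about -100 degC upward, up to several simultaneous relaxation processes with
Arrhenius or VFT temperature laws, a fractional-exponent conductivity term
with a two-regime temperature dependence, multiplicative measurement noise,
and a thickness-drift factor that rescales apparent eps' and eps'' equally
(so tan(delta) is untouched by it).

Preset temperature-law parameters follow published relaxation-map fits for
neutralized (A90) and non-neutralized (A0) chitosan films; dielectric
strengths, shape exponents, noise and conductivity magnitudes are package
choices (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .io import SpectraDataset
from .models import (
    CompositeDielectricModel,
    ConductivityTerm,
    HNProcess,
    IsothermalSpectrum,
)
from .relaxation import LN10, R_GAS, MapEntry, RelaxationMap

__all__ = [
    "ProcessLaw",
    "ConductivityLaw",
    "SyntheticProtocol",
    "generate_dataset",
    "preset",
    "PRESET_NAMES",
    "truth_relaxation_map",
    "conductivity_series_points",
]

#: processes are dropped from an isotherm once their relaxation frequency
#: falls this far below the decade scale of any measurement (frozen out)
_LOG_F0_FLOOR = -20.0


@dataclass
class ProcessLaw:
    """Temperature law and shape of one generated relaxation process.

    ``kind`` is "arrhenius" (params log10_f_inf, Ea kJ/mol) or "vft"
    (params log10_f_inf, B K, T0 K).  ``delta_eps`` is either a constant or
    a (c0, c1) pair for a linear-in-T strength c0 + c1*T.
    """

    label: str
    kind: str
    log10_f_inf: float
    Ea: Optional[float] = None  # kJ/mol, arrhenius
    B: Optional[float] = None  # K, vft
    T0: Optional[float] = None  # K, vft
    delta_eps: float | tuple[float, float] = 1.0
    a: float = 0.8
    b: float = 1.0

    def __post_init__(self):
        if self.kind == "arrhenius":
            if self.Ea is None or self.Ea < 0:
                raise ValueError(f"{self.label}: Arrhenius law needs Ea >= 0 kJ/mol")
        elif self.kind == "vft":
            if self.B is None or self.B <= 0 or self.T0 is None or self.T0 < 0:
                raise ValueError(f"{self.label}: VFT law needs B > 0 K and T0 >= 0 K")
        else:
            raise ValueError(f"{self.label}: unknown law kind {self.kind!r}")

    def log10_f0_at(self, T: float) -> Optional[float]:
        """log10 relaxation frequency at T (K); None when frozen out."""
        if self.kind == "arrhenius":
            return self.log10_f_inf - self.Ea * 1e3 / (LN10 * R_GAS * T)
        if T <= self.T0 + 1.0:
            return None
        logf = self.log10_f_inf - self.B / (LN10 * (T - self.T0))
        return logf if logf >= _LOG_F0_FLOOR else None

    def delta_eps_at(self, T: float) -> float:
        if isinstance(self.delta_eps, tuple):
            c0, c1 = self.delta_eps
            return c0 + c1 * T
        return float(self.delta_eps)


@dataclass
class ConductivityLaw:
    """Two-regime Arrhenius dc conductivity with a step in the exponent n.

    sigma0(T) is continuous at ``T_break`` (value ``sigma_at_break``) with
    activation energies Ea_low below and Ea_high above the break, in kJ/mol;
    n steps from n_low to n_high across the break.  A single-regime law is
    the special case Ea_low == Ea_high, n_low == n_high.
    """

    T_break: float
    sigma_at_break: float
    Ea_low: float = 20.0
    Ea_high: float = 70.0
    n_low: float = 0.35
    n_high: float = 0.9

    def sigma0_at(self, T: float) -> float:
        ea = self.Ea_low if T < self.T_break else self.Ea_high
        expo = -(ea * 1e3 / (LN10 * R_GAS)) * (1.0 / T - 1.0 / self.T_break)
        return self.sigma_at_break * 10.0**expo

    def n_at(self, T: float) -> float:
        return self.n_low if T < self.T_break else self.n_high


@dataclass
class SyntheticProtocol:
    """Full description of one synthetic measurement campaign."""

    processes: list[ProcessLaw]
    conductivity: Optional[ConductivityLaw] = None
    eps_inf: float = 4.0
    t_start_C: float = -100.0
    t_stop_C: float = 140.0
    t_step_C: float = 10.0
    f_min: float = 0.1
    f_max: float = 1e6
    points_per_decade: int = 10
    noise_sd: float = 0.01
    thickness_drift: tuple[float, float] = (1.0, 1.0)  # g at coldest, g at hottest
    sample_id: str = "synthetic"

    def __post_init__(self):
        if self.t_step_C <= 0 or self.t_stop_C < self.t_start_C:
            raise ValueError("invalid temperature grid")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if min(self.thickness_drift) <= 0:
            raise ValueError("thickness-drift factor must stay positive")

    @property
    def temperatures_K(self) -> np.ndarray:
        n = int(round((self.t_stop_C - self.t_start_C) / self.t_step_C)) + 1
        return self.t_start_C + self.t_step_C * np.arange(n) + 273.15

    @property
    def frequencies(self) -> np.ndarray:
        decades = math.log10(self.f_max / self.f_min)
        n = int(round(decades * self.points_per_decade)) + 1
        return self.f_min * 10.0 ** (np.linspace(0.0, decades, n))

    def drift_at(self, T: float) -> float:
        g0, g1 = self.thickness_drift
        tk = self.temperatures_K
        if tk[-1] == tk[0]:
            return g0
        x = (T - tk[0]) / (tk[-1] - tk[0])
        return g0 + (g1 - g0) * float(np.clip(x, 0.0, 1.0))


def model_at_temperature(protocol: SyntheticProtocol, T: float) -> tuple[CompositeDielectricModel, dict]:
    """Composite model and exact generating parameters at one temperature."""
    procs = []
    truth_p = {}
    for law in protocol.processes:
        logf = law.log10_f0_at(T)
        deps = law.delta_eps_at(T)
        if logf is None or deps < 1e-2:  # frozen out or switched off
            continue
        p = HNProcess(
            delta_eps=deps, f0=10.0**logf, a=law.a, b=law.b, label=law.label
        )
        procs.append(p)
        truth_p[law.label] = {"delta_eps": p.delta_eps, "f0": p.f0, "a": p.a, "b": p.b}
    cond = None
    truth = {"temperature_K": float(T), "processes": truth_p, "g": protocol.drift_at(T)}
    if protocol.conductivity is not None:
        cond = ConductivityTerm(
            sigma0=protocol.conductivity.sigma0_at(T), n=protocol.conductivity.n_at(T)
        )
        truth["sigma0"] = cond.sigma0
        truth["n"] = cond.n
    model = CompositeDielectricModel(
        eps_inf=protocol.eps_inf, processes=procs, conductivity=cond
    )
    return model, truth


def generate_dataset(
    protocol: SyntheticProtocol, seed: Optional[int] = 0
) -> tuple[SpectraDataset, dict]:
    """Generate spectra plus a ground-truth record; deterministic per seed."""
    rng = np.random.default_rng(seed)
    f = protocol.frequencies
    spectra = []
    per_t = []
    for T in protocol.temperatures_K:
        model, truth = model_at_temperature(protocol, T)
        eps = model.eps(f)
        g = truth["g"]
        re = np.real(eps) * g
        im = -np.imag(eps) * g
        if protocol.noise_sd > 0:
            re = re * rng.lognormal(0.0, protocol.noise_sd, size=f.size)
            im = im * rng.lognormal(0.0, protocol.noise_sd, size=f.size)
        spectra.append(
            IsothermalSpectrum(
                temperature=float(T),
                frequencies=f.copy(),
                eps_real=re,
                eps_imag=im,
                meta={"sample_id": protocol.sample_id, "ramp": 0},
            )
        )
        per_t.append(truth)
    ground_truth = {
        "eps_inf": protocol.eps_inf,
        "seed": seed,
        "laws": {law.label: asdict(law) for law in protocol.processes},
        "conductivity_law": asdict(protocol.conductivity) if protocol.conductivity else None,
        "per_temperature": per_t,
    }
    dataset = SpectraDataset(
        spectra=spectra,
        protocol={
            "t_step_C": protocol.t_step_C,
            "t_start_C": protocol.t_start_C,
            "t_stop_C": protocol.t_stop_C,
            "sample_id": protocol.sample_id,
        },
    )
    return dataset, ground_truth


def truth_relaxation_map(protocol: SyntheticProtocol) -> RelaxationMap:
    """Relaxation map of the generating laws on the protocol's temperature grid."""
    entries = []
    for T in protocol.temperatures_K:
        for law in protocol.processes:
            logf = law.log10_f0_at(T)
            if logf is not None and law.delta_eps_at(T) >= 1e-2:
                entries.append(MapEntry(law.label, float(T), 10.0**logf, "truth"))
    return RelaxationMap(entries=entries)


def conductivity_series_points(
    law: ConductivityLaw,
    temperatures_K,
    log_noise_sd: float = 0.0,
    seed: Optional[int] = 0,
):
    """(T, sigma0) samples of a conductivity law, optional lognormal scatter."""
    rng = np.random.default_rng(seed)
    T = np.asarray(temperatures_K, dtype=float)
    sig = np.array([law.sigma0_at(t) for t in T])
    if log_noise_sd > 0:
        sig = sig * 10.0 ** rng.normal(0.0, log_noise_sd, size=T.size)
    n = np.array([law.n_at(t) for t in T])
    return T, sig, n


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

# dielectric strengths / width exponents are package choices mimicking the
# relative peak sizes of measured chitosan spectra (secondary process weakest,
# interfacial and electrode polarization strongest); b = 1 throughout.
_SHAPES = {
    # widths follow the usual shape systematics of polymer dielectrics:
    # secondary relaxations are very broad, the structural process broad,
    # interfacial (MWS) and electrode polarization close to Debye
    "beta_f": dict(delta_eps=0.8, a=0.5),
    "beta": dict(delta_eps=1.0, a=0.45),
    "alpha_a": dict(delta_eps=10.0, a=0.55),
    "alpha_c": dict(delta_eps=2.0, a=0.6),
    "slow": dict(delta_eps=4.0, a=0.9),
    # electrode polarization: a charge layer across the whole sample gives an
    # apparent strength orders of magnitude above molecular processes, but
    # only once dc conduction is active -- emulated by a linear-in-T strength
    # that switches on near room temperature and reaches ~1.7e3 at the top
    # of the ramp
    "EP": dict(delta_eps=(-14.0 * 293.15, 14.0), a=0.95),
}


def _p(label, kind, *params):
    shape = _SHAPES[label]
    if kind == "arrhenius":
        return ProcessLaw(label, "arrhenius", params[0], Ea=params[1], **shape)
    return ProcessLaw(label, "vft", params[0], B=params[1], T0=params[2], **shape)


def _presets() -> dict[str, SyntheticProtocol]:
    return {
        # neutralized film, as produced (~10% residual water)
        "A90_no_annealing": SyntheticProtocol(
            processes=[
                _p("beta", "vft", 16.40, 5324.0, 25.93),
                _p("alpha_a", "vft", 10.03, 2529.0, 144.5),
                _p("slow", "arrhenius", 14.02, 68.91),
                _p("EP", "arrhenius", 2.60, 20.96),
            ],
            conductivity=ConductivityLaw(230.1, 1e-14, 20.0, 70.0, 0.35, 0.9),
            eps_inf=4.0,
            sample_id="A90_no_annealing",
        ),
        # neutralized film after annealing at 100 degC
        "A90_Ta100": SyntheticProtocol(
            processes=[
                _p("beta", "vft", 12.90, 3168.0, 70.75),
                _p("alpha_c", "arrhenius", 12.74, 51.66),
                _p("slow", "arrhenius", 11.68, 67.50),
                _p("EP", "arrhenius", -0.2, 5.46),
            ],
            conductivity=ConductivityLaw(240.0, 3e-15, 20.0, 70.0, 0.35, 0.9),
            eps_inf=4.0,
            t_stop_C=100.0,
            sample_id="A90_Ta100",
        ),
        # neutralized film after annealing at 140 degC
        "A90_Ta140": SyntheticProtocol(
            processes=[
                _p("beta", "vft", 12.0, 3160.0, 45.78),
                _p("alpha_a", "vft", 6.03, 933.7, 306.4),
                _p("alpha_c", "arrhenius", 12.7, 58.14),
                _p("slow", "arrhenius", 12.83, 88.94),
                _p("EP", "arrhenius", 0.599, 12.77),
            ],
            conductivity=ConductivityLaw(250.0, 1e-15, 20.0, 70.0, 0.35, 0.9),
            eps_inf=4.0,
            sample_id="A90_Ta140",
        ),
        # non-neutralized film, as produced (~12% residual water)
        "A0_no_annealing": SyntheticProtocol(
            processes=[
                _p("beta_f", "arrhenius", 9.04, 11.01),
                _p("beta", "arrhenius", 13.5, 48.54),
                _p("alpha_a", "vft", 7.72, 2340.8, 144.7),
                _p("slow", "arrhenius", 5.70, 29.93),
            ],
            conductivity=ConductivityLaw(241.35, 3e-14, 20.0, 70.0, 0.4, 0.95),
            eps_inf=4.0,
            sample_id="A0_no_annealing",
        ),
        # single noiseless Debye process, no conductivity (oracle fixture)
        "debye_single": SyntheticProtocol(
            processes=[
                ProcessLaw("debye", "arrhenius", 5.0, Ea=10.0, delta_eps=2.0, a=1.0, b=1.0)
            ],
            conductivity=None,
            eps_inf=3.0,
            t_start_C=-20.0,
            t_stop_C=40.0,
            t_step_C=10.0,
            noise_sd=0.0,
            sample_id="debye_single",
        ),
        # conductivity-only sample with the low/high activation-energy regimes
        "two_regime_conductivity": SyntheticProtocol(
            processes=[],
            conductivity=ConductivityLaw(230.0, 1e-12, 20.0, 70.0, 0.35, 0.95),
            eps_inf=4.0,
            t_start_C=-103.15,
            t_stop_C=16.85,
            t_step_C=5.0,
            sample_id="two_regime_conductivity",
        ),
    }


PRESET_NAMES = tuple(_presets().keys())


def preset(name: str) -> SyntheticProtocol:
    """A fully specified protocol by name; see PRESET_NAMES."""
    table = _presets()
    if name not in table:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(table)}")
    return table[name]
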