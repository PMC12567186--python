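"""Per-isotherm least-squares fitting of dielectric spectra.

The fitting protocol mirrors routine broadband-dielectric practice: the
unrelaxed permittivity eps_inf is read off the coldest spectrum at the
highest frequency; spectra are then fitted isotherm by isotherm (loss eps''
for a first pass, the loss tangent for the refined pass, since tan(delta)
is immune to sample-thickness drift); processes that leave the measurement
window on heating are kept in the model with their relaxation frequency
imposed from an Arrhenius extrapolation of their own lower-temperature fits.

Optimization is bounded trust-region least squares (via lmfit), with
relaxation frequencies, strengths and conductivity handled on a log10 scale,
peak-picking initialization and a small number of seeded jittered restarts.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import lmfit
import numpy as np
from scipy.signal import find_peaks

from .io import SpectraDataset
from .models import (
    EPS0,
    CompositeDielectricModel,
    ConductivityTerm,
    HNProcess,
    IsothermalSpectrum,
)
from .relaxation import ArrheniusFit, fit_arrhenius, fit_vft

__all__ = [
    "ProcessSpec",
    "FitConfig",
    "FitWindow",
    "FitPlan",
    "IsothermFitResult",
    "estimate_eps_inf",
    "fit_isotherm",
    "fix_process_frequency",
    "fit_dataset",
]

#: default parameter bounds (log10 space for strengths/frequencies/conductivity)
DEFAULT_BOUNDS = {
    "log_delta_eps": (-4.0, 4.0),
    "log_f0": (-6.0, 9.0),
    "a": (0.05, 1.0),
    "b": (0.05, 1.0),
    "log_sigma0": (-20.0, 2.0),
    "n": (0.05, 1.0),
}


@dataclass
class ProcessSpec:
    """Declarative description of one process in a fit configuration.

    ``a``/``b`` fixed to a value when given (b defaults to the b=1
    convention); ``f0_policy`` is "free", "fixed" (uses ``f0_value``), or
    "arrhenius"/"vft" (value imposed per temperature by extrapolating the
    named law fitted to the same process at lower temperatures).  ``init``
    optionally seeds initial values for the free parameters (keys
    delta_eps, f0, a, b).
    """

    label: str
    a: Optional[float] = None  # None -> free
    b: Optional[float] = 1.0  # None -> free; fixed by convention otherwise
    f0_policy: str = "free"
    f0_value: Optional[float] = None
    init: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.f0_policy not in ("free", "fixed", "arrhenius", "vft"):
            raise ValueError(f"unknown f0 policy {self.f0_policy!r}")
        if self.f0_policy == "fixed" and not self.f0_value:
            raise ValueError(f"process {self.label!r}: fixed f0 requires f0_value")


@dataclass
class FitConfig:
    """Configuration of one isotherm fit."""

    processes: list[ProcessSpec]
    include_conductivity: bool = True
    eps_inf: Optional[float] = None  # None -> taken from the spectrum's own high-f eps'
    representation: str = "tan_delta"  # or "eps_imag"
    #: keep processes in their configured speed order (fastest first) by
    #: parametrizing each next log f0 as the previous one minus a gap >= 0;
    #: prevents label swapping between shape-identical overlapping processes
    order_f0: bool = True
    #: "none": unweighted residuals in the linear scale of the fitted
    #: quantity; "relative": residuals divided by the data, the near-ML
    #: choice when measurement noise is multiplicative
    residual_weighting: str = "none"
    n_restarts: int = 6
    seed: int = 0
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    max_nfev: Optional[int] = None
    #: stop multi-starting once the residual norm falls below this fraction
    #: of the data norm (i.e. the fit is at the measurement noise floor)
    early_stop_rnorm: float = 0.02
    #: a later start displaces an earlier one only if it improves the
    #: residual norm by more than this relative margin; near-ties go to the
    #: earlier (continuation / data-driven) start, which damps hopping
    #: between noise-equivalent basins along a temperature series
    start_preference_rtol: float = 0.01
    unresolved_delta_eps: float = 1e-3
    unresolved_window_decades: float = 2.0

    def __post_init__(self):
        if not self.processes and not self.include_conductivity:
            raise ValueError("fit needs at least one process or a conductivity term")
        if self.representation not in ("tan_delta", "eps_imag"):
            raise ValueError(f"unknown representation {self.representation!r}")
        if self.residual_weighting not in ("none", "relative"):
            raise ValueError(f"unknown residual weighting {self.residual_weighting!r}")
        labels = [p.label for p in self.processes]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate process labels in config: {labels}")


@dataclass
class IsothermFitResult:
    temperature: float  # K
    model: CompositeDielectricModel
    residual_norm: float
    representation: str
    stderr: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    success: bool = True
    message: str = ""
    n_starts: int = 1


def estimate_eps_inf(dataset: SpectraDataset) -> float:
    """Unrelaxed permittivity: eps' at the coldest temperature, highest frequency."""
    if not dataset.spectra:
        raise ValueError("empty dataset")
    coldest = dataset.coldest()
    return float(coldest.eps_real[-1])


def fix_process_frequency(result_map: ArrheniusFit, T: float) -> float:
    """Relaxation frequency (Hz) extrapolated from an Arrhenius law at T (K)."""
    return float(result_map.frequency_at(T))


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _pick_peaks(spectrum: IsothermalSpectrum, representation: str):
    """Local maxima of the fitted quantity on the log-frequency grid."""
    y = spectrum.tan_delta if representation == "tan_delta" else spectrum.eps_imag
    logy = np.log10(np.clip(y, 1e-12, None))
    if logy.size >= 7:  # light smoothing against point noise
        kernel = np.ones(3) / 3.0
        logy = np.convolve(logy, kernel, mode="same")
    idx, _ = find_peaks(logy, prominence=0.02)
    order = np.argsort(y[idx])[::-1]  # tallest first
    return [(float(spectrum.frequencies[i]), float(y[i])) for i in np.asarray(idx)[order]]


def _initial_guesses(
    spectrum: IsothermalSpectrum,
    config: FitConfig,
    eps_inf: float,
    overrides: Optional[dict] = None,
    stacked: bool = False,
) -> dict:
    """Peak-picking initial values for every free parameter.

    ``overrides`` (label -> parameter dict) takes precedence over the spec's
    own ``init`` and is how temperature continuation seeds a fit from the
    previous isotherm.  Peaks detected in the fitted representation are
    assigned, most prominent first, to the free-frequency processes in their
    configured (fastest-first) order; peaks already accounted for by fixed or
    seeded frequencies are not handed out again.  Processes without a
    matching peak start just below the measurement window, where slow
    processes enter on heating.
    """
    overrides = overrides or {}
    f = spectrum.frequencies
    peaks = _pick_peaks(spectrum, config.representation)
    init: dict = {"processes": {}}

    def eff_init(spec):
        return {**spec.init, **overrides.get(spec.label, {})}

    known_logf = [
        math.log10(s.f0_value)
        for s in config.processes
        if s.f0_policy in ("fixed", "arrhenius", "vft") and s.f0_value
    ] + [
        math.log10(eff_init(s)["f0"])
        for s in config.processes
        if s.f0_policy == "free" and "f0" in eff_init(s)
    ]
    peaks = [
        (fp, hp)
        for fp, hp in peaks
        if all(abs(math.log10(fp) - lk) > 0.5 for lk in known_logf)
    ]

    need_f0 = [
        p for p in config.processes if p.f0_policy == "free" and "f0" not in eff_init(p)
    ]
    # keep the most prominent peaks, then hand them out fastest-first to the
    # configured processes (configs list processes in decreasing speed)
    top = sorted(peaks[: len(need_f0)], key=lambda t: -t[0])
    assigned = {}
    for spec, (fpk, hpk) in zip(need_f0, top):
        assigned[spec.label] = (fpk, hpk)
    # leftovers: either just below the window (processes entering on heating)
    # or, in the "stacked" variant, just below their faster neighbour (a
    # second process hiding under a merged peak)
    k = 0
    prev_logf = None
    for spec in need_f0:
        if spec.label in assigned:
            prev_logf = math.log10(assigned[spec.label][0])
            continue
        if stacked and prev_logf is not None:
            logf = prev_logf - 0.8
        else:
            k += 1
            logf = math.log10(float(f[0])) - 0.5 * k
        assigned[spec.label] = (10.0**logf, None)
        prev_logf = logf

    for spec in config.processes:
        ini = eff_init(spec)
        d = {}
        d["f0"] = ini.get("f0", assigned.get(spec.label, (None,))[0])
        height = assigned.get(spec.label, (None, None))[1] if spec.label in assigned else None
        if "delta_eps" in ini:
            d["delta_eps"] = ini["delta_eps"]
        elif height is not None:
            # Debye-like height: max eps'' ~ delta_eps / 2; tan(delta) peaks scale by eps'
            scale = 2.0
            if config.representation == "tan_delta":
                i = int(np.argmin(np.abs(f - d["f0"])))
                scale = 2.0 * float(spectrum.eps_real[i])
            d["delta_eps"] = max(height * scale, 1e-3)
        else:
            d["delta_eps"] = 1.0
        d["a"] = ini.get("a", 0.8)
        d["b"] = ini.get("b", 1.0)
        init["processes"][spec.label] = d

    if config.include_conductivity:
        # low-frequency tan(delta) plateau -> n; lowest-frequency loss -> sigma0
        td0 = float(np.median(spectrum.tan_delta[: max(3, f.size // 10)]))
        n0 = float(np.clip(2.0 / math.pi * math.atan(max(td0, 1e-3)), 0.1, 0.97))
        sig0 = float(spectrum.eps_imag[0]) * EPS0 * (2.0 * math.pi * float(f[0])) ** n0
        init["conductivity"] = {"sigma0": max(sig0 * 0.5, 1e-18), "n": n0}
    return init


# ---------------------------------------------------------------------------
# lmfit machinery
# ---------------------------------------------------------------------------

def _param_name(label: str, what: str) -> str:
    safe = "".join(ch if ch.isalnum() else "_" for ch in label)
    return f"p_{safe}__{what}"


def _build_params(config: FitConfig, init: dict, eps_inf: float) -> lmfit.Parameters:
    bounds = config.bounds
    params = lmfit.Parameters()
    prev_f0_name = None  # anchor of the speed-ordering chain
    for spec in config.processes:
        d = init["processes"][spec.label]
        lo, hi = bounds["log_delta_eps"]
        params.add(_param_name(spec.label, "log_deps"),
                   value=float(np.clip(math.log10(d["delta_eps"]), lo + 0.01, hi - 0.01)),
                   min=lo, max=hi)
        lo, hi = bounds["log_f0"]
        name = _param_name(spec.label, "log_f0")
        if spec.f0_policy in ("fixed", "arrhenius", "vft"):
            params.add(name, value=math.log10(spec.f0_value), vary=False)
            prev_f0_name = name
        elif config.order_f0 and prev_f0_name is not None:
            gap0 = float(params[prev_f0_name].value) - math.log10(d["f0"])
            params.add(_param_name(spec.label, "f0_gap"),
                       value=float(np.clip(gap0, 0.05, 24.0)), min=0.0, max=25.0)
            params.add(name, expr=f"{prev_f0_name} - {_param_name(spec.label, 'f0_gap')}")
            prev_f0_name = name
        else:
            params.add(name,
                       value=float(np.clip(math.log10(d["f0"]), lo + 0.01, hi - 0.01)),
                       min=lo, max=hi)
            prev_f0_name = name
        lo, hi = bounds["a"]
        if spec.a is None:
            params.add(_param_name(spec.label, "a"),
                       value=float(np.clip(d["a"], lo + 0.01, hi)), min=lo, max=hi)
        else:
            params.add(_param_name(spec.label, "a"), value=spec.a, vary=False)
        lo, hi = bounds["b"]
        if spec.b is None:
            params.add(_param_name(spec.label, "b"),
                       value=float(np.clip(d["b"], lo + 0.01, hi)), min=lo, max=hi)
        else:
            params.add(_param_name(spec.label, "b"), value=spec.b, vary=False)
    if config.include_conductivity:
        c = init["conductivity"]
        lo, hi = bounds["log_sigma0"]
        params.add("log_sigma0",
                   value=float(np.clip(math.log10(c["sigma0"]), lo + 0.01, hi - 0.01)),
                   min=lo, max=hi)
        lo, hi = bounds["n"]
        params.add("n_exp", value=float(np.clip(c["n"], lo + 0.01, hi)), min=lo, max=hi)
    params.add("eps_inf", value=eps_inf, vary=False)
    return params


def _model_from_params(params, config: FitConfig) -> CompositeDielectricModel:
    procs = []
    for spec in config.processes:
        procs.append(
            HNProcess(
                delta_eps=10.0 ** params[_param_name(spec.label, "log_deps")].value,
                f0=10.0 ** params[_param_name(spec.label, "log_f0")].value,
                a=params[_param_name(spec.label, "a")].value,
                b=params[_param_name(spec.label, "b")].value,
                label=spec.label,
            )
        )
    cond = None
    if config.include_conductivity:
        cond = ConductivityTerm(sigma0=10.0 ** params["log_sigma0"].value,
                                n=params["n_exp"].value)
    return CompositeDielectricModel(eps_inf=params["eps_inf"].value,
                                    processes=procs, conductivity=cond)


def _eval_representation(params, config: FitConfig, f: np.ndarray) -> np.ndarray:
    """Model curve in the fitted representation, vectorized over frequency."""
    re = np.full(f.shape, float(params["eps_inf"].value))
    im = np.zeros_like(f)  # positive loss
    for spec in config.processes:
        deps = 10.0 ** params[_param_name(spec.label, "log_deps")].value
        f0 = 10.0 ** params[_param_name(spec.label, "log_f0")].value
        a = params[_param_name(spec.label, "a")].value
        b = params[_param_name(spec.label, "b")].value
        x = (f / f0) ** a * np.exp(1j * math.pi * a / 2.0)
        term = deps / (1.0 + x) ** b
        re += term.real
        im -= term.imag
    if config.include_conductivity:
        sigma0 = 10.0 ** params["log_sigma0"].value
        n = params["n_exp"].value
        mag = sigma0 / (EPS0 * (2.0 * math.pi * f) ** n)
        re += mag * math.cos(math.pi * n / 2.0)
        im += mag * math.sin(math.pi * n / 2.0)
    if config.representation == "eps_imag":
        return im
    return im / re


def fit_isotherm(
    spectrum: IsothermalSpectrum,
    config: FitConfig,
    warm_start: Optional[dict] = None,
) -> IsothermFitResult:
    """Least-squares fit of one isothermal spectrum.

    Residuals are the unweighted difference between data and model in the
    linear scale of the fitted quantity (tan(delta) or eps''), evaluated at
    the measured frequencies.  ``warm_start`` optionally seeds parameters
    from a neighbouring isotherm; a purely data-driven start is always kept
    in the multi-start set alongside it, so a poor warm start cannot trap
    the whole temperature series.  The best of ``n_restarts`` seeded starts
    is returned; ties in residual norm break toward the earliest start, so
    results are deterministic for a given seed.
    """
    f = spectrum.frequencies
    data = spectrum.tan_delta if config.representation == "tan_delta" else spectrum.eps_imag
    n_free_expected = sum(
        (1 if p.f0_policy == "free" else 0) + 1 + (p.a is None) + (p.b is None)
        for p in config.processes
    ) + 2 * bool(config.include_conductivity)
    if f.size < 5 * max(n_free_expected, 1):
        warnings.warn(
            f"only {f.size} points for {n_free_expected} free parameters", stacklevel=2
        )

    eps_inf = config.eps_inf if config.eps_inf is not None else float(spectrum.eps_real[-1])
    families = [_initial_guesses(spectrum, config, eps_inf, overrides=warm_start)]
    if warm_start:
        families.append(_initial_guesses(spectrum, config, eps_inf))
    stacked = _initial_guesses(spectrum, config, eps_inf, stacked=True)
    if stacked not in families:
        families.append(stacked)
        # hybrid: intermediate leftovers stacked under their neighbour but the
        # slowest one kept below the window (e.g. electrode polarization)
        free_labels = [s.label for s in config.processes if s.f0_policy == "free"]
        if free_labels:
            hybrid = copy.deepcopy(stacked)
            last = free_labels[-1]
            plain = _initial_guesses(spectrum, config, eps_inf)
            hybrid["processes"][last] = plain["processes"][last]
            if hybrid not in families:
                families.append(hybrid)
    rng = np.random.default_rng(config.seed)

    if config.residual_weighting == "relative":
        scale = np.maximum(np.abs(data), 1e-12)
        floor = config.early_stop_rnorm * math.sqrt(f.size)
    else:
        scale = np.ones_like(data)
        floor = config.early_stop_rnorm * float(np.linalg.norm(data))

    def residual(params):
        return (_eval_representation(params, config, f) - data) / scale

    def jitter(base):
        trial = copy.deepcopy(base)
        for spec in config.processes:
            d = trial["processes"][spec.label]
            if spec.f0_policy == "free":
                d["f0"] *= 10.0 ** rng.normal(0.0, 0.4)
            d["delta_eps"] *= 10.0 ** rng.normal(0.0, 0.25)
            if spec.a is None:
                d["a"] = float(np.clip(d["a"] + rng.normal(0.0, 0.08), 0.1, 1.0))
        if config.include_conductivity:
            trial["conductivity"]["sigma0"] *= 10.0 ** rng.normal(0.0, 0.5)
        return trial

    n_starts = max(config.n_restarts, len(families))
    best = None
    messages = []
    for start in range(n_starts):
        fam = families[start % len(families)]
        trial = copy.deepcopy(fam) if start < len(families) else jitter(fam)
        params = _build_params(config, trial, eps_inf)
        minimizer = lmfit.Minimizer(residual, params)
        try:
            with warnings.catch_warnings():
                # near-degenerate covariances are expected for overlapping
                # processes; stderr simply comes back as None
                warnings.simplefilter("ignore", RuntimeWarning)
                out = minimizer.minimize(method="least_squares", max_nfev=config.max_nfev)
        except Exception as exc:  # keep going; a later start may converge
            messages.append(f"start {start}: {exc}")
            continue
        norm = float(np.sqrt(np.sum(np.asarray(out.residual) ** 2)))
        if best is None or norm < best[0] * (1.0 - config.start_preference_rtol):
            best = (norm, out, start)
        if not out.success:
            messages.append(f"start {start}: {out.message}")
        if best[0] <= floor:
            break  # at the noise floor; further starts cannot do better

    if best is None:
        model = _model_from_params(_build_params(config, init, eps_inf), config)
        return IsothermFitResult(
            temperature=spectrum.temperature, model=model, residual_norm=float("inf"),
            representation=config.representation, success=False,
            message="; ".join(messages) or "no start converged",
            n_starts=n_starts,
        )

    norm, out, _ = best
    model = _model_from_params(out.params, config)

    stderr = {}
    for spec in config.processes:
        s = {}
        p = out.params[_param_name(spec.label, "log_deps")]
        if p.stderr is not None:
            s["delta_eps"] = math.log(10.0) * 10.0**p.value * p.stderr
        p = out.params[_param_name(spec.label, "log_f0")]
        if (p.vary or p.expr) and p.stderr is not None:
            s["f0"] = math.log(10.0) * 10.0**p.value * p.stderr
        for nm in ("a", "b"):
            p = out.params[_param_name(spec.label, nm)]
            if p.vary and p.stderr is not None:
                s[nm] = p.stderr
        stderr[spec.label] = s

    provenance = {}
    flags = {}
    fmin, fmax = float(f[0]), float(f[-1])
    for spec, proc in zip(config.processes, model.processes):
        prov = {
            "delta_eps": "fit",
            "f0": {"free": "fit", "fixed": "fixed:user", "arrhenius": "fixed:arrhenius",
                   "vft": "fixed:vft"}[spec.f0_policy],
            "a": "fit" if spec.a is None else "fixed:user",
            "b": "fit" if spec.b is None else "fixed:convention",
        }
        provenance[spec.label] = prov
        off_window = (
            proc.f0 < fmin * 10.0 ** -config.unresolved_window_decades
            or proc.f0 > fmax * 10.0 ** config.unresolved_window_decades
        )
        if spec.f0_policy == "free" and (
            proc.delta_eps < config.unresolved_delta_eps or off_window
        ):
            flags[spec.label] = "unresolved"
        at_bound = []
        for nm in ("log_deps", "log_f0", "a", "b"):
            p = out.params[_param_name(spec.label, nm)]
            if p.vary and (
                abs(p.value - p.min) < 1e-8 or abs(p.value - p.max) < 1e-8
            ) and not (nm in ("a", "b") and abs(p.value - 1.0) < 1e-8):
                at_bound.append(nm)
        if at_bound and spec.label not in flags:
            flags[spec.label] = f"at_bound:{','.join(at_bound)}"
    provenance["eps_inf"] = "fixed:user" if config.eps_inf is not None else "fixed:estimated"

    return IsothermFitResult(
        temperature=spectrum.temperature,
        model=model,
        residual_norm=norm,
        representation=config.representation,
        stderr=stderr,
        provenance=provenance,
        flags=flags,
        success=bool(out.success),
        message="; ".join(messages),
        n_starts=n_starts,
    )


# ---------------------------------------------------------------------------
# dataset-level staged protocol
# ---------------------------------------------------------------------------

def _robust_law_fit(points, law: str):
    """Arrhenius or VFT fit with one round of gross-outlier rejection (>0.5 dec)."""
    fitter = fit_arrhenius if law == "arrhenius" else fit_vft
    nmin = 2 if law == "arrhenius" else 4
    fit = fitter(points)
    if len(points) > nmin:
        pts = np.asarray(points, dtype=float)
        resid = np.log10(pts[:, 1]) - fit.log10_frequency_at(pts[:, 0])
        keep = np.abs(resid) <= 0.5
        if keep.sum() >= nmin and keep.sum() < len(points):
            fit = fitter(pts[keep])
    return fit


@dataclass
class FitWindow:
    """A temperature window [t_min, t_max) (K) sharing one fit configuration."""

    t_min: float
    t_max: float
    config: FitConfig

    def contains(self, T: float) -> bool:
        return self.t_min <= T < self.t_max


@dataclass
class FitPlan:
    windows: list[FitWindow]
    eps_inf: Optional[float] = None  # None -> estimate from the dataset

    def window_for(self, T: float) -> Optional[FitWindow]:
        for w in self.windows:
            if w.contains(T):
                return w
        return None


def fit_dataset(dataset: SpectraDataset, plan: FitPlan) -> list[IsothermFitResult]:
    """Run the staged fitting protocol over a whole temperature series.

    Spectra are fitted coldest first.  Each isotherm's free parameters are
    warm-started from the previous result when the process carries over
    (temperature continuation).  Processes declared with the "arrhenius"
    frequency policy get their f0 imposed from an Arrhenius fit of the same
    process's free results at lower temperatures, with provenance recorded.
    """
    eps_inf = plan.eps_inf if plan.eps_inf is not None else estimate_eps_inf(dataset)
    results: list[IsothermFitResult] = []
    free_points: dict[str, list[tuple[float, float]]] = {}
    prev: Optional[IsothermFitResult] = None

    for spectrum in sorted(dataset.spectra, key=lambda s: s.temperature):
        window = plan.window_for(spectrum.temperature)
        if window is None:
            warnings.warn(
                f"no fit window covers T = {spectrum.temperature:.2f} K; spectrum skipped",
                stacklevel=2,
            )
            continue
        config = replace(window.config, eps_inf=eps_inf)
        specs = []
        for spec in config.processes:
            if spec.f0_policy in ("arrhenius", "vft"):
                pts = free_points.get(spec.label, [])
                nmin = 2 if spec.f0_policy == "arrhenius" else 3
                if len(pts) < nmin:
                    raise ValueError(
                        f"process {spec.label!r} needs >= {nmin} lower-temperature free "
                        f"fits before its frequency can be imposed from a "
                        f"{spec.f0_policy} law"
                    )
                law = _robust_law_fit(pts, spec.f0_policy)
                spec = replace(
                    spec, f0_value=fix_process_frequency(law, spectrum.temperature)
                )
            specs.append(spec)
        config = replace(config, processes=specs)

        warm = None
        if prev is not None:  # temperature continuation
            warm = {}
            for proc in prev.model.processes:
                if prev.flags.get(proc.label) == "unresolved":
                    continue
                w = {"delta_eps": proc.delta_eps, "a": proc.a, "b": proc.b, "f0": proc.f0}
                warm[proc.label] = w
        res = fit_isotherm(spectrum, config, warm_start=warm)
        results.append(res)
        prev = res
        for spec, proc in zip(config.processes, res.model.processes):
            if (
                spec.f0_policy == "free"
                and res.flags.get(spec.label) is None
                and res.success
            ):
                free_points.setdefault(spec.label, []).append(
                    (spectrum.temperature, proc.f0)
                )
    return results
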