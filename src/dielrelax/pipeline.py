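"""End-to-end orchestration: preset fit plans, law summaries, report assembly.

The staged analysis follows the measurement logic: estimate eps_inf from the
coldest spectrum, fit the low-temperature window where only the fastest
process lives, pre-fit its Arrhenius law, then carry the extrapolated
frequency as a fixed parameter into the crowded high-temperature windows.
Windows and process inventories per preset are inspection choices, mirroring
how practitioners decide process counts; they are configuration, not code.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import numpy as np

from .fitting import FitConfig, FitPlan, FitWindow, ProcessSpec, fit_dataset
from .io import SpectraDataset
from .relaxation import (
    RelaxationMap,
    MapEntry,
    build_relaxation_map,
    fit_arrhenius,
    fit_vft,
    fragility_from_vft,
    tg_from_vft,
)

__all__ = [
    "analysis_plan",
    "law_plan",
    "summarize_temperature_laws",
    "run_analysis",
    "map_from_report",
    "config_hash",
]


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _window(t_min_C, t_max_C, labels, fixed=None, representation="tan_delta",
            include_conductivity=True, seed=0, n_restarts=6):
    fixed = fixed or {}
    specs = [ProcessSpec(lab, f0_policy=fixed.get(lab, "free")) for lab in labels]
    cfg = FitConfig(
        processes=specs,
        include_conductivity=include_conductivity,
        representation=representation,
        residual_weighting="relative",
        seed=seed,
        n_restarts=n_restarts,
    )
    lo = -np.inf if t_min_C is None else t_min_C + 273.15
    hi = np.inf if t_max_C is None else t_max_C + 273.15
    return FitWindow(lo, hi, cfg)


# per-preset inspection choices: which processes are resolvable in which
# temperature range, and where a fast process must be pinned to its
# lower-temperature Arrhenius extrapolation. Labels are ordered fastest first.
_PLAN_TABLE = {
    "A90_no_annealing": [
        (None, -45.0, ["beta"], {}),
        # the interfacial (slow) process enters the window before the
        # structural one and is still the faster of the two here; beta is
        # already pinned so that the entering tail cannot split its peak
        (-45.0, -22.0, ["beta", "slow"], {"beta": "vft"}),
        # beta's peak has left the window: pin it to the VFT extrapolation
        # of its own lower-temperature fits (it is super-Arrhenius)
        (-22.0, 25.0, ["beta", "alpha_a", "slow"], {"beta": "vft"}),
        (25.0, None, ["beta", "alpha_a", "slow", "EP"], {"beta": "vft"}),
    ],
    "A90_Ta100": [
        (None, -73.0, ["beta"], {}),
        (-73.0, -3.0, ["beta", "alpha_c"], {}),
        (-3.0, 83.0, ["beta", "alpha_c", "slow"], {"beta": "vft"}),
        (83.0, None, ["beta", "alpha_c", "slow", "EP"], {"beta": "vft"}),
    ],
    "A90_Ta140": [
        (None, -51.0, ["beta"], {}),
        (-51.0, 2.0, ["beta", "alpha_c"], {}),
        (2.0, 63.0, ["beta", "alpha_c"], {"beta": "vft"}),
        (63.0, 91.0, ["beta", "alpha_c", "slow"], {"beta": "vft"}),
        (91.0, None, ["beta", "alpha_c", "alpha_a", "slow"], {"beta": "vft"}),
    ],
    "A0_no_annealing": [
        (None, -84.0, ["beta_f", "beta"], {}),
        (-84.0, -39.0, ["beta_f", "beta"], {"beta_f": "arrhenius"}),
        (-39.0, -11.0, ["beta_f", "beta", "slow"], {"beta_f": "arrhenius"}),
        (-11.0, 66.0, ["beta_f", "beta", "alpha_a", "slow"], {"beta_f": "arrhenius"}),
        (66.0, None, ["beta_f", "beta", "alpha_a", "slow"],
         {"beta_f": "arrhenius", "beta": "arrhenius"}),
    ],
}

#: which temperature law summarizes each labelled process, per preset
_LAW_TABLE = {
    "A90_no_annealing": {"beta": "vft", "alpha_a": "vft", "slow": "arrhenius", "EP": "arrhenius"},
    "A90_Ta100": {"beta": "vft", "alpha_c": "arrhenius", "slow": "arrhenius", "EP": "arrhenius"},
    "A90_Ta140": {"beta": "vft", "alpha_c": "arrhenius", "alpha_a": "vft", "slow": "arrhenius"},
    "A0_no_annealing": {"beta_f": "arrhenius", "beta": "arrhenius", "alpha_a": "vft",
                        "slow": "arrhenius"},
    "debye_single": {"debye": "arrhenius"},
    "two_regime_conductivity": {},
}


def analysis_plan(name: str, representation: str = "tan_delta", seed: int = 0) -> FitPlan:
    """The staged fit plan shipped for a synthetic preset."""
    if name == "debye_single":
        cfg = FitConfig(
            processes=[ProcessSpec("debye")],
            include_conductivity=False,
            representation=representation,
            seed=seed,
        )
        return FitPlan(windows=[FitWindow(-np.inf, np.inf, cfg)])
    if name == "two_regime_conductivity":
        cfg = FitConfig(
            processes=[], include_conductivity=True, representation=representation, seed=seed
        )
        return FitPlan(windows=[FitWindow(-np.inf, np.inf, cfg)])
    if name not in _PLAN_TABLE:
        raise KeyError(f"no analysis plan for preset {name!r}")
    windows = [
        _window(lo, hi, labels, fixed, representation=representation, seed=seed)
        for lo, hi, labels, fixed in _PLAN_TABLE[name]
    ]
    return FitPlan(windows=windows)


def law_plan(name: str) -> dict[str, str]:
    if name not in _LAW_TABLE:
        raise KeyError(f"no law plan for preset {name!r}")
    return dict(_LAW_TABLE[name])


def summarize_temperature_laws(
    rmap: RelaxationMap,
    laws: dict[str, str],
    fixed_f_inf: Optional[dict[str, float]] = None,
) -> list[dict]:
    """Fit the declared temperature law to each map group.

    Returns one row per process with the law parameters and, for VFT groups,
    the derived glass-transition temperature (degC) and fragility index.
    Rows mirror the usual relaxation-summary table: label, law, log f_inf,
    B, T0, Tg, m, Ea.
    """
    fixed_f_inf = fixed_f_inf or {}
    rows = []
    for label in rmap.labels:
        law = laws.get(label, "arrhenius")
        pts = rmap.group(label, free_only=True)
        row = {"label": label, "law": law, "n_points": len(pts),
               "log10_f_inf": None, "B_K": None, "T0_K": None,
               "Tg_C": None, "fragility_m": None, "Ea_kJ_per_mol": None,
               "rms_log10f": None, "ok": True, "message": ""}
        try:
            if law == "vft":
                fit = fit_vft(pts, fixed_log10_f_inf=fixed_f_inf.get(label), robust=True)
                row.update(
                    log10_f_inf=fit.log10_f_inf, B_K=fit.B, T0_K=fit.T0,
                    rms_log10f=fit.rms_residual, ok=fit.ok, message=fit.message,
                )
                if fit.ok:
                    row["Tg_C"] = tg_from_vft(fit)
                    row["fragility_m"] = fragility_from_vft(fit)
            else:
                fit = fit_arrhenius(pts, robust=True)
                row.update(
                    log10_f_inf=fit.log10_f_inf, Ea_kJ_per_mol=fit.Ea,
                    rms_log10f=fit.rms_residual,
                )
        except ValueError as exc:
            row.update(ok=False, message=str(exc))
        rows.append(row)
    return rows


def run_analysis(
    dataset: SpectraDataset,
    plan: FitPlan,
    laws: dict[str, str],
    fixed_f_inf: Optional[dict[str, float]] = None,
):
    """fit_dataset -> relaxation map -> temperature-law summary."""
    results = fit_dataset(dataset, plan)
    rmap = build_relaxation_map(results)
    summary = summarize_temperature_laws(rmap, laws, fixed_f_inf=fixed_f_inf)
    return results, rmap, summary


def map_from_report(report: dict) -> RelaxationMap:
    """Rebuild a relaxation map from a fit-report JSON document."""
    entries = []
    for rec in report["results"]:
        for label in rec.get("process_order", []):
            if rec.get("flags", {}).get(label) == "unresolved":
                continue
            p = rec["processes"][label]
            prov = rec.get("provenance", {}).get(label, {}).get("f0", "fit")
            entries.append(MapEntry(label, rec["temperature_K"], p["f0"], prov))
    return RelaxationMap(entries=entries)
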