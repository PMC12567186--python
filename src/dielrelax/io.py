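"""Plain-text I/O: long-table spectra, JSON fit reports, relaxation-map CSV.

The long-table dialect has columns ``temperature_C, frequency_Hz, eps_real,
eps_imag`` (comma- or tab-delimited, '#' comments ignored); temperatures are
degrees Celsius on disk and kelvin in memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .models import IsothermalSpectrum

REQUIRED_COLUMNS = ("temperature_C", "frequency_Hz", "eps_real", "eps_imag")
FIT_REPORT_SCHEMA = "dielrelax/fit-report/1"

__all__ = [
    "SpectraDataset",
    "ParseError",
    "read_spectra",
    "write_spectra",
    "write_fit_report",
    "read_fit_report",
    "write_relaxation_map_csv",
]


class ParseError(ValueError):
    pass


@dataclass
class SpectraDataset:
    """An acquisition-ordered collection of isothermal spectra for one sample."""

    spectra: list[IsothermalSpectrum] = field(default_factory=list)
    protocol: Optional[dict] = None

    def __post_init__(self):
        ids = {s.meta.get("sample_id") for s in self.spectra}
        if len(ids) > 1:
            raise ValueError(f"all spectra must share one sample id, got {ids}")

    def __len__(self):
        return len(self.spectra)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([s.temperature for s in self.spectra])

    def coldest(self) -> IsothermalSpectrum:
        return min(self.spectra, key=lambda s: s.temperature)


def read_spectra(path, dialect: str = "long-table") -> SpectraDataset:
    """Read a spectra file; one spectrum per distinct (temperature, ramp)."""
    if dialect != "long-table":
        raise ValueError(f"unknown dialect {dialect!r}; supported: 'long-table'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for col in REQUIRED_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0]) + 2  # 1-based + header line
            raise ParseError(f"{path}: non-numeric value in column {col!r} at line {row}")
        df[col] = vals
    if "ramp" not in df.columns:
        df["ramp"] = 0
    dup = df.duplicated(subset=["temperature_C", "frequency_Hz", "ramp"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ParseError(f"{path}: duplicate (temperature, frequency) pair at line {row}")

    spectra = []
    sample_id = None
    if "sample_id" in df.columns:
        sample_id = str(df["sample_id"].iloc[0])
    for (ramp, t_c), grp in df.groupby(["ramp", "temperature_C"], sort=True):
        grp = grp.sort_values("frequency_Hz")
        meta = {"ramp": int(ramp)}
        if sample_id is not None:
            meta["sample_id"] = sample_id
        spectra.append(
            IsothermalSpectrum(
                temperature=float(t_c) + 273.15,
                frequencies=grp["frequency_Hz"].to_numpy(),
                eps_real=grp["eps_real"].to_numpy(),
                eps_imag=grp["eps_imag"].to_numpy(),
                meta=meta,
            )
        )
    return SpectraDataset(spectra=spectra)


def write_spectra(dataset: SpectraDataset, path) -> Path:
    """Write a dataset in the long-table CSV dialect (full double precision)."""
    path = Path(path)
    frames = []
    for s in dataset.spectra:
        frames.append(
            pd.DataFrame(
                {
                    "temperature_C": np.repeat(s.temperature - 273.15, s.frequencies.size),
                    "frequency_Hz": s.frequencies,
                    "eps_real": s.eps_real,
                    "eps_imag": s.eps_imag,
                    "ramp": np.repeat(s.meta.get("ramp", 0), s.frequencies.size),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    return path


def _result_to_record(result) -> dict:
    model = result.model
    rec = {
        "temperature_K": result.temperature,
        "representation": result.representation,
        "residual_norm": result.residual_norm,
        "success": result.success,
        "eps_inf": model.eps_inf,
        "processes": model.to_dict()["processes"],
        "process_order": [p.label for p in model.processes],
        "provenance": result.provenance,
        "flags": result.flags,
        "stderr": result.stderr,
    }
    if model.conductivity is not None:
        rec["sigma0"] = model.conductivity.sigma0
        rec["n"] = model.conductivity.n
    return rec


def write_fit_report(results, path, extra: Optional[dict] = None) -> Path:
    """Serialize per-isotherm fit results to a schema-versioned JSON document."""
    doc = {"schema": FIT_REPORT_SCHEMA, "results": [_result_to_record(r) for r in results]}
    if extra:
        doc.update(extra)
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return path


def read_fit_report(path) -> dict:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != FIT_REPORT_SCHEMA:
        raise ParseError(f"{path}: unexpected fit-report schema {doc.get('schema')!r}")
    return doc


def write_relaxation_map_csv(rmap, path) -> Path:
    """Relaxation-map export: process_label, temperature_K, inv1000_over_T, log10_f0."""
    rows = [
        {
            "process_label": e.label,
            "temperature_K": e.temperature,
            "inv1000_over_T": 1000.0 / e.temperature,
            "log10_f0": np.log10(e.f0),
            "provenance": e.provenance,
        }
        for e in rmap.entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return path
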