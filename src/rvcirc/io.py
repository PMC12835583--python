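"""File formats and run configuration.

Waveforms travel as two-column CSV (``t`` plus ``P_mmHg`` or ``Q_mL_s``)
with an optional ``# T=<cycle length>`` comment line; clinical summaries as
a CSV table matching the packaged cohort fixture; parameters as flat JSON;
the effective run configuration as YAML written beside every output set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import WaveformSeries
from .initialize import ClinicalSummary

__all__ = [
    "read_waveform_csv",
    "write_waveform_csv",
    "read_clinical_csv",
    "load_reference_cohort",
    "RunConfig",
]

_KIND_HEADER = {"pressure": "P_mmHg", "flow": "Q_mL_s"}
_HEADER_KIND = {v: k for k, v in _KIND_HEADER.items()}


def write_waveform_csv(path, w: WaveformSeries) -> None:
    """Write ``t,<unit header>`` rows preceded by a ``# T=`` comment."""
    header = _KIND_HEADER[w.kind]
    with open(path, "w") as fh:
        fh.write(f"# T={w.T:.10g}\n")
        fh.write(f"t,{header}\n")
        for t, v in zip(w.t, w.v):
            fh.write(f"{t:.10g},{v:.10g}\n")


def read_waveform_csv(path) -> WaveformSeries:
    """Read a one-cycle waveform; unit/kind inferred from the value header.

    The cycle length comes from the ``# T=`` comment when present,
    otherwise it is inferred from the (uniform) sample spacing.  Validation
    failures report the offending line number.
    """
    path = Path(path)
    T = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    if i < len(lines) and lines[i].startswith("#"):
        txt = lines[i].lstrip("#").strip()
        if txt.startswith("T="):
            T = float(txt[2:])
        i += 1
    if i >= len(lines):
        raise ValueError(f"{path}: missing header line")
    header = [h.strip() for h in lines[i].split(",")]
    if len(header) != 2 or header[0] != "t" or header[1] not in _HEADER_KIND:
        raise ValueError(
            f"{path}:{i + 1}: expected header 't,P_mmHg' or 't,Q_mL_s', "
            f"got {lines[i].strip()!r}")
    kind = _HEADER_KIND[header[1]]
    t_vals, v_vals = [], []
    for ln, line in enumerate(lines[i + 1:], start=i + 2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected two columns")
        try:
            tv, vv = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-numeric value") from exc
        if not (np.isfinite(tv) and np.isfinite(vv)):
            raise ValueError(f"{path}:{ln}: non-finite value")
        if t_vals and tv <= t_vals[-1]:
            raise ValueError(f"{path}:{ln}: time not strictly increasing")
        t_vals.append(tv)
        v_vals.append(vv)
    t = np.asarray(t_vals)
    if T is None:
        if len(t) < 2:
            raise ValueError(f"{path}: too few samples to infer cycle length")
        T = float(t[-1] + (t[-1] - t[0]) / (len(t) - 1))
    return WaveformSeries(t=t, v=np.asarray(v_vals), kind=kind, T=T)


_REQUIRED_CLINICAL = ("subject", "cohort", "HR", "CO", "PAWP", "mPAP")
_OPTIONAL_CLINICAL = ("sex", "age", "RAP", "sPAP", "dPAP", "EDV", "ESV")


def read_clinical_csv(path) -> list[ClinicalSummary]:
    """Read a clinical-summary table into typed records.

    Required columns: subject, cohort, HR, CO, PAWP, mPAP; optional:
    sex, age, RAP, sPAP, dPAP, EDV, ESV.  Malformed numeric fields are
    reported with their row number.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_CLINICAL if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for idx, row in df.iterrows():
        kwargs = {}
        for col in ("HR", "CO", "PAWP", "mPAP", "RAP", "sPAP", "dPAP",
                    "EDV", "ESV", "age"):
            if col in df.columns and pd.notna(row[col]):
                try:
                    kwargs[col] = float(row[col])
                except (TypeError, ValueError) as exc:
                    raise ValueError(
                        f"{path}: row {idx + 2}: malformed {col}="
                        f"{row[col]!r}") from exc
        try:
            out.append(ClinicalSummary(
                subject=str(row["subject"]), phenotype=str(row["cohort"]),
                sex=str(row.get("sex", "")), **kwargs))
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx + 2}: {exc}") from exc
    return out


def load_reference_cohort() -> list[ClinicalSummary]:
    """The packaged 25-subject clinical-hemodynamics fixture."""
    with resources.as_file(
            resources.files("rvcirc.data").joinpath("table1.csv")) as p:
        return read_clinical_csv(p)


@dataclass
class RunConfig:
    """Effective settings of a pipeline run; serialized beside outputs."""

    n_cycles: int = 40
    n_out: int = 200
    rtol: float = 1e-6
    atol: float = 1e-6
    calibration_Nt: int = 100
    n_starts: int = 20
    seed: int = 0
    morris_r: int = 20
    morris_levels: int = 8
    morris_scale_range: tuple = (0.8, 1.25)
    bounds_lo_frac: float = 0.01
    bounds_hi_frac: float = 6.0
    noise: dict = field(default_factory=lambda: {
        "pressure": {"multiplicative_sd": 0.05, "additive_sd": 1.0,
                     "phase_jitter": 0.0},
        "flow": {"multiplicative_sd": 0.10, "additive_sd": 5.0,
                 "phase_jitter": 0.02},
    })

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(asdict(self))), fh,
                           sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "morris_scale_range" in d:
            d["morris_scale_range"] = tuple(d["morris_scale_range"])
        return cls(**d)
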