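"""Map routine clinical hemodynamics to baseline model parameters and bounds.

A patient's right-heart-catheterization summary (heart rate, cardiac output,
PAWP, mean/systolic/diastolic PA pressures, mean RA pressure, optional RV
volumes) determines every baseline parameter of the circulation model through
simple algebraic relations: Ohm-analog resistances from mean pressure drops
over cardiac output, compliances from unstressed volume over mean pressure,
and elastance extremes from RV pressure/volume ratios.  The baselines seed
the waveform calibration, which refines the influential subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, asdict
from typing import Sequence

import numpy as np

from .model import ModelParameters, INFLUENTIAL_ORDER

__all__ = [
    "ClinicalSummary",
    "PressureEstimates",
    "ParameterBounds",
    "PHENOTYPES",
    "derive_pressure_estimates",
    "build_initial_parameters",
    "build_bounds",
]

log = logging.getLogger(__name__)

#: Canonical phenotype labels.
PHENOTYPES = ("Pre-capillary", "Ipc-PH", "Cpc-PH", "No PH")

_PHENOTYPE_ALIASES = {
    "pre-cap": "Pre-capillary", "pre-capillary": "Pre-capillary",
    "precap": "Pre-capillary", "pre-capillary ph": "Pre-capillary",
    "ipc-ph": "Ipc-PH", "ipc": "Ipc-PH",
    "cpc-ph": "Cpc-PH", "cpc": "Cpc-PH",
    "no ph": "No PH", "noph": "No PH", "none": "No PH",
}

#: Default mean RA pressure (mmHg) when not measured.  Kept low-normal
#: (slightly higher where pre-capillary disease is present): the tricuspid
#: baseline resistance scales with RAP minus the 2 mmHg diastolic-RV guess,
#: so a low default keeps the uncalibrated model's cardiac output consistent
#: with the measured value.  Configurable per record via ``RAP``.
DEFAULT_RAP = {
    "Pre-capillary": 3.2, "Cpc-PH": 3.2, "Ipc-PH": 3.0, "No PH": 3.0,
}

#: Default RV end-diastolic volume (mL) when echo volumes are unavailable.
DEFAULT_EDV = 120.0

#: dPAP/mPAP ratio used to impute systolic/diastolic PA pressures from mPAP
#: alone, inverting the mPAP = (2·dPAP + sPAP)/3 estimate.
DEFAULT_DPAP_RATIO = 0.6

#: Floor for derived resistances (mmHg·s/mL); keeps multiplicative bounds
#: well-posed when a pressure-drop formula degenerates.
RESISTANCE_FLOOR = 1e-4


def normalize_phenotype(label: str) -> str:
    key = str(label).strip().lower()
    if key in _PHENOTYPE_ALIASES:
        return _PHENOTYPE_ALIASES[key]
    for ph in PHENOTYPES:
        if key == ph.lower():
            return ph
    raise ValueError(f"unknown phenotype label: {label!r}")


@dataclass
class ClinicalSummary:
    """One patient's routine hemodynamic scalars.

    HR in beats/min, CO in L/min, pressures in mmHg, volumes in mL.
    Optional fields default to None and are imputed where a formula
    requires them.
    """

    HR: float
    CO: float
    PAWP: float
    mPAP: float
    subject: str = ""
    phenotype: str = ""
    sex: str = ""
    age: float | None = None
    RAP: float | None = None
    sPAP: float | None = None
    dPAP: float | None = None
    EDV: float | None = None
    ESV: float | None = None

    def __post_init__(self):
        if not self.HR > 0:
            raise ValueError(f"HR must be positive, got {self.HR}")
        if not self.CO > 0:
            raise ValueError(f"CO must be positive, got {self.CO}")
        if self.PAWP < 0:
            raise ValueError(f"PAWP must be non-negative, got {self.PAWP}")
        if self.phenotype:
            self.phenotype = normalize_phenotype(self.phenotype)
        if self.sPAP is not None and self.dPAP is not None:
            if not (self.dPAP < self.mPAP < self.sPAP):
                raise ValueError(
                    f"require dPAP < mPAP < sPAP, got {self.dPAP}, "
                    f"{self.mPAP}, {self.sPAP}")

    # -- unit helpers ---------------------------------------------------
    @property
    def CO_mls(self) -> float:
        """Cardiac output in mL/s."""
        return self.CO * 1000.0 / 60.0

    @property
    def SV(self) -> float:
        """Stroke volume, mL/beat."""
        return self.CO * 1000.0 / self.HR

    @property
    def T(self) -> float:
        """Cardiac cycle length, s."""
        return 60.0 / self.HR

    def imputed(self, dpap_ratio: float = DEFAULT_DPAP_RATIO) -> "ClinicalSummary":
        """Fill missing optional fields with documented defaults.

        sPAP/dPAP are imputed from mPAP with a fixed pulse-pressure ratio
        chosen so the (2·dPAP + sPAP)/3 estimate returns mPAP exactly; RAP
        defaults by phenotype; EDV defaults to a population-typical value
        and ESV to EDV − SV.
        """
        c = replace(self)
        if c.dPAP is None or c.sPAP is None:
            c.dPAP = dpap_ratio * c.mPAP
            c.sPAP = 3.0 * c.mPAP - 2.0 * c.dPAP
        if c.RAP is None:
            ph = c.phenotype or "No PH"
            c.RAP = DEFAULT_RAP[normalize_phenotype(ph)]
            log.debug("imputed RAP=%.1f for %s", c.RAP, c.subject or "patient")
        if c.EDV is None:
            # keep a plausible end-systolic reserve for high-output patients
            c.EDV = max(DEFAULT_EDV, c.SV + 30.0)
        if c.ESV is None:
            c.ESV = max(c.EDV - c.SV, 5.0)
        return c

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PressureEstimates:
    """Compartment pressure estimates derived from the clinical summary (mmHg)."""

    P_MeanRA: float
    P_SysRV: float
    P_DiaRV: float
    P_SysPA: float
    P_DiaPA: float
    P_MeanPA: float
    P_MeanPC: float
    P_MeanPV: float
    P_MeanLA: float
    P_Grad: float

    def to_dict(self) -> dict:
        return asdict(self)


def derive_pressure_estimates(c: ClinicalSummary) -> PressureEstimates:
    """Estimate compartment pressures from a (possibly imputed) summary.

    Conventions: systolic RV pressure sits 0.5 mmHg above systolic PA
    pressure (a slight forward gradient across the pulmonic valve);
    diastolic RV pressure starts at 2 mmHg as an initial guess; mean PA
    pressure uses the (2·dPAP + sPAP)/3 estimate; mean LA pressure is the
    lower of PAWP and diastolic PA pressure; the mean PA→LA gradient is
    split 30%/30%/40% over the arterial, capillary and venous segments.
    """
    c = c.imputed()
    for name in ("sPAP", "dPAP", "RAP"):
        if getattr(c, name) is None:
            raise ValueError(f"missing required field {name}")
    P_SysPA = float(c.sPAP)
    P_DiaPA = float(c.dPAP)
    P_MeanPA = (2.0 * P_DiaPA + P_SysPA) / 3.0
    P_MeanLA = min(float(c.PAWP), P_DiaPA)
    P_Grad = P_MeanPA - P_MeanLA
    P_MeanPC = P_MeanPA - 0.3 * P_Grad
    P_MeanPV = P_MeanPC - 0.3 * P_Grad
    return PressureEstimates(
        P_MeanRA=float(c.RAP),
        P_SysRV=P_SysPA + 0.5,
        P_DiaRV=2.0,
        P_SysPA=P_SysPA,
        P_DiaPA=P_DiaPA,
        P_MeanPA=P_MeanPA,
        P_MeanPC=P_MeanPC,
        P_MeanPV=P_MeanPV,
        P_MeanLA=P_MeanLA,
        P_Grad=P_Grad,
    )


def build_initial_parameters(
    c: ClinicalSummary,
    pe: PressureEstimates | None = None,
    tmax_fraction: float = 0.2,
    tmin_fraction: float = 0.5,
) -> ModelParameters:
    """Baseline parameter vector from clinical scalars.

    Resistances are mean pressure drops over cardiac output; compliances are
    unstressed volume over mean pressure; unstressed volumes partition the
    stroke volume 23%/49%/28% across the arterial, capillary and venous
    beds; elastance extremes follow from RV pressures over RV volumes; the
    elastance timing defaults to fixed fractions of the cycle.
    """
    c = c.imputed()
    if pe is None:
        pe = derive_pressure_estimates(c)
    CO = c.CO_mls
    SV = c.SV

    def resistance(dp: float, what: str) -> float:
        r = dp / CO
        if r < RESISTANCE_FLOOR:
            log.warning("derived %s = %.3g mmHg·s/mL clamped to floor %.1g",
                        what, r, RESISTANCE_FLOOR)
            return RESISTANCE_FLOOR
        return r

    V0_PA = 0.23 * SV
    V0_PC = 0.49 * SV
    V0_PV = 0.28 * SV
    T = c.T
    return ModelParameters(
        Rval_T=resistance(pe.P_MeanRA - pe.P_DiaRV, "Rval_T"),
        Rval_P=resistance(pe.P_SysRV - pe.P_SysPA, "Rval_P"),
        R_PA=resistance(pe.P_MeanPA - pe.P_MeanPC, "R_PA"),
        R_PC=resistance(pe.P_MeanPC - pe.P_MeanPV, "R_PC"),
        R_PV=resistance(pe.P_MeanPV - pe.P_MeanLA, "R_PV"),
        C_PA=V0_PA / pe.P_MeanPA,
        C_PC=V0_PC / pe.P_MeanPC,
        C_PV=V0_PV / pe.P_MeanPV,
        Emax=pe.P_SysRV / c.ESV,
        Emin=pe.P_DiaRV / c.EDV,
        tmax=tmax_fraction * T,
        tmin=tmin_fraction * T,
        V0_PA=V0_PA, V0_PC=V0_PC, V0_PV=V0_PV,
        P_RA=pe.P_MeanRA,
        P_LA=pe.P_MeanLA,
        T=T,
    )


@dataclass(frozen=True)
class ParameterBounds:
    """Elementwise box bounds for a named parameter subvector."""

    names: tuple
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        if not np.all(self.lower < self.upper):
            raise ValueError("lower bounds must be strictly below upper bounds")

    def contains(self, theta: Sequence[float]) -> bool:
        th = np.asarray(theta, dtype=float)
        return bool(np.all(th >= self.lower) and np.all(th <= self.upper))

    def clip(self, theta: Sequence[float]) -> np.ndarray:
        return np.clip(np.asarray(theta, dtype=float), self.lower, self.upper)


#: Timing bounds as fractions of the cycle length.
TIMING_FRACTIONS = {"tmax": (0.05, 0.35), "tmin": (0.35, 0.70)}


def build_bounds(
    p: ModelParameters,
    names: Sequence[str] = INFLUENTIAL_ORDER,
    lo_frac: float = 0.01,
    hi_frac: float = 6.0,
) -> ParameterBounds:
    """Calibration bounds: [1%, 600%] of baseline for magnitudes; fixed
    cycle-fraction windows for the elastance timing parameters (which keeps
    tmax < tmin by construction of the disjoint intervals)."""
    lower, upper = [], []
    for n in names:
        if n in TIMING_FRACTIONS:
            # fixed cycle-fraction window, narrowed when the multiplicative
            # range around baseline is itself narrower (local screens)
            f0, f1 = TIMING_FRACTIONS[n]
            t0 = getattr(p, n)
            lo = max(f0 * p.T, lo_frac * t0)
            hi = min(f1 * p.T, hi_frac * t0)
            if not lo < hi:
                lo, hi = f0 * p.T, f1 * p.T
            lower.append(lo)
            upper.append(hi)
        else:
            v = getattr(p, n)
            if v == 0:
                raise ValueError(f"baseline {n} is zero; multiplicative bounds "
                                 "would collapse")
            lower.append(lo_frac * v)
            upper.append(hi_frac * v)
    return ParameterBounds(tuple(names), np.array(lower), np.array(upper))
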