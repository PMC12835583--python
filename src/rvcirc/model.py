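"""Forward simulation of the right-ventricle / pulmonary-circulation lumped model.

The circulation is reduced to four dynamic compartments — right ventricle (RV),
pulmonary arteries (PA), pulmonary capillaries (PC) and pulmonary veins (PV) —
bounded by constant right- and left-atrial pressure sources.  The RV is a
time-varying elastance chamber; each vascular compartment is a linearly
compliant Windkessel element; compartments are connected through constant
resistances, with the tricuspid and pulmonic valves acting as ideal diodes.

States are the four compartment volumes (mL); pressures are in mmHg, flows in
mL/s, time in s.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np
from scipy.integrate import odeint

__all__ = [
    "ModelParameters",
    "SimulationResult",
    "SimulationError",
    "elastance",
    "compartment_pressures",
    "junction_flows",
    "rhs",
    "simulate",
    "MMHG_ML_TO_J",
]

#: 1 mL·mmHg expressed in joules.
MMHG_ML_TO_J = 1.33322e-4

# Canonical ordering of the calibrated ("influential") parameter subvector.
INFLUENTIAL_ORDER = (
    "Rval_T", "R_PA", "R_PC", "R_PV", "C_PA", "Emax", "Emin", "tmax", "tmin",
)

# Full set screened by sensitivity analysis: all resistances, compliances and
# elastance (incl. timing) parameters.
SCREENED_ORDER = (
    "Rval_T", "Rval_P", "R_PA", "R_PC", "R_PV",
    "C_PA", "C_PC", "C_PV",
    "Emax", "Emin", "tmax", "tmin",
)


class SimulationError(RuntimeError):
    """Integration failure or non-physiological blow-up.

    Carries the offending parameter vector for diagnostics.
    """

    def __init__(self, message: str, params: "ModelParameters | None" = None):
        super().__init__(message)
        self.params = params


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter vector of the lumped circulation model.

    Resistances in mmHg·s/mL, compliances in mL/mmHg, elastances in mmHg/mL,
    volumes in mL, pressures in mmHg, times in s.
    """

    Rval_T: float      # tricuspid valve resistance
    Rval_P: float      # pulmonic valve resistance
    R_PA: float        # pulmonary arterial resistance
    R_PC: float        # pulmonary capillary resistance
    R_PV: float        # pulmonary venous resistance
    C_PA: float        # pulmonary arterial compliance
    C_PC: float        # pulmonary capillary compliance
    C_PV: float        # pulmonary venous compliance
    Emax: float        # peak RV elastance
    Emin: float        # diastolic RV elastance
    tmax: float        # time of peak elastance within the cycle
    tmin: float        # end of relaxation (diastolic plateau onset)
    V0_PA: float       # unstressed PA volume
    V0_PC: float       # unstressed PC volume
    V0_PV: float       # unstressed PV volume
    P_RA: float        # right atrial source pressure
    P_LA: float        # left atrial source pressure
    T: float           # cardiac cycle length
    V0_RV: float = 0.0  # RV volume at zero pressure

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("Rval_T", "Rval_P", "R_PA", "R_PC", "R_PV",
                     "C_PA", "C_PC", "C_PV", "Emax", "T"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        if not (0 < self.Emin < self.Emax):
            raise ValueError(
                f"require 0 < Emin < Emax, got Emin={self.Emin}, Emax={self.Emax}")
        if not (0 < self.tmax < self.tmin < self.T):
            raise ValueError(
                f"require 0 < tmax < tmin < T, got tmax={self.tmax}, "
                f"tmin={self.tmin}, T={self.T}")
        for name in ("V0_PA", "V0_PC", "V0_PV", "V0_RV"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("P_RA", "P_LA"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def unchecked(cls, **fields) -> "ModelParameters":
        """Construct without validation.

        Intended for exploratory parameter screens that sample hypercube
        corners where the physiological ordering constraints (e.g.
        Emin < Emax) may be violated; the model equations extend
        continuously to such points.  Still requires tmax < tmin < T.
        """
        obj = object.__new__(cls)
        d = {"V0_RV": 0.0}
        d.update(fields)
        for k, v in d.items():
            object.__setattr__(obj, k, float(v))
        if not (0 < obj.tmax < obj.tmin < obj.T):
            raise ValueError("require 0 < tmax < tmin < T")
        return obj

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    # -- theta helpers --------------------------------------------------
    def theta(self, names: Sequence[str] = INFLUENTIAL_ORDER) -> np.ndarray:
        """Extract a named parameter subvector as an array."""
        return np.array([getattr(self, n) for n in names], dtype=float)

    def with_theta(self, theta: Sequence[float],
                   names: Sequence[str] = INFLUENTIAL_ORDER) -> "ModelParameters":
        """Return a copy with the named subvector replaced."""
        return replace(self, **dict(zip(names, map(float, theta))))


def elastance(t, p: ModelParameters):
    """Time-varying RV elastance E(t), mmHg/mL.  Accepts scalar or array t.

    Piecewise raised cosine: rises from Emin at t=0 to Emax at t=tmax,
    relaxes back to Emin at t=tmin, and stays at the diastolic plateau Emin
    for the remainder of the cycle.  Continuous and T-periodic.
    """
    t = np.asarray(t, dtype=float) % p.T
    amp = 0.5 * (p.Emax - p.Emin)
    e = np.full_like(t, p.Emin)
    rising = t <= p.tmax
    falling = (t > p.tmax) & (t <= p.tmin)
    e = np.where(rising, p.Emin + amp * (1.0 - np.cos(np.pi * t / p.tmax)), e)
    e = np.where(
        falling,
        p.Emin + amp * (1.0 + np.cos(np.pi * (t - p.tmax) / (p.tmin - p.tmax))),
        e,
    )
    if e.ndim == 0:
        return float(e)
    return e


def _elastance_scalar(t, Emin, Emax, tmax, tmin, T):
    # scalar fast path used inside the ODE right-hand side
    t = t % T
    if t <= tmax:
        return Emin + 0.5 * (Emax - Emin) * (1.0 - math.cos(math.pi * t / tmax))
    if t <= tmin:
        return Emin + 0.5 * (Emax - Emin) * (
            1.0 + math.cos(math.pi * (t - tmax) / (tmin - tmax)))
    return Emin


def compartment_pressures(state, t, p: ModelParameters):
    """Pressures (P_RV, P_PA, P_PC, P_PV) from volumes; vectorized.

    P_RV = E(t)·(V_RV − V0_RV); vascular P_i = (V_i − V0_i)/C_i.
    """
    V_RV, V_PA, V_PC, V_PV = state
    P_RV = elastance(t, p) * (np.asarray(V_RV) - p.V0_RV)
    P_PA = (np.asarray(V_PA) - p.V0_PA) / p.C_PA
    P_PC = (np.asarray(V_PC) - p.V0_PC) / p.C_PC
    P_PV = (np.asarray(V_PV) - p.V0_PV) / p.C_PV
    return P_RV, P_PA, P_PC, P_PV


def junction_flows(pressures, p: ModelParameters):
    """Flows (Q_val_T, Q_val_P, Q_PA, Q_PC, Q_PV) from pressures; vectorized.

    Valve flows are diode-gated (non-negative); vascular segment flows are
    ungated and may reverse transiently.
    """
    P_RV, P_PA, P_PC, P_PV = pressures
    Q_val_T = np.maximum(0.0, (p.P_RA - np.asarray(P_RV)) / p.Rval_T)
    Q_val_P = np.maximum(0.0, (np.asarray(P_RV) - np.asarray(P_PA)) / p.Rval_P)
    Q_PA = (np.asarray(P_PA) - np.asarray(P_PC)) / p.R_PA
    Q_PC = (np.asarray(P_PC) - np.asarray(P_PV)) / p.R_PC
    Q_PV = (np.asarray(P_PV) - p.P_LA) / p.R_PV
    return Q_val_T, Q_val_P, Q_PA, Q_PC, Q_PV


def rhs(t, state, p: ModelParameters):
    """dV/dt for the four volume states: conservation of volume per compartment."""
    pres = compartment_pressures(state, t, p)
    Q_val_T, Q_val_P, Q_PA, Q_PC, Q_PV = junction_flows(pres, p)
    return np.array([
        Q_val_T - Q_val_P,
        Q_val_P - Q_PA,
        Q_PA - Q_PC,
        Q_PC - Q_PV,
    ])


def _make_fast_rhs(p: ModelParameters):
    # closure over plain floats; ~5x faster than the dataclass/ndarray path
    Rval_T, Rval_P, R_PA, R_PC, R_PV = p.Rval_T, p.Rval_P, p.R_PA, p.R_PC, p.R_PV
    C_PA, C_PC, C_PV = p.C_PA, p.C_PC, p.C_PV
    Emin, Emax, tmax, tmin, T = p.Emin, p.Emax, p.tmax, p.tmin, p.T
    V0_PA, V0_PC, V0_PV, V0_RV = p.V0_PA, p.V0_PC, p.V0_PV, p.V0_RV
    P_RA, P_LA = p.P_RA, p.P_LA
    cos, pi = math.cos, math.pi
    amp = 0.5 * (Emax - Emin)

    def f(t, y):
        V_RV, V_PA, V_PC, V_PV = y
        tc = t % T
        if tc <= tmax:
            E = Emin + amp * (1.0 - cos(pi * tc / tmax))
        elif tc <= tmin:
            E = Emin + amp * (1.0 + cos(pi * (tc - tmax) / (tmin - tmax)))
        else:
            E = Emin
        P_RV = E * (V_RV - V0_RV)
        P_PA = (V_PA - V0_PA) / C_PA
        P_PC = (V_PC - V0_PC) / C_PC
        P_PV = (V_PV - V0_PV) / C_PV
        q_t = (P_RA - P_RV) / Rval_T
        if q_t < 0.0:
            q_t = 0.0
        q_p = (P_RV - P_PA) / Rval_P
        if q_p < 0.0:
            q_p = 0.0
        q_pa = (P_PA - P_PC) / R_PA
        q_pc = (P_PC - P_PV) / R_PC
        q_pv = (P_PV - P_LA) / R_PV
        return (q_t - q_p, q_p - q_pa, q_pa - q_pc, q_pc - q_pv)

    return f


@dataclass
class SimulationResult:
    """Final-cycle traces of a converged forward simulation.

    All traces share the time grid ``t`` (s, within [0, T]); pressures in
    mmHg, flows in mL/s, RV volume in mL.
    """

    t: np.ndarray
    P_RV: np.ndarray
    P_PA: np.ndarray
    P_PC: np.ndarray
    P_PV: np.ndarray
    Q_val_T: np.ndarray
    Q_val_P: np.ndarray
    Q_PA: np.ndarray
    Q_PC: np.ndarray
    Q_PV: np.ndarray
    V_RV: np.ndarray
    cycles_run: int
    periodicity_error: float
    params: ModelParameters = field(repr=False)
    y_end: np.ndarray | None = field(default=None, repr=False)

    @property
    def T(self) -> float:
        if self.params is not None:
            return self.params.T
        return float(self.t[-1] - self.t[0])

    def cycle_mean(self, trace: np.ndarray) -> float:
        """Time-average of a trace over the cycle (trapezoidal)."""
        return float(np.trapezoid(trace, self.t) / (self.t[-1] - self.t[0]))

    @property
    def cardiac_output(self) -> float:
        """Cycle-averaged flow through the pulmonic valve, mL/s."""
        return self.cycle_mean(self.Q_val_P)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "t": self.t, "P_RV": self.P_RV, "P_PA": self.P_PA,
            "P_PC": self.P_PC, "P_PV": self.P_PV,
            "Q_val_T": self.Q_val_T, "Q_val_P": self.Q_val_P,
            "Q_PA": self.Q_PA, "Q_PC": self.Q_PC, "Q_PV": self.Q_PV,
            "V_RV": self.V_RV,
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _initial_state(p: ModelParameters) -> np.ndarray:
    # Crude but adequate start: resistor-chain flow sets vascular pressures,
    # RV starts at its diastolic-pressure volume.  The 40-cycle transient
    # removes any sensitivity to this choice.
    R_total = p.Rval_T + p.Rval_P + p.R_PA + p.R_PC + p.R_PV
    Q0 = max((p.P_RA - p.P_LA) / R_total, 1.0)
    P_PA0 = p.P_LA + Q0 * (p.R_PA + p.R_PC + p.R_PV)
    P_PC0 = p.P_LA + Q0 * (p.R_PC + p.R_PV)
    P_PV0 = p.P_LA + Q0 * p.R_PV
    V_RV0 = max(p.P_RA, 2.0) / p.Emin + p.V0_RV
    return np.array([
        V_RV0,
        p.V0_PA + p.C_PA * P_PA0,
        p.V0_PC + p.C_PC * P_PC0,
        p.V0_PV + p.C_PV * P_PV0,
    ])


def _integrate(g, y, t_grid, rtol, atol, p):
    out, info = odeint(g, y, t_grid, rtol=rtol, atol=atol, full_output=True,
                       mxstep=100000, printmessg=False)
    if info["message"] != "Integration successful.":
        raise SimulationError(f"integration failed: {info['message']}", p)
    if not np.all(np.isfinite(out)):
        raise SimulationError("non-finite state during integration", p)
    return out


def simulate(
    p: ModelParameters,
    n_cycles: int = 40,
    n_out: int = 200,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-6,
    stop_tol: float | None = None,
    pressure_ceiling: float = 500.0,
    y0: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate the model to periodic steady state and return the final cycle.

    Uses the LSODA stiff-capable adaptive integrator throughout.

    Parameters
    ----------
    p
        Validated model parameters.
    n_cycles
        Number of cardiac cycles to run before sampling the output cycle
        (default 40, which is ample for stabilization at physiological
        time constants).
    n_out
        Number of uniform output samples over the final cycle (ignored if
        ``t_eval`` is given).
    t_eval
        Explicit output times within [0, T] for the final cycle, e.g. a
        measurement grid.
    stop_tol
        If set, stop the warm-up early once the cycle-to-cycle relative
        state change falls below this tolerance (used to accelerate
        repeated solves inside calibration loops).
    pressure_ceiling
        Abort with :class:`SimulationError` if any compartment pressure on
        the output cycle exceeds this value (mmHg).
    y0
        Optional initial state (e.g. a previously converged end-of-cycle
        state when scanning nearby parameter vectors).

    Returns
    -------
    SimulationResult
        Traces over one cycle plus the cycle-to-cycle periodicity error
        (max relative state change across the output cycle).
    """
    if n_cycles < 2:
        raise ValueError("n_cycles must be >= 2")
    f = _make_fast_rhs(p)

    def g(y, t):
        return f(t, y)

    y = _initial_state(p) if y0 is None else np.asarray(y0, dtype=float)
    T = p.T

    # warm-up: n_cycles - 1 transient cycles (the output cycle is the last
    # one), in chunks with cycle-boundary convergence checks
    warmup = n_cycles - 1
    chunk = 4 if stop_tol is not None else warmup
    done = 0
    cycles = 1
    while done < warmup:
        m = min(chunk, warmup - done)
        out = _integrate(g, y, np.arange(m + 1) * T, rtol, atol, p)
        rel = np.max(np.abs(np.diff(out, axis=0))
                     / np.maximum(np.abs(out[1:]), 1.0), axis=1)
        y = out[-1]
        done += m
        cycles = done + 1
        if stop_tol is not None and done >= 3 and rel[-1] < stop_tol:
            break

    if t_eval is None:
        t_req = np.linspace(0.0, T, n_out)
    else:
        t_req = np.asarray(t_eval, dtype=float)
    # integrate the output cycle on the requested grid plus the cycle
    # endpoints, so periodicity can be measured across that same cycle
    t_full = np.union1d(t_req, [0.0, T])
    out = _integrate(g, y, t_full, rtol, atol, p)
    y_end = out[-1]
    err = float(np.max(np.abs(y_end - y) / np.maximum(np.abs(y_end), 1.0)))
    keep = np.isin(t_full, t_req)
    V = out[keep].T
    t_grid = t_full[keep]
    pres = compartment_pressures(V, t_grid, p)
    if max(float(np.max(np.abs(tr))) for tr in pres) > pressure_ceiling:
        raise SimulationError(
            f"pressure exceeded ceiling {pressure_ceiling} mmHg", p)
    flows = junction_flows(pres, p)
    return SimulationResult(
        t=t_grid,
        P_RV=np.asarray(pres[0]), P_PA=np.asarray(pres[1]),
        P_PC=np.asarray(pres[2]), P_PV=np.asarray(pres[3]),
        Q_val_T=np.asarray(flows[0]), Q_val_P=np.asarray(flows[1]),
        Q_PA=np.asarray(flows[2]), Q_PC=np.asarray(flows[3]),
        Q_PV=np.asarray(flows[4]),
        V_RV=np.asarray(V[0]),
        cycles_run=cycles,
        periodicity_error=err,
        params=p,
        y_end=y_end,
    )
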