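"""RV pressure-volume loop metrics from a converged simulation.

End-diastolic and end-systolic volumes are the extrema of the RV volume
trace; the corresponding pressures are sampled at those same instants
(EDP at maximum volume — end of filling; ESP at minimum volume — end of
ejection).  Stroke work is the area enclosed by the (V, P) loop, the time
integral of P·dV/dt over one cycle, evaluated by cyclic trapezoidal
quadrature; it is positive for the physiological loop orientation and
reported both in mL·mmHg and in joules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from .model import SimulationResult, MMHG_ML_TO_J

__all__ = ["PVLoopMetrics", "pv_loop_metrics", "stroke_work", "loop_work"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PVLoopMetrics:
    """Corner metrics and stroke work of one RV pressure-volume loop."""

    EDV: float        # end-diastolic volume, mL
    ESV: float        # end-systolic volume, mL
    SV: float         # stroke volume, mL
    EDP: float        # pressure at EDV, mmHg
    ESP: float        # pressure at ESV, mmHg
    SW: float         # stroke work, mL·mmHg
    SW_J: float       # stroke work, J

    def to_dict(self) -> dict:
        return asdict(self)


def loop_work(V: np.ndarray, P: np.ndarray) -> float:
    """Signed area enclosed by the (V, P) loop, by cyclic trapezoidal
    quadrature of the pressure-volume work integral.

    Positive for the physiological loop orientation (counter-clockwise in
    the (V, P) plane: fill at low pressure, eject at high pressure);
    antisymmetric under time reversal.  The loop is closed between the
    last and first samples if the trace does not already return to its
    start.
    """
    P = np.asarray(P, dtype=float)
    V = np.asarray(V, dtype=float)
    dV = np.diff(V, append=V[0])
    Pmid = 0.5 * (P + np.roll(P, -1))
    return -float(np.sum(Pmid * dV))


def stroke_work(sim: SimulationResult, gap_tolerance: float = 0.05) -> tuple[float, float]:
    """Stroke work of the final cycle, in (mL·mmHg, J).

    Warns if the loop is open (start/end volume mismatch beyond
    ``gap_tolerance`` of the stroke volume).
    """
    V, P = sim.V_RV, sim.P_RV
    sv = float(np.max(V) - np.min(V))
    gap = abs(float(V[-1] - V[0]))
    if sv > 0 and gap > gap_tolerance * sv:
        log.warning("open PV loop: start/end volume gap %.3g mL (%.1f%% of SV)",
                    gap, 100 * gap / sv)
    # drop a duplicated endpoint so the wrap-around segment is not counted twice
    if len(sim.t) > 2 and np.isclose(sim.t[-1] - sim.t[0], sim.T):
        V, P = V[:-1], P[:-1]
    sw = loop_work(V, P)
    return sw, sw * MMHG_ML_TO_J


def pv_loop_metrics(sim: SimulationResult,
                    periodicity_tol: float = 1e-2,
                    min_sv: float = 1e-6) -> PVLoopMetrics:
    """Extract EDV/ESV/SV, EDP/ESP and stroke work from the final cycle.

    Refuses non-periodic cycles (periodicity error above tolerance) and
    degenerate, non-beating traces (stroke volume below ``min_sv``).
    """
    if sim.periodicity_error > periodicity_tol:
        raise ValueError(
            f"cycle not periodic: periodicity_error={sim.periodicity_error:.3g} "
            f"> {periodicity_tol:.3g}; increase n_cycles")
    i_ed = int(np.argmax(sim.V_RV))
    i_es = int(np.argmin(sim.V_RV))
    EDV = float(sim.V_RV[i_ed])
    ESV = float(sim.V_RV[i_es])
    SV = EDV - ESV
    if SV < min_sv:
        raise ValueError(f"degenerate PV loop: stroke volume {SV:.3g} mL")
    sw, sw_j = stroke_work(sim)
    return PVLoopMetrics(
        EDV=EDV, ESV=ESV, SV=SV,
        EDP=float(sim.P_RV[i_ed]), ESP=float(sim.P_RV[i_es]),
        SW=sw, SW_J=sw_j,
    )
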