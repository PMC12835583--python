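"""Virtual-patient generator for the four pulmonary-hypertension phenotypes.

Because catheterization/echo waveform recordings are not distributable, the
package ships a cohort emulator: each phenotype has a preset — a median
ground-truth parameter vector whose forward simulation lands in that
phenotype's published hemodynamic envelope (mean PA pressure, cardiac
output, wedge pressure), with group-typical RV volumes setting the
elastance scale.  Patients are drawn around the preset with multiplicative
log-normal spread, forward-simulated to steady state, summarized like a
catheterization report, and observed through a configurable measurement
noise model (multiplicative + additive Gaussian noise and, for flow, a
small phase jitter emulating residual pressure/flow alignment error
between modalities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .model import ModelParameters, SimulationError, SimulationResult, simulate
from .initialize import (
    ClinicalSummary,
    PHENOTYPES,
    build_initial_parameters,
    normalize_phenotype,
)
from .calibrate import WaveformSeries

__all__ = [
    "NoiseModel",
    "DEFAULT_NOISE",
    "PhenotypePreset",
    "VirtualPatient",
    "phenotype_preset",
    "generate_patient",
    "generate_cohort",
    "add_noise",
    "DEFAULT_GROUP_SIZES",
    "GROUP_TARGETS",
]

log = logging.getLogger(__name__)

#: Study-sized default cohort composition.
DEFAULT_GROUP_SIZES = {
    "Pre-capillary": 5, "Ipc-PH": 12, "Cpc-PH": 5, "No PH": 3,
}

#: Phenotype-level hemodynamic targets for the preset medians.  HR in bpm,
#: CO in L/min, pressures in mmHg, volumes in mL.  Values sit inside each
#: group's published clinical envelope and are ordered to express the
#: qualitative group contrasts: combined pre/post-capillary disease is the
#: stiffest, highest-pressure circulation; isolated post-capillary disease
#: has a dilated, low-elastance ventricle with preserved output; the No PH
#: group is the least loaded.
GROUP_TARGETS = {
    "Pre-capillary": dict(HR=71.0, CO=4.7, PAWP=13.0, mPAP=38.0,
                          EDV=115.0, ESV=68.0),
    "Ipc-PH":        dict(HR=72.0, CO=5.8, PAWP=16.0, mPAP=24.0,
                          EDV=236.0, ESV=178.0),
    "Cpc-PH":        dict(HR=69.0, CO=4.5, PAWP=20.0, mPAP=45.0,
                          EDV=96.0, ESV=55.0),
    "No PH":         dict(HR=87.0, CO=6.1, PAWP=10.0, mPAP=19.0,
                          EDV=106.0, ESV=59.0),
}

#: Multiplicative log-normal spread (SD of log) per sampled parameter.
DEFAULT_SPREAD = {
    "Rval_T": 0.08, "Rval_P": 0.08, "R_PA": 0.08, "R_PC": 0.08, "R_PV": 0.08,
    "C_PA": 0.10, "C_PC": 0.10, "C_PV": 0.10,
    "Emax": 0.10, "Emin": 0.10,
    "tmax": 0.05, "tmin": 0.04,
    "P_RA": 0.10, "P_LA": 0.12, "T": 0.05,
}


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise: v_obs = v·(1+ε_m) + ε_a with i.i.d. Gaussian ε,
    plus an optional uniform circular phase shift up to ``phase_jitter``·T."""

    multiplicative_sd: float = 0.0
    additive_sd: float = 0.0
    phase_jitter: float = 0.0

    def __post_init__(self):
        if self.multiplicative_sd < 0 or self.additive_sd < 0 \
                or self.phase_jitter < 0:
            raise ValueError("noise magnitudes must be non-negative")


#: Default measurement noise per signal kind.  High-fidelity catheter
#: pressure is comparatively clean; Doppler/VTI-derived flow compounds
#: tracing and outflow-tract-area errors and is substantially noisier.
#: Phase jitter defaults to zero — the emulated recordings stand for
#: signals that have already been beat-aligned, as upstream clinical
#: processing does — but remains available to study misalignment.
DEFAULT_NOISE = {
    "pressure": NoiseModel(multiplicative_sd=0.05, additive_sd=0.5,
                           phase_jitter=0.0),
    "flow": NoiseModel(multiplicative_sd=0.18, additive_sd=8.0,
                       phase_jitter=0.0),
}


def add_noise(w: WaveformSeries, model: NoiseModel,
              seed=None) -> WaveformSeries:
    """Corrupt a waveform with the observation-noise model (reproducible
    under a fixed seed or Generator)."""
    rng = np.random.default_rng(seed)
    v = w.v.copy()
    if model.phase_jitter > 0:
        shift = rng.uniform(-model.phase_jitter, model.phase_jitter) * w.T
        v = np.interp((w.t + shift) % w.T, w.t, v, period=w.T)
    if model.multiplicative_sd > 0:
        v = v * (1.0 + rng.normal(0.0, model.multiplicative_sd, size=v.shape))
    if model.additive_sd > 0:
        v = v + rng.normal(0.0, model.additive_sd, size=v.shape)
    return WaveformSeries(t=w.t.copy(), v=v, kind=w.kind, T=w.T)


@dataclass(frozen=True)
class PhenotypePreset:
    """Median ground-truth parameters and sampling spread for one phenotype."""

    label: str
    median: ModelParameters
    spread: dict = field(default_factory=lambda: dict(DEFAULT_SPREAD))
    targets: dict = field(default_factory=dict)


def _tune_preset(p: ModelParameters, CO_target_mls: float, mPAP_target: float,
                 max_iter: int = 10, tol: float = 0.02) -> ModelParameters:
    """Fixed-point adjustment of the preset median.

    The tricuspid resistance steers simulated cardiac output to the group
    target; the three series vascular resistances are rescaled together so
    the mean PA→LA gradient at that output matches the target mean PA
    pressure.  Converges in a handful of iterations and is deterministic.
    """
    for _ in range(max_iter):
        s = simulate(p, stop_tol=1e-6, n_out=100)
        co = s.cardiac_output
        mpap = s.cycle_mean(s.P_PA)
        co_err = co / CO_target_mls - 1.0
        mpap_err = (mpap - p.P_LA) / (mPAP_target - p.P_LA) - 1.0
        if abs(co_err) < tol and abs(mpap_err) < tol:
            break
        f_fill = (co / CO_target_mls) ** 0.8
        f_r = 1.0 / (1.0 + mpap_err)
        p = replace(
            p,
            Rval_T=p.Rval_T * f_fill,
            R_PA=p.R_PA * f_r, R_PC=p.R_PC * f_r, R_PV=p.R_PV * f_r,
        )
    return p


@lru_cache(maxsize=None)
def phenotype_preset(label: str) -> PhenotypePreset:
    """Ground-truth preset for a phenotype label.

    Built by initializing the model from the phenotype's target
    hemodynamics and tuning the tricuspid and series vascular resistances
    until the simulated cardiac output and mean PA pressure hit the
    targets (within 2%).
    """
    label = normalize_phenotype(label)
    tg = GROUP_TARGETS[label]
    c = ClinicalSummary(HR=tg["HR"], CO=tg["CO"], PAWP=tg["PAWP"],
                        mPAP=tg["mPAP"], EDV=tg["EDV"], ESV=tg["ESV"],
                        phenotype=label)
    p0 = build_initial_parameters(c)
    p = _tune_preset(p0, CO_target_mls=c.CO_mls, mPAP_target=tg["mPAP"])
    return PhenotypePreset(label=label, median=p, targets=dict(tg))


@dataclass
class VirtualPatient:
    """One synthetic subject: ground truth, noiseless summary, noisy data."""

    id: str
    phenotype: str
    truth: ModelParameters
    summary: ClinicalSummary
    pressure_true: WaveformSeries
    flow_true: WaveformSeries
    pressure_obs: WaveformSeries
    flow_obs: WaveformSeries
    noise: dict
    seed: int
    simulation: SimulationResult = field(repr=False)


def _sample_truth(preset: PhenotypePreset, rng) -> ModelParameters:
    d = preset.median.to_dict()
    for name, sd in preset.spread.items():
        d[name] *= float(np.exp(rng.normal(0.0, sd)))
    # keep timing inside its legal window for the sampled cycle length
    d["tmax"] = float(np.clip(d["tmax"], 0.06 * d["T"], 0.34 * d["T"]))
    d["tmin"] = float(np.clip(d["tmin"], max(0.36 * d["T"], 1.05 * d["tmax"]),
                              0.69 * d["T"]))
    return ModelParameters(**d)


def generate_patient(
    preset: PhenotypePreset,
    seed: int,
    noise: dict | None = None,
    Nt: int = 100,
    patient_id: str = "",
    max_attempts: int = 10,
) -> VirtualPatient:
    """Sample one virtual patient from a phenotype preset.

    Draws truth parameters (log-normal around the preset median),
    simulates to periodic steady state, derives the clinical-style summary
    from the noiseless final cycle (CO from cycle-mean pulmonic flow, PA
    pressures from the P_PA trace, PAWP from the left-atrial source), and
    produces observed waveforms through the noise model.  Fully
    reproducible under the seed; parameter draws that fail to simulate are
    redrawn (up to ``max_attempts``, logged).
    """
    noise = dict(DEFAULT_NOISE) if noise is None else noise
    rng = np.random.default_rng(seed)
    last_err = None
    for attempt in range(max_attempts):
        try:
            truth = _sample_truth(preset, rng)
            sim = simulate(truth, t_eval=np.arange(Nt) * (truth.T / Nt))
            break
        except (SimulationError, ValueError) as exc:
            last_err = exc
            log.warning("patient draw failed (attempt %d): %s", attempt + 1, exc)
    else:
        raise SimulationError(
            f"could not sample a simulable patient after {max_attempts} "
            f"attempts: {last_err}")

    co_lmin = sim.cardiac_output * 60.0 / 1000.0
    sPAP = float(np.max(sim.P_PA))
    dPAP = float(np.min(sim.P_PA))
    mPAP = sim.cycle_mean(sim.P_PA)
    summary = ClinicalSummary(
        HR=60.0 / truth.T, CO=co_lmin,
        PAWP=truth.P_LA, mPAP=mPAP, sPAP=sPAP, dPAP=dPAP,
        RAP=truth.P_RA,
        EDV=float(np.max(sim.V_RV)), ESV=float(np.min(sim.V_RV)),
        subject=patient_id, phenotype=preset.label,
    )
    pressure_true = WaveformSeries(t=sim.t, v=sim.P_PA, kind="pressure",
                                   T=truth.T)
    flow_true = WaveformSeries(t=sim.t, v=sim.Q_val_P, kind="flow", T=truth.T)
    pressure_obs = add_noise(pressure_true, noise["pressure"], rng)
    flow_obs = add_noise(flow_true, noise["flow"], rng)
    return VirtualPatient(
        id=patient_id or f"{preset.label}-{seed}",
        phenotype=preset.label, truth=truth, summary=summary,
        pressure_true=pressure_true, flow_true=flow_true,
        pressure_obs=pressure_obs, flow_obs=flow_obs,
        noise={k: vars(v) for k, v in noise.items()},
        seed=seed, simulation=sim,
    )


def generate_cohort(
    n_per_group: dict | None = None,
    seed: int = 0,
    noise: dict | None = None,
    Nt: int = 100,
) -> tuple[list[VirtualPatient], pd.DataFrame]:
    """Generate a reproducible multi-phenotype cohort with a manifest.

    Default composition mirrors the study cohort (5 pre-capillary, 12
    isolated post-capillary, 5 combined, 3 without PH).  Per-patient seeds
    are drawn once from the cohort seed, so patients are independent and
    the whole cohort is reproducible.
    """
    sizes = dict(DEFAULT_GROUP_SIZES) if n_per_group is None else {
        normalize_phenotype(k): int(v) for k, v in n_per_group.items()}
    if any(v < 0 for v in sizes.values()):
        raise ValueError("group sizes must be non-negative")
    sizes = {k: v for k, v in sizes.items() if v > 0}
    if not sizes:
        raise ValueError("need at least one patient in some group")
    rng = np.random.default_rng(seed)
    total = sum(sizes.values())
    child_seeds = rng.integers(0, 2**31 - 1, size=total)
    patients = []
    rows = []
    k = 0
    for label in PHENOTYPES:
        if label not in sizes:
            continue
        preset = phenotype_preset(label)
        for i in range(sizes[label]):
            pid = f"{label.replace(' ', '')}-{i + 1:02d}"
            pt = generate_patient(preset, int(child_seeds[k]), noise=noise,
                                  Nt=Nt, patient_id=pid)
            patients.append(pt)
            rows.append({"id": pid, "phenotype": label,
                         "seed": int(child_seeds[k]),
                         "HR": pt.summary.HR, "CO": pt.summary.CO,
                         "mPAP": pt.summary.mPAP, "PAWP": pt.summary.PAWP})
            k += 1
    return patients, pd.DataFrame(rows)
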