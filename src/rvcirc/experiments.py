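"""Reproduction workflows: the package's headline numerical experiments.

Each function runs one self-contained study on synthetic cohorts — model
conservation checks, parameter recovery from noiseless or noise-corrupted
waveforms, sensitivity screening stability, phenotype-level PV-loop
contrasts, and LDA separability — and returns a flat dict of summary
numbers.  ``scripts/acceptance.py`` assembles these into a single report.
"""

from __future__ import annotations

import numpy as np

from .model import INFLUENTIAL_ORDER, simulate
from .initialize import ClinicalSummary, build_initial_parameters
from .sensitivity import screen_model, select_influential
from .calibrate import prepare_data, calibrate
from .pvloop import pv_loop_metrics, loop_work
from .synth import phenotype_preset, generate_patient, generate_cohort, \
    DEFAULT_NOISE, NoiseModel
from .analysis import build_feature_table, cohort_feature_frame, \
    lda_separability
from .io import load_reference_cohort

__all__ = [
    "conservation_suite",
    "recovery_experiment",
    "screening_stability",
    "phenotype_contrast_experiment",
    "lda_replicates",
    "PHENOTYPE_CYCLE",
]

PHENOTYPE_CYCLE = ("Pre-capillary", "Ipc-PH", "Cpc-PH", "No PH")


def _random_truths(seed: int, n: int):
    from .synth import _sample_truth
    rng = np.random.default_rng(seed)
    return [_sample_truth(phenotype_preset(PHENOTYPE_CYCLE[i % 4]), rng)
            for i in range(n)]


def conservation_suite(seed: int = 0, n: int = 50) -> dict:
    """Conservation, valve gating and periodicity over random valid
    parameter vectors spanning the phenotype presets."""
    from .model import rhs, junction_flows, compartment_pressures
    worst_conservation = 0.0
    worst_valve = 0.0
    worst_periodicity = 0.0
    rng = np.random.default_rng(seed + 1)
    for p in _random_truths(seed, n):
        # algebraic conservation identity at random states
        for _ in range(5):
            s = rng.uniform([50, 5, 20, 10], [250, 60, 120, 80])
            t = rng.uniform(0, p.T)
            d = rhs(t, s, p)
            q = junction_flows(compartment_pressures(s, t, p), p)
            worst_conservation = max(
                worst_conservation, abs(float(np.sum(d) - (q[0] - q[4]))))
        sim = simulate(p, n_cycles=40)
        worst_valve = max(worst_valve,
                          -min(float(sim.Q_val_T.min()),
                               float(sim.Q_val_P.min())))
        worst_periodicity = max(worst_periodicity, sim.periodicity_error)
    return {
        "n_vectors": n,
        "max_conservation_violation": worst_conservation,
        "max_valve_backflow": worst_valve,
        "max_periodicity_error": worst_periodicity,
    }


def recovery_experiment(
    seed: int = 0,
    n_per_group: int = 5,
    n_starts: int = 5,
    noiseless: bool = False,
    Nt: int = 100,
) -> dict:
    """Self-consistency calibration: fit each virtual patient's waveforms
    with the non-calibrated parameters held at truth and starts perturbed
    +/-30% around truth; report parameter-recovery errors and fit quality.
    """
    noise = None
    if noiseless:
        noise = {"pressure": NoiseModel(), "flow": NoiseModel()}
    errs = {n: [] for n in INFLUENTIAL_ORDER}
    timing_err = []
    r2p, r2q = {}, {}
    k = 0
    for label in PHENOTYPE_CYCLE:
        preset = phenotype_preset(label)
        for _ in range(n_per_group):
            pt = generate_patient(preset, seed=seed + 700 + 13 * k,
                                  noise=noise, Nt=Nt)
            k += 1
            data = prepare_data(pt.pressure_obs, pt.flow_obs, Nt=Nt)
            # noiseless fits chase a deep minimum: keep the steady-state
            # truncation error well below the attainable cost
            sim_kwargs = {"stop_tol": 1e-6} if noiseless else {"stop_tol": 1e-4}
            res = calibrate(data, pt.truth, n_starts=n_starts, seed=seed + k,
                            perturbation=("uniform", 0.7, 1.3),
                            include_theta0_start=False, sim_kwargs=sim_kwargs)
            truth = pt.truth.theta()
            for name, th, tr in zip(INFLUENTIAL_ORDER, res.theta, truth):
                if name in ("tmax", "tmin"):
                    timing_err.append(abs(th - tr) / pt.truth.T)
                else:
                    errs[name].append(abs(th / tr - 1.0))
            r2p.setdefault(label, []).append(res.r2_pressure)
            r2q.setdefault(label, []).append(res.r2_flow)
    all_r2p = [x for v in r2p.values() for x in v]
    all_r2q = [x for v in r2q.values() for x in v]
    return {
        "n_patients": 4 * n_per_group,
        "n_starts": n_starts,
        "median_err_R_PA": float(np.median(errs["R_PA"])),
        "median_err_C_PA": float(np.median(errs["C_PA"])),
        "median_err_Rval_T": float(np.median(errs["Rval_T"])),
        "median_err_Emax": float(np.median(errs["Emax"])),
        "max_err_R_PA": float(np.max(errs["R_PA"])),
        "max_err_Rval_T": float(np.max(errs["Rval_T"])),
        "max_err_C_PA": float(np.max(errs["C_PA"])),
        "max_err_Emax": float(np.max(errs["Emax"])),
        "max_timing_err_frac_T": float(np.max(timing_err)),
        "median_r2_pressure": float(np.median(all_r2p)),
        "median_r2_flow": float(np.median(all_r2q)),
        "min_r2_pressure": float(np.min(all_r2p)),
        "min_r2_flow": float(np.min(all_r2q)),
        "group_mean_r2_pressure": {g: float(np.mean(v))
                                   for g, v in r2p.items()},
        "group_mean_r2_flow": {g: float(np.mean(v)) for g, v in r2q.items()},
        "n_groups_pressure_ge_flow": int(sum(
            np.mean(r2p[g]) >= np.mean(r2q[g]) for g in r2p)),
        "pressure_beats_flow_all_groups": bool(all(
            np.mean(r2p[g]) >= np.mean(r2q[g]) for g in r2p)),
    }


def screening_stability(seeds=(0, 1, 2, 3, 4), r: int = 20) -> dict:
    """Morris screen on the cohort-mean baseline across several seeds;
    reports how often the expected least-influential set is excluded."""
    rc = load_reference_cohort()
    mean = ClinicalSummary(
        HR=float(np.mean([c.HR for c in rc])),
        CO=float(np.mean([c.CO for c in rc])),
        PAWP=float(np.mean([c.PAWP for c in rc])),
        mPAP=float(np.mean([c.mPAP for c in rc])),
        phenotype="Ipc-PH")
    p0 = build_initial_parameters(mean)
    expected_excluded = {"Rval_P", "C_PC", "C_PV"}
    hits = 0
    selections = []
    for s in seeds:
        res = screen_model(p0, r=r, seed=s)
        sel = select_influential(res)
        selections.append(sel)
        if set(res.combined_ranking()[:3]) == expected_excluded \
                and tuple(sel) == tuple(INFLUENTIAL_ORDER):
            hits += 1
    return {
        "n_seeds": len(seeds),
        "n_matching_exclusion": hits,
        "selections": selections,
    }


def phenotype_contrast_experiment(seed: int = 0, scale: int = 3) -> dict:
    """Group PV-loop contrasts on a generated cohort (default triple the
    study size, where the group-mean trend is stable against sampling
    noise)."""
    sizes = {"Pre-capillary": 5 * scale, "Ipc-PH": 12 * scale,
             "Cpc-PH": 5 * scale, "No PH": 3 * scale}
    patients, _ = generate_cohort(sizes, seed=seed)
    sw, esp, edv = {}, {}, {}
    for pt in patients:
        m = pv_loop_metrics(pt.simulation)
        sw.setdefault(pt.phenotype, []).append(m.SW_J)
        esp.setdefault(pt.phenotype, []).append(m.ESP)
        edv.setdefault(pt.phenotype, []).append(m.EDV)
    mean_sw = {g: float(np.mean(v)) for g, v in sw.items()}
    mean_esp = {g: float(np.mean(v)) for g, v in esp.items()}
    order = ("No PH", "Ipc-PH", "Pre-capillary", "Cpc-PH")
    return {
        "n_patients": len(patients),
        "group_mean_SW_J": mean_sw,
        "group_mean_ESP": mean_esp,
        "group_mean_EDV": {g: float(np.mean(v)) for g, v in edv.items()},
        "sw_ordering_holds": bool(all(
            mean_sw[order[i]] < mean_sw[order[i + 1]] for i in range(3))),
        "esp_highest_in_cpc": max(mean_esp, key=mean_esp.get) == "Cpc-PH",
    }


def lda_replicates(seed: int = 0, n_seeds: int = 20) -> dict:
    """LDA separability on repeated study-sized cohorts: fraction of
    replicates where the combined feature set matches or beats the
    clinical-only set in leave-one-out accuracy."""
    wins = 0
    accs = {"clinical": [], "model": [], "combined": []}
    for s in range(seed, seed + n_seeds):
        patients, _ = generate_cohort(seed=s)
        metrics = {pt.id: pv_loop_metrics(pt.simulation) for pt in patients}
        frame = cohort_feature_frame(patients, metrics)
        a = {}
        for sel in accs:
            ft = build_feature_table(frame, selector=sel)
            a[sel] = lda_separability(ft).loo_accuracy
            accs[sel].append(a[sel])
        if a["combined"] >= a["clinical"]:
            wins += 1
    return {
        "n_seeds": n_seeds,
        "combined_ge_clinical_fraction": wins / n_seeds,
        "mean_accuracy": {k: float(np.mean(v)) for k, v in accs.items()},
    }
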