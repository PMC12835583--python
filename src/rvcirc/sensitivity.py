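"""Morris elementary-effects screening of circulation-model parameters.

One-at-a-time trajectories over a discretized parameter hypercube yield, for
each parameter and each model output, the mean absolute elementary effect
mu* (overall influence) and its standard deviation sigma (interaction /
nonlinearity).  Screening is run on the two simulated signals that anchor
calibration — the pulmonary-artery pressure and pulmonic-valve flow
waveforms of the final cycle — and is used to drop the least influential
parameters from calibration.

Outputs may be scalars or whole waveforms: for a waveform output the
elementary effect is the RMS of the waveform change per unit step in
normalized parameter coordinates, relative to the RMS of the baseline
waveform.  For a scalar output this reduces to the classic |Δy|/Δx
elementary effect (up to sign, which mu* discards anyway).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import (
    ModelParameters,
    SCREENED_ORDER,
    INFLUENTIAL_ORDER,
    SimulationError,
    simulate,
)
from .initialize import ParameterBounds, build_bounds

__all__ = [
    "SensitivityResult",
    "morris_sample",
    "morris_screen",
    "select_influential",
    "screen_model",
    "DEFAULT_OUTPUTS",
]

log = logging.getLogger(__name__)

#: Names of the default output signals.
DEFAULT_OUTPUTS = ("P_PA", "Q_val_P")


@dataclass
class SensitivityResult:
    """mu*/sigma per parameter per output, with ascending-mu* rankings."""

    names: tuple
    outputs: tuple
    mu_star: pd.DataFrame      # index = parameter, columns = outputs
    sigma: pd.DataFrame
    r: int
    levels: int
    seed: int | None
    n_failed: int = 0

    def ranking(self, output: str) -> list[str]:
        """Parameters ordered from least to most influential on ``output``."""
        return list(self.mu_star[output].sort_values(kind="stable").index)

    def bottom(self, output: str, n: int) -> set[str]:
        return set(self.ranking(output)[:n])

    def combined_ranking(self) -> list[str]:
        """Parameters ordered by their influence on *either* output.

        The score is the maximum mu* across outputs, so a parameter ranks
        low only if it is uninfluential on every screened signal.
        """
        return list(self.mu_star.max(axis=1).sort_values(kind="stable").index)

    def to_frame(self) -> pd.DataFrame:
        mu = self.mu_star.add_prefix("mu_star_")
        sg = self.sigma.add_prefix("sigma_")
        return pd.concat([mu, sg], axis=1)


def morris_sample(
    bounds: ParameterBounds,
    r: int = 20,
    levels: int = 8,
    seed: int | None = None,
) -> np.ndarray:
    """Build r one-at-a-time trajectories of k+1 points each.

    Returns an array of shape ``(r*(k+1), k)`` in physical parameter units.
    Each trajectory starts from a random point on a ``levels``-level grid in
    the unit hypercube and perturbs every coordinate exactly once by
    ``delta = levels / (2*(levels-1))``, in random order and direction.
    """
    if r < 4:
        raise ValueError("r must be >= 4 for a meaningful screen")
    if levels % 2:
        raise ValueError("levels must be even")
    k = len(bounds.names)
    span = bounds.upper - bounds.lower
    if np.any(span <= 0):
        raise ValueError("degenerate bounds")
    rng = np.random.default_rng(seed)
    delta = levels / (2.0 * (levels - 1.0))
    base_levels = np.arange(0, levels // 2) / (levels - 1.0)  # start grid

    rows = np.empty((r * (k + 1), k))
    for i in range(r):
        x = rng.choice(base_levels, size=k)
        direction = np.where(rng.random(k) < 0.5, 1.0, -1.0)
        # flip directions that would leave the cube
        direction = np.where(x + direction * delta > 1.0, -1.0, direction)
        direction = np.where(x + direction * delta < 0.0, 1.0, direction)
        order = rng.permutation(k)
        traj = np.empty((k + 1, k))
        traj[0] = x
        for step, j in enumerate(order):
            x = x.copy()
            x[j] += direction[j] * delta
            traj[step + 1] = x
        rows[i * (k + 1):(i + 1) * (k + 1)] = traj
    return bounds.lower + rows * span


def _as_output_list(out, n_outputs: int):
    arrs = [np.atleast_1d(np.asarray(o, dtype=float)) for o in out]
    if len(arrs) != n_outputs:
        raise ValueError(f"output_fn returned {len(arrs)} outputs, "
                         f"expected {n_outputs}")
    return arrs


def morris_screen(
    design: np.ndarray,
    output_fn: Callable[[np.ndarray], "Sequence | None"],
    bounds: ParameterBounds,
    outputs: Sequence[str] = DEFAULT_OUTPUTS,
    r: int | None = None,
    levels: int = 8,
    seed: int | None = None,
    y_ref: "Sequence | None" = None,
    max_failed_fraction: float = 0.2,
) -> SensitivityResult:
    """Compute elementary effects from a trajectory design.

    ``output_fn`` maps a parameter vector (physical units) to a sequence of
    outputs (scalar or 1-D waveform each, one per name in ``outputs``), or
    None on model failure; failed evaluations drop the whole trajectory.
    Effects are computed in normalized (unit-hypercube) coordinates; when
    ``y_ref`` is given each output change is normalized by the RMS of the
    corresponding reference output, making mu* dimensionless.
    """
    k = len(bounds.names)
    n_rows = design.shape[0]
    if n_rows % (k + 1):
        raise ValueError("design size is not a multiple of k+1")
    r_design = n_rows // (k + 1)
    span = bounds.upper - bounds.lower
    n_out = len(outputs)

    if y_ref is not None:
        ref_rms = [float(np.sqrt(np.mean(np.square(np.atleast_1d(y)))))
                   for y in _as_output_list(y_ref, n_out)]
    else:
        ref_rms = [1.0] * n_out

    evals: list = []
    for row in design:
        out = output_fn(row)
        evals.append(None if out is None else _as_output_list(out, n_out))

    effects = {name: {out: [] for out in outputs} for name in bounds.names}
    n_failed = 0
    for t in range(r_design):
        block = evals[t * (k + 1):(t + 1) * (k + 1)]
        if any(e is None or not all(np.all(np.isfinite(a)) for a in e)
               for e in block):
            n_failed += 1
            continue
        xtraj = (design[t * (k + 1):(t + 1) * (k + 1)] - bounds.lower) / span
        for step in range(k):
            dx = xtraj[step + 1] - xtraj[step]
            j = int(np.argmax(np.abs(dx)))
            h = abs(dx[j])
            for m, out in enumerate(outputs):
                dy = block[step + 1][m] - block[step][m]
                ee = float(np.sqrt(np.mean(np.square(dy)))) / (h * ref_rms[m])
                effects[bounds.names[j]][out].append(ee)
    if n_failed > max_failed_fraction * r_design:
        raise SimulationError(
            f"{n_failed}/{r_design} Morris trajectories failed; "
            "bounds may be non-physiological")
    if n_failed:
        log.warning("dropped %d/%d failed Morris trajectories", n_failed, r_design)

    mu = pd.DataFrame(index=list(bounds.names), columns=list(outputs), dtype=float)
    sg = pd.DataFrame(index=list(bounds.names), columns=list(outputs), dtype=float)
    for name in bounds.names:
        for out in outputs:
            ee = np.asarray(effects[name][out])
            mu.loc[name, out] = np.mean(np.abs(ee))
            sg.loc[name, out] = np.std(ee, ddof=1) if len(ee) > 1 else 0.0
    return SensitivityResult(
        names=tuple(bounds.names), outputs=tuple(outputs),
        mu_star=mu, sigma=sg,
        r=r if r is not None else r_design, levels=levels, seed=seed,
        n_failed=n_failed,
    )


def _simulation_outputs(p0: ModelParameters, bounds: ParameterBounds,
                        sim_kwargs: dict):
    """Waveform outputs (P_PA, Q_val_P) on a fixed final-cycle grid.

    Parameters are constructed without the Emin < Emax ordering check so
    hypercube corners remain evaluable; genuinely failing points return
    None and drop their trajectory.
    """
    base = p0.to_dict()

    def fn(theta: np.ndarray):
        d = dict(base)
        d.update(zip(bounds.names, map(float, theta)))
        try:
            p = ModelParameters.unchecked(**d)
            s = simulate(p, pressure_ceiling=1e5, **sim_kwargs)
        except (SimulationError, ValueError):
            return None
        return s.P_PA, s.Q_val_P

    return fn


def screen_model(
    p0: ModelParameters,
    names: Sequence[str] = SCREENED_ORDER,
    r: int = 20,
    levels: int = 8,
    seed: int | None = None,
    scale_range: tuple[float, float] = (0.8, 1.25),
    n_cycles: int = 40,
    stop_tol: float | None = 1e-4,
    n_out: int = 100,
) -> SensitivityResult:
    """End-to-end screen of a baseline parameter vector.

    Samples Morris trajectories over a multiplicative range around ``p0``
    (default 0.8x-1.25x, a local relative-perturbation screen; timing
    parameters are additionally confined to their cycle-fraction windows),
    simulates each design point, and aggregates elementary effects of the
    baseline-normalized pressure and flow waveforms.
    """
    bounds = build_bounds(p0, names=names,
                          lo_frac=scale_range[0], hi_frac=scale_range[1])
    design = morris_sample(bounds, r=r, levels=levels, seed=seed)
    sim_kwargs = dict(n_cycles=n_cycles, stop_tol=stop_tol, n_out=n_out)
    fn = _simulation_outputs(p0, bounds, sim_kwargs)
    y0 = fn(p0.theta(bounds.names))
    if y0 is None:
        raise SimulationError("baseline simulation failed", p0)
    return morris_screen(design, fn, bounds, r=r, levels=levels, seed=seed,
                         y_ref=y0)


def select_influential(
    result: SensitivityResult,
    n_exclude: int = 3,
) -> tuple[str, ...]:
    """Drop the parameters that are least influential on *both* outputs.

    Parameters are ranked by their combined score (max mu* across outputs)
    and the bottom ``n_exclude`` are removed, provided each of them also
    sits in the bottom half of every per-output ranking — i.e. is genuinely
    uninfluential on both signals.  The default screen excludes the
    pulmonic-valve resistance and the capillary/venous compliances, leaving
    the nine-parameter calibration subvector.  If the sanity check fails,
    the fixed default subvector is returned with a logged notice.
    """
    if n_exclude == 0:
        return tuple(result.names)
    k = len(result.names)
    excluded = set(result.combined_ranking()[:n_exclude])
    for out in result.outputs:
        if not excluded <= result.bottom(out, k // 2):
            log.warning(
                "combined bottom set %s is not uninfluential on %s; falling "
                "back to the default influential subvector", sorted(excluded), out)
            return tuple(INFLUENTIAL_ORDER)
    return tuple(n for n in result.names if n not in excluded)
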