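"""Particle-swarm calibration of the free shape/rate coefficients
against a prototype length profile.

The fit runs on the non-stochastic system: the objective is the
discrete L2 distance between the simulated deterministic length and the
target profile sampled on the same grid.  The relay makes the landscape
non-smooth (parameter changes move switching times discontinuously), so
a derivative-free global optimizer is used: standard global-best PSO
with constriction-style coefficients.  An optional feature objective
(mismatch in oscillation extrema and phase/interval durations) is
provided for periodic targets, where the plain norm is phase-sensitive.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .model_core import (
    ModelParameters,
    PhenotypeStats,
    BaseConstants,
    TEC,
    derive_parameters,
    set_parameter,
)
from .simulator import CellState, SimulationConfig, simulate
from .statistical_cell import PrototypeProfile, Trace, measure_trace
from .sensitivity import trajectory_to_trace

__all__ = [
    "CalibrationProblem",
    "PSOConfig",
    "PSOResult",
    "objective",
    "pso_minimize",
    "solve_problem",
    "calibrate_phenotype",
    "DEFAULT_BOUNDS",
]

log = logging.getLogger(__name__)

#: Finite penalty returned when a candidate blows up the integrator.
BLOWUP_PENALTY = 1e12

#: Search bounds spanning the sensitivity ranges and calibrated values.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "M1": (10.0, 1e5),
    "M2": (1e-3, 1e2),
    "M3": (1e-6, 1e-2),
    "lam": (1e-5, 1e-2),
    "c_eq": (1.05, 9.95),
}

CALIBRATABLE = ("M1", "M2", "M3", "lam", "c_eq")


@dataclass(frozen=True)
class CalibrationProblem:
    free_names: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    template: ModelParameters
    target: PrototypeProfile
    sim_cfg: SimulationConfig
    init: CellState
    kind: str = "l2"   # "l2" | "features"

    def __post_init__(self) -> None:
        if not self.free_names:
            raise ValueError("free_names must be nonempty")
        for nm in self.free_names:
            if nm not in CALIBRATABLE:
                raise ValueError(f"{nm!r} is not a calibratable parameter")
            lo, hi = self.bounds[nm]
            if not lo < hi:
                raise ValueError(f"bounds for {nm} must satisfy low < high")
        if self.target.times[-1] > self.sim_cfg.T + 1e-9:
            raise ValueError("target grid extends beyond the sim horizon")
        if self.sim_cfg.stochastic:
            raise ValueError("calibration runs on the non-stochastic system")

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[nm][0] for nm in self.free_names])
        hi = np.array([self.bounds[nm][1] for nm in self.free_names])
        return lo, hi

    def substitute(self, theta: Sequence[float]) -> ModelParameters:
        p = self.template
        for nm, v in zip(self.free_names, theta):
            p = set_parameter(p, nm, float(v))  # lam change re-derives S_max
        return p


@dataclass(frozen=True)
class PSOConfig:
    swarm_size: int = 40
    iterations: int = 200
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.swarm_size, self.iterations) < 1:
            raise ValueError("swarm_size and iterations must be >= 1")
        if min(self.inertia, self.cognitive, self.social) <= 0:
            raise ValueError("PSO weights must be positive")


@dataclass
class PSOResult:
    theta_best: np.ndarray
    J_best: float
    history: np.ndarray      # best J after each iteration (nonincreasing)
    evaluations: int
    names: tuple[str, ...] = ()

    def report_json(self, bounds: dict | None = None,
                    seed: int | None = None) -> str:
        doc = {"theta_best": {nm: float(v) for nm, v in
                              zip(self.names, self.theta_best)}
               if self.names else list(map(float, self.theta_best)),
               "J_best": float(self.J_best),
               "history": [float(h) for h in self.history],
               "evaluations": int(self.evaluations)}
        if bounds is not None:
            doc["bounds"] = {k: list(v) for k, v in bounds.items()}
        if seed is not None:
            doc["seed"] = seed
        return json.dumps(doc, indent=2)


def _sample_on_grid(traj, grid_times: np.ndarray) -> np.ndarray:
    return np.interp(grid_times, traj.t, traj.L)


def objective(theta: Sequence[float], prob: CalibrationProblem) -> float:
    """Misfit of one candidate parameter vector.

    "l2": sqrt(sum (L(theta, t_i) - L_s(t_i))^2 * dt_grid), the discrete
    L2 norm of the length mismatch on the target grid.  "features":
    relative mismatch in (min, max, T_P, T_I) of the oscillation,
    phase-insensitive.  Integrator blow-ups return a large finite
    penalty so the swarm can keep moving.
    """
    p = prob.substitute(theta)
    try:
        traj = simulate(p, prob.init, prob.sim_cfg)
    except ArithmeticError as exc:
        log.warning("objective penalized: %s", exc)
        return BLOWUP_PENALTY
    if prob.kind == "l2":
        L = _sample_on_grid(traj, prob.target.times)
        delta = float(prob.target.times[1] - prob.target.times[0])
        return float(math.sqrt(np.sum((L - prob.target.lengths) ** 2) * delta))
    # feature objective
    sim = measure_trace(trajectory_to_trace(traj))
    tgt = measure_trace(Trace(times=prob.target.times,
                              lengths=prob.target.lengths))
    terms = [(sim.L_min - tgt.L_min) / tgt.L_min,
             (sim.L_max - tgt.L_max) / tgt.L_max]
    for s_val, t_val in ((sim.T_P_mean, tgt.T_P_mean),
                         (sim.T_I_mean, tgt.T_I_mean)):
        if t_val:
            terms.append(((s_val or 0.0) - t_val) / t_val)
    return float(np.sqrt(np.mean(np.square(terms))))


def pso_minimize(fun: Callable[[np.ndarray], float],
                 bounds: tuple[np.ndarray, np.ndarray],
                 cfg: PSOConfig = PSOConfig()) -> PSOResult:
    """Global-best PSO over a box.

    Uniform random init, inertia/cognitive/social velocity update,
    positions clipped to the box.  Always returns the best point found;
    the per-iteration best history is nonincreasing by construction.
    """
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    dim = len(lo)
    rng = np.random.default_rng(cfg.seed)
    span = hi - lo
    x = lo + span * rng.random((cfg.swarm_size, dim))
    v = 0.1 * span * (2.0 * rng.random((cfg.swarm_size, dim)) - 1.0)
    pbest = x.copy()
    pval = np.array([fun(xi) for xi in x])
    g = int(np.argmin(pval))
    gbest, gval = pbest[g].copy(), float(pval[g])
    history = np.empty(cfg.iterations)
    evals = cfg.swarm_size
    for it in range(cfg.iterations):
        r1 = rng.random((cfg.swarm_size, dim))
        r2 = rng.random((cfg.swarm_size, dim))
        v = (cfg.inertia * v
             + cfg.cognitive * r1 * (pbest - x)
             + cfg.social * r2 * (gbest[None, :] - x))
        x = np.clip(x + v, lo, hi)
        val = np.array([fun(xi) for xi in x])
        evals += cfg.swarm_size
        improved = val < pval
        pbest[improved] = x[improved]
        pval[improved] = val[improved]
        g = int(np.argmin(pval))
        if pval[g] < gval:
            gbest, gval = pbest[g].copy(), float(pval[g])
        history[it] = gval
    return PSOResult(theta_best=gbest, J_best=gval, history=history,
                     evaluations=evals)


def solve_problem(prob: CalibrationProblem,
                  cfg: PSOConfig = PSOConfig()) -> PSOResult:
    """Run PSO on a calibration problem."""
    res = pso_minimize(lambda th: objective(th, prob), prob.bounds_arrays(),
                       cfg)
    res.names = prob.free_names
    return res


def calibrate_phenotype(label: str, stats: PhenotypeStats,
                        base: BaseConstants = BaseConstants(),
                        cfg: PSOConfig = PSOConfig(),
                        sim_cfg: SimulationConfig | None = None,
                        lam_fixed: float = 8.75e-4,
                        bounds: dict[str, tuple[float, float]] | None = None,
                        kind: str = "l2",
                        ) -> tuple[ModelParameters, PSOResult]:
    """Calibrate the free coefficients of one phenotype.

    TEC frees (M1, M2, lam, c_eq) with M3 fixed a priori at 1e-5 (the
    oscillatory regime requires small M3); REC/UEC free (M1, M2, M3,
    c_eq) with lam fixed to the TEC value.  Derived constants are
    pre-filled from the length statistics; the calibrated parameter set
    and the optimizer result are returned.
    """
    from .statistical_cell import make_prototype
    from .tables import default_initial_conditions

    if sim_cfg is None:
        sim_cfg = SimulationConfig(dt=1e-2, T=43200.0, stochastic=False,
                                   record_every=1200)
    if label == TEC:
        free = ("M1", "M2", "lam", "c_eq")
        fixed = {"M3": 1e-5, "lam": lam_fixed}
    else:
        free = ("M1", "M2", "M3", "c_eq")
        fixed = {"M3": 1e-4, "lam": lam_fixed}
    template = derive_parameters(
        stats, base, lam=fixed["lam"], M1=1e3, M2=1.0, M3=fixed["M3"],
        c_eq=0.5 * (base.c_L + base.c_h))
    a0, L0, c0 = default_initial_conditions(template)
    target = make_prototype(stats, duration=sim_cfg.T,
                            grid=sim_cfg.dt * sim_cfg.record_every)
    prob = CalibrationProblem(
        free_names=free,
        bounds={nm: (bounds or DEFAULT_BOUNDS)[nm] for nm in free},
        template=template, target=target, sim_cfg=sim_cfg,
        init=CellState(t=0.0, a=a0, L=L0, c=c0), kind=kind)
    res = solve_problem(prob, cfg)
    return prob.substitute(res.theta_best), res
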