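"""Time integration of the coupled F-actin / length / ATP system.

The scheme is a one-step IMEX method: within each step the three
equations are updated sequentially (a, then L, then c), each implicitly
in its own variable and explicitly in the switching functions ``K(c)``
and ``H(c)``; the length noise enters as an Euler-Maruyama increment.
This keeps every sub-update a stable scalar solve even though the linear
parts are stiff (``sigma/phi`` reaches ~60 1/s while ATP moves on the
``1/lam`` ~ 20 min scale).

Hysteresis branch state: the relay follows the sign of the ATP drift and
flips when the drift on the current branch falls below
``SimulationConfig.stall_tol`` (relay completion).  The smooth two-branch
relay admits an attracting micro-equilibrium a fraction of a percent
below the homeostatic ATP level; treating that stagnation point as the
completed end of the branch is what produces the finite-period tumbling
limit cycle.  See docs/methods.md for the analysis.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _fast
from .model_core import HysteresisBranch, ModelParameters, params_to_dict

__all__ = [
    "CellState",
    "SimulationConfig",
    "Trajectory",
    "NumericalBlowupError",
    "imex_step",
    "simulate",
    "ou_moments",
    "ou_ensemble",
]

_BLOWUP_NAMES = {_fast.BLOWUP_A: "F-actin (a)", _fast.BLOWUP_L: "length (L)",
                 _fast.BLOWUP_C: "ATP (c)"}


class NumericalBlowupError(ArithmeticError):
    """A state variable became non-finite during integration."""


@dataclass(frozen=True)
class CellState:
    """Instantaneous cell state ``(t, a, L, c, branch)``."""

    t: float
    a: float
    L: float
    c: float
    branch: HysteresisBranch = HysteresisBranch.RISING

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.L > 0 and self.c >= 0):
            raise ValueError("require a > 0, L > 0, c >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    dt : time step (s); the reference value is 1e-3, and 1e-2 is
        validated against it by the convergence tests.
    T : horizon (s).
    stochastic : draw length-noise increments when True; with
        ``beta = 0`` the stochastic trajectory equals the deterministic
        one exactly.
    seed : RNG seed (stochastic mode).
    record_every : output decimation in steps.
    stall_tol : ATP drift magnitude (mM/s) below which the active relay
        branch is considered exhausted and flips.
    xi_noise_scale : amplitude of the optional stochastic offset in the
        release gate (0 disables it; all reported results use 0).
    """

    dt: float = 1e-3
    T: float = 43200.0
    stochastic: bool = False
    seed: int = 0
    record_every: int = 1
    stall_tol: float = 1e-10
    xi_noise_scale: float = 0.0

    def __post_init__(self) -> None:
        if not (self.dt > 0 and self.T >= self.dt):
            raise ValueError("require dt > 0 and T >= dt")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.T / self.dt))


@dataclass
class Trajectory:
    """Recorded time series with its provenance metadata."""

    t: np.ndarray
    a: np.ndarray
    L: np.ndarray
    c: np.ndarray
    branch: np.ndarray
    params: ModelParameters
    config: SimulationConfig

    def __len__(self) -> int:
        return len(self.t)

    @property
    def final_state(self) -> CellState:
        return CellState(t=float(self.t[-1]), a=float(self.a[-1]),
                         L=float(self.L[-1]), c=float(self.c[-1]),
                         branch=HysteresisBranch(int(self.branch[-1])))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "a_mM": self.a, "L_um": self.L,
                             "c_mM": self.c, "branch": self.branch})

    def write_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write ``t_s,a_mM,L_um,c_mM,branch`` CSV plus a JSON sidecar
        with parameters, config and seed."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            meta = {"parameters": params_to_dict(self.params),
                    "config": dataclasses.asdict(self.config),
                    "code_version": _version()}
            path.with_suffix(path.suffix + ".meta.json").write_text(
                json.dumps(meta, indent=2, sort_keys=True))


def _version() -> str:
    from . import __version__
    return __version__


def imex_step(state: CellState, p: ModelParameters, cfg: SimulationConfig,
              dW: float = 0.0) -> CellState:
    """Advance one IMEX step from ``state``.

    ``dW`` is the Brownian increment for the length equation (0 in
    deterministic mode).  Shares the compiled scalar update with
    :func:`simulate`.
    """
    pv = _fast.pack_params(p)
    a, L, c, branch = _fast.step(state.a, state.L, state.c,
                                 int(state.branch), pv, cfg.dt, dW, 1.0,
                                 cfg.stall_tol)
    for name, val in (("F-actin (a)", a), ("length (L)", L), ("ATP (c)", c)):
        if not math.isfinite(val):
            raise NumericalBlowupError(
                f"{name} became non-finite after one step from t={state.t}")
    return CellState(t=state.t + cfg.dt, a=a, L=L, c=c,
                     branch=HysteresisBranch(branch))


def simulate(p: ModelParameters, init: CellState,
             cfg: SimulationConfig) -> Trajectory:
    """Integrate the coupled system over ``cfg.T``.

    Deterministic mode sets the Brownian increment to zero and the
    release-gate offset to 1; stochastic mode draws dW ~ N(0, dt) per
    step from a generator seeded with ``cfg.seed``.  Identical seed and
    config give bit-identical trajectories.
    """
    pv = _fast.pack_params(p)
    t, a, L, c, br, status, bad_step = _fast.integrate(
        pv, init.a, init.L, init.c, int(init.branch), cfg.dt, cfg.n_steps,
        cfg.record_every, cfg.stall_tol, cfg.stochastic,
        cfg.xi_noise_scale, cfg.seed)
    if status != _fast.OK:
        raise NumericalBlowupError(
            f"{_BLOWUP_NAMES[status]} became non-finite at step {bad_step} "
            f"(t = {bad_step * cfg.dt:.6g} s)")
    return Trajectory(t=t + init.t, a=a, L=L, c=c, branch=br,
                      params=p, config=cfg)


def ou_moments(t: float, L0: float, alpha: float, mu: float,
               beta: float) -> tuple[float, float]:
    """Closed-form mean and variance of the OU length process.

    mean(t) = mu + (L0 - mu) e^{-alpha t},
    var(t)  = beta^2/(2 alpha) (1 - e^{-2 alpha t}).

    Used as the independent oracle for the stochastic length equation
    with frozen contractility (alpha = sigma(a)/phi, mu = v_p/sigma(a)).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    mean = mu + (L0 - mu) * math.exp(-alpha * t)
    var = beta**2 / (2.0 * alpha) * (1.0 - math.exp(-2.0 * alpha * t))
    return mean, var


def ou_ensemble(n_paths: int, T: float, dt: float, L0: float, alpha: float,
                mu: float, beta: float, seed: int = 0) -> np.ndarray:
    """Terminal length of ``n_paths`` OU paths under the simulator's
    discretization (implicit drift, Euler-Maruyama noise)."""
    n_steps = int(round(T / dt))
    return _fast.ou_endpoints(n_paths, n_steps, dt, L0, alpha, mu, beta, seed)
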