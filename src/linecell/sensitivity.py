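"""Regime classification, tumbling metrics, one-at-a-time sweeps and the
(c_eq, M2, M3) phase diagram.

A trajectory is classified as ``tumbling`` (periodic rounding below the
20-um threshold), ``constant`` (relative length variation below 1%
throughout), or ``constant_with_transient`` (settles to within 1% only
after an excursion of more than 10%).  Tumbling exists for intermediate
``c_eq`` combined with large ``M2`` and small ``M3``; the sweep and
phase-diagram helpers map that region.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .model_core import ModelParameters, set_parameter
from .simulator import CellState, SimulationConfig, Trajectory, simulate
from .statistical_cell import TUMBLE_THRESHOLD, Trace, _episodes

__all__ = [
    "TUMBLING",
    "CONSTANT",
    "CONSTANT_WITH_TRANSIENT",
    "TumblingMetrics",
    "SweepRecord",
    "InsufficientCyclesError",
    "tumbling_metrics",
    "classify_regime",
    "sweep_parameter",
    "phase_diagram",
    "PhaseDiagram",
]

TUMBLING = "tumbling"
CONSTANT = "constant"
CONSTANT_WITH_TRANSIENT = "constant_with_transient"


class InsufficientCyclesError(ValueError):
    """Fewer than two complete tumbling episodes after the discard."""


@dataclass(frozen=True)
class TumblingMetrics:
    """Oscillation summary over complete cycles after the transient."""

    T_P: float        # mean tumbling-phase duration (s)
    T_I: float        # mean inter-tumble interval (s)
    L_osc_min: float  # um
    L_osc_max: float  # um
    n_cycles: int


@dataclass(frozen=True)
class SweepRecord:
    """Outcome of one simulation in a parameter sweep."""

    parameter: str
    value: float
    regime: str | None
    L_steady: float | None = None
    L_osc_min: float | None = None
    L_osc_max: float | None = None
    T_P: float | None = None
    T_I: float | None = None
    c_steady: float | None = None     # time-mean ATP over the final window
    error: str | None = None


def _post_discard(traj: Trajectory, discard: float):
    mask = traj.t >= traj.t[0] + discard
    return traj.t[mask], traj.L[mask], traj.c[mask]


def tumbling_metrics(traj: Trajectory, threshold: float = TUMBLE_THRESHOLD,
                     discard: float = 7200.0) -> TumblingMetrics:
    """Tumbling-phase/interval durations and oscillation extrema.

    Applies the trace-measurement episode logic to the post-transient
    portion of L(t); extrema are taken over whole cycles only (from the
    first to the last episode start after the discard).
    """
    t, L, _ = _post_discard(traj, discard)
    if len(t) < 3:
        raise InsufficientCyclesError("trajectory shorter than the discard")
    dt_rec = float(t[1] - t[0])
    eps = _episodes(L < threshold)
    complete = [(s, e) for (s, e) in eps if s > 0 and e < len(L)]
    if len(eps) < 2:
        raise InsufficientCyclesError(
            f"found {len(eps)} tumbling episode(s) after discard; need >= 2")
    T_P = float(np.mean([(e - s) * dt_rec for s, e in complete])) \
        if complete else float("nan")
    gaps = [(eps[k + 1][0] - eps[k][1]) * dt_rec for k in range(len(eps) - 1)]
    T_I = float(np.mean(gaps))
    lo, hi = eps[0][0], eps[-1][0]
    window = L[lo:hi] if hi > lo else L
    return TumblingMetrics(T_P=T_P, T_I=T_I,
                           L_osc_min=float(window.min()),
                           L_osc_max=float(window.max()),
                           n_cycles=len(eps) - 1)


def classify_regime(traj: Trajectory, discard: float = 7200.0,
                    threshold: float = TUMBLE_THRESHOLD,
                    const_tol: float = 0.01,
                    transient_tol: float = 0.10) -> str:
    """Label a trajectory as tumbling / constant / constant-with-transient.

    Tumbling: at least two crossings below the rounding threshold after
    the discard.  Constant: relative length variation (max-min)/mean
    below ``const_tol`` both after the discard and within the first
    hour.  Otherwise, if the post-discard window is settled but the
    early trajectory moved by more than ``transient_tol``, the label is
    constant-with-transient.
    """
    t, L, _ = _post_discard(traj, discard)
    if len(t) < 2 or traj.t[-1] - traj.t[0] < discard + 3600.0:
        raise ValueError("trajectory must extend >= 1 h beyond the discard")
    low = L < threshold
    crossings = int(np.abs(np.diff(low.astype(np.int8))).sum())
    if crossings >= 2:
        return TUMBLING
    late_var = (L.max() - L.min()) / L.mean()
    first_hour = traj.L[traj.t <= traj.t[0] + 3600.0]
    early_var = (first_hour.max() - first_hour.min()) / first_hour.mean()
    if late_var < const_tol and early_var < const_tol:
        return CONSTANT
    full_excursion = (traj.L.max() - traj.L.min()) / traj.L.mean()
    if late_var < const_tol and full_excursion > transient_tol:
        return CONSTANT_WITH_TRANSIENT
    # settled-by-the-end fallback: treat residual drift as transient
    return CONSTANT_WITH_TRANSIENT


def _analyze(traj: Trajectory, name: str, value: float,
             discard: float) -> SweepRecord:
    regime = classify_regime(traj, discard=discard)
    _, L, c = _post_discard(traj, discard)
    c_steady = float(c.mean())
    if regime == TUMBLING:
        try:
            m = tumbling_metrics(traj, discard=discard)
            return SweepRecord(parameter=name, value=value, regime=regime,
                               L_osc_min=m.L_osc_min, L_osc_max=m.L_osc_max,
                               T_P=m.T_P, T_I=m.T_I, c_steady=c_steady)
        except InsufficientCyclesError:
            return SweepRecord(parameter=name, value=value, regime=regime,
                               L_osc_min=float(L.min()),
                               L_osc_max=float(L.max()), c_steady=c_steady)
    return SweepRecord(parameter=name, value=value, regime=regime,
                       L_steady=float(L.mean()), c_steady=c_steady)


def sweep_parameter(name: str, values, template: ModelParameters,
                    cfg: SimulationConfig, init: CellState | None = None,
                    discard: float = 7200.0) -> list[SweepRecord]:
    """One deterministic simulation per value of a single parameter.

    ``S_max`` is re-derived whenever ``lam`` or ``L_max`` changes (the
    discharge balance is a modeling constraint, not a free constant).
    Per-value failures are recorded and the sweep continues.
    """
    cfg = dataclasses.replace(cfg, stochastic=False)
    records: list[SweepRecord] = []
    for v in values:
        try:
            p = set_parameter(template, name, float(v))
            start = init if init is not None else _default_init(p)
            traj = simulate(p, start, cfg)
            records.append(_analyze(traj, name, float(v), discard))
        except (ArithmeticError, ValueError) as exc:
            records.append(SweepRecord(parameter=name, value=float(v),
                                       regime=None, error=str(exc)))
    return records


def _default_init(p: ModelParameters) -> CellState:
    from .tables import default_initial_conditions
    a0, L0, c0 = default_initial_conditions(p)
    return CellState(t=0.0, a=a0, L=L0, c=c0)


def records_to_dataframe(records: list[SweepRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


@dataclass
class PhaseDiagram:
    """Regime labels over a (c_eq, M2, M3) grid."""

    c_eq: np.ndarray
    M2: np.ndarray
    M3: np.ndarray
    labels: np.ndarray          # shape (len(c_eq), len(M2), len(M3)), object
    records: list[SweepRecord]

    def tumbling_box(self) -> dict[str, tuple[float, float]] | None:
        """Axis-aligned bounding box of the tumbling region, or None."""
        idx = np.argwhere(self.labels == TUMBLING)
        if idx.size == 0:
            return None
        axes = {"c_eq": self.c_eq, "M2": self.M2, "M3": self.M3}
        out = {}
        for axis, (nm, vals) in enumerate(axes.items()):
            lo, hi = idx[:, axis].min(), idx[:, axis].max()
            out[nm] = (float(vals[lo]), float(vals[hi]))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (i, ce), (j, m2), (k, m3) in product(
                enumerate(self.c_eq), enumerate(self.M2), enumerate(self.M3)):
            rows.append({"c_eq": ce, "M2": m2, "M3": m3,
                         "regime": self.labels[i, j, k]})
        return pd.DataFrame(rows)


def phase_diagram(c_eq_values, M2_values, M3_values,
                  template: ModelParameters, cfg: SimulationConfig,
                  discard: float = 7200.0) -> PhaseDiagram:
    """Classify the regime at every point of a (c_eq, M2, M3) grid."""
    c_eq_values = np.asarray(c_eq_values, float)
    M2_values = np.asarray(M2_values, float)
    M3_values = np.asarray(M3_values, float)
    labels = np.empty((len(c_eq_values), len(M2_values), len(M3_values)),
                      dtype=object)
    records: list[SweepRecord] = []
    cfg = dataclasses.replace(cfg, stochastic=False)
    for (i, ce), (j, m2), (k, m3) in product(
            enumerate(c_eq_values), enumerate(M2_values), enumerate(M3_values)):
        p = template
        for nm, v in (("c_eq", ce), ("M2", m2), ("M3", m3)):
            p = set_parameter(p, nm, v)
        try:
            traj = simulate(p, _default_init(p), cfg)
            rec = _analyze(traj, "grid", float(ce), discard)
        except (ArithmeticError, ValueError) as exc:
            rec = SweepRecord(parameter="grid", value=float(ce), regime=None,
                              error=str(exc))
        labels[i, j, k] = rec.regime
        records.append(rec)
    return PhaseDiagram(c_eq=c_eq_values, M2=M2_values, M3=M3_values,
                        labels=labels, records=records)


def trajectory_to_trace(traj: Trajectory, label: str | None = None) -> Trace:
    """View a simulated trajectory as a measured-length trace."""
    return Trace(times=np.asarray(traj.t, float),
                 lengths=np.asarray(traj.L, float), label=label)
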