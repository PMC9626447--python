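"""Prototype ("statistical cell") length profiles, synthetic length
traces, and trace statistics.

The prototype profile is the idealized target a calibrated model should
reproduce: a constant length for the running (REC) and undecided (UEC)
phenotypes, and a two-level square wave (tumbling level ``L_min`` for
spans ``T_P``, elongated level ``L_max`` for spans ``T_I``) for tumbling
cells (TEC).  ``synth_trace`` produces experiment-like sampled traces
(2-min frames by default) with OU noise and, for TECs, jittered dwell
times; ``measure_trace`` recovers the summary statistics, including
tumbling-episode detection with the 20-um rounding threshold.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import REC, TEC, UEC, PhenotypeStats

__all__ = [
    "PrototypeProfile",
    "Trace",
    "TraceStats",
    "make_prototype",
    "synth_trace",
    "measure_trace",
    "classify_trace",
    "TUMBLE_THRESHOLD",
]

#: Length below which a cell is considered rounded (tumbling), um.
TUMBLE_THRESHOLD = 20.0

#: Experimental bounds on a single tumbling-phase duration, s.
DWELL_RANGE = (600.0, 14400.0)


@dataclass(frozen=True)
class PrototypeProfile:
    """Deterministic target length series on a uniform grid."""

    label: str
    times: np.ndarray   # s
    lengths: np.ndarray  # um

    def __post_init__(self) -> None:
        if len(self.times) != len(self.lengths):
            raise ValueError("times and lengths must have equal length")


@dataclass(frozen=True)
class Trace:
    """Sampled length trace (uniform frame interval)."""

    times: np.ndarray     # s
    lengths: np.ndarray   # um
    label: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.lengths):
            raise ValueError("times and lengths must have equal length")
        if len(self.times) and np.any(np.asarray(self.lengths) <= 0):
            raise ValueError("lengths must be positive")

    @property
    def frame(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t_s": self.times, "L_um": self.lengths}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = None) -> "Trace":
        df = pd.read_csv(path)
        return cls(times=df["t_s"].to_numpy(float),
                   lengths=df["L_um"].to_numpy(float), label=label)


@dataclass(frozen=True)
class TraceStats:
    """Summary statistics of a length trace."""

    L_max: float
    L_min: float
    L_mean: float
    sd: float
    beta_hat: float          # um/sqrt(s), lag-1 quadratic-variation estimate
    n_tumbles: int
    T_P_mean: float | None   # s, mean complete-episode duration
    T_I_mean: float | None   # s, mean gap between consecutive episodes

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def make_prototype(stats: PhenotypeStats, duration: float,
                   grid: float = 120.0) -> PrototypeProfile:
    """Build the prototype target profile from measured statistics.

    REC/UEC: constant at ``L_mean``.  TEC: square wave starting in the
    tumbling (low) level, dwelling ``T_P`` at ``L_min`` and ``T_I`` at
    ``L_max``.
    """
    times = np.arange(0.0, duration + 0.5 * grid, grid)
    if stats.label in (REC, UEC):
        lengths = np.full_like(times, float(stats.L_mean))
    else:
        period = stats.T_P + stats.T_I
        phase = np.mod(times, period)
        lengths = np.where(phase < stats.T_P, stats.L_min, stats.L_max)
    return PrototypeProfile(label=stats.label, times=times, lengths=lengths)


def _ou_exact(n: int, frame: float, mean: float, alpha: float, sd: float,
              rng: np.random.Generator, x0: float | None = None) -> np.ndarray:
    """Exact-transition OU sample at frame resolution."""
    decay = math.exp(-alpha * frame)
    innov_sd = sd * math.sqrt(1.0 - decay * decay)
    x = np.empty(n)
    x[0] = mean if x0 is None else x0
    noise = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        x[i] = mean + (x[i - 1] - mean) * decay + innov_sd * noise[i - 1]
    return x


def synth_trace(stats: PhenotypeStats, duration: float = 86400.0,
                frame: float = 120.0, seed: int = 0,
                jitter: float | None = None) -> Trace:
    """Generate an experiment-like sampled length trace.

    REC/UEC: OU path around ``L_mean`` with diffusion ``stats.beta`` and
    reversion rate set so the stationary sd is ``(L_max - L_min)/4``
    (two sd on either side span the observed range), clipped to
    [L_min, L_max].  TEC: square wave whose low/high dwells are drawn
    uniformly on ``mean +- jitter`` (clipped to the experimental
    10 min - 4 h range; ``jitter=None`` uses the widest centered window,
    0 gives the exact periodic wave), with OU noise of sd 5 um on the
    elongated level.  Fully reproducible from ``seed``.
    """
    if frame < 1.0:
        raise ValueError("frame interval must be >= 1 s")
    rng = np.random.default_rng(seed)
    n = int(duration / frame) + 1
    times = frame * np.arange(n)

    if stats.label in (REC, UEC):
        sd = (stats.L_max - stats.L_min) / 4.0
        alpha = stats.beta**2 / (2.0 * sd**2)
        lengths = _ou_exact(n, frame, float(stats.L_mean), alpha, sd, rng)
        lengths = np.clip(lengths, stats.L_min, stats.L_max)
        return Trace(times=times, lengths=lengths, label=stats.label, seed=seed)

    lengths = np.empty(n)
    high_sd = 5.0
    high_alpha = stats.beta**2 / (2.0 * high_sd**2)
    decay = math.exp(-high_alpha * frame)
    innov = high_sd * math.sqrt(1.0 - decay * decay)
    i = 0
    low = True  # tumbling level first, matching TEC initial conditions
    wobble = 0.0
    while i < n:
        mean_dwell = stats.T_P if low else stats.T_I
        if jitter is None:
            half = min(mean_dwell - DWELL_RANGE[0], DWELL_RANGE[1] - mean_dwell)
        else:
            half = jitter
        half = max(0.0, half)
        dwell = rng.uniform(mean_dwell - half, mean_dwell + half)
        dwell = min(max(dwell, DWELL_RANGE[0]), DWELL_RANGE[1])
        n_frames = max(1, int(round(dwell / frame)))
        j = min(n, i + n_frames)
        if low:
            lengths[i:j] = stats.L_min
            wobble = 0.0
        else:
            for idx in range(i, j):
                wobble = wobble * decay + innov * rng.standard_normal()
                lengths[idx] = stats.L_max + wobble
        i = j
        low = not low
    lengths = np.clip(lengths, 1.0, None)
    return Trace(times=times, lengths=lengths, label=stats.label, seed=seed)


def _episodes(low: np.ndarray, min_frames: int = 2) -> list[tuple[int, int]]:
    """Maximal runs of True, as [start, end) index pairs, ignoring runs
    shorter than ``min_frames`` frames (noise robustness)."""
    runs: list[tuple[int, int]] = []
    n = len(low)
    i = 0
    while i < n:
        if low[i]:
            j = i
            while j < n and low[j]:
                j += 1
            if j - i >= min_frames:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def measure_trace(trace: Trace,
                  tumble_threshold: float = TUMBLE_THRESHOLD) -> TraceStats:
    """Extract summary statistics from a length trace.

    Tumbling episodes are maximal runs with ``L < tumble_threshold``;
    episodes touching a trace boundary are excluded from the duration
    means (their true extent is censored).  ``T_I_mean`` is the mean gap
    from one episode's end to the next episode's start.  ``beta_hat`` is
    the lag-1 quadratic-variation estimate sd(diff L)/sqrt(frame).
    """
    L = np.asarray(trace.lengths, dtype=float)
    if L.size < 2:
        raise ValueError("trace must have at least 2 frames")
    frame = trace.frame
    low = L < tumble_threshold
    eps = _episodes(low)
    n_tumbles = len(eps)

    complete = [(s, e) for (s, e) in eps if s > 0 and e < len(L)]
    T_P_mean = float(np.mean([(e - s) * frame for s, e in complete])) \
        if complete else None
    gaps = [(eps[k + 1][0] - eps[k][1]) * frame for k in range(len(eps) - 1)]
    T_I_mean = float(np.mean(gaps)) if gaps else None

    return TraceStats(
        L_max=float(L.max()), L_min=float(L.min()), L_mean=float(L.mean()),
        sd=float(L.std(ddof=1)),
        beta_hat=float(np.std(np.diff(L), ddof=1) / math.sqrt(frame)),
        n_tumbles=n_tumbles, T_P_mean=T_P_mean, T_I_mean=T_I_mean)


def classify_trace(stats: TraceStats, uec_length: float = 100.0) -> str:
    """Threshold phenotype classifier: any tumbling episode -> TEC;
    otherwise UEC if the mean length exceeds ``uec_length`` um, else REC."""
    if stats.n_tumbles >= 1:
        return TEC
    return UEC if stats.L_mean > uec_length else REC
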