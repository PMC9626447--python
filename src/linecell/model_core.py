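"""Parameters and algebraic kernels of the line-pattern cell-length model.

The model couples three state variables of a single endothelial cell
confined to an adhesive line:

``a``
    filamentous-actin (F-actin) concentration (mM), relaxing toward a
    homeostatic set point ``a_h`` at rate ``k`` and pulled down by an
    ATP-gated switching term ``a*K(c)``;
``L``
    cell length (um), an Ornstein-Uhlenbeck process set by the balance
    of a constant protrusion velocity ``v_p`` and an actin-dependent
    contractility ``sigma(a)*L``, with friction ``phi`` and length-noise
    amplitude ``beta``;
``c``
    intracellular ATP concentration (mM), produced toward its
    homeostatic level ``c_h`` at rate ``lam`` and released on stretch at
    rate ``S_max * R(L) * H(c)``, where ``H`` is a two-branch hysteresis
    relay.

This module holds the parameter containers, the four nonlinear kernels
(``K``, ``sigma``, ``R``, ``H``), the algebraic equilibria, and the
constraint-based derivation that turns measured length statistics into
the phenotype-specific rate constants.

Units are fixed globally: time s, length um, concentration mM.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping

import numpy as np
from scipy.optimize import bisect

__all__ = [
    "REC",
    "UEC",
    "TEC",
    "PHENOTYPES",
    "HysteresisBranch",
    "ActinParams",
    "LengthParams",
    "ATPParams",
    "ModelParameters",
    "PhenotypeStats",
    "BaseConstants",
    "actin_switch_rate",
    "contractility",
    "release_fraction",
    "hysteresis_value",
    "equilibrium_actin",
    "equilibrium_length",
    "derive_parameters",
    "rederive_smax",
    "set_parameter",
    "params_to_dict",
    "params_from_dict",
]

REC = "REC"  # running cell: constant, moderate length
UEC = "UEC"  # undecided cell: constant, highly elongated
TEC = "TEC"  # tumbling cell: periodic rounding/elongation
PHENOTYPES = (REC, UEC, TEC)


class HysteresisBranch(IntEnum):
    """Active branch of the ATP-release relay.

    RISING (``f1``) is traversed while ATP increases, FALLING (``f2``)
    while it decreases.  ``f2 >= f1`` everywhere, which is what makes the
    loop a hysteresis rather than a single curve.
    """

    RISING = 1
    FALLING = -1


class ParameterError(ValueError):
    """A parameter set violates a model invariant."""


class NoRootError(ValueError):
    """The contractility equation has no admissible F-actin root."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class ActinParams:
    """F-actin sub-system constants.

    ``a_min = k*a_h/(k+k1)`` and ``a_max = k*a_h/(k+k2)`` are the two
    equilibria selected by the ATP switch; ``k1 > k2`` so that low ATP
    (large ``K``) drives F-actin to its minimum.
    """

    k: float        # F-actin regulation rate (1/s)
    a_h: float      # homeostatic F-actin concentration (mM)
    k1: float       # convergence rate to a_min (1/s)
    k2: float       # convergence rate to a_max (1/s)
    M2: float       # dimensionless slope modulator of K(c)
    a_min: float    # minimum F-actin concentration (mM)
    a_max: float    # maximum F-actin concentration (mM)

    def __post_init__(self) -> None:
        _require(self.k > 0 and self.a_h > 0, "k and a_h must be positive")
        _require(self.k1 > self.k2 > 0, "need k1 > k2 > 0")
        _require(self.M2 > 0, "M2 must be positive")
        for name, val, rate in (("a_min", self.a_min, self.k1),
                                ("a_max", self.a_max, self.k2)):
            ref = self.k * self.a_h / (self.k + rate)
            _require(abs(val - ref) <= 1e-10 * ref,
                     f"{name} inconsistent with its rate constant")
        _require(0 < self.a_min < self.a_max <= self.a_h,
                 "need 0 < a_min < a_max <= a_h")


@dataclass(frozen=True)
class LengthParams:
    """Length sub-system constants.

    ``psi`` is constructed so that contractility is maximal exactly at
    ``a_min`` (which equals ``2*a_sat``), pinning the shortest
    equilibrium length to the measured ``L_min``.
    """

    v_p: float      # protrusion velocity (um/s)
    phi: float      # friction coefficient (dimensionless)
    psi: float      # contractility constant (1/(mM^2 s))
    a_sat: float    # actin saturation concentration (mM)
    beta: float     # length-noise amplitude (um/sqrt(s))
    L_min: float    # minimum length (um)
    L_max: float    # maximum length (um)

    def __post_init__(self) -> None:
        for name in ("v_p", "phi", "psi", "a_sat", "L_min", "L_max"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        _require(self.beta >= 0, "beta must be nonnegative")
        _require(self.L_min < self.L_max, "need L_min < L_max")


@dataclass(frozen=True)
class ATPParams:
    """ATP sub-system constants.

    ``c_L < c_eq < c_h`` are the relay thresholds: release dies at
    ``c_L`` on the falling branch and only re-engages above ``c_eq`` on
    the rising branch.
    """

    c_h: float      # homeostatic ATP concentration (mM)
    c_L: float      # minimum ATP threshold (mM)
    c_eq: float     # equilibrium ATP concentration (mM)
    lam: float      # ATP production rate (1/s)
    S_max: float    # maximal ATP release rate (mM/s)
    M1: float       # dimensionless release-shape coefficient
    M3: float       # hysteresis slope modulator (1/mM)

    def __post_init__(self) -> None:
        _require(self.c_L < self.c_eq < self.c_h, "need c_L < c_eq < c_h")
        _require(self.lam > 0, "lam must be positive")
        _require(self.S_max >= 0, "S_max must be nonnegative")
        _require(self.M1 > 0 and self.M3 > 0, "M1 and M3 must be positive")


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set for one phenotype."""

    actin: ActinParams
    length: LengthParams
    atp: ATPParams
    phenotype: str

    def __post_init__(self) -> None:
        _require(self.phenotype in PHENOTYPES,
                 f"unknown phenotype {self.phenotype!r}")


@dataclass(frozen=True)
class PhenotypeStats:
    """Measured per-phenotype length statistics.

    ``L_mean`` is defined for the constant-length phenotypes (REC, UEC);
    the tumbling-phase duration ``T_P`` and inter-tumble interval ``T_I``
    only for TEC.  ``beta`` is the standard deviation of length used as
    the noise amplitude of the length equation.
    """

    label: str
    n_cells: int
    L_max: float                    # um
    L_min: float                    # um
    L_mean: float | None = None     # um (REC/UEC only)
    T_P: float | None = None        # s (TEC only)
    T_I: float | None = None        # s (TEC only)
    beta: float = 0.0               # um/sqrt(s)

    def __post_init__(self) -> None:
        _require(self.label in PHENOTYPES, f"unknown phenotype {self.label!r}")
        _require(self.L_min < self.L_max, "need L_min < L_max")
        if self.label == TEC:
            _require(self.L_mean is None, "TEC stats carry no L_mean")
            _require(self.T_P is not None and self.T_I is not None,
                     "TEC stats require T_P and T_I")
            _require(self.T_P > 0 and self.T_I > 0, "durations must be positive")
        else:
            _require(self.L_mean is not None, f"{self.label} stats require L_mean")
            _require(self.L_min <= self.L_mean <= self.L_max,
                     "need L_min <= L_mean <= L_max")
            _require(self.T_P is None and self.T_I is None,
                     f"{self.label} stats carry no tumbling durations")

    @property
    def L_ref(self) -> float:
        """Target equilibrium length: L_max for TEC, L_mean otherwise."""
        return self.L_max if self.label == TEC else float(self.L_mean)


@dataclass(frozen=True)
class BaseConstants:
    """Literature constants shared by all phenotypes.

    ``a_min`` is the lower bound of the literature F-actin range and is
    shared across phenotypes.
    """

    k: float = 347.0        # F-actin regulation rate (1/s)
    a_h: float = 0.2        # homeostatic F-actin (mM)
    v_p: float = 25.0       # protrusion velocity (um/s)
    phi: float = 3e-2       # friction coefficient
    c_h: float = 10.0       # homeostatic ATP (mM)
    c_L: float = 1.0        # minimum ATP threshold (mM)
    a_min: float = 0.05     # minimum F-actin (mM)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def actin_switch_rate(c: float, p: ModelParameters) -> float:
    """ATP-dependent F-actin switching rate ``K(c)`` (1/s).

    ``K`` decreases from ``k1`` at c=0 to ``k2`` at and above the
    homeostatic ATP level ``c_h``, moving the F-actin equilibrium from
    ``a_min`` to ``a_max`` as ATP recovers.  ``M2`` sets how sharply the
    transition is localized near ``c_h`` (large ``M2`` approaches a step).
    """
    if not math.isfinite(c):
        raise ValueError("ATP concentration must be finite")
    if c < 0:
        raise ValueError("ATP concentration must be nonnegative")
    ap = p.actin
    c_h = p.atp.c_h
    if c >= c_h:
        return ap.k2
    return (ap.k1 - ap.k2) * math.exp(-c / (ap.M2 * (c_h - c))) + ap.k2


def contractility(a: float, p: ModelParameters) -> float:
    """Contractility ``sigma(a) = psi * a^2 * exp(-a/a_sat)`` (1/s).

    Quasi-quadratic in F-actin up to the network-compaction maximum at
    ``a = 2*a_sat``, exponentially decreasing beyond it.
    """
    if not math.isfinite(a):
        raise ValueError("F-actin concentration must be finite")
    if a < 0:
        raise ValueError("F-actin concentration must be nonnegative")
    lp = p.length
    return lp.psi * a * a * math.exp(-a / lp.a_sat)


def release_fraction(L: float, p: ModelParameters, xi: float = 1.0) -> float:
    """Stretch-induced ATP release gate ``R(L)`` in [0, 1].

    Sigmoidal in the relative extension ``L/L_min``; the base is clamped
    to [0, 1] before cubing so the gate never goes negative when
    ``L < L_min * xi``.  ``xi`` is the stretch offset (1 in deterministic
    runs).
    """
    if L <= 0:
        raise ValueError("length must be positive")
    z = p.atp.M1 * (L / p.length.L_min - xi)
    if z <= 0.0:  # below the stretch offset the (clamped) gate is closed
        return 0.0
    base = 1.0 - math.exp(-z)
    return base * base * base


def hysteresis_value(c: float, branch: HysteresisBranch,
                     p: ModelParameters) -> float:
    """Hysteresis relay ``H(c)`` on the given branch, in [0, 1].

    On the rising branch (``f1``) release is off below ``c_eq`` and
    saturates at ``c_h``; on the falling branch (``f2``) release stays
    maximal down to ``c_eq`` and dies at ``c_L``.  ``f2 >= f1``, so the
    loop is traversed counterclockwise in the (c, H) plane.
    """
    if c < 0:
        raise ValueError("ATP concentration must be nonnegative")
    atp = p.atp
    if branch == HysteresisBranch.RISING:
        if c <= atp.c_eq:
            return 0.0
        if c >= atp.c_h:
            return 1.0
        return math.exp(-(atp.c_h - c) / (atp.M3 * (c - atp.c_eq) ** 2))
    if c <= atp.c_L:
        return 0.0
    if c >= atp.c_eq:
        return 1.0
    return math.exp(-(atp.c_eq - c) / (atp.M3 * (c - atp.c_L) ** 2))


def equilibrium_actin(K_value: float, p: ModelParameters) -> float:
    """F-actin equilibrium ``k*a_h/(k + K)`` for a frozen switch rate."""
    if K_value < 0:
        raise ValueError("switch rate must be nonnegative")
    ap = p.actin
    return ap.k * ap.a_h / (ap.k + K_value)


def equilibrium_length(a: float, p: ModelParameters) -> float:
    """Deterministic length equilibrium ``v_p / sigma(a)`` (um).

    Minimal (``= L_min``) exactly when contractility is maximal, i.e. at
    ``a = a_min = 2*a_sat``.
    """
    if a == 0:
        raise ZeroDivisionError("length equilibrium undefined at zero F-actin")
    return p.length.v_p / contractility(a, p)


# ---------------------------------------------------------------------------
# Constraint-based parameter derivation
# ---------------------------------------------------------------------------

def derive_parameters(
    stats: PhenotypeStats,
    base: BaseConstants = BaseConstants(),
    *,
    lam: float,
    M1: float,
    M2: float,
    M3: float,
    c_eq: float,
) -> ModelParameters:
    """Derive the computed rate constants from length statistics.

    The chain inverts the equilibrium relations:

    1. ``k1 = k*(a_h - a_min)/a_min``  (F-actin minimum constraint);
    2. ``a_sat = a_min/2``             (contractility maximal at a_min);
    3. ``psi = v_p/(L_min * a_min^2 * e^-2)``  (pins sigma(a_min) to v_p/L_min);
    4. ``a_max`` = root of ``sigma(a) = v_p/L_ref`` on the decreasing
       branch ``a > 2*a_sat`` (L_ref = L_max for TEC, L_mean otherwise);
    5. ``k2 = k*(a_h - a_max)/a_max``;
    6. ``S_max = lam*(c_h - c_L)/R(L_max)``  (release balances production
       over one full discharge from c_h to c_L).

    The switching/relay shape coefficients ``M1, M2, M3, c_eq`` and the
    production rate ``lam`` are free (calibrated) inputs.
    """
    k, a_h = base.k, base.a_h
    a_min = base.a_min
    k1 = k * (a_h - a_min) / a_min
    a_sat = a_min / 2.0
    psi = base.v_p / (stats.L_min * a_min**2 * math.exp(-2.0))

    sigma_target = base.v_p / stats.L_ref

    def sigma(a: float) -> float:
        return psi * a * a * math.exp(-a / a_sat)

    sigma_peak = sigma(2.0 * a_sat)
    if sigma_target > sigma_peak:
        raise NoRootError(
            f"requested equilibrium length {stats.L_ref} um is below the "
            f"minimum attainable L_min = {stats.L_min} um")
    if sigma(a_h) > sigma_target:
        raise NoRootError("no F-actin root below the homeostatic level")
    # sigma is strictly decreasing on [2*a_sat, a_h]; bracket is guaranteed.
    a_max = float(bisect(lambda a: sigma(a) - sigma_target,
                         2.0 * a_sat, a_h, xtol=1e-12))
    k2 = k * (a_h - a_max) / a_max

    actin = ActinParams(k=k, a_h=a_h, k1=k1, k2=k2, M2=M2,
                        a_min=k * a_h / (k + k1), a_max=k * a_h / (k + k2))
    length = LengthParams(v_p=base.v_p, phi=base.phi, psi=psi, a_sat=a_sat,
                          beta=stats.beta, L_min=stats.L_min, L_max=stats.L_max)
    # R at full stretch with the deterministic offset xi = 1
    base_r = 1.0 - math.exp(-M1 * (stats.L_max / stats.L_min - 1.0))
    R_Lmax = min(max(base_r, 0.0), 1.0) ** 3
    if R_Lmax <= 0:
        raise NoRootError("release gate closed at L_max; cannot derive S_max")
    S_max = lam * (base.c_h - base.c_L) / R_Lmax
    atp = ATPParams(c_h=base.c_h, c_L=base.c_L, c_eq=c_eq, lam=lam,
                    S_max=S_max, M1=M1, M3=M3)
    return ModelParameters(actin=actin, length=length, atp=atp,
                           phenotype=stats.label)


def rederive_smax(p: ModelParameters) -> ModelParameters:
    """Return a copy with ``S_max`` re-derived from the current ``lam``.

    Keeps the discharge balance ``lam = S_max*R(L_max)/(c_h - c_L)``
    invariant after ``lam`` (or ``L_max``) changes.
    """
    R_Lmax = release_fraction(p.length.L_max, p)
    S_max = p.atp.lam * (p.atp.c_h - p.atp.c_L) / R_Lmax
    return dataclasses.replace(
        p, atp=dataclasses.replace(p.atp, S_max=S_max))


_PARAM_GROUP = {
    "k": "actin", "a_h": "actin", "k1": "actin", "k2": "actin",
    "M2": "actin", "a_min": "actin", "a_max": "actin",
    "v_p": "length", "phi": "length", "psi": "length", "a_sat": "length",
    "beta": "length", "L_min": "length", "L_max": "length",
    "c_h": "atp", "c_L": "atp", "c_eq": "atp", "lam": "atp",
    "S_max": "atp", "M1": "atp", "M3": "atp",
}


def set_parameter(p: ModelParameters, name: str, value: float) -> ModelParameters:
    """Return a copy of ``p`` with one named constant replaced.

    ``lam`` and ``L_max`` changes re-derive ``S_max`` so the discharge
    balance stays consistent.
    """
    try:
        group = _PARAM_GROUP[name]
    except KeyError:
        raise KeyError(f"unknown model parameter {name!r}") from None
    sub = dataclasses.replace(getattr(p, group), **{name: float(value)})
    out = dataclasses.replace(p, **{group: sub})
    if name in ("lam", "L_max"):
        out = rederive_smax(out)
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_FLAT_KEYS = ("k", "a_h", "k1", "k2", "M1", "M2", "M3", "c_h", "c_L", "c_eq",
              "lam", "S_max", "v_p", "phi", "psi", "a_sat", "beta",
              "L_min", "L_max")


def params_to_dict(p: ModelParameters) -> dict:
    """Flatten to the canonical key set (plus ``phenotype``)."""
    merged = {**dataclasses.asdict(p.actin), **dataclasses.asdict(p.length),
              **dataclasses.asdict(p.atp)}
    out = {key: merged[key] for key in _FLAT_KEYS}
    out["phenotype"] = p.phenotype
    return out


def params_from_dict(d: Mapping) -> ModelParameters:
    """Rebuild :class:`ModelParameters` from a flat mapping.

    ``a_min``/``a_max`` are recomputed from the rates so hand-edited
    configs cannot silently violate the equilibrium identities.
    """
    d = dict(d)
    phenotype = d.pop("phenotype")
    unknown = set(d) - set(_FLAT_KEYS)
    if unknown:
        raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
    missing = set(_FLAT_KEYS) - set(d)
    if missing:
        raise ParameterError(f"missing parameter keys: {sorted(missing)}")
    k, a_h = float(d["k"]), float(d["a_h"])
    actin = ActinParams(k=k, a_h=a_h, k1=float(d["k1"]), k2=float(d["k2"]),
                        M2=float(d["M2"]),
                        a_min=k * a_h / (k + float(d["k1"])),
                        a_max=k * a_h / (k + float(d["k2"])))
    length = LengthParams(v_p=float(d["v_p"]), phi=float(d["phi"]),
                          psi=float(d["psi"]), a_sat=float(d["a_sat"]),
                          beta=float(d["beta"]), L_min=float(d["L_min"]),
                          L_max=float(d["L_max"]))
    atp = ATPParams(c_h=float(d["c_h"]), c_L=float(d["c_L"]),
                    c_eq=float(d["c_eq"]), lam=float(d["lam"]),
                    S_max=float(d["S_max"]), M1=float(d["M1"]),
                    M3=float(d["M3"]))
    return ModelParameters(actin=actin, length=length, atp=atp,
                           phenotype=phenotype)


def params_to_json(p: ModelParameters) -> str:
    return json.dumps(params_to_dict(p), indent=2, sort_keys=True)


def params_from_json(text: str) -> ModelParameters:
    return params_from_dict(json.loads(text))


def params_set_to_yaml(params: Mapping[str, ModelParameters]) -> str:
    """Serialize several parameter sets, one YAML section per phenotype."""
    import yaml

    doc = {}
    for label, p in params.items():
        d = params_to_dict(p)
        d.pop("phenotype")
        doc[label] = d
    return yaml.safe_dump(doc, sort_keys=True)


def params_set_from_yaml(text: str) -> dict[str, ModelParameters]:
    """Inverse of :func:`params_set_to_yaml`."""
    import yaml

    doc = yaml.safe_load(text)
    out = {}
    for label, d in doc.items():
        out[label] = params_from_dict({**d, "phenotype": label})
    return out
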