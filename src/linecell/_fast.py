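"""Compiled inner loop of the IMEX / Euler-Maruyama integrator.

Parameters travel as a flat float64 vector so the stepping kernel stays
njit-compilable; :data:`PV_LAYOUT` documents the slot order and
:func:`pack_params` builds the vector from a ModelParameters instance.
The scalar step :func:`step` is the single source of truth for the
update map; both the Python-facing ``imex_step`` and the trajectory loop
call it.
"""

from __future__ import annotations

import numpy as np
from numba import njit

PV_LAYOUT = ("k", "a_h", "k1", "k2", "M2", "a_sat", "psi", "v_p", "phi",
             "beta", "L_min", "c_h", "c_L", "c_eq", "lam", "S_max",
             "M1", "M3")

(_K, _AH, _K1, _K2, _M2, _ASAT, _PSI, _VP, _PHI, _BETA, _LMIN,
 _CH, _CL, _CEQ, _LAM, _SMAX, _M1, _M3) = range(18)

OK, BLOWUP_A, BLOWUP_L, BLOWUP_C = 0, 1, 2, 3


def pack_params(p) -> np.ndarray:
    """Flatten ModelParameters into the PV_LAYOUT vector."""
    a, ln, at = p.actin, p.length, p.atp
    return np.array([a.k, a.a_h, a.k1, a.k2, a.M2, ln.a_sat, ln.psi,
                     ln.v_p, ln.phi, ln.beta, ln.L_min, at.c_h, at.c_L,
                     at.c_eq, at.lam, at.S_max, at.M1, at.M3],
                    dtype=np.float64)


@njit(cache=True)
def switch_rate(c, pv):
    if c >= pv[_CH]:
        return pv[_K2]
    return (pv[_K1] - pv[_K2]) * np.exp(-c / (pv[_M2] * (pv[_CH] - c))) + pv[_K2]


@njit(cache=True)
def sigma_of(a, pv):
    return pv[_PSI] * a * a * np.exp(-a / pv[_ASAT])


@njit(cache=True)
def release_gate(L, xi, pv):
    z = pv[_M1] * (L / pv[_LMIN] - xi)
    if z <= 0.0:  # clamped: gate closed below the stretch offset
        return 0.0
    base = 1.0 - np.exp(-z)
    return base * base * base


@njit(cache=True)
def relay(c, branch, pv):
    if branch > 0:  # rising, f1
        if c <= pv[_CEQ]:
            return 0.0
        if c >= pv[_CH]:
            return 1.0
        d = c - pv[_CEQ]
        return np.exp(-(pv[_CH] - c) / (pv[_M3] * d * d))
    if c <= pv[_CL]:  # falling, f2
        return 0.0
    if c >= pv[_CEQ]:
        return 1.0
    d = c - pv[_CL]
    return np.exp(-(pv[_CEQ] - c) / (pv[_M3] * d * d))


@njit(cache=True)
def step(a, L, c, branch, pv, dt, dW, xi, stall_tol):
    """One IMEX step: sequential a -> L -> c update, then branch logic.

    Each sub-update is implicit in its own (stiff, linear) variable and
    explicit in the switching functions K and H, so every sub-step is an
    unconditionally stable scalar solve.  The hysteresis branch follows
    the sign of the ATP drift; when the drift magnitude on the current
    branch drops below ``stall_tol`` the relay is considered exhausted
    and the branch flips (relay completion).
    """
    K = switch_rate(c, pv)
    a_new = (a + dt * pv[_K] * pv[_AH]) / (1.0 + dt * (pv[_K] + K))
    sig = sigma_of(a_new, pv)
    L_new = (L + dt * pv[_VP] / pv[_PHI] + pv[_BETA] * dW) / \
        (1.0 + dt * sig / pv[_PHI])
    R = release_gate(L_new, xi, pv)
    H = relay(c, branch, pv)
    release = pv[_SMAX] * R * H
    drift = pv[_LAM] * (pv[_CH] - c) - release
    c_new = (c + dt * (pv[_LAM] * pv[_CH] - release)) / (1.0 + dt * pv[_LAM])
    if abs(drift) < stall_tol:
        branch = -branch
    elif c_new > c:
        branch = 1
    elif c_new < c:
        branch = -1
    return a_new, L_new, c_new, branch


@njit(cache=True)
def integrate(pv, a0, L0, c0, branch0, dt, n_steps, record_every,
              stall_tol, stochastic, xi_noise_scale, seed):
    """Run ``n_steps`` steps, recording every ``record_every``-th state.

    In stochastic mode the generator is seeded once and draws, per step,
    the length-noise increment dW ~ N(0, dt) and then (only if
    ``xi_noise_scale > 0``) a standard normal for the release-gate
    offset, in that order.
    """
    m = n_steps // record_every + 1
    t_out = np.empty(m)
    a_out = np.empty(m)
    L_out = np.empty(m)
    c_out = np.empty(m)
    b_out = np.empty(m, dtype=np.int8)
    if stochastic:
        np.random.seed(seed)
    sqrt_dt = np.sqrt(dt)
    a, L, c, branch = a0, L0, c0, branch0
    j = 0
    status = OK
    bad_step = -1
    for i in range(n_steps + 1):
        if i % record_every == 0:
            t_out[j] = i * dt
            a_out[j] = a
            L_out[j] = L
            c_out[j] = c
            b_out[j] = branch
            j += 1
        if i == n_steps:
            break
        dW = 0.0
        xi = 1.0
        if stochastic:
            dW = sqrt_dt * np.random.normal()
            if xi_noise_scale > 0.0:
                xi = 1.0 + xi_noise_scale * np.random.normal()
        a, L, c, branch = step(a, L, c, branch, pv, dt, dW, xi, stall_tol)
        if not np.isfinite(a):
            status = BLOWUP_A
        elif not np.isfinite(L):
            status = BLOWUP_L
        elif not np.isfinite(c):
            status = BLOWUP_C
        if status != OK:
            bad_step = i + 1
            break
    return t_out[:j], a_out[:j], L_out[:j], c_out[:j], b_out[:j], status, bad_step


@njit(cache=True)
def ou_endpoints(n_paths, n_steps, dt, L0, alpha, mu, beta, seed):
    """Terminal values of ``n_paths`` implicit Euler-Maruyama OU paths.

    Same discretization as the length sub-update with frozen
    contractility: L' = (L + dt*alpha*mu + beta*dW) / (1 + dt*alpha).
    """
    np.random.seed(seed)
    out = np.empty(n_paths)
    denom = 1.0 + dt * alpha
    drift = dt * alpha * mu
    sqrt_dt = np.sqrt(dt)
    for k in range(n_paths):
        L = L0
        for _ in range(n_steps):
            L = (L + drift + beta * sqrt_dt * np.random.normal()) / denom
        out[k] = L
    return out
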