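# Methods

`linecell` models the length dynamics of a single endothelial cell
confined to a narrow adhesive line, where three migration phenotypes are
observed: running cells (REC) with a constant, moderate length;
undecided cells (UEC) with a constant, much larger length; and
tumbling-like cells (TEC) that alternate periodically between an
elongated state and a rounded ("tumbling") state.  The model's premise
is that these profiles are selected by intracellular ATP dynamics alone.

## Governing equations

State variables: F-actin concentration `a` (mM), cell length `L` (um),
intracellular ATP concentration `c` (mM).  Units are globally fixed to
seconds, micrometers and millimolar.

```
da/dt = k (a_h - a) - a K(c)
dL/dt = (v_p - sigma(a) L) / phi + beta xi(t)
dc/dt = lam (c_h - c) - S_max R(L) H(c)
```

* `K(c) = (k1 - k2) exp(-c / (M2 (c_h - c))) + k2` for `c < c_h`, else
  `k2`.  The switch moves the F-actin equilibrium `k a_h / (k + K)`
  from `a_min` (low ATP, `K -> k1`) to `a_max` (high ATP, `K -> k2`).
  `M2` sets how sharply the transition localizes near `c_h`.
* `sigma(a) = psi a^2 exp(-a / a_sat)` is the contractility:
  quasi-quadratic up to the network-compaction maximum at `a = 2 a_sat`,
  decreasing beyond.  Deterministic length equilibria satisfy
  `L = v_p / sigma(a)`; because `sigma` is maximal at
  `a_min = 2 a_sat`, the minimum length `L_min` is attained exactly at
  minimum F-actin.  With noise, `L` is an Ornstein-Uhlenbeck process
  with reversion rate `alpha = sigma/phi` and mean `mu = v_p/sigma`.
* `R(L) = clamp(1 - exp(-M1 (L/L_min - xi)), 0, 1)^3` gates
  stretch-induced ATP release; `xi = 1` in all reported runs (a
  stochastic offset is available but disabled by default).
* `H(c)` is a two-branch hysteresis relay: the rising branch `f1` is 0
  below `c_eq`, saturating at `c_h`; the falling branch `f2` stays 1
  down to `c_eq` and dies at `c_L`.  `f2 >= f1` everywhere, so the
  (c, H) loop is traversed rather than retraced.

## Parameter derivation

Literature constants: `k = 347 /s`, `a_h = 0.2 mM`, `v_p = 25 um/s`,
`phi = 3e-2`, `c_h = 10 mM`, `c_L = 1 mM`, and the F-actin range lower
bound `a_min = 0.05 mM` (shared by all phenotypes).  From the measured
length statistics (per phenotype: `L_min`, `L_max`, and `L_mean` for
REC/UEC or `T_P`, `T_I` for TEC) the code derives:

1. `k1 = k (a_h - a_min)/a_min = 1041 /s`;
2. `a_sat = a_min / 2`;
3. `psi = v_p / (L_min a_min^2 e^-2)` (pins `sigma(a_min)` to
   `v_p/L_min`);
4. `a_max`: root of `sigma(a) = v_p / L_ref` on the decreasing branch
   `a > 2 a_sat` (`L_ref` is `L_max` for TEC, `L_mean` otherwise;
   bisection, absolute tolerance 1e-12 mM);
5. `k2 = k (a_h - a_max)/a_max`;
6. `S_max = lam (c_h - c_L) / R(L_max)`: the release rate that balances
   production over one full discharge from `c_h` to `c_L`.  `S_max` is
   re-derived automatically whenever `lam` or `L_max` changes.

The derivation reproduces the published constants (TEC/REC/UEC
`k2 = 142.3/404.3/352.1 /s` against printed 142.2/404/351.8).  The UEC
contractility constant printed as 752 /mM^2/s is inconsistent with the
`L_min` constraint, which gives 725.1, and with the printed
`k2 = 351.8` (consistent only with 725.1); the recomputed value is used
and the printed one retained in `tables.py` for the audit trail.

The remaining coefficients (`M1`, `M2`, `M3`, `lam`, `c_eq`) are
calibrated quantities; their baseline values are bundled per phenotype.

## Numerical scheme

One-step IMEX: within each step the updates run `a -> L -> c`, each
implicit in its own variable and explicit in `K` and `H`:

```
a' = (a + dt k a_h) / (1 + dt (k + K(c)))
L' = (L + dt v_p/phi + beta dW) / (1 + dt sigma(a')/phi)
c' = (c + dt (lam c_h - S_max R(L') H(c, branch))) / (1 + dt lam)
```

Every sub-update is a stable scalar solve, so the stiff linear parts
(`k + K` up to ~1400 /s, `sigma/phi` up to ~60 /s) impose no step-size
restriction.  The reference step is `dt = 1e-3 s`; production runs,
sweeps and the acceptance script use `dt = 1e-2 s`, validated by the
convergence tests (REC/UEC lengths agree pointwise to <0.5% between the
two steps; TEC threshold-crossing times agree to a few seconds).  In
stochastic mode `dW ~ N(0, dt)` is drawn once per step from a
generator seeded per simulation; identical seed and configuration give
bit-identical trajectories.  The compiled (numba) loop and the
Python-facing single step share one scalar kernel.

### Relay branch semantics

The branch follows the sign of the ATP drift.  The smooth two-branch
relay has a structural subtlety: on the rising branch, production
`lam (c_h - c)` always crosses the release onset `S_max f1(c)` at an
attracting equilibrium a fraction of a percent below `c_h` (for the
baseline TEC set, ~0.005 mM below), and a mirror-image equilibrium sits
just below `c_eq` on the falling branch.  A branch that simply holds at
zero drift therefore parks there forever and the deterministic system
never oscillates, for any parameter values.  We close the model with a
*relay-completion* rule: when the drift magnitude on the active branch
falls below `stall_tol` (default 1e-10 mM/s), the branch is considered
exhausted and flips.  The stall tolerance is a model-closure constant,
not a tuning knob: it must sit well below the dynamical drift scale
`lam (c_h - c_L)` (~1e-2 mM/s) and high enough that the drift is
resolvable above double-precision rounding at the working step sizes;
within that window it affects only the logarithmic dwell the cell
spends at peak ATP before release overcomes production.  Because the
discrete fixed point of the implicit update coincides with the exact
balance point for every `dt`, the completion time is nearly
dt-independent, which is what makes the tumbling period converge under
step refinement.

Two consequences are documented rather than hidden.  First, for REC/UEC
parameter sets the ATP level does not sit at a strict equilibrium but
cycles slowly within ~8-10 mM; length is unaffected because the small
`M2` decouples `K(c)` from ATP over that range (REC length stays within
0.1% of 50.1 um over 12 h).  Second, a TEC-shaped parameter set
(`M2 = 6.4`, `M3 = 1e-5`) keeps cycling even at high `c_eq`; the
constant-length regime at the REC/UEC corner of the phase diagram comes
from the small `M2` there, and a genuinely constant-at-minimum state at
large `M2` requires `M3` of order 1 (smooth hysteresis confining the
ATP cycle to a low window where `L ~ L_min`).

### Baseline deterministic results (12 h, dt = 1e-2 s, 2 h discard)

* TEC: sustained oscillation, `L in [13.11, 64.17] um`;
  tumbling phase `T_P ~ 70.4 min`, interval `T_I ~ 131.9 min`
  (the length threshold for "tumbling" is 20 um).
* REC: constant `50.1 um`; UEC: constant `185.5 um`.
* Bounds `c in [c_L, c_h]`, `a in [a_min, a_max]` hold throughout.

Initial conditions: TEC starts rounded (`a_min`, `L_min`); REC/UEC
start at their elongated equilibrium; ATP starts at the intermediate
value `(c_h + c_L)/2 = 5.5 mM`.  Steady-state results are insensitive
to the ATP start; transients are not.

## Synthetic traces ("statistical cell")

`make_prototype` builds the idealized target profile: constant `L_mean`
for REC/UEC, and for TEC a square wave starting in the tumbling level
(dwells `T_P` at `L_min`, `T_I` at `L_max`).  `synth_trace` emulates
time-lapse measurements (2-min frames, 12-24 h):

* REC/UEC: an exact-transition OU path around `L_mean` with diffusion
  `beta` and reversion rate chosen so the stationary sd equals
  `(L_max - L_min)/4` (two sd either side span the observed range),
  clipped to `[L_min, L_max]`.
* TEC: a square wave whose dwells are drawn uniformly on
  `mean +- jitter`, clipped to the experimentally observed 10 min - 4 h
  range (default jitter: the widest centered window; 0 recovers the
  exact periodic wave), plus OU noise of sd 5 um on the elongated
  level only (3 sd clear of the 20-um threshold).

What the generator does *not* emulate: measurement error of the manual
length annotation, cell collisions or phenotype switching, frame drops,
or any correlation between successive dwell durations.  Tests passing
on these traces therefore validate the estimators and classifier
against the assumed noise model, not against raw microscopy.

`measure_trace` recovers extrema, mean, sd, the diffusion amplitude
(lag-1 quadratic variation, `sd(diff L)/sqrt(frame)` -- valid when the
frame interval is short against `1/alpha`; at 2-min frames this holds
for slowly reverting traces), and tumbling episodes: maximal runs below
20 um, runs shorter than 2 frames ignored, boundary-censored episodes
excluded from duration means, `T_I` measured end-of-episode to
next-start.  A threshold classifier (any episode -> TEC, else mean
length over 100 um -> UEC, else REC) recovers generator labels on
>= 95% of seeded traces.

## Calibration

The objective is the discrete L2 norm between the deterministic
simulated length and the target profile on the target grid
(`J = sqrt(sum_i (L(theta, t_i) - L_s(t_i))^2 * dt_grid)`); an optional
feature objective (relative mismatch in oscillation min/max and
`T_P`/`T_I`) is provided for periodic targets where the norm is
phase-sensitive.  Integrator failures map to a large finite penalty.
The optimizer is standard global-best PSO (inertia 0.72, cognitive =
social = 1.49, positions clipped to bounds), reproducible from its
seed.  Default search bounds: `M1 in [10, 1e5]`, `M2 in [1e-3, 1e2]`,
`M3 in [1e-6, 1e-2]`, `lam in [1e-5, 1e-2] /s`,
`c_eq in (c_L, c_h)`.  Phenotype presets follow the original study
design: TEC frees `(M1, M2, lam, c_eq)` with `M3` fixed at `1e-5`;
REC/UEC free `(M1, M2, M3, c_eq)` with `lam` fixed to the TEC value.
Calibration runs at `dt = 1e-2 s` on the non-stochastic system.

Identifiability note: `lam` scales both production and (through the
discharge-balance constraint on `S_max`) release, so it acts as a pure
time scale of the ATP cycle; timing features alone leave a
one-parameter degeneracy among `(lam, c_eq, M2)` that the full-profile
L2 objective resolves through the transition shapes.  The recovery test
frees `(c_eq, lam, M2)` against an 8-h simulated tumbling target
(swarm 16, 40 iterations).

## Sensitivity and phase diagram

One-at-a-time sweeps run deterministically at `dt = 1e-2 s` over 12 h
with a 2-h transient discard.  Regime labels: `tumbling` (>= 2
threshold crossings after the discard), `constant` (relative length
variation < 1% after the discard and in the first hour), else
`constant_with_transient` (settled late but moved > 10% early).  The
1%/2-crossing thresholds are configuration, chosen to separate the
three baseline parameter sets robustly.  Reported sweep quantities:
oscillation extrema and `T_P`/`T_I` over complete cycles when tumbling;
the post-discard mean length and mean ATP otherwise (the ATP "steady
level" is reported as a time average because of the residual ATP
cycling noted above).

Reproduced trends: oscillation frequency increases with `lam` (exact
time-scaling) and with `c_eq`; tumbling-phase duration increases with
`M2` (a sharper switch keeps the cell short over a wider ATP range);
steady ATP decreases with `M3`; tumbling occupies intermediate `c_eq`
(present across [1.5, 5.5] mM at `M2 = 6.4`, `M3 = 1e-5`) and is absent
at the REC/UEC parameter corner.

## Known limitations

* The tumbling period's `T_I` component includes the relay-completion
  dwell; with the default stall tolerance the simulated `T_I` sits
  ~14% below the measured 2 h 33 min (the tumbling phase `T_P` is
  within 5%).  The dwell depends logarithmically on the stall
  tolerance, which we fix a priori rather than fit.
* Tumbling is strictly periodic; the experimentally observed dwell
  variability (10 min - 4 h) is emulated only by the synthetic-trace
  generator, not by the deterministic model.
* No cell polarization, migration, or division; length is the only
  geometric variable.
* F-actin and ATP trajectories are model predictions without direct
  experimental counterparts; only length is calibrated.
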