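"""Kernels, equilibria and the constraint-based parameter derivation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from linecell import tables
from linecell.model_core import (
    REC,
    TEC,
    UEC,
    BaseConstants,
    HysteresisBranch,
    NoRootError,
    ParameterError,
    PhenotypeStats,
    actin_switch_rate,
    contractility,
    derive_parameters,
    equilibrium_actin,
    equilibrium_length,
    hysteresis_value,
    params_from_dict,
    params_from_json,
    params_to_dict,
    params_to_json,
    release_fraction,
    rederive_smax,
    set_parameter,
)

RISING, FALLING = HysteresisBranch.RISING, HysteresisBranch.FALLING
ALL = (REC, UEC, TEC)


# ---------------------------------------------------------------------------
# K(c): the ATP-gated F-actin switch
# ---------------------------------------------------------------------------

class TestActinSwitchRate:
    def test_equals_k2_at_and_above_homeostasis(self, params):
        for p in params.values():
            assert actin_switch_rate(p.atp.c_h, p) == p.actin.k2
            assert actin_switch_rate(p.atp.c_h + 3.0, p) == p.actin.k2

    @pytest.mark.parametrize("c, expected", [
        # direct evaluation of the switch formula with the derived TEC set
        (2.26, 1000.9212553657238),
        (9.0, 362.56529031123773),
    ])
    def test_frozen_values_tec(self, params, c, expected):
        assert actin_switch_rate(c, params[TEC]) == pytest.approx(
            expected, rel=1e-12)

    def test_continuous_at_homeostasis(self, params):
        for p in params.values():
            just_below = actin_switch_rate(p.atp.c_h - 1e-9, p)
            assert abs(just_below - p.actin.k2) < 1e-8 * p.actin.k1

    @settings(max_examples=200, derandomize=True)
    @given(c=st.floats(0.0, 15.0), dc=st.floats(1e-6, 1.0))
    def test_bounded_and_nonincreasing(self, params, c, dc):
        p = params[TEC]
        k_lo, k_hi = actin_switch_rate(c + dc, p), actin_switch_rate(c, p)
        assert p.actin.k2 <= k_lo <= k_hi <= p.actin.k1

    def test_rejects_bad_input(self, params):
        with pytest.raises(ValueError):
            actin_switch_rate(float("nan"), params[TEC])
        with pytest.raises(ValueError):
            actin_switch_rate(-1.0, params[TEC])


# ---------------------------------------------------------------------------
# sigma(a): contractility
# ---------------------------------------------------------------------------

class TestContractility:
    def test_zero_at_zero_actin(self, params):
        assert contractility(0.0, params[TEC]) == 0.0

    def test_peak_pins_minimum_length(self, params):
        # sigma(a_min) = v_p / L_min is forced by the psi construction
        for label, p in params.items():
            v = contractility(p.actin.a_min, p)
            assert v == pytest.approx(p.length.v_p / p.length.L_min, rel=1e-12)

    def test_value_at_tec_a_max(self, params):
        p = params[TEC]
        # cross-check: sigma(a_max) must equal v_p / L_max = 25 / 64.1
        assert contractility(p.actin.a_max, p) == pytest.approx(
            25.0 / 64.1, rel=1e-9)

    def test_single_interior_maximum_at_twice_a_sat(self, params):
        p = params[TEC]
        grid = np.linspace(1e-4, p.actin.a_h, 4001)
        vals = np.array([contractility(a, p) for a in grid])
        peak = grid[np.argmax(vals)]
        assert peak == pytest.approx(2.0 * p.length.a_sat, abs=1e-4)
        # unimodal: increasing then decreasing
        d = np.diff(vals)
        switch = np.flatnonzero(np.diff(np.sign(d)))
        assert len(switch) == 1


# ---------------------------------------------------------------------------
# R(L): stretch-induced release gate
# ---------------------------------------------------------------------------

class TestReleaseFraction:
    def test_closed_at_minimum_length(self, params):
        for p in params.values():
            assert release_fraction(p.length.L_min, p) == 0.0

    def test_saturates_at_twice_minimum(self, params):
        p = params[TEC]  # M1 = 7.4e4 -> exp(-7.4e4) underflows
        assert release_fraction(2.0 * p.length.L_min, p) == 1.0

    def test_asymptote_and_monotonicity(self, params):
        for p in params.values():
            assert release_fraction(1e9, p) == 1.0
            grid = np.linspace(0.5 * p.length.L_min, 3.0 * p.length.L_min, 500)
            vals = [release_fraction(L, p) for L in grid]
            assert all(0.0 <= v <= 1.0 for v in vals)
            assert np.all(np.diff(vals) >= 0.0)

    def test_clamped_below_stretch_offset(self, params):
        # L < L_min * xi would make the base negative; the gate stays 0
        assert release_fraction(5.0, params[TEC], xi=1.0) == 0.0


# ---------------------------------------------------------------------------
# H(c): hysteresis relay
# ---------------------------------------------------------------------------

class TestHysteresis:
    def test_rising_branch_endpoints(self, params):
        for p in params.values():
            assert hysteresis_value(p.atp.c_eq, RISING, p) == 0.0
            assert hysteresis_value(0.3, RISING, p) == 0.0
            assert hysteresis_value(p.atp.c_h, RISING, p) == 1.0

    def test_falling_branch_frozen_value_tec(self, params):
        # exponent ~ -1.6e5 at c = 1.63: zero within double precision
        assert hysteresis_value(1.63, FALLING, params[TEC]) == 0.0

    def test_rising_branch_frozen_value_rec(self, params):
        # exp(-0.9351/(8.5e-4*0.8649)) at c = 9: zero within double precision
        assert hysteresis_value(9.0, RISING, params[REC]) == 0.0

    @pytest.mark.parametrize("label", ALL)
    def test_branch_order_and_monotonicity(self, params, label):
        p = params[label]
        grid = np.linspace(0.0, p.atp.c_h + 1.0, 2000)
        f1 = np.array([hysteresis_value(c, RISING, p) for c in grid])
        f2 = np.array([hysteresis_value(c, FALLING, p) for c in grid])
        assert np.all((0.0 <= f1) & (f1 <= 1.0))
        assert np.all((0.0 <= f2) & (f2 <= 1.0))
        assert np.all(f2 - f1 >= -1e-15)
        assert np.all(np.diff(f1) >= -1e-12)
        assert np.all(np.diff(f2) >= -1e-12)

    def test_branch_continuity_at_patch_points(self, params):
        for p in params.values():
            eps = 1e-10
            # f1 at c_eq and c_h; f2 at c_L and c_eq
            assert hysteresis_value(p.atp.c_eq + eps, RISING, p) < 1e-8
            assert hysteresis_value(p.atp.c_h - eps, RISING, p) > 1.0 - 1e-4
            assert hysteresis_value(p.atp.c_L + eps, FALLING, p) < 1e-8
            assert hysteresis_value(p.atp.c_eq - eps, FALLING, p) > 1.0 - 1e-4


# ---------------------------------------------------------------------------
# Equilibria
# ---------------------------------------------------------------------------

class TestEquilibria:
    def test_actin_equilibrium_published_minimum(self, params):
        # k = 347, a_h = 0.2, K = k1 -> a_min = 5e-2 mM
        p = params[TEC]
        assert equilibrium_actin(p.actin.k1, p) == pytest.approx(0.05,
                                                                 rel=1e-9)

    def test_actin_equilibrium_limits(self, params):
        p = params[REC]
        assert equilibrium_actin(0.0, p) == p.actin.a_h
        # frozen: 69.4 / 489.2 with the printed TEC k2
        assert equilibrium_actin(142.2, params[TEC]) == pytest.approx(
            0.14186426819296813, rel=1e-12)

    def test_length_equilibrium_constraints(self, params):
        for label, p in params.items():
            assert equilibrium_length(p.actin.a_min, p) == pytest.approx(
                p.length.L_min, rel=1e-12)
            L_ref = tables.STATS[label].L_ref
            assert equilibrium_length(p.actin.a_max, p) == pytest.approx(
                L_ref, rel=1e-6)

    def test_length_equilibrium_is_floor(self, params):
        p = params[TEC]
        for a in np.linspace(0.01, p.actin.a_h, 200):
            assert equilibrium_length(a, p) >= p.length.L_min - 1e-9

    def test_zero_actin_raises(self, params):
        with pytest.raises(ZeroDivisionError):
            equilibrium_length(0.0, params[TEC])


# ---------------------------------------------------------------------------
# derive_parameters
# ---------------------------------------------------------------------------

class TestDeriveParameters:
    def test_reproduces_published_constants(self, params):
        # closed-form k1 and the root-found k2 per phenotype
        expected_k2 = {TEC: 142.2, REC: 404.0, UEC: 351.8}
        for label, p in params.items():
            assert p.actin.k1 == pytest.approx(1.04e3, rel=5e-3)
            assert p.actin.k2 == pytest.approx(expected_k2[label], rel=5e-3)
        assert params[TEC].length.psi == pytest.approx(5.6e3, rel=0.01)
        assert params[REC].length.psi == pytest.approx(2.4e3, rel=0.021)
        # UEC psi from the L_min constraint (printed 752 is inconsistent)
        assert params[UEC].length.psi == pytest.approx(725.1, rel=1e-3)

    def test_smax_from_discharge_balance(self, params):
        # lam * (c_h - c_L) / R(L_max) with R(L_max) = 1 to machine precision
        for p in params.values():
            assert p.atp.S_max == pytest.approx(7.875e-3, rel=1e-12)

    def test_roundtrip_on_length_statistics(self, params):
        # re-derive (L_min, L_ref) from the derived parameters: identity
        for label, p in params.items():
            assert equilibrium_length(p.actin.a_min, p) == pytest.approx(
                tables.STATS[label].L_min, rel=1e-6)
            a_back = equilibrium_actin(p.actin.k2, p)
            assert equilibrium_length(a_back, p) == pytest.approx(
                tables.STATS[label].L_ref, rel=1e-6)

    def test_unattainable_length_raises(self):
        stats = PhenotypeStats(label=REC, n_cells=1, L_max=40.0, L_min=31.4,
                               L_mean=35.0, beta=1.6)
        # ask for an equilibrium below L_min via a doctored base constant
        base = BaseConstants()
        bad = PhenotypeStats(label=REC, n_cells=1, L_max=200.0, L_min=150.0,
                             L_mean=160.0, beta=1.6)
        ok = derive_parameters(stats, base, **tables.OPTIMIZED[REC])
        assert ok.actin.a_max > ok.actin.a_min
        with pytest.raises(NoRootError):
            # L_ref smaller than L_min is impossible by construction, so
            # emulate it through a tiny protrusion-to-length ratio
            derive_parameters(bad, BaseConstants(v_p=25.0, a_min=0.199),
                              **tables.OPTIMIZED[REC])

    def test_invariant_validation(self, params):
        with pytest.raises(ParameterError):
            set_parameter(params[TEC], "c_eq", 12.0)  # violates c_eq < c_h
        with pytest.raises(KeyError):
            set_parameter(params[TEC], "nope", 1.0)

    def test_set_lam_rederives_smax(self, params):
        p2 = set_parameter(params[TEC], "lam", 1.75e-3)
        assert p2.atp.S_max == pytest.approx(2 * 7.875e-3, rel=1e-12)
        assert rederive_smax(p2).atp.S_max == p2.atp.S_max


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

class TestSerialization:
    @pytest.mark.parametrize("label", ALL)
    def test_roundtrip(self, params, label):
        p = params[label]
        assert params_from_dict(params_to_dict(p)) == p
        assert params_from_json(params_to_json(p)) == p

    def test_unknown_key_rejected(self, params):
        d = params_to_dict(params[TEC])
        d["bogus"] = 1.0
        with pytest.raises(ParameterError):
            params_from_dict(d)

    def test_missing_key_rejected(self, params):
        d = params_to_dict(params[TEC])
        d.pop("psi")
        with pytest.raises(ParameterError):
            params_from_dict(d)

    def test_yaml_sections_roundtrip(self, params):
        from linecell.model_core import params_set_from_yaml, params_set_to_yaml
        text = params_set_to_yaml(params)
        back = params_set_from_yaml(text)
        assert back == params
        for label in params:
            assert f"{label}:" in text
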