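"""Unit and property tests for the subcellular chemistry module."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from episkin import kinetics as K
from episkin.kinetics import (
    ChemParams,
    ChemState,
    PHModel,
    RateConstants,
    ScalingSpec,
    batch_chem_rhs,
    chem_rhs,
    estimate_cnd_concentration,
    estimate_enzyme_concentration,
    initial_chem_state,
    integrate_chem,
    integrate_chem_batch,
    klk_lekti_rates,
    ph_at,
    scale_rates,
    simulate_single_cell,
)

from conftest import random_chem_states

ZERO_RATES = RateConstants(k_plus1=0.0, k_minus1=0.0, k_2=0.0, K_M=0.0,
                           a3=0.0, b3=0.0, A3=0.0)


# ---------------------------------------------------------------------------
# pH model
# ---------------------------------------------------------------------------

class TestPH:
    def test_intercept(self):
        assert ph_at(0.0) == pytest.approx(6.8482, abs=1e-12)

    def test_surface_value(self):
        # sum of the four polynomial coefficients
        assert ph_at(1.0) == pytest.approx(4.4846, abs=1e-10)

    def test_midpoint(self):
        # direct polynomial evaluation
        expected = 6.8482 - 0.3765 * 0.5 - 5.1663 * 0.25 + 3.1792 * 0.125
        assert ph_at(0.5) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(5.7658, abs=1e-4)

    def test_clamping(self):
        assert ph_at(-2.0) == ph_at(0.0)
        assert ph_at(7.5) == ph_at(1.0)

    def test_monotone_decreasing(self):
        xi = np.linspace(0, 1, 501)
        ph = ph_at(xi)
        assert np.all(np.diff(ph) < 0)
        assert ph_at(0.0) > ph_at(1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ph_at(float("nan"))

    def test_vectorised(self):
        out = ph_at(np.array([0.0, 1.0]))
        assert out.shape == (2,)


# ---------------------------------------------------------------------------
# rate constants
# ---------------------------------------------------------------------------

class TestRates:
    def test_kp3_root_floor(self):
        kp3, _ = klk_lekti_rates(3.75)
        assert kp3 == 0.0

    def test_kp3_at_base_ph(self):
        kp3, _ = klk_lekti_rates(6.8482)
        assert kp3 == pytest.approx(1.611e8, rel=1e-3)

    def test_km3_at_base_ph(self):
        _, km3 = klk_lekti_rates(6.8482)
        assert km3 == pytest.approx(2.75e-3, rel=1e-3)

    def test_nonnegative_over_physiological_range(self):
        for ph in np.linspace(4.4, 7.0, 27):
            kp3, km3 = klk_lekti_rates(ph)
            assert kp3 >= 0 and km3 >= 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            klk_lekti_rates(2.0)

    def test_michaelis_invariant_enforced(self):
        with pytest.raises(ValueError, match="Michaelis"):
            RateConstants(k_plus1=1e7, k_2=2.29e3, K_M=4.6e-5)

    def test_default_michaelis_consistent(self):
        r = RateConstants()
        assert (r.k_minus1 + r.k_2) / r.k_plus1 == pytest.approx(r.K_M, rel=5e-3)


class TestScaling:
    def test_table_values(self, single_cell_rates):
        scaled = scale_rates(single_cell_rates, ScalingSpec())
        assert ScalingSpec().lam == pytest.approx(3.0)
        assert scaled.k_2 == pytest.approx(6.87e3, rel=1e-3)
        assert scaled.k_plus1 == pytest.approx(1.49e8, rel=1e-3)

    def test_scaled_rate_function_coefficients(self, single_cell_rates):
        scaled = scale_rates(single_cell_rates, ScalingSpec())
        assert scaled.a3 == pytest.approx(15.6, rel=1e-12)
        assert scaled.b3 == pytest.approx(58.5, rel=1e-12)
        assert scaled.A3 == pytest.approx(6.9e6, rel=1e-12)

    def test_invariants_unchanged(self, single_cell_rates):
        scaled = scale_rates(single_cell_rates, ScalingSpec())
        assert scaled.K_M == single_cell_rates.K_M
        assert scaled.B3 == single_cell_rates.B3

    def test_identity_scaling(self, single_cell_rates):
        spec = ScalingSpec(T_M=160.0)  # T_hat = 160 -> lam = 1
        assert scale_rates(single_cell_rates, spec) == single_cell_rates

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            ScalingSpec(tau_T=-1.0)


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

class TestInitialConditions:
    def test_fully_inhibited(self, multiscale_rates):
        st0 = initial_chem_state(ChemParams(1e-5, 1e-10, 1e-10), multiscale_rates)
        assert (st0.e, st0.s, st0.i, st0.c_s, st0.c_i, st0.p) == (0, 1, 0, 0, 1, 0)

    def test_no_inhibitor(self, multiscale_rates):
        st0 = initial_chem_state(ChemParams(1e-5, 1e-10, 0.0), multiscale_rates)
        # 0.8218 from table-rounded k_plus1 = 1.49e8; exact rates give 0.82167
        assert st0.e == pytest.approx(0.8218, abs=2e-4)
        assert st0.c_s == pytest.approx(0.1782, abs=2e-4)

    def test_half_inhibited(self, multiscale_rates):
        st0 = initial_chem_state(ChemParams(1e-5, 1e-10, 0.5e-10), multiscale_rates)
        assert st0.e == pytest.approx(0.4109, abs=1e-4)
        assert st0.c_i == pytest.approx(0.5)
        assert st0.c_s == pytest.approx(0.0891, abs=1e-4)

    def test_conservation_at_t0(self, multiscale_rates):
        params = ChemParams(1e-5, 1e-10, 0.3e-10)
        st0 = initial_chem_state(params, multiscale_rates)
        st0.check(params, tol=1e-9)

    def test_degenerate_enzyme_warns(self, multiscale_rates):
        with pytest.warns(UserWarning):
            st0 = initial_chem_state(ChemParams(1e-5, 0.0, 0.0), multiscale_rates)
        assert st0.e == st0.c_s == st0.c_i == 0.0

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ChemParams(1e-5, 1e-10, 2e-10)  # i_T > e_T
        with pytest.raises(ValueError):
            ChemParams(-1e-5, 1e-10, 0.0)


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

class TestRHS:
    def test_zero_rates_zero_derivative(self):
        params = ChemParams(1e-5, 1e-10, 0.5e-10)
        state = ChemState(0.2, 0.7, 1e-6, 0.3, 0.5, 0.1)
        assert np.all(chem_rhs(state, params, ZERO_RATES, 5.5) == 0.0)

    def test_single_surviving_term(self, single_cell_rates):
        # e = s = 1, everything else 0: de/dt = -k_plus1 * s_0
        params = ChemParams(1e-5, 0.7e-6, 0.0)
        state = ChemState(1.0, 1.0, 0.0, 0.0, 0.0, 0.0)
        d = chem_rhs(state, params, single_cell_rates, 6.8482)
        assert d[0] == pytest.approx(-497.0, rel=1e-10)

    @given(e=st.floats(0, 1), s=st.floats(0, 1), i=st.floats(0, 1e-5),
           cs=st.floats(0, 1), ci=st.floats(0, 1), ph=st.floats(4.0, 7.0))
    @settings(max_examples=50, deadline=None)
    def test_conservation_sums_vanish(self, e, s, i, cs, ci, ph):
        params = ChemParams(1e-5, 1e-10, 1e-10)
        state = ChemState(e, s, i, cs, ci, 0.0)
        d = chem_rhs(state, params, K.MULTISCALE_RATES, ph)
        eps = params.eps
        assert d[0] + d[3] + d[4] == pytest.approx(0.0, abs=1e-9)
        assert d[1] + eps * d[3] + d[5] == pytest.approx(0.0, abs=1e-12)
        assert d[2] + eps * d[4] == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def rk4_oracle(y0, params, rates, ph, duration, n_steps):
    """Fixed-step classical RK4, independent of the production integrators."""
    a = rates.k_plus1 * params.s_0
    b = rates.k_minus1 + rates.k_2
    kp3, km3 = rates.k_plus3(ph), rates.k_minus3(ph)
    q, m = kp3 * params.s_0, km3
    eps, k2, km1 = params.eps, rates.k_2, rates.k_minus1
    h = duration / n_steps
    y = np.array(y0, dtype=float)[None, :]
    for _ in range(n_steps):
        k1 = batch_chem_rhs(y, a, b, q, m, eps, k2, km1)
        k2_ = batch_chem_rhs(y + 0.5 * h * k1, a, b, q, m, eps, k2, km1)
        k3 = batch_chem_rhs(y + 0.5 * h * k2_, a, b, q, m, eps, k2, km1)
        k4 = batch_chem_rhs(y + h * k3, a, b, q, m, eps, k2, km1)
        y = y + (h / 6.0) * (k1 + 2 * k2_ + 2 * k3 + k4)
    return y[0]


class TestIntegrateChem:
    def test_no_enzyme_leaves_s_unchanged(self, multiscale_rates):
        params = ChemParams(1e-5, 0.0, 0.0)
        state = ChemState(0.0, 1.0, 0.0, 0.0, 0.0, 0.0)
        out = integrate_chem(state, params, multiscale_rates, 6.0, dt=5.0)
        assert out.s == 1.0
        assert out.t == pytest.approx(5.0)

    def test_locked_inhibitor_freezes_state(self):
        # i_T = e_T with no dissociation (A3 = 0): all enzyme stays complexed
        rates = RateConstants(A3=0.0)
        params = ChemParams(1e-5, 1e-10, 1e-10)
        state = initial_chem_state(params, rates)
        out = integrate_chem(state, params, rates, 5.0, dt=2.0)
        np.testing.assert_allclose(out.as_array(), state.as_array(), atol=1e-12)

    def test_matches_rk4_oracle(self, multiscale_rates, rng):
        params = ChemParams(1e-5, 1e-10, 1e-10)
        states = random_chem_states(rng, 4, params, multiscale_rates)
        for y0 in states:
            ph = float(rng.uniform(4.5, 6.8))
            ref = rk4_oracle(y0, params, multiscale_rates, ph, 1.0, 10_000)
            out = integrate_chem(ChemState.from_array(y0), params,
                                 multiscale_rates, ph, dt=1.0,
                                 rtol=1e-8, atol=1e-10)
            np.testing.assert_allclose(out.as_array(), ref, atol=2e-4, rtol=1e-3)

    def test_batch_matches_scalar(self, multiscale_rates, rng):
        params = ChemParams(1e-5, 1e-10, 0.6e-10)
        Y = random_chem_states(rng, 6, params, multiscale_rates)
        ph = rng.uniform(4.5, 6.8, 6)
        out = Y.copy()
        for _ in range(12):  # 12 steps of 1/120 hr
            out = integrate_chem_batch(out, params, multiscale_rates, ph, 1 / 120)
        for k in range(6):
            ref = integrate_chem(ChemState.from_array(Y[k]), params,
                                 multiscale_rates, float(ph[k]), dt=0.1,
                                 rtol=1e-10, atol=1e-12)
            # random (non-equilibrated) states put first-order error in the
            # fast boundary layer; smooth-trajectory accuracy is ~1e-4
            # (test_conservation_along_trajectory + acceptance runs)
            np.testing.assert_allclose(out[k], ref.as_array(), atol=2e-3)

    def test_conservation_along_trajectory(self, multiscale_rates, rng):
        params = ChemParams(1e-5, 1e-10, 1e-10)
        Y = random_chem_states(rng, 8, params, multiscale_rates)
        ph = rng.uniform(4.5, 6.8, 8)
        res0 = [ChemState.from_array(y).conservation_residuals(params) for y in Y]
        out = Y.copy()
        for _ in range(240):
            out = integrate_chem_batch(out, params, multiscale_rates, ph, 1 / 120)
        for y, r0 in zip(out, res0):
            r = ChemState.from_array(y).conservation_residuals(params)
            assert max(abs(a - b) for a, b in zip(r, r0)) < 1e-5

    def test_invalid_dt(self, multiscale_rates):
        state = ChemState(0, 1, 0, 0, 0, 0)
        with pytest.raises(ValueError):
            integrate_chem(state, ChemParams(), multiscale_rates, 6.0, dt=0.0)


class TestSingleCell:
    def test_flat_trajectory_without_enzyme(self, single_cell_rates):
        df = simulate_single_cell(0.0, 24.0, ChemParams(1e-5, 0.0, 0.0),
                                  single_cell_rates)
        assert np.all(df.s == 1.0)
        assert np.all(df.xi == 0.0)

    def test_literature_run_degrades_within_a_day(self, single_cell_rates):
        df = simulate_single_cell(0.05, 24.0, K.LITERATURE_CHEM, single_cell_rates)
        assert df.s.iloc[-1] < 0.05

    def test_effective_run_majority_degraded_by_20_days(self, single_cell_rates):
        df = simulate_single_cell(0.05, 480.0, K.EFFECTIVE_CHEM, single_cell_rates)
        assert df.s.iloc[-1] < 0.5

    def test_s_monotone_p_monotone(self, single_cell_rates):
        df = simulate_single_cell(0.05, 480.0, K.EFFECTIVE_CHEM, single_cell_rates)
        assert np.all(np.diff(df.s) <= 1e-12)
        assert np.all(np.diff(df.p) >= -1e-12)

    def test_monotone_inhibition(self, single_cell_rates):
        # reducing i_T never increases s at fixed t
        s_24 = []
        for f in (1.0, 0.5, 0.0):
            params = ChemParams(1e-5, 0.7e-6, f * 0.7e-6)
            df = simulate_single_cell(0.05, 24.0, params, single_cell_rates)
            s_24.append(df.s.iloc[-1])
        assert s_24[0] >= s_24[1] >= s_24[2]

    def test_time_rescaling_equivalence(self, single_cell_rates):
        # scaled rates over T/lam with a compressed xi schedule reproduce the
        # unscaled trajectory over T
        spec = ScalingSpec()  # lam = 3
        scaled = scale_rates(single_cell_rates, spec)
        full = simulate_single_cell(0.05, 480.0, K.EFFECTIVE_CHEM,
                                    single_cell_rates, sample_dt=480.0)
        fast = simulate_single_cell(0.05 * spec.lam, 160.0, K.EFFECTIVE_CHEM,
                                    scaled, sample_dt=160.0)
        np.testing.assert_allclose(
            fast.iloc[-1][["e", "s", "i", "c_s", "c_i", "p"]].to_numpy(),
            full.iloc[-1][["e", "s", "i", "c_s", "c_i", "p"]].to_numpy(),
            atol=1e-4)

    def test_invalid_inputs(self, single_cell_rates):
        with pytest.raises(ValueError):
            simulate_single_cell(-0.1, 24.0, K.EFFECTIVE_CHEM, single_cell_rates)
        with pytest.raises(ValueError):
            simulate_single_cell(0.05, 0.0, K.EFFECTIVE_CHEM, single_cell_rates)


# ---------------------------------------------------------------------------
# concentration estimation
# ---------------------------------------------------------------------------

class TestConcentrations:
    def test_published_enzyme_estimate(self):
        c = estimate_enzyme_concentration(3.1, 33.0, 0.5, 0.13)
        assert c == pytest.approx(0.723e-6, rel=1e-3)

    def test_enzyme_linearity(self):
        c1 = estimate_enzyme_concentration(3.1, 33.0, 0.5, 0.13)
        c2 = estimate_enzyme_concentration(6.2, 33.0, 0.5, 0.13)
        assert c2 == pytest.approx(2 * c1)

    def test_enzyme_halved_by_double_extracellular_water(self):
        c = estimate_enzyme_concentration(3.1, 33.0, 0.5, 0.26)
        assert c == pytest.approx(0.361e-6, rel=2e-3)

    def test_enzyme_invalid(self):
        with pytest.raises(ValueError):
            estimate_enzyme_concentration(3.1, 33.0, 0.5, 1.5)
        with pytest.raises(ValueError):
            estimate_enzyme_concentration(-1.0, 33.0, 0.5, 0.13)

    def test_cnd_zero_density(self):
        assert estimate_cnd_concentration(0.0, 0.0, 30.0, 0.3, 0.044) == 0.0

    def test_cnd_linearity(self):
        c1 = estimate_cnd_concentration(16, 10, 30, 0.3, 0.044)
        c2 = estimate_cnd_concentration(32, 20, 30, 0.3, 0.044)
        assert c2 == pytest.approx(2 * c1)

    def test_cnd_geometry_oracle(self):
        # independent hand calculation: counts over the half-gap volume
        side = 4 * 30 * 0.3          # side face area, um^2
        faces = 2 * 30 * 30          # top + bottom, um^2
        count = 16 * side + 10 * faces
        volume_l = (side + faces) * 0.022 * 1e-15
        expected = count / (6.02214076e23 * volume_l)
        c = estimate_cnd_concentration(16, 10, 30, 0.3, 0.044)
        assert c == pytest.approx(expected, rel=1e-12)
        # the published 6.6 uM figure is NOT reproduced by this geometry
        assert not (6.0e-6 < c < 7.2e-6)

    def test_cnd_invalid_gap(self):
        with pytest.raises(ValueError):
            estimate_cnd_concentration(16, 10, 30, 0.3, 0.0)
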