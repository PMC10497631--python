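"""Box-model recursion, steady-state algebra and forward simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cl36soil as cs
from cl36soil.data_model import Species, ValidationError
from cl36soil.forcing import PulseShape, build_forcing
from cl36soil.massbalance import simulate_cl36_ensemble

BOUNDS = np.array([0.0, 5.0, 15.0, 30.0, 45.0, 60.0])


class TestRootAbsorptionWeights:
    def test_closed_form_surface_layer(self):
        w = cs.root_absorption_weights(BOUNDS, 15.0)
        expected = (1 - math.exp(-1 / 3)) / (1 - math.exp(-4))
        assert w[0] == pytest.approx(expected, rel=1e-12)
        assert w[0] == pytest.approx(0.2888, abs=2e-4)

    @settings(deadline=None, derandomize=True)
    @given(z0=st.floats(0.5, 500.0))
    def test_weights_sum_to_one(self, z0):
        w = cs.root_absorption_weights(BOUNDS, z0)
        assert w.sum() == pytest.approx(1.0, rel=1e-12)
        assert np.all(w >= 0)

    def test_deep_efolding_limit_is_thickness_proportional(self):
        w = cs.root_absorption_weights(BOUNDS, 1e7)
        thickness = np.diff(BOUNDS)
        np.testing.assert_allclose(w, thickness / thickness.sum(), rtol=1e-5)

    def test_nonpositive_efolding_rejected(self):
        with pytest.raises(ValidationError):
            cs.root_absorption_weights(BOUNDS, 0.0)


class TestClInputCascade:
    def test_no_uptake_gives_uniform_input(self):
        inp = cs.cl_input_cascade(100.0, 0.0, np.zeros(5))
        np.testing.assert_allclose(inp, 100.0)

    def test_sequential_subtraction(self):
        inp = cs.cl_input_cascade(90.0, 10.0, np.array([4.0, 3, 2, 1, 0]))
        np.testing.assert_allclose(inp, [100, 96, 93, 91, 90])

    def test_deepest_drainage_returns_rainfall(self):
        # telescoping: D_5 = I_5 - A_5 = R, chloride in = chloride out
        a = np.array([4.0, 3, 2, 1, 0])
        inp = cs.cl_input_cascade(90.0, 10.0, a)
        assert inp[-1] - a[-1] == pytest.approx(90.0)

    def test_closure_violation_rejected(self):
        with pytest.raises(ValidationError, match="litterfall"):
            cs.cl_input_cascade(90.0, 10.0, np.array([4.0, 3, 2, 1, 5]))


class TestSteadyAlgebra:
    def test_unit_residence_time(self):
        assert cs.residence_time(50.0, 50.0) == pytest.approx(1.0)

    def test_retention_duration_and_release_fraction(self):
        t_r, x = 9.0, 0.045
        s, i = t_r * 100.0, 100.0
        assert cs.retention_duration(s, x, i) == pytest.approx(200.0)
        assert cs.z_from_x(x, t_r) == pytest.approx(0.005)

    def test_full_retention_identity(self):
        assert cs.retention_duration(100.0, 1.0, 10.0) == pytest.approx(
            cs.residence_time(100.0, 10.0)
        )

    def test_zero_x_flagged_infinite(self):
        with pytest.raises(ValidationError, match="infinite"):
            cs.retention_duration(100.0, 0.0, 10.0)

    def test_infeasible_release_fraction_rejected(self):
        with pytest.raises(ValidationError, match="Z"):
            cs.z_from_x(0.9, 0.5)

    def test_initial_stock_multiplication(self):
        assert cs.initial_cl36_stock(1e5, 50.0) == pytest.approx(5e6)
        assert cs.initial_cl36_stock(0.0, 50.0) == 0.0

    def test_initial_stock_preserves_isotope_ratio(self):
        # no fractionation: S0(36)/S0(Cl) = I(36)/I(Cl)
        t_r = 37.0
        i36, icl = 2e5, 8e12
        assert cs.initial_cl36_stock(i36, t_r) / cs.initial_cl36_stock(icl, t_r) \
            == pytest.approx(i36 / icl, rel=1e-12)


class TestStepLayer:
    def test_hand_arithmetic(self):
        s_new, d, clamped = cs.step_layer(100.0, 50.0, 0.2, 0.1, 5.0)
        assert (s_new, d, clamped) == (100.0, 45.0, False)
        # conservation: I = dS + D + A
        assert 50.0 == pytest.approx((s_new - 100.0) + d + 5.0)

    def test_inert_layer_passes_input_through(self):
        s_new, d, _ = cs.step_layer(77.0, 30.0, 0.0, 0.0, 4.0)
        assert s_new == 77.0
        assert d == pytest.approx(26.0)

    def test_fixed_point(self):
        x, z, i = 0.2, 0.05, 40.0
        s_star = x * i / z
        s_new, _, _ = cs.step_layer(s_star, i, x, z, 0.0)
        assert s_new == pytest.approx(s_star, rel=1e-12)

    def test_clamped_drainage_flagged(self):
        _, d, clamped = cs.step_layer(0.0, 10.0, 0.0, 0.0, 50.0)
        assert clamped and d == 0.0

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        s=st.floats(0, 1e6), i=st.floats(0, 1e5), x=st.floats(0, 1),
        z=st.floats(0, 1), a=st.floats(0, 10.0),
    )
    def test_conservation_identity(self, s, i, x, z, a):
        s_new, d, clamped = cs.step_layer(s, i, x, z, a)
        if not clamped:
            resid = i - ((s_new - s) + d + a)
            assert abs(resid) <= 1e-9 * max(i, 1.0)


class TestSimulate:
    def test_conservation_over_full_grid(self, truth, steady, scenario):
        state = cs.simulate(cs.ModelParams(x=truth.x_true), steady, scenario)
        assert state.conservation_residual() <= 1e-9

    def test_constant_forcing_keeps_stocks_constant(self, truth, steady):
        flat = build_forcing(
            {Species.CL36: truth.config.background_cl36,
             Species.CL: truth.config.background_cl},
            pulse=PulseShape(amplitude=0.0),
            start_year=1940, end_year=2020,
        )
        state = cs.simulate(cs.ModelParams(x=truth.x_true), steady, flat)
        for sp in Species:
            s = state.stocks[sp]
            drift = np.abs(s - s[:, [0]]) / s[:, [0]]
            assert drift.max() < 1e-10

    def test_constant_forcing_steady_for_random_feasible_x(self, truth, steady, rng):
        flat = build_forcing(
            {Species.CL36: truth.config.background_cl36,
             Species.CL: truth.config.background_cl},
            pulse=PulseShape(amplitude=0.0),
        )
        for _ in range(5):
            x = rng.uniform(0, 1, size=5) * np.minimum(steady.t_r, 1.0) * 0.999
            state = cs.simulate(cs.ModelParams(x=x), steady, flat)
            s36 = state.stocks[Species.CL36]
            assert (np.abs(s36 - s36[:, [0]]) / s36[:, [0]]).max() < 1e-10

    def test_attractor_reached_geometrically_from_arbitrary_stock(self):
        # S* = I*T_R independent of X; approach at rate (1 - Z)
        x, t_r, i = 0.3, 5.0, 100.0
        z = cs.z_from_x(x, t_r)
        s_star = i * t_r
        s = 4200.0
        for t in range(1, 30):
            s, _, _ = cs.step_layer(s, i, x, z, 0.0)
            expected = s_star + (1 - z) ** t * (4200.0 - s_star)
            assert s == pytest.approx(expected, rel=1e-12)

    def test_single_layer_post_pulse_matches_geometric_closed_form(self, truth):
        cfg = truth.config
        steady1 = cs.derive_steady_state(
            s_cl=np.array([3.0 * (1.11 * cfg.background_cl)]),
            rainfall_cl=cfg.background_cl,
            litterfall_cl=0.11 * cfg.background_cl,
            boundaries_cm=np.array([0.0, 60.0]),
        )
        scen = truth.scenario()
        x = np.array([0.02])
        state = cs.simulate(cs.ModelParams(x=x), steady1, scen)
        z = cs.z_from_x(x, steady1.t_r)[0]
        i0 = scen.index_of(1972)
        s0 = state.stocks[Species.CL36][0, i0]
        i36 = scen.total_input(Species.CL36)[scen.index_of(2000)]
        s_star = i36 * steady1.t_r[0]
        for year in range(1973, 2021):
            t = year - 1972
            expected = s_star + (1 - z) ** t * (s0 - s_star)
            got = state.stocks[Species.CL36][0, scen.index_of(year)]
            assert abs(got - expected) / expected <= 1e-9

    def test_start_year_insensitivity(self, truth, steady):
        cfg = truth.config
        stocks = {}
        for start in (1910, 1940):
            scen = build_forcing(
                {Species.CL36: cfg.background_cl36, Species.CL: cfg.background_cl},
                pulse=cfg.pulse, start_year=start, end_year=2020,
            )
            state = cs.simulate(cs.ModelParams(x=truth.x_true), steady, scen)
            stocks[start] = state.stock_at(Species.CL36, 2010)
        rel = np.abs(stocks[1910] - stocks[1940]) / stocks[1940]
        assert rel.max() < 1e-9

    def test_relaxation_time_approximates_retention_duration(self):
        # e-folding -1/ln(1-Z) -> T' as Z -> 0; first-order agreement Z < 0.05
        for z in (0.005, 0.02, 0.05):
            t_prime = 1.0 / z  # with T_R/X = 1/Z by construction
            efold = -1.0 / math.log1p(-z)
            assert efold == pytest.approx(t_prime, rel=z)

    def test_root_depth_distribution_has_minor_impact(self, truth):
        cfg = truth.config
        scen = truth.scenario()
        results = []
        for z0 in (8.0, 15.0, 40.0):
            steady = cs.derive_steady_state(
                truth.t_r_true * truth._i_cl(),
                cfg.background_cl, 0.11 * cfg.background_cl,
                np.array(cfg.boundaries_cm), z0_cm=z0,
            )
            state = cs.simulate(cs.ModelParams(x=truth.x_true, z0_cm=z0),
                                steady, scen)
            results.append(state.stock_at(Species.CL36, 2010))
        spread = np.ptp(results, axis=0) / np.mean(results, axis=0)
        assert spread.max() < 0.05

    def test_ensemble_kernel_agrees_with_reference_simulation(self, truth, steady):
        scen = truth.scenario().slice(1940, 2010)
        state = cs.simulate(cs.ModelParams(x=truth.x_true), steady, scen)
        ref = state.stock_at(Species.CL36, 2010)
        s, clamps = simulate_cl36_ensemble(
            truth.x_true[None, :], steady.t_r, steady.inputs, steady.absorption,
            scen.rainfall[Species.CL36], scen.litterfall(Species.CL36),
        )
        assert clamps == 0
        np.testing.assert_allclose(s[0], ref, rtol=1e-10)

    def test_negative_intermediate_aborts_with_diagnostics(self, truth, steady):
        with pytest.raises(ValidationError):
            cs.simulate(cs.ModelParams(x=np.full(5, 0.99)), steady,
                        truth.scenario())
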