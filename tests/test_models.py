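"""Model construction and exact ZOH simulation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hrid import make_model, simulate, step_response, dc_gain
from hrid.errors import DomainError, ParameterError
from hrid.models import STRUCTURES, n_states
from hrid.synthetic import PRBSConfig, generate_prbs

from conftest import TM_LIKE_PARAMS


class TestMakeModel:
    def test_table_parameters_accepted(self):
        for structure, params in TM_LIKE_PARAMS.items():
            model = make_model(structure, params)
            assert model.free_values() == pytest.approx(params)

    def test_constrained_parameters_held_at_zero(self):
        model = make_model("P1", {"k": 28.6, "tau1": 70.6})
        assert model.Td == 0.0 and model.Tz == 0.0 and model.tau2 == 0.0

    @pytest.mark.parametrize("structure,params", [
        ("P1", {"k": 1, "tau1": 10, "Td": 5}),       # Td not free for P1
        ("P1D", {"k": 1, "tau1": 10}),               # Td missing
        ("P2Z", {"k": 1, "tau1": 1, "tau2": 2}),     # Tz missing
        ("XX", {"k": 1}),                            # unknown structure
    ])
    def test_missing_or_extra_parameter_rejected(self, structure, params):
        with pytest.raises(ParameterError):
            make_model(structure, params)

    @pytest.mark.parametrize("params", [
        {"k": 1, "tau1": -3, "tau2": 5},
        {"k": 1, "tau1": 3, "tau2": -5},
    ])
    def test_negative_time_constant_rejected(self, params):
        with pytest.raises(DomainError):
            make_model("P2", params)

    def test_negative_dead_time_rejected(self):
        with pytest.raises(DomainError):
            make_model("P1D", {"k": 1, "tau1": 10, "Td": -1})

    def test_negative_zero_time_constant_allowed(self):
        model = make_model("P2Z", {"k": 1, "tau1": 10, "tau2": 20, "Tz": -15})
        assert model.Tz == -15.0


class TestSimulate:
    def test_first_order_step_closed_form(self):
        model = make_model("P1", {"k": 1.0, "tau1": 10.0})
        y = step_response(model, 1.0, 50.0, 5.0)
        t = np.arange(len(y)) * 5.0
        np.testing.assert_allclose(y, 1.0 - np.exp(-t / 10.0), rtol=1e-12)

    def test_delayed_step_is_zero_then_shifted(self):
        model = make_model("P1D", {"k": 25.0, "tau1": 47.7, "Td": 13.1})
        h = 0.1
        y = step_response(model, 1.0, 200.0, h)
        t = np.arange(len(y)) * h
        expected = np.where(t > 13.1,
                            25.0 * (1.0 - np.exp(-(t - 13.1) / 47.7)), 0.0)
        np.testing.assert_allclose(y, expected, atol=1e-9)
        # one time constant past the dead time: 63.2 % of the 25 bpm gain
        i = int(round((13.1 + 47.7) / h))
        assert y[i] == pytest.approx(25.0 * (1 - np.exp(-1)), abs=1e-6)

    def test_zero_input_zero_state_gives_zero_output(self):
        for structure, params in TM_LIKE_PARAMS.items():
            y = simulate(make_model(structure, params), np.zeros(50), 5.0)
            assert np.all(y == 0.0)

    @given(st.integers(0, 2**31 - 1), st.sampled_from(sorted(STRUCTURES)))
    def test_linearity(self, seed, structure):
        rng = np.random.default_rng(seed)
        u = rng.normal(size=80)
        v = rng.normal(size=80)
        a, b = rng.normal(size=2)
        model = make_model(structure, TM_LIKE_PARAMS[structure])
        lhs = simulate(model, a * u + b * v, 5.0)
        rhs = a * simulate(model, u, 5.0) + b * simulate(model, v, 5.0)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-9)

    @pytest.mark.parametrize("m", [0, 1, 3])
    def test_whole_sample_delay_is_a_shift(self, m, tm_prbs_input):
        u = tm_prbs_input[:120]
        delayed = make_model("P1D", {"k": 25.0, "tau1": 47.7, "Td": m * 5.0})
        plain = make_model("P1", {"k": 25.0, "tau1": 47.7})
        y_d = simulate(delayed, u, 5.0)
        y_0 = simulate(plain, u, 5.0)
        np.testing.assert_allclose(y_d[m:], y_0[:len(u) - m], rtol=1e-12)
        assert np.all(y_d[:m] == 0.0)

    def test_structure_reductions(self, tm_prbs_input):
        u = tm_prbs_input[:120]
        h = 5.0
        p2zd = make_model("P2ZD", {"k": 2.0, "tau1": 20.0, "tau2": 45.0,
                                   "Tz": 0.0, "Td": 0.0})
        p2 = make_model("P2", {"k": 2.0, "tau1": 20.0, "tau2": 45.0})
        np.testing.assert_allclose(simulate(p2zd, u, h), simulate(p2, u, h),
                                   rtol=1e-9, atol=1e-9)
        p2_deg = make_model("P2", {"k": 2.0, "tau1": 30.0, "tau2": 0.0})
        p1 = make_model("P1", {"k": 2.0, "tau1": 30.0})
        np.testing.assert_allclose(simulate(p2_deg, u, h),
                                   simulate(p1, u, h), rtol=1e-9, atol=1e-9)
        par = make_model("P1parP1D", {"kp1": 0.0, "taup1": 100.0,
                                      "kp2": 20.2, "taup2": 34.3, "Td": 17.9})
        p1d = make_model("P1D", {"k": 20.2, "tau1": 34.3, "Td": 17.9})
        np.testing.assert_allclose(simulate(par, u, h), simulate(p1d, u, h),
                                   rtol=1e-9, atol=1e-9)

    def test_parallel_is_sum_of_branches(self, tm_prbs_input):
        u = tm_prbs_input[:200]
        params = TM_LIKE_PARAMS["P1parP1D"]
        par = make_model("P1parP1D", params)
        branch1 = make_model("P1", {"k": params["kp1"], "tau1": params["taup1"]})
        branch2 = make_model("P1D", {"k": params["kp2"],
                                     "tau1": params["taup2"],
                                     "Td": params["Td"]})
        np.testing.assert_array_equal(
            simulate(par, u, 5.0),
            simulate(branch1, u, 5.0) + simulate(branch2, u, 5.0))

    def test_pole_zero_cancellation(self, tm_prbs_input):
        u = tm_prbs_input[:120]
        p2z = make_model("P2Z", {"k": 3.0, "tau1": 25.0, "tau2": 60.0,
                                 "Tz": 25.0})
        p1 = make_model("P1", {"k": 3.0, "tau1": 60.0})
        np.testing.assert_allclose(simulate(p2z, u, 5.0),
                                   simulate(p1, u, 5.0), rtol=1e-9, atol=1e-9)

    def test_repeated_pole_matches_near_repeated(self, tm_prbs_input):
        u = tm_prbs_input[:120]
        tied = make_model("P2", {"k": 2.0, "tau1": 40.0, "tau2": 40.0})
        near = make_model("P2", {"k": 2.0, "tau1": 40.0, "tau2": 40.0001})
        np.testing.assert_allclose(simulate(tied, u, 5.0),
                                   simulate(near, u, 5.0), atol=1e-4)

    def test_degenerate_static_gain_still_simulates(self):
        u = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
        model = make_model("P2D", {"k": 2.0, "tau1": 0.0, "tau2": 0.0,
                                   "Td": 5.0})
        np.testing.assert_array_equal(simulate(model, u, 5.0),
                                      2.0 * np.array([0, 0, 1, 1, 0.0]))

    def test_zero_without_poles_is_improper(self):
        model = make_model("P2Z", {"k": 1.0, "tau1": 0.0, "tau2": 0.0,
                                   "Tz": 10.0})
        with pytest.raises(DomainError):
            simulate(model, np.ones(5), 5.0)

    def test_initial_state_free_decay(self):
        model = make_model("P1", {"k": 2.0, "tau1": 10.0})
        y = simulate(model, np.zeros(20), 5.0, initial_state=[3.0])
        t = np.arange(20) * 5.0
        np.testing.assert_allclose(y, 2.0 * 3.0 * np.exp(-t / 10.0),
                                   rtol=1e-12)

    def test_initial_state_length_checked(self):
        model = make_model("P2", {"k": 1.0, "tau1": 10.0, "tau2": 20.0})
        with pytest.raises(DomainError):
            simulate(model, np.zeros(10), 5.0, initial_state=[1.0])
        assert n_states(model) == 2


class TestStepResponse:
    def test_final_value_is_gain_times_amplitude(self):
        params = TM_LIKE_PARAMS["P1parP1D"]
        model = make_model("P1parP1D", params)
        y = step_response(model, 1.0, 1e4, 5.0)
        assert dc_gain(model) == pytest.approx(27.2)
        assert y[-1] == pytest.approx(27.2, rel=1e-9)

    def test_zero_amplitude_gives_zeros(self):
        model = make_model("P1", {"k": 5.0, "tau1": 30.0})
        assert np.all(step_response(model, 0.0, 100.0, 5.0) == 0.0)

    def test_nonpositive_horizon_rejected(self):
        model = make_model("P1", {"k": 5.0, "tau1": 30.0})
        with pytest.raises(DomainError):
            step_response(model, 1.0, 0.0, 5.0)
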