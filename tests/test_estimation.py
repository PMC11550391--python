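"""Fit metric, bounded multi-start estimation, cross-validation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from hrid import (OptimizerOptions, ParameterBounds, ProcessModelRegressor,
                  PreprocessConfig, RecordPair, SignalRecord, compute_fit,
                  cross_validate, fit_model, make_model, preprocess, simulate)
from hrid.errors import DataError, DomainError, ExcitationError, StateError
from hrid.synthetic import PRBSConfig, SyntheticTruth, generate_record

from conftest import TM_LIKE_PARAMS, noise_free_record


class TestComputeFit:
    def test_perfect_reproduction_is_100(self):
        y = np.array([1.0, 2.0, 5.0, 3.0])
        assert compute_fit(y, y) == 100.0

    def test_mean_predictor_is_0(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert compute_fit(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_hand_computed_negative_fit(self):
        # ||e|| = 4, ||y - ybar|| = sqrt(5): fit = 100 (1 - 4/sqrt(5))
        fit = compute_fit([1, 2, 3, 4], [1, 2, 3, 0])
        assert fit == pytest.approx(100.0 * (1.0 - 4.0 / np.sqrt(5.0)))
        assert fit == pytest.approx(-78.885, abs=0.001)

    def test_sum_of_squares_variant(self):
        fit = compute_fit([1, 2, 3, 4], [1, 2, 3, 0], formula="ssq")
        assert fit == pytest.approx(100.0 * (1.0 - 16.0 / 5.0))

    def test_constant_y_undefined(self):
        with pytest.raises(DomainError):
            compute_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 2**31 - 1))
    def test_translation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=30)
        ysim = rng.normal(size=30)
        c = rng.normal() * 50
        assert compute_fit(y + c, ysim + c) == pytest.approx(
            compute_fit(y, ysim), abs=1e-9)


class TestParameterBounds:
    def test_defaults_cover_the_reported_estimates(self):
        tm = ParameterBounds.default("TM")
        ce = ParameterBounds.default("CE")
        assert tm.contains(make_model("P1D", TM_LIKE_PARAMS["P1D"]))
        assert tm.contains(make_model("P1parP1D", TM_LIKE_PARAMS["P1parP1D"]))
        assert ce.contains(make_model("P1D", {"k": 0.40, "tau1": 45.9,
                                              "Td": 13.8}))

    def test_inverted_bound_rejected(self):
        with pytest.raises(DomainError):
            ParameterBounds({"k": (5.0, 1.0)})


class TestRegressorAPI:
    def test_get_params_round_trip_and_clone(self):
        reg = ProcessModelRegressor(structure="P2D", n_starts=3, seed=7)
        params = reg.get_params()
        assert params["structure"] == "P2D" and params["seed"] == 7
        twin = clone(reg)
        assert twin.get_params() == params

    def test_fit_predict_score_noise_free(self, tm_prbs_input):
        u = tm_prbs_input - tm_prbs_input.mean()
        truth = make_model("P1D", TM_LIKE_PARAMS["P1D"])
        y = simulate(truth, u, 5.0)
        reg = ProcessModelRegressor(structure="P1D", n_starts=4, seed=0)
        reg.fit(u.reshape(-1, 1), y - y.mean())
        assert reg.fit_percent_ == pytest.approx(100.0, abs=1e-6)
        assert reg.model_.free_values() == pytest.approx(
            TM_LIKE_PARAMS["P1D"], rel=1e-6)
        yhat = reg.predict(u.reshape(-1, 1))
        assert reg.score(u.reshape(-1, 1), y - y.mean()) == pytest.approx(
            1.0, abs=1e-8)
        assert yhat.shape == y.shape

    def test_constant_input_raises_excitation_error(self):
        reg = ProcessModelRegressor(structure="P1", n_starts=2)
        with pytest.raises(ExcitationError):
            reg.fit(np.ones((50, 1)), np.random.default_rng(0).normal(size=50))


class TestFitModel:
    def test_requires_deviation_form(self, tm_prbs_input):
        rec = noise_free_record("P1D", TM_LIKE_PARAMS["P1D"], tm_prbs_input)
        with pytest.raises(StateError):
            fit_model(rec, "P1D")

    def test_dead_time_recovered_to_half_a_second(self, centered_p1d_record):
        res = fit_model(centered_p1d_record, "P1D")
        assert abs(res.model.Td - 13.1) < 0.5
        assert res.model.k == pytest.approx(25.0, rel=0.01)
        assert res.model.tau1 == pytest.approx(47.7, rel=0.01)
        assert res.n_starts_converged >= 1
        assert len(res.residuals) == res.N

    def test_pole_pair_reported_in_canonical_order(self, tm_prbs_input):
        rec = preprocess(noise_free_record("P2", TM_LIKE_PARAMS["P2"],
                                           tm_prbs_input),
                         PreprocessConfig())
        res = fit_model(rec, "P2")
        assert res.model.tau1 <= res.model.tau2

    def test_objective_non_increasing_with_nested_structures(self,
                                                             tm_prbs_input):
        """Each enlarged structure, warm-started from the solution of the
        structure it nests, can only decrease the training objective."""
        truth = SyntheticTruth(
            subject_id="S01",
            truth_model=make_model("P1parP1D", TM_LIKE_PARAMS["P1parP1D"]),
            modality="TM", baseline_hr=140.0, noise_sd=2.0, seed=77)
        rec = preprocess(
            generate_record(truth, PRBSConfig(1.2, 2.0, seed=5), 1),
            PreprocessConfig())
        # bounds admitting the nested constraint values (tau2 ~ 0, Td = 0)
        bounds = ParameterBounds.from_dict(
            {"tau1": (1e-3, 600.0), "tau2": (1e-3, 600.0)}, "TM")
        opts = OptimizerOptions(n_starts=6, seed=0)

        chain = {}
        chain["P1"] = fit_model(rec, "P1", bounds, opts)
        p1 = chain["P1"].model
        chain["P1D"] = fit_model(
            rec, "P1D", bounds, opts,
            extra_starts=[{"k": p1.k, "tau1": p1.tau1, "Td": 0.0}])
        p1d = chain["P1D"].model
        chain["P2D"] = fit_model(
            rec, "P2D", bounds, opts,
            extra_starts=[{"k": p1d.k, "tau1": p1d.tau1, "tau2": 1e-3,
                           "Td": p1d.Td}])
        p2d = chain["P2D"].model
        chain["P2ZD"] = fit_model(
            rec, "P2ZD", bounds, opts,
            extra_starts=[{"k": p2d.k, "tau1": p2d.tau1, "tau2": p2d.tau2,
                           "Tz": 0.0, "Td": p2d.Td}])
        objectives = [chain[s].objective for s in ("P1", "P1D", "P2D", "P2ZD")]
        for larger, smaller in zip(objectives, objectives[1:]):
            assert smaller <= larger * (1.0 + 1e-6)


class TestCrossValidate:
    def test_identical_records_give_equal_fits(self, tm_prbs_input):
        rec1 = preprocess(noise_free_record("P1D", TM_LIKE_PARAMS["P1D"],
                                            tm_prbs_input, test_index=1),
                          PreprocessConfig())
        rec2 = preprocess(noise_free_record("P1D", TM_LIKE_PARAMS["P1D"],
                                            tm_prbs_input, test_index=2),
                          PreprocessConfig())
        pair = RecordPair("S01", rec1, rec2)
        res1, res2 = cross_validate(pair, "P1D",
                                    options=OptimizerOptions(n_starts=4))
        assert res1.fit_validation == pytest.approx(res1.fit_estimation,
                                                    abs=1e-9)
        assert res2.fit_validation == pytest.approx(res2.fit_estimation,
                                                    abs=1e-9)

    def test_mismatched_sample_period_rejected(self):
        rng = np.random.default_rng(0)
        r1 = SignalRecord("S01", 1, "TM", 5.0, rng.uniform(1, 2, 10),
                          rng.uniform(90, 150, 10))
        r2 = SignalRecord("S01", 2, "TM", 10.0, rng.uniform(1, 2, 10),
                          rng.uniform(90, 150, 10))
        with pytest.raises(DataError):
            RecordPair("S01", r1, r2)
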