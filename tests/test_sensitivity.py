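"""Unit tests for local sensitivities and the designed-experiment methods."""

import math

import numpy as np
import pandas as pd
import pytest

from vfpop.model import PARAM_NAMES, ParameterSet
from vfpop.population import PopulationSample, VirtualSubject, nominal_array
from vfpop.sensitivity import (
    OUTPUT_NAMES,
    SensitivityTensor,
    classify_consistency,
    cotter_design,
    cotter_indices,
    d_optimal_design,
    evaluate_design,
    factor_map,
    fit_rsm,
    local_sensitivity,
    log_det_information,
    n_quadratic_terms,
    oat_analysis,
    pair_mean_sd,
    population_sensitivity,
    quadratic_model_matrix,
    rank_inputs,
    rsm_sensitivity,
    summarize_pairs,
    validate_rsm,
)

from conftest import stub_measures

NOMINAL = nominal_array()


def power_law_evaluate(index: int, exponent: float, output: str = "mean_flow"):
    """Stub pipeline: one output is (factor_index)**exponent, rest constant."""

    def evaluate(params):
        f = params[index] / NOMINAL[index]
        return stub_measures(**{output: 100.0 * f ** exponent})

    return evaluate


class TestLocalSensitivity:
    def test_square_law_forward_difference(self):
        """Output = input^2: the +1% forward difference gives exactly 2.01."""
        evaluate = power_law_evaluate(0, 2.0)
        s, valid = local_sensitivity(NOMINAL.copy(), delta=0.01, evaluate=evaluate)
        j = OUTPUT_NAMES.index("mean_flow")
        expected = (1.01 ** 2 - 1.0) / 0.01
        assert s[0, j] == pytest.approx(expected, rel=1e-9)
        assert valid[0, j]
        # every other input leaves every output untouched
        assert np.all(s[1:] == 0.0)

    def test_convergence_to_log_derivative(self):
        """S* approaches the analytic elasticity as delta shrinks (order >= 1)."""
        evaluate = power_law_evaluate(3, 1.7)
        j = OUTPUT_NAMES.index("mean_flow")
        errs = []
        for delta in (0.02, 0.002):
            s, _ = local_sensitivity(NOMINAL.copy(), delta=delta, evaluate=evaluate)
            errs.append(abs(s[3, j] - 1.7))
        assert errs[1] < errs[0] / 5.0

    def test_failed_perturbation_is_flagged(self):
        calls = {"n": 0}

        def evaluate(params):
            calls["n"] += 1
            # base run oscillates; every perturbed run fails
            return stub_measures(oscillating=calls["n"] == 1)

        s, valid = local_sensitivity(NOMINAL.copy(), evaluate=evaluate)
        assert not valid.any()

    def test_d2_has_exactly_zero_sensitivity(self):
        """d2 enters no force or flow term, so all its sensitivities vanish."""
        subject = VirtualSubject(subject_id=0, params=NOMINAL.copy(),
                                 factors=np.ones(16), measures=stub_measures(),
                                 passed=True)
        from vfpop.measures import evaluate_parameters
        s, valid = local_sensitivity(NOMINAL.copy(), delta=0.01)
        i = PARAM_NAMES.index("d2")
        assert valid[i].all()
        assert np.all(s[i] == 0.0)


def _tensor_from_values(values: np.ndarray, rmax: float) -> SensitivityTensor:
    n = values.shape[0]
    return SensitivityTensor(rmax=rmax, subject_ids=np.arange(n), s=values,
                             valid=np.ones_like(values, dtype=bool))


class TestAggregation:
    def test_single_subject_tensor_has_96_records(self):
        sample = PopulationSample(rmax=1.5, seed=0, attempted=1)
        sample.subjects.append(VirtualSubject(
            subject_id=0, params=NOMINAL.copy(), factors=np.ones(16),
            measures=stub_measures(), passed=True))
        tensor = population_sensitivity(sample, evaluate=power_law_evaluate(0, 2.0))
        assert tensor.s.shape == (1, 16, 6)
        df = tensor.to_dataframe()
        assert len(df) == 96
        assert set(df["input"]) == set(PARAM_NAMES)

    def test_percentiles_averaged_across_ranges(self):
        a = _tensor_from_values(np.full((10, 16, 6), 2.0), 1.1)
        b = _tensor_from_values(np.full((10, 16, 6), 4.0), 5.0)
        summ = summarize_pairs([a, b])
        assert np.allclose(summ["median"], 3.0)
        assert np.allclose(summ["p5"], 3.0)
        assert summ["n_valid"].iloc[0] == 20

    def test_constant_tensor_is_consistent_class(self):
        t = _tensor_from_values(np.full((10, 16, 6), 1.5), 1.5)
        ms = pair_mean_sd(t)
        assert (ms["sd"] == 0.0).all()
        assert (ms["class"] == "consistent").all()

    def test_median_invariant_under_subject_reordering(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(50, 16, 6))
        t1 = _tensor_from_values(vals, 1.5)
        t2 = _tensor_from_values(vals[::-1], 1.5)
        s1 = summarize_pairs([t1])
        s2 = summarize_pairs([t2])
        assert np.allclose(s1["median"], s2["median"])

    def test_classify_consistency_partition_and_sign_flip(self):
        for mean, sd, expected in [(1.0, 0.1, "consistent"),
                                   (0.1, 1.0, "within-1sd"),
                                   (0.15, 0.1, "within-2sd")]:
            assert classify_consistency(mean, sd) == expected
            assert classify_consistency(-mean, sd) == expected

    def test_rank_inputs_with_tie_breaks_lexicographically(self):
        rows = []
        for inp in ("b_in", "a_in", "c_in"):
            for out in OUTPUT_NAMES:
                med = {"b_in": 1.0, "a_in": 1.0, "c_in": 2.0}[inp]
                rows.append({"input": inp, "output": out, "median": med})
        order = rank_inputs(pd.DataFrame(rows))
        assert order == ["c_in", "a_in", "b_in"]


class TestOAT:
    def test_linear_stub_recovers_slope(self):
        # output linear in the factor of P: elasticity at nominal is b/F0 = 1
        def evaluate(params):
            return stub_measures(mean_flow=50.0 * params[0] / NOMINAL[0])

        _, sens = oat_analysis(NOMINAL.copy(), percent_range=0.05,
                               evaluate=evaluate)
        row = sens[(sens.input == "P") & (sens.output == "mean_flow")]
        assert row.s_star.iloc[0] == pytest.approx(1.0, rel=1e-9)
        others = sens[(sens.input != "P") & (sens.output == "mean_flow")]
        assert np.allclose(others.s_star, 0.0)

    def test_blind_to_pure_interactions(self):
        """OAT reports zero for a response driven only by a two-way interaction."""

        def evaluate(params):
            z = params / NOMINAL - 1.0
            return stub_measures(mean_flow=100.0 * (1.0 + z[0] * z[1]))

        _, sens = oat_analysis(NOMINAL.copy(), percent_range=0.05,
                               evaluate=evaluate)
        sub = sens[sens.output == "mean_flow"]
        assert np.allclose(sub.s_star, 0.0, atol=1e-9)

    def test_failed_endpoint_marks_pair_unavailable(self):
        def evaluate(params):
            # the P-high endpoint fails to oscillate
            return stub_measures(oscillating=bool(params[0] <= NOMINAL[0]))

        _, sens = oat_analysis(NOMINAL.copy(), percent_range=0.05,
                               evaluate=evaluate)
        p_rows = sens[sens.input == "P"]
        assert not p_rows.available.any()
        assert sens[sens.input == "L"].available.all()

    def test_rejects_nonpositive_range(self):
        with pytest.raises(ValueError):
            oat_analysis(NOMINAL.copy(), percent_range=0.0)


class TestCotter:
    def test_design_structure(self):
        low = -np.ones(16)
        high = np.ones(16)
        d = cotter_design(16, low, high)
        assert d.shape == (34, 16)
        assert np.array_equal(d[0], low)
        assert np.array_equal(d[-1], high)
        for j in range(16):
            assert (d[1 + j] != low).sum() == 1 and d[1 + j, j] == 1.0
            assert (d[17 + j] != high).sum() == 1 and d[17 + j, j] == -1.0

    def test_additive_stub_recovers_coefficients(self):
        rng = np.random.default_rng(1)
        b = rng.normal(size=16)
        d = cotter_design(16, -np.ones(16), np.ones(16))
        y = d @ b
        idx = cotter_indices(y)
        assert np.allclose(idx["c_odd"], b, atol=1e-12)
        assert np.allclose(idx["c_even"], 0.0, atol=1e-12)

    def test_pure_interaction_lands_in_even_index(self):
        d = cotter_design(16, -np.ones(16), np.ones(16))
        y = d[:, 0] * d[:, 1]
        idx = cotter_indices(y)
        assert idx["c_odd"].abs().max() < 1e-12
        assert idx["c_even"].iloc[0] == pytest.approx(1.0)
        assert idx["c_even"].iloc[1] == pytest.approx(1.0)
        assert idx["c_even"].iloc[2:].abs().max() < 1e-12

    def test_constant_response_gives_zero_indices(self):
        y = np.full(34, 3.3)
        idx = cotter_indices(y)
        assert np.allclose(idx[["c_odd", "c_even", "total"]], 0.0)

    def test_failed_run_invalidates_whole_analysis(self):
        y = np.full(34, 1.0)
        y[5] = math.nan
        with pytest.raises(ValueError):
            cotter_indices(y)


class TestDOptimal:
    def test_requesting_all_candidates_returns_all(self):
        cand = np.random.default_rng(0).uniform(-1, 1, (40, 3))
        idx = d_optimal_design(cand, 40)
        assert np.array_equal(idx, np.arange(40))

    def test_beats_random_subsets(self):
        rng = np.random.default_rng(1)
        cand = rng.uniform(-1, 1, (300, 4))
        n_pts = n_quadratic_terms(4) + 5
        idx = d_optimal_design(cand, n_pts)
        ld = log_det_information(cand, idx)
        best_random = max(
            log_det_information(cand, rng.choice(300, n_pts, replace=False))
            for _ in range(100))
        assert ld >= best_random


class TestRSM:
    def test_exact_quadratic_recovery(self):
        rng = np.random.default_rng(2)
        k = 4
        Z = rng.uniform(-1, 1, (40, k))
        true = rng.normal(size=(n_quadratic_terms(k), 2))
        Y = quadratic_model_matrix(Z) @ true
        surf = fit_rsm(Z, Y, rmax=1.1)
        assert np.allclose(surf.coefs, true, rtol=1e-8, atol=1e-10)
        # least-squares identity: prediction reproduces fitted responses
        assert np.allclose(surf.predict(Z), Y, atol=1e-9)

    def test_constant_response_is_intercept_only(self):
        rng = np.random.default_rng(3)
        Z = rng.uniform(-1, 1, (30, 3))
        Y = np.full((30, 1), 7.0)
        surf = fit_rsm(Z, Y, rmax=1.1)
        assert surf.coefs[0, 0] == pytest.approx(7.0)
        assert np.allclose(surf.coefs[1:], 0.0, atol=1e-9)

    def test_underdetermined_fit_rejected(self):
        Z = np.zeros((5, 3))
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            fit_rsm(Z, np.zeros((5, 1)), rmax=1.1)

    def test_square_law_gradient_at_nominal(self):
        """Surface fit to output = factor^2 yields S* = 2 exactly at nominal
        (the linear factor map makes the response exactly quadratic in z)."""
        rmax = 1.1
        c, s = factor_map(rmax)
        rng = np.random.default_rng(4)
        Z = rng.uniform(-1, 1, (40, 2))
        f = c + s * Z[:, 0]
        Y = (f ** 2)[:, None]
        surf = fit_rsm(Z, Y, rmax=rmax)
        sens = rsm_sensitivity(surf)
        assert sens.s_star.iloc[0] == pytest.approx(2.0, rel=1e-8)
        assert sens.s_star.iloc[1] == pytest.approx(0.0, abs=1e-8)

    def test_zero_gradient_surface(self):
        surf = fit_rsm(np.random.default_rng(5).uniform(-1, 1, (30, 3)),
                       np.full((30, 1), 2.0), rmax=1.2)
        sens = rsm_sensitivity(surf)
        assert np.allclose(sens.s_star, 0.0, atol=1e-8)

    def test_validation_against_itself_is_exact(self):
        """Stub simulator equal to the fitted surface: zero validation error."""
        rmax = 1.1
        c, s = factor_map(rmax)
        rng = np.random.default_rng(6)
        k = 16
        Z = rng.uniform(-1, 1, (200, k))
        true = rng.normal(size=(n_quadratic_terms(k), 6)) * 0.05
        true[0] += 5.0  # keep outputs away from zero
        Y = quadratic_model_matrix(Z) @ true
        surf = fit_rsm(Z, Y, rmax=rmax)

        def evaluate(params):
            z = (params / NOMINAL - c) / s
            y = quadratic_model_matrix(z[None, :]) @ true
            return stub_measures(**dict(zip(OUTPUT_NAMES, y[0])))

        stats = validate_rsm(surf, n_points=20, seed=7, evaluate=evaluate)
        assert stats["n_failed"] == 0
        assert stats["avg_max_error"] < 1e-7
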