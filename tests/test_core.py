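"""Analytic probabilities: closed forms, linearization, integral engine, fluxes."""

import numpy as np
import pytest

from ineqrad import (
    InequalityScheme,
    ODMatrix,
    ValidationError,
    build_probability_matrix,
    compute_distances,
    estimate_mobile_fraction,
    general_probability_integral,
    linearized_probability,
    linearized_rho,
    modified_probability_two_class,
    predict_fluxes,
    radiation_probability,
)

from conftest import random_two_class_system


class TestRadiationProbability:
    def test_symmetric_unit_case(self):
        assert radiation_probability(1, 1, 0) == pytest.approx(0.5)

    def test_direct_arithmetic(self):
        assert radiation_probability(2, 3, 5) == pytest.approx(6 / 70)

    def test_two_city_closed_form(self):
        n1, n2 = 10_000, 1_000_000
        assert radiation_probability(n1, n2, 0) == pytest.approx(n2 / (n1 + n2))
        assert radiation_probability(n2, n1, 0) == pytest.approx(n1 / (n1 + n2))

    def test_invalid_populations_rejected(self):
        with pytest.raises(ValidationError):
            radiation_probability(0, 1, 0)


class TestTwoClassClosedForms:
    @pytest.mark.parametrize("case", [(1, 1), (1, 2), (2, 1), (2, 2)])
    def test_delta_one_reduces_to_standard(self, case):
        oc, dc = case
        p = modified_probability_two_class(3, 7, 4, 6, oc, dc, 1.0)
        assert p == pytest.approx(radiation_probability(3, 7, 10), abs=1e-15)

    def test_case_22_is_standard_over_delta_power_s1(self):
        p = modified_probability_two_class(4, 5, 3, 2, 2, 2, 2.0)
        assert p == pytest.approx(radiation_probability(4, 5, 5) / 8)

    def test_case_21_hand_example(self):
        # m=2, n=1, s=0, delta=2: (1/3)*[1 + 2*(1 - 1/2)] = 2/3
        assert modified_probability_two_class(2, 1, 0, 0, 2, 1, 2.0) == pytest.approx(2 / 3)

    def test_case_11_bracket_sums_to_one_at_delta_one(self):
        p = modified_probability_two_class(1, 1, 1, 1, 1, 1, 1.0)
        assert p == pytest.approx(radiation_probability(1, 1, 2), abs=1e-15)

    def test_monotone_decreasing_in_delta_for_case_22(self):
        deltas = np.linspace(1.0, 5.0, 40)
        vals = [modified_probability_two_class(3, 9, 6, 2, 2, 2, d) for d in deltas]
        assert np.all(np.diff(vals) <= 1e-15)

    def test_delta_below_one_agrees_with_integral(self):
        # advantaged class 2: evaluated through the rescaling symmetry
        p = modified_probability_two_class(5, 28, 23, 59, 1, 2, 0.8636838454663294)
        q = general_probability_integral(5, 28, [23, 59], 1, 2, [1.0, 0.8636838454663294])
        assert p == pytest.approx(q, rel=1e-10)

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValidationError):
            modified_probability_two_class(1, 1, 0, 0, 1, 1, 0.0)


class TestLinearized:
    def test_delta_one_gives_standard(self):
        for case in [(1, 1), (1, 2), (2, 1), (2, 2)]:
            p = linearized_probability(3, 7, 4, 6, *case, 1.0)
            assert p == pytest.approx(radiation_probability(3, 7, 10), abs=1e-15)

    @pytest.mark.parametrize(
        "case,expected_rho",
        [((2, 1), lambda m, s1, s2: m + s2), ((2, 2), lambda m, s1, s2: -s1),
         ((1, 2), lambda m, s1, s2: -m - s1), ((1, 1), lambda m, s1, s2: s2)],
    )
    def test_slope_matches_numeric_derivative_of_closed_form(self, case, expected_rho):
        m, n, s1, s2 = 4, 6, 3, 5
        oc, dc = case
        assert linearized_rho(m, n, s1, s2, oc, dc) == expected_rho(m, s1, s2)
        h = 1e-6
        pR = radiation_probability(m, n, s1 + s2)
        num = (
            modified_probability_two_class(m, n, s1, s2, oc, dc, 1.0 + h)
            - modified_probability_two_class(m, n, s1, s2, oc, dc, 1.0 - h)
        ) / (2 * h)
        assert num / pR == pytest.approx(expected_rho(m, s1, s2), rel=1e-5)

    def test_negative_values_clipped(self, caplog):
        # huge delta drives the first-order term far negative
        p = linearized_probability(5, 5, 50, 0, 2, 2, 1.5)
        assert p == 0.0


class TestIntegralEngine:
    def test_homogeneous_case_is_standard_radiation(self):
        p = general_probability_integral(4, 9, [13], 1, 1, [1.0])
        assert p == pytest.approx(radiation_probability(4, 9, 13), rel=1e-12)

    def test_randomized_agreement_with_closed_form(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = int(rng.integers(1, 51))
            n = int(rng.integers(1, 51))
            s1 = int(rng.integers(0, 101))
            s2 = int(rng.integers(0, 101))
            oc = int(rng.integers(1, 3))
            dc = int(rng.integers(1, 3))
            delta = float(rng.uniform(0.5, 3.0))
            closed = modified_probability_two_class(m, n, s1, s2, oc, dc, delta)
            integ = general_probability_integral(m, n, [s1, s2], oc, dc, [1.0, delta])
            assert integ == pytest.approx(closed, rel=1e-8, abs=1e-300)

    def test_equal_deltas_collapse_classes(self):
        a = general_probability_integral(5, 7, [3, 2, 4], 1, 3, [1.0, 1.7, 1.7])
        b = general_probability_integral(5, 7, [3, 6], 1, 2, [1.0, 1.7])
        assert a == pytest.approx(b, rel=1e-12)

    def test_large_populations_stay_finite(self):
        p = general_probability_integral(10**6, 10**5, [10**6, 10**5], 1, 2, [1.0, 1.0001])
        assert 0.0 <= p <= 1.0


class TestProbabilityMatrix:
    def test_two_location_standard_rows(self):
        t = random_two_class_system(np.random.default_rng(1), L=2)
        P = build_probability_matrix(t, model="standard").matrix
        assert np.allclose(P, [[0, 1], [1, 0]])

    def test_rows_normalized_diag_zero(self, small_system, scheme_delta2):
        for model in ("standard", "two_class", "linearized", "integral"):
            sch = scheme_delta2 if model != "linearized" else InequalityScheme.two_class(1.001)
            P = build_probability_matrix(small_system, sch, model).matrix
            assert np.all(np.diag(P) == 0)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_two_class_matches_integral_engine(self, small_system, scheme_delta2, small_distances):
        P2 = build_probability_matrix(small_system, scheme_delta2, "two_class", distances=small_distances).matrix
        Pi = build_probability_matrix(small_system, scheme_delta2, "integral", distances=small_distances).matrix
        assert np.allclose(P2, Pi, rtol=1e-8, atol=1e-12)

    def test_two_class_requires_two_class_scheme(self, small_system):
        with pytest.raises(ValidationError):
            build_probability_matrix(small_system, InequalityScheme({1: 1.0, 2: 2.0, 3: 3.0}), "two_class")

    def test_linearized_multiclass_tracks_integral_to_first_order(self):
        # three classes with small penalties: superposition of per-class
        # first-order terms must match the exact integral beyond first order
        rng = np.random.default_rng(3)
        t = random_two_class_system(rng, L=8, p_max=100)
        classes = t.classes.copy()
        classes[np.flatnonzero(classes == 1)[:2]] = 3
        # relabel so classes are contiguous 1..3
        t = t.with_classes(np.sort(np.unique(classes)).searchsorted(classes) + 1)
        ratios = []
        for eps in (1e-3, 1e-4, 1e-5):
            sch = InequalityScheme({1: 1.0, 2: 1.0 + eps, 3: 1.0 + 2 * eps})
            Pl = build_probability_matrix(t, sch, "linearized", normalize=False).matrix
            Pi = build_probability_matrix(t, sch, "integral", normalize=False).matrix
            ratios.append(np.max(np.abs(Pl - Pi)) / eps**2)
        # a second-order residual has err/eps^2 converging to a constant
        assert max(ratios) < 1.3 * min(ratios)


class TestFluxPrediction:
    def test_zero_outflow_gives_zero_row(self, small_system):
        P = build_probability_matrix(small_system, model="standard")
        T = np.zeros(len(small_system))
        assert np.all(predict_fluxes(P, T).matrix == 0)

    def test_rounding_convention(self, small_system):
        P = build_probability_matrix(small_system, model="standard")
        flux = predict_fluxes(P, np.full(len(small_system), 100.0), round_to_int=True).matrix
        unrounded = 100.0 * P.matrix
        assert np.array_equal(flux, np.floor(unrounded + 0.5).astype(np.int64))

    def test_unrounded_rows_conserve_outflow(self, small_system):
        P = build_probability_matrix(small_system, model="standard")
        T = np.arange(1.0, len(small_system) + 1.0) * 10
        flux = predict_fluxes(P, T, round_to_int=False).matrix
        assert np.allclose(flux.sum(axis=1), T, atol=1e-9)

    def test_negative_outflow_rejected(self, small_system):
        P = build_probability_matrix(small_system, model="standard")
        with pytest.raises(ValidationError):
            predict_fluxes(P, np.full(len(small_system), -1.0))


class TestMobileFraction:
    def _od_from_outflows(self, outflows):
        L = len(outflows)
        mat = np.zeros((L, L))
        mat[:, 0] = outflows
        mat[0, 0] = 0.0
        mat[0, 1] = outflows[0]
        return ODMatrix(matrix=mat)

    def test_exact_linear_data(self, small_system):
        T = 0.1 * small_system.populations
        assert estimate_mobile_fraction(self._od_from_outflows(T), small_system) == pytest.approx(0.1)

    def test_noisy_data_matches_closed_form_slope(self, small_system):
        rng = np.random.default_rng(5)
        m = small_system.populations.astype(float)
        T = 0.1 * m + rng.normal(0, 1, len(m))
        T = np.maximum(T, 0)
        slope = estimate_mobile_fraction(self._od_from_outflows(T), small_system)
        assert slope == pytest.approx(float(np.sum(m * T) / np.sum(m * m)), rel=1e-12)
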