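"""Error matrices, Mann-Whitney, Hamming/binomial tests and permutation nulls."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from ineqrad import (
    InequalityScheme,
    ODMatrix,
    ValidationError,
    binomial_hamming_test,
    compare_models,
    compute_distances,
    error_matrix,
    estimation_tally,
    generate_od,
    generate_system,
    hamming_distance,
    mann_whitney_one_sided,
    permutation_null,
    SyntheticSystemConfig,
)
from ineqrad.evaluation import _u_statistic


def od(mat):
    return ODMatrix(matrix=np.asarray(mat))


class TestErrorMatrix:
    def test_equal_matrices_are_all_correct(self):
        m = od([[0, 3], [2, 0]])
        err = error_matrix(m, m)
        assert np.all(err.errors == 0)
        assert estimation_tally(err) == (0, 2, 0)

    def test_over_and_under_flags(self):
        err = error_matrix(od([[0, 5], [0, 0]]), od([[0, 3], [7, 0]]))
        assert err.errors[0, 1] == 2 and err.flags[0, 1] == 1
        assert err.errors[1, 0] == 7 and err.flags[1, 0] == -1
        assert estimation_tally(err) == (1, 0, 1)

    def test_hamming_complement_identity(self):
        rng = np.random.default_rng(0)
        L = 6
        a = rng.integers(0, 3, (L, L))
        b = rng.integers(0, 3, (L, L))
        np.fill_diagonal(a, 0)
        np.fill_diagonal(b, 0)
        err = error_matrix(od(a), od(b))
        n_over, n_correct, n_under = estimation_tally(err)
        assert hamming_distance(err) == L * L - L - n_correct
        assert n_over + n_correct + n_under == L * L - L

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            error_matrix(od(np.zeros((2, 2))), od(np.zeros((3, 3))))


def brute_force_mw_midp(x, y):
    """Independent oracle: enumerate assignments, U from pairwise comparisons."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(sample1, sample2):
        # U of sample1: pairs it wins (x > y), ties counting one half
        return sum(1.0 * (a > b) + 0.5 * (a == b) for a in sample1 for b in sample2)

    u_obs = u_of(x, y)
    less = equal = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        s1 = [pooled[i] for i in idx]
        s2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_of(s1, s2)
        if u < u_obs - 1e-9:
            less += 1
        elif u <= u_obs + 1e-9:
            equal += 1
        total += 1
    return (less + 0.5 * equal) / total


class TestMannWhitney:
    def test_identical_samples_give_half(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        u, p = mann_whitney_one_sided(x, x.copy())
        assert p == pytest.approx(0.5)
        u, p = mann_whitney_one_sided(np.zeros(300), np.zeros(300))
        assert p == pytest.approx(0.5)

    def test_dominated_sample_exact_enumeration(self):
        x = np.array([0.0, 0.0, 1.0])
        y = np.array([5.0, 6.0, 7.0])
        u, p = mann_whitney_one_sided(x, y, method="exact")
        assert u == 0.0
        assert p == pytest.approx(brute_force_mw_midp(x, y))
        assert p == pytest.approx(0.5 / 20)  # one of C(6,3) assignments, mid-p

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_matches_brute_force_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, 5).astype(float)
        y = rng.integers(0, 4, 6).astype(float)
        _, p = mann_whitney_one_sided(x, y, method="exact")
        assert p == pytest.approx(brute_force_mw_midp(x, y), abs=1e-12)

    def test_asymptotic_agrees_with_scipy_when_untied(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 60)
        y = rng.normal(0.5, 1, 70)
        u, p = mann_whitney_one_sided(x, y, method="asymptotic")
        ref = stats.mannwhitneyu(x, y, alternative="less", method="asymptotic", use_continuity=False)
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_joint_zero_filter_reduces_sample(self):
        x = np.array([0.0, 0.0, 2.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, 0.0])
        # two cells are jointly zero; they drop out and the rest remain
        u_f, _ = mann_whitney_one_sided(x, y, drop_joint_zeros=True, method="exact")
        assert u_f == _u_statistic(np.array([0.0, 2.0]), np.array([1.0, 0.0]))

    def test_all_filtered_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_one_sided(np.zeros(3), np.zeros(3), drop_joint_zeros=True)


def brute_force_binom_cdf(k, n, p):
    """Log-space cumulative binomial sum, term by term."""
    if p == 0:
        return 1.0
    if p == 1:
        return 1.0 if k >= n else 0.0
    terms = []
    for i in range(0, k + 1):
        lg = (
            math.lgamma(n + 1)
            - math.lgamma(i + 1)
            - math.lgamma(n - i + 1)
            + i * math.log(p)
            + (n - i) * math.log1p(-p)
        )
        terms.append(math.exp(lg))
    return min(math.fsum(terms), 1.0)


class TestBinomialHamming:
    def test_equal_hamming_is_not_significant(self):
        assert binomial_hamming_test(40, 40, 10) > 0.5

    def test_example_against_brute_force(self):
        p = binomial_hamming_test(5, 10, 10)
        assert p == pytest.approx(brute_force_binom_cdf(5, 100, 0.1), abs=1e-12)

    def test_zero_modified_hamming_single_term(self):
        L, H_std = 8, 12
        p_hat = H_std / L**2
        assert binomial_hamming_test(0, H_std, L) == pytest.approx((1 - p_hat) ** (L**2))

    def test_degenerate_standard_hamming(self):
        assert binomial_hamming_test(3, 0, 5) == 0.0
        assert binomial_hamming_test(0, 0, 5) == 1.0

    @pytest.mark.parametrize("L,H_std,H_mod", [(10, 37, 20), (50, 400, 380), (100, 1200, 1100)])
    def test_matches_brute_force_up_to_1e4_trials(self, L, H_std, H_mod):
        assert binomial_hamming_test(H_mod, H_std, L) == pytest.approx(
            brute_force_binom_cdf(H_mod, L * L, H_std / L**2), abs=1e-12
        )

    @pytest.mark.parametrize("L,H_std,H_mod", [(10, 37, 20), (50, 400, 380), (100, 9000, 8900)])
    def test_cross_check_against_scipy_incomplete_beta(self, L, H_std, H_mod):
        # independent route: regularized incomplete beta instead of summation
        assert binomial_hamming_test(H_mod, H_std, L) == pytest.approx(
            float(stats.binom.cdf(H_mod, L * L, H_std / L**2)), abs=1e-9
        )


class TestPermutationNull:
    @pytest.fixture
    def protocol_inputs(self):
        cfg = SyntheticSystemConfig(L=12, p_max=2000, true_delta=1.001)
        system, scheme = generate_system(cfg, seed=21)
        obs = generate_od(system, scheme, "two_class", sampling="multinomial", seed=22)
        return system, scheme, obs

    def test_fixed_seed_reproduces_null(self, protocol_inputs):
        system, scheme, obs = protocol_inputs
        from ineqrad import build_probability_matrix, intervening_population, predict_fluxes

        d = compute_distances(system)
        T = obs.outflows.astype(float)

        def runner(classes):
            loc = system.with_classes(classes)
            P = build_probability_matrix(loc, scheme, "two_class", distances=d)
            return predict_fluxes(P, T)

        P_std = build_probability_matrix(system, model="standard", distances=d)
        err_std = error_matrix(predict_fluxes(P_std, T), obs)
        null1, q1 = permutation_null(runner, system.classes, obs, err_std, "hamming", n_reps=30, seed=5)
        null2, q2 = permutation_null(runner, system.classes, obs, err_std, "hamming", n_reps=30, seed=5)
        assert np.array_equal(null1, null2) and q1 == q2
        assert np.all(null1 >= 0)

    def test_compare_models_report_structure(self, protocol_inputs):
        system, scheme, obs = protocol_inputs
        report = compare_models(system, scheme, obs, model="two_class", n_reps=50, seed=3)
        d = report.to_dict()
        assert 0 <= d["mw_p"] <= 1 and 0 <= d["binomial_p"] <= 1
        assert d["significant"] == (d["verdict_mw"] and d["verdict_hamming"])
        assert sum(d["tally_modified"].values()) == len(system) ** 2 - len(system)

    def test_verdict_requires_both_tests(self, protocol_inputs):
        system, scheme, obs = protocol_inputs
        report = compare_models(
            system, scheme, obs, model="two_class", n_reps=30, seed=3, skip_null_if_insignificant=True
        )
        # conjunction semantics hold regardless of which stage ran
        assert report.significant == (
            report.mw_p < report.alpha
            and report.binomial_p < report.alpha
            and bool(report.mw_perm_pass)
            and bool(report.hamming_perm_pass)
        )
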