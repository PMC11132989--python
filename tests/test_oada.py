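import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from socdiff.data_model import DomainError
from socdiff.networks import ExposureMatrix
from socdiff.oada import (
    DiffusionData,
    OADAModelSpec,
    build_diffusion_data,
    fit_oada,
    oada_loglik,
    percent_st,
    percent_st_ci,
    profile_ci_s,
    relative_rate,
    uniform_order_loglik,
)
from socdiff.synthetic import recovery_config, simulate_diffusion


def make_data(exposures, acquirer, groups=None, X=None, risk=None):
    """Assemble a DiffusionData directly from matrices (test harness)."""
    exposures = np.asarray(exposures, dtype=float)
    K, N = exposures.shape
    acquirer = np.asarray(acquirer)
    if risk is None:
        risk = np.ones((K, N), dtype=bool)
        gone: set[int] = set()
        for k in range(K):
            for i in gone:
                risk[k, i] = False
            gone.add(int(acquirer[k]))
    groups = np.asarray(groups if groups is not None else np.ones(N, dtype=int))
    X = np.asarray(X if X is not None else np.zeros((N, 3)))
    em = ExposureMatrix(
        ids=[f"I{i}" for i in range(N)], times=np.arange(K, dtype=float),
        acquirer=acquirer, matrix=exposures, risk=risk, variant="absolute_observation",
    )
    return DiffusionData(
        exposures=em, groups=groups, group_levels=sorted(set(groups.tolist())), X=X,
        ids=em.ids,
    )


def brute_force_loglik(theta, spec, data):
    """Independent enumeration of the order likelihood, event by event."""
    n_s = spec.n_free_s
    n_b = len(spec.ilvs_asocial)
    s_free = list(theta[:n_s])
    beta = np.asarray(theta[n_s : n_s + n_b])
    gamma = np.asarray(theta[n_s + n_b :])
    if spec.s_constraint == "s1_eq_s2":
        s_of_group = {g: s_free[0] for g in data.group_levels}
    elif spec.s_constraint == "asocial":
        s_of_group = {g: 0.0 for g in data.group_levels}
    elif spec.s_constraint == "s1_ne_s2":
        s_of_group = dict(zip(data.group_levels, s_free))
    elif spec.s_constraint == "s1_zero":
        s_of_group = {data.group_levels[0]: 0.0, data.group_levels[1]: s_free[0]}
    else:
        s_of_group = {data.group_levels[0]: s_free[0], data.group_levels[1]: 0.0}

    cols_a = [("sex", "age", "rank").index(n) for n in spec.ilvs_asocial]
    cols_g = [("sex", "age", "rank").index(n) for n in spec.ilvs_social]
    total = 0.0
    for k in range(data.n_events):
        rates = {}
        for i in range(len(data.ids)):
            if not data.exposures.risk[k, i]:
                continue
            soc = math.exp(sum(g * data.X[i, c] for g, c in zip(gamma, cols_g)))
            aso = math.exp(sum(b * data.X[i, c] for b, c in zip(beta, cols_a)))
            rates[i] = (
                s_of_group[int(data.groups[i])] * data.exposures.matrix[k, i] * soc + aso
            )
        a = int(data.exposures.acquirer[k])
        total += math.log(rates[a]) - math.log(sum(rates.values()))
    return total


class TestLoglik:
    def test_uniform_order_null_at_s_zero(self):
        data = make_data(np.random.default_rng(0).uniform(0, 5, (4, 6)), [0, 1, 2, 3])
        spec = OADAModelSpec(s_constraint="s1_eq_s2")
        sizes = [6, 5, 4, 3]
        expected = sum(math.log(1 / n) for n in sizes)
        assert oada_loglik([0.0], spec, data) == pytest.approx(expected, abs=1e-12)
        assert uniform_order_loglik(data) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_two_identical_individuals(self):
        data = make_data([[2.0, 2.0]], [0])
        spec = OADAModelSpec(s_constraint="s1_eq_s2")
        for s in (0.0, 0.5, 7.0):
            assert oada_loglik([s], spec, data) == pytest.approx(math.log(0.5), abs=1e-12)

    def test_matches_brute_force_enumeration(self):
        """Four-individual toy with exposures {0,1,2,3}, s=1: explicit event sums."""
        expo = np.array(
            [[0.0, 1.0, 2.0, 3.0], [0.0, 1.5, 2.5, 3.5], [1.0, 1.0, 4.0, 0.5]]
        )
        data = make_data(expo, [3, 1, 2])
        spec = OADAModelSpec(s_constraint="s1_eq_s2")
        ll = oada_loglik([1.0], spec, data)
        # independent enumeration
        assert ll == pytest.approx(brute_force_loglik([1.0], spec, data), abs=1e-12)
        # and fully by hand for the first event: r = 1 + E
        hand = math.log(4 / (1 + 2 + 3 + 4))
        ll_first = oada_loglik([1.0], spec, make_data(expo[:1], [3]))
        assert ll_first == pytest.approx(hand, abs=1e-12)

    @given(
        seed=st.integers(0, 100),
        s=st.floats(0, 20),
        b=st.floats(-1.5, 1.5),
        g=st.floats(-1.5, 1.5),
    )
    def test_brute_force_agreement_with_ilvs_and_groups(self, seed, s, b, g):
        rng = np.random.default_rng(seed)
        N, K = 6, 4
        data = make_data(
            rng.uniform(0, 4, (K, N)),
            rng.permutation(N)[:K],
            groups=np.array([1, 1, 1, 2, 2, 2]),
            X=rng.normal(0, 1, (N, 3)),
        )
        spec = OADAModelSpec(
            s_constraint="s1_ne_s2", ilvs_asocial=("age",), ilvs_social=("rank",)
        )
        theta = [s, s / 2 + 0.1, b, g]
        assert oada_loglik(theta, spec, data) == pytest.approx(
            brute_force_loglik(theta, spec, data), abs=1e-12
        )

    @given(seed=st.integers(0, 50), s=st.floats(0, 50))
    def test_event_probabilities_sum_to_one(self, seed, s):
        rng = np.random.default_rng(seed)
        data = make_data(rng.uniform(0, 3, (3, 5)), [0, 1, 2], X=rng.normal(0, 1, (5, 3)))
        spec = OADAModelSpec(s_constraint="s1_eq_s2", ilvs_asocial=("sex",), ilvs_social=("age",))
        from socdiff.oada import _rates

        r = _rates(spec, np.array([s]), np.array([0.3]), np.array([-0.2]), data)
        for k in range(3):
            probs = r[k, data.exposures.risk[k]] / r[k, data.exposures.risk[k]].sum()
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_s_rejected(self):
        data = make_data([[1.0, 2.0]], [0])
        with pytest.raises(DomainError):
            oada_loglik([-0.5], OADAModelSpec(s_constraint="s1_eq_s2"), data)

    def test_order_invariance_under_time_rescaling(self, toy_log, toy_ilv):
        """Only the order matters: a monotone time warp leaves the likelihood unchanged."""
        from socdiff.data_model import EventLog

        warped = EventLog(
            solves=[(t**2 + 1, s) for t, s in toy_log.solves],
            observations=[(t**2 + 1, o, s) for t, o, s in toy_log.observations],
            first_manipulations=[(t**2 + 1, i) for t, i in toy_log.first_manipulations],
        )
        spec = OADAModelSpec(s_constraint="s1_eq_s2")
        d1 = build_diffusion_data(toy_log, toy_ilv, "absolute_observation")
        d2 = build_diffusion_data(warped, toy_ilv, "absolute_observation")
        for s in (0.0, 1.0, 10.0):
            assert oada_loglik([s], spec, d1) == pytest.approx(
                oada_loglik([s], spec, d2), abs=1e-12
            )


class TestFit:
    def test_asocial_fit_equals_uniform_null(self):
        data = make_data(np.random.default_rng(1).uniform(0, 5, (4, 6)), [0, 1, 2, 3])
        fit = fit_oada(OADAModelSpec(s_constraint="asocial"), data)
        assert fit.n_params == 0
        assert fit.loglik == pytest.approx(uniform_order_loglik(data), abs=1e-12)

    def test_grid_search_matches_optimizer(self):
        """Independent grid-search MLE agrees with the quasi-Newton maximum."""
        # last acquirer has zero exposure, so the maximum is interior (s-hat ~ 2.2)
        expo = np.array(
            [
                [3.0, 0.0, 1.0, 0.0, 0.5, 0.0],
                [0.0, 1.0, 2.0, 0.0, 1.0, 0.0],
                [0.0, 0.0, 2.0, 0.0, 3.0, 1.0],
                [0.0, 0.0, 0.0, 0.0, 4.0, 2.0],
            ]
        )
        data = make_data(expo, [0, 2, 4, 3])
        spec = OADAModelSpec(s_constraint="s1_eq_s2")
        fit = fit_oada(spec, data)
        coarse = np.concatenate([[0.0], np.logspace(-3, 3, 600)])
        lls = [oada_loglik([s], spec, data) for s in coarse]
        best = int(np.argmax(lls))
        lo = coarse[max(best - 1, 0)]
        hi = coarse[min(best + 1, len(coarse) - 1)]
        fine = np.linspace(lo, hi, 4000)
        ll_grid = max(oada_loglik([s], spec, data) for s in fine)
        assert fit.loglik == pytest.approx(ll_grid, abs=1e-6)
        assert fit.loglik >= ll_grid - 1e-9

    def test_nesting_social_never_below_asocial(self):
        rng = np.random.default_rng(3)
        data = make_data(rng.uniform(0, 3, (4, 6)), [5, 0, 3, 1])
        ll_social = fit_oada(OADAModelSpec(s_constraint="s1_eq_s2"), data).loglik
        ll_null = uniform_order_loglik(data)
        assert ll_social >= ll_null - 1e-10

    def test_s_recovered_larger_when_truth_larger(self):
        """Median s-hat under truth s=0 stays below the s=2 recovery median."""
        meds = {}
        for truth in (0.0, 2.0):
            s_hats = []
            for rep in range(30):
                seed = int(np.random.default_rng([101, rep]).integers(2**31 - 1))
                study = simulate_diffusion(recovery_config(truth_s=truth, seed=seed))
                data = build_diffusion_data(study.log, study.ilv, "absolute_observation")
                if data.n_events < 5:
                    continue
                s_hats.append(fit_oada(OADAModelSpec(s_constraint="s1_eq_s2"), data).theta[0])
            meds[truth] = float(np.median(s_hats))
        assert meds[0.0] < meds[2.0]
        assert meds[0.0] < 0.5

    def test_strong_social_signal_lifts_likelihood_above_null(self):
        study = simulate_diffusion(recovery_config(truth_s=10.0, seed=42))
        data = build_diffusion_data(study.log, study.ilv, "absolute_observation")
        fit = fit_oada(OADAModelSpec(s_constraint="s1_eq_s2"), data)
        assert fit.theta[0] > 0
        assert fit.loglik > uniform_order_loglik(data) + 2


class TestProfileCI:
    def test_flat_likelihood_gives_zero_to_infinity(self):
        data = make_data(np.zeros((3, 5)), [0, 1, 2])
        spec = OADAModelSpec(s_constraint="s1_eq_s2")
        fit = fit_oada(spec, data)
        lo, hi = profile_ci_s(fit, data)
        assert lo == 0.0 and math.isinf(hi)

    def test_lower_bound_positive_rejects_asocial(self):
        study = simulate_diffusion(recovery_config(truth_s=15.0, seed=5))
        data = build_diffusion_data(study.log, study.ilv, "absolute_observation")
        fit = fit_oada(OADAModelSpec(s_constraint="s1_eq_s2"), data)
        lo, _ = profile_ci_s(fit, data)
        assert lo > 0


class TestPercentST:
    def test_zero_at_s_zero(self):
        data = make_data([[1.0, 2.0, 0.5]], [1])
        spec = OADAModelSpec(s_constraint="s1_eq_s2")
        assert percent_st([0.0], spec, data) == 0.0

    def test_limit_is_hundred_when_social_dominates(self):
        data = make_data([[1.0, 2.0, 0.5]], [1])
        spec = OADAModelSpec(s_constraint="s1_eq_s2")
        assert percent_st([1e12], spec, data) == pytest.approx(100.0, abs=1e-6)

    def test_hand_computed_event_fractions(self):
        """Fractions {1/2, 2/3} average to 58.33%."""
        data = make_data([[1.0, 9.0], [0.0, 2.0]], [0, 1])
        spec = OADAModelSpec(s_constraint="s1_eq_s2")
        assert percent_st([1.0], spec, data) == pytest.approx(100 * (0.5 + 2 / 3) / 2, abs=1e-9)

    def test_interval_endpoints_ordered_and_infinite_limit(self):
        data = make_data([[0.0, 1.0, 2.0], [0.0, 0.0, 3.0]], [1, 2])
        spec = OADAModelSpec(s_constraint="s1_eq_s2")
        fit = fit_oada(spec, data)
        lo, hi = percent_st_ci(fit, data, (0.0, np.inf))
        assert 0.0 <= lo <= hi <= 100.0
        assert hi == pytest.approx(100.0)  # both acquirers had positive exposure


class TestRelativeRate:
    def test_published_worked_example(self):
        assert round(relative_rate(0.461, 10), 2) == 5.61

    @pytest.mark.parametrize("s,n,expected", [(0.7, 0, 1.0), (2.0, 3, 7.0)])
    def test_identity_and_product(self, s, n, expected):
        assert relative_rate(s, n) == expected

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            relative_rate(-1.0, 2)
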