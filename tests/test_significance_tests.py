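import math
from fractions import Fraction

import numpy as np
import pytest

from wahr import (
    DegenerateTestError,
    SimConfig,
    TrialDataset,
    WeightScheme,
    hypergeometric_moments,
    logrank_test,
    permutation_test,
    simulate_trial,
    two_sided_p,
    weight_based_logrank_test,
)
from wahr.estimators import NONPARAMETRIC

from _oracles import (
    hypergeometric_moments_enumerated,
    logrank_by_hand,
    permutation_pvalue_enumerated,
)


def test_logrank_toy_example(toy_dataset):
    """Hand evaluation: terms (-1/2 + 1/3) over sqrt(1/4 + 2/9)."""
    res = logrank_test(toy_dataset)
    expected = (-0.5 + 1 / 3) / math.sqrt(0.25 + 2 / 9)
    assert res.statistic == pytest.approx(expected, rel=1e-12)
    assert res.statistic == pytest.approx(-0.2425, abs=1e-4)
    assert not res.reject


def test_logrank_symmetric_data_gives_zero():
    data = TrialDataset([1.0, 2.0, 1.0, 2.0], [1, 0, 1, 0], ["I", "I", "C", "C"], k=1, tau=2.0)
    assert logrank_test(data).statistic == pytest.approx(0.0, abs=1e-14)


def test_logrank_single_event_positive_statistic():
    data = TrialDataset([1.0, 3.0, 2.0, 3.0], [1, 0, 0, 0], ["I", "I", "C", "C"], k=1, tau=3.0)
    res = logrank_test(data)
    assert res.statistic > 0 and not res.reject


def test_logrank_matches_hand_recount(simulated_dataset):
    _, data = simulated_dataset
    res = logrank_test(data)
    assert res.statistic == pytest.approx(
        logrank_by_hand(data.times, data.causes, data.groups), rel=1e-12
    )


def test_logrank_degenerate_cases():
    with pytest.raises(DegenerateTestError):
        logrank_test(TrialDataset([1.0, 1.0], [0, 0], ["I", "C"], k=1, tau=2.0))
    with pytest.raises(DegenerateTestError):
        logrank_test(TrialDataset([1.0, 1.0], [1, 0], ["I", "I"], k=1, tau=2.0))


@pytest.mark.parametrize("nI,nC,d", [(2, 2, 1), (3, 5, 4), (6, 6, 12), (1, 4, 0)])
def test_hypergeometric_moments_examples(nI, nC, d):
    e, v = hypergeometric_moments(nI, nC, d)
    e_or, v_or = hypergeometric_moments_enumerated(nI, nC, d)
    assert e == pytest.approx(float(e_or), rel=1e-14)
    assert v == pytest.approx(float(v_or), rel=1e-14)


def test_hypergeometric_moments_exhaustive_small_margins():
    """Exact agreement with rational-arithmetic enumeration for every margin
    configuration with at most 12 subjects at risk."""
    for n in range(2, 13):
        for nI in range(0, n + 1):
            nC = n - nI
            for d in range(0, n + 1):
                e, v = hypergeometric_moments(nI, nC, d)
                e_or, v_or = hypergeometric_moments_enumerated(nI, nC, d)
                assert Fraction(e).limit_denominator(10**12) == e_or or abs(e - float(e_or)) < 1e-12
                assert abs(v - float(v_or)) < 1e-12


def test_hypergeometric_boundary_cases():
    assert hypergeometric_moments(3, 4, 0) == (0.0, 0.0)
    e, v = hypergeometric_moments(3, 4, 7)
    assert e == 3.0 and v == 0.0
    with pytest.raises(DegenerateTestError):
        hypergeometric_moments(1, 0, 1)


def test_weight_based_reduces_to_logrank_with_unit_weights(simulated_dataset):
    _, data = simulated_dataset
    lr = logrank_test(data)
    wb = weight_based_logrank_test(data, WeightScheme.ones(2))
    assert wb.statistic == pytest.approx(lr.statistic, rel=1e-13)
    assert wb.p_value == pytest.approx(lr.p_value, rel=1e-12)


def test_weight_based_scale_invariance_and_antisymmetry(simulated_dataset):
    _, data = simulated_dataset
    w = WeightScheme((1, 0.1))
    base = weight_based_logrank_test(data, w)
    scaled = weight_based_logrank_test(data, WeightScheme((5, 0.5)))
    assert scaled.statistic == pytest.approx(base.statistic, rel=1e-13)
    swapped = TrialDataset(
        data.times, data.causes, np.where(data.groups == "I", "C", "I"), k=2, tau=data.tau
    )
    assert weight_based_logrank_test(swapped, w).statistic == pytest.approx(
        -base.statistic, rel=1e-12
    )
    assert logrank_test(swapped).statistic == pytest.approx(-logrank_test(data).statistic, rel=1e-12)


def test_cross_type_tie_warns():
    data = TrialDataset([1.0, 1.0, 2.0, 2.0], [1, 2, 0, 0], ["I", "C", "I", "C"], k=2, tau=2.0)
    with pytest.warns(UserWarning, match="different types"):
        weight_based_logrank_test(data, WeightScheme((1, 0.5)))


def test_two_sided_helper(simulated_dataset):
    _, data = simulated_dataset
    res = logrank_test(data)
    assert two_sided_p(res) == pytest.approx(min(1.0, 2 * min(res.p_value, 1 - res.p_value)))


def _tiny_estimable_dataset():
    # 2 subjects per group, all events, distinct times: every permutation is estimable
    return TrialDataset(
        [0.5, 1.5, 1.0, 2.0], [1, 2, 2, 1], ["I", "I", "C", "C"], k=2, tau=2.5
    )


def test_permutation_complete_enumeration_matches_oracle():
    from wahr.estimators import _na_log_ratio_sorted, _prepare_sorted

    data = _tiny_estimable_dataset()
    w = WeightScheme((1, 0.5))
    result, inference = permutation_test(
        data, w, 2.5, estimator_method=NONPARAMETRIC, complete=True
    )
    ts, cs, pos_first = _prepare_sorted(data.times, data.causes)
    is_event = cs > 0
    warr = w.as_array()
    wsub = np.where(is_event, warr[np.maximum(cs - 1, 0)], 0.0)
    base = np.argsort(data.times, kind="stable")

    def stat(z):
        return _na_log_ratio_sorted(wsub, pos_first, is_event, z[base])

    p_oracle = permutation_pvalue_enumerated(stat, 4, 2, result.statistic)
    assert result.p_value == pytest.approx(p_oracle, abs=1e-14)


def test_permutation_symmetric_groups_large_p():
    data = TrialDataset(
        [0.5, 1.5, 0.5, 1.5], [1, 2, 1, 2], ["I", "I", "C", "C"], k=2, tau=2.0
    )
    result, _ = permutation_test(
        data, WeightScheme((1, 0.5)), 2.0, estimator_method=NONPARAMETRIC, complete=True
    )
    assert result.p_value >= 0.5


def test_permutation_seed_determinism(simulated_dataset):
    _, data = simulated_dataset
    w = WeightScheme((1, 0.1))
    r1, i1 = permutation_test(data, w, data.tau, NONPARAMETRIC, n_perm=200, seed=11)
    r2, i2 = permutation_test(data, w, data.tau, NONPARAMETRIC, n_perm=200, seed=11)
    assert r1.p_value == r2.p_value
    assert i1.se == i2.se
    np.testing.assert_array_equal(i1.permutation_logs, i2.permutation_logs)


def test_permutation_ci_is_centred_normal_interval(simulated_dataset):
    _, data = simulated_dataset
    _, inf = permutation_test(data, WeightScheme((1, 0.1)), data.tau, NONPARAMETRIC, n_perm=100, seed=3)
    assert inf.ci_low == pytest.approx(inf.observed_log - 1.959964 * inf.se)
    assert inf.ci_high == pytest.approx(inf.observed_log + 1.959964 * inf.se)
    assert inf.ci_low < inf.ci_high


def test_permutation_pvalues_super_uniform_under_null():
    """Over exchangeable null replicates, P(p <= alpha) never exceeds
    alpha + 1/(n_perm + 1) by more than Monte-Carlo noise."""
    n_perm = 99
    reps = 300
    cfg = SimConfig(
        "scenario_6", tau=2.0, weights=WeightScheme((1, 0.1)), n_per_group=20,
        reps=1, n_perm=0, seed=0,
    )
    pvals = []
    children = np.random.SeedSequence(77).spawn(reps)
    for seq in children:
        rng = np.random.Generator(np.random.MT19937(seq))
        data = simulate_trial(cfg, rng)
        try:
            res, _ = permutation_test(
                data, cfg.weights, cfg.tau, NONPARAMETRIC, n_perm=n_perm, rng=rng
            )
        except Exception:
            continue
        pvals.append(res.p_value)
    p = np.asarray(pvals)
    for alpha in (0.05, 0.1, 0.25):
        bound = alpha + 1 / (n_perm + 1) + 3 * math.sqrt(alpha * (1 - alpha) / len(p))
        assert np.mean(p <= alpha) <= bound


def test_permutation_monte_carlo_approaches_enumeration(rng):
    """With 4 subjects per group, 20,000 Monte-Carlo permutations land within
    0.01 of the exhaustive p-value."""
    data = TrialDataset(
        [0.3, 0.9, 1.4, 2.1, 0.6, 1.1, 1.7, 2.4],
        [1, 2, 1, 0, 2, 1, 2, 1],
        ["I"] * 4 + ["C"] * 4,
        k=2,
        tau=2.5,
    )
    w = WeightScheme((1, 0.4))
    exact, _ = permutation_test(data, w, 2.5, NONPARAMETRIC, complete=True)
    mc, _ = permutation_test(data, w, 2.5, NONPARAMETRIC, n_perm=20_000, seed=5)
    assert mc.p_value == pytest.approx(exact.p_value, abs=0.01)
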