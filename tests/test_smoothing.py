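"""Empirical-Bayes smoothing against exact rational-arithmetic oracles."""

from fractions import Fraction

import numpy as np
import pytest

from intensitybounds import (
    AreaMap,
    CaseVector,
    marshall_global,
    marshall_local,
    smoothed_probabilities,
)
from intensitybounds.map_model import ValidationError


def exact_marshall(y, n):
    """Method-of-moments shrinkage evaluated in exact rational arithmetic."""
    y = [Fraction(v) for v in y]
    n = [Fraction(v) for v in n]
    K = len(y)
    t = [yi / ni for yi, ni in zip(y, n)]
    m = sum(y) / sum(n)
    s2 = sum(ni * (ti - m) ** 2 for ni, ti in zip(n, t)) / sum(n)
    n_bar = sum(n) / K
    A = max(Fraction(0), s2 - m / n_bar)
    theta, w = [], []
    for ti, ni in zip(t, n):
        denom = A + m / ni
        wi = A / denom if denom > 0 else Fraction(0)
        w.append(wi)
        theta.append(wi * ti + (1 - wi) * m)
    return theta, w, m, A


def test_global_three_area_exact_oracle():
    y, n = [0, 3, 12], [100, 100, 100]
    theta, w, m, A = exact_marshall(y, n)
    amap = AreaMap(
        ("A", "B", "C"),
        np.array([[0.0, 0], [1, 0], [2, 0]]),
        np.array(n),
    )
    sm = marshall_global(CaseVector(np.array(y)), amap)
    np.testing.assert_allclose(sm.theta_hat, [float(v) for v in theta], rtol=1e-14)
    np.testing.assert_allclose(sm.weights, [float(v) for v in w], rtol=1e-14)
    assert sm.prior_mean[0] == pytest.approx(float(m))
    assert sm.prior_var[0] == pytest.approx(float(A))


def test_global_complete_shrinkage_when_rates_equal():
    amap = AreaMap(
        ("A", "B", "C"),
        np.array([[0.0, 0], [1, 0], [2, 0]]),
        np.array([100, 200, 400]),
    )
    sm = marshall_global(CaseVector(np.array([5, 10, 20])), amap)
    np.testing.assert_allclose(sm.theta_hat, 0.05, rtol=1e-14)
    assert sm.prior_var[0] == 0.0
    np.testing.assert_array_equal(sm.weights, 0.0)


def test_global_large_population_dominates():
    # w_i -> 1 as n_i grows, so the raw rate survives shrinkage
    amap = AreaMap(
        ("big", "s1", "s2"),
        np.array([[0.0, 0], [1, 0], [2, 0]]),
        np.array([10_000_000, 50, 50]),
    )
    y = np.array([30_000, 1, 4])
    sm = marshall_global(CaseVector(y), amap)
    assert sm.weights[0] > 0.99
    assert sm.weights[0] > sm.weights[1]
    assert sm.theta_hat[0] == pytest.approx(30_000 / 10_000_000, rel=1e-3)


def test_global_zero_population_named_error():
    amap = AreaMap(
        ("A", "B"), np.array([[0.0, 0], [1, 0]]), np.array([10, 0])
    )
    with pytest.raises(ValidationError, match="B"):
        marshall_global(CaseVector(np.array([1, 0])), amap)


def test_local_hex_flower_exact_oracle(hex_flower):
    # all 7 cases at the center; each area's estimate from its own
    # neighbourhood, verified against the rational-arithmetic oracle
    y = np.array([7, 0, 0, 0, 0, 0, 0])
    sm = marshall_local(CaseVector(y), hex_flower)
    nbrs = hex_flower.neighbor_indices()
    for i in range(7):
        hood = sorted(set(nbrs[i]) | {i})
        theta, w, _, _ = exact_marshall(
            [int(y[j]) for j in hood], [int(hex_flower.populations[j]) for j in hood]
        )
        k = hood.index(i)
        # oracle weight uses the area's own population in the denominator
        assert sm.theta_hat[i] == pytest.approx(float(theta[k]), rel=1e-12)
        assert sm.weights[i] == pytest.approx(float(w[k]), rel=1e-12)


def test_local_equal_rates_returns_common_rate(hex_flower):
    sm = marshall_local(CaseVector(np.full(7, 3)), hex_flower)
    np.testing.assert_allclose(sm.theta_hat, 0.03, rtol=1e-14)


def test_local_ignores_distant_region():
    # two 3-area islands: smoothing of one island never sees the other
    cent = np.array([[0.0, 0], [1, 0], [2, 0], [100, 0], [101, 0], [102, 0]])
    ids = tuple("abcdef")
    adj = {
        "a": frozenset({"b"}), "b": frozenset({"a", "c"}), "c": frozenset({"b"}),
        "d": frozenset({"e"}), "e": frozenset({"d", "f"}), "f": frozenset({"e"}),
    }
    amap = AreaMap(ids, cent, np.full(6, 100), adj)
    y1 = np.array([1, 2, 3, 0, 0, 0])
    y2 = np.array([1, 2, 3, 9, 9, 9])
    sm1 = marshall_local(CaseVector(y1), amap)
    sm2 = marshall_local(CaseVector(y2), amap)
    np.testing.assert_allclose(sm1.theta_hat[:3], sm2.theta_hat[:3], rtol=1e-14)


def test_local_equals_global_on_complete_graph():
    ids = ("A", "B", "C")
    adj = {a: frozenset(set(ids) - {a}) for a in ids}
    amap = AreaMap(ids, np.array([[0.0, 0], [1, 0], [2, 0]]), np.array([100, 150, 50]), adj)
    cases = CaseVector(np.array([2, 9, 1]))
    sm_l = marshall_local(cases, amap)
    sm_g = marshall_global(cases, amap)
    np.testing.assert_allclose(sm_l.theta_hat, sm_g.theta_hat, rtol=1e-14)


def test_local_isolated_area_keeps_raw_rate():
    amap = AreaMap(
        ("A", "B", "C"),
        np.array([[0.0, 0], [1, 0], [50, 0]]),
        np.array([100, 100, 100]),
        {"A": frozenset({"B"}), "B": frozenset({"A"}), "C": frozenset()},
    )
    sm = marshall_local(CaseVector(np.array([1, 5, 4])), amap)
    assert sm.theta_hat[2] == pytest.approx(0.04)
    assert sm.weights[2] == 0.0


def test_theta_between_raw_rate_and_prior_mean():
    rng = np.random.default_rng(12)
    cent = rng.uniform(0, 5, size=(8, 2))
    amap = AreaMap(tuple(f"a{i}" for i in range(8)), cent, rng.integers(50, 500, 8))
    cases = CaseVector(rng.integers(0, 30, 8))
    sm = marshall_global(cases, amap)
    t = cases.counts / amap.populations
    lo = np.minimum(t, sm.prior_mean)
    hi = np.maximum(t, sm.prior_mean)
    assert ((sm.theta_hat >= lo - 1e-12) & (sm.theta_hat <= hi + 1e-12)).all()


class TestSmoothedProbabilities:
    def test_uniform_rates_give_population_share(self, hex_flower):
        sm = marshall_local(CaseVector(np.full(7, 2)), hex_flower)
        p = smoothed_probabilities(sm, hex_flower)
        np.testing.assert_allclose(p, hex_flower.populations / hex_flower.total_population)

    def test_raw_rate_identity(self, tiny_map):
        # theta_hat = t_i reproduces the raw multinomial c_i / C
        amap, cases = tiny_map
        from intensitybounds.smoothing import SmoothedRates

        t = cases.counts / amap.populations
        sm = SmoothedRates(t, np.ones(3), t, np.zeros(3), "global")
        np.testing.assert_allclose(
            smoothed_probabilities(sm, amap), cases.counts / cases.total
        )

    def test_scale_invariance(self, tiny_map):
        amap, cases = tiny_map
        sm = marshall_global(cases, amap)
        from intensitybounds.smoothing import SmoothedRates

        scaled = SmoothedRates(
            sm.theta_hat * 7.5, sm.weights, sm.prior_mean, sm.prior_var, sm.mode
        )
        np.testing.assert_allclose(
            smoothed_probabilities(scaled, amap), smoothed_probabilities(sm, amap)
        )

    def test_all_zero_rates_error(self, tiny_map):
        amap, _ = tiny_map
        from intensitybounds.smoothing import SmoothedRates

        sm = SmoothedRates(np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3), "global")
        with pytest.raises(ValidationError):
            smoothed_probabilities(sm, amap)

    def test_three_area_oracle_probabilities(self):
        y, n = [0, 3, 12], [100, 100, 100]
        theta, _, _, _ = exact_marshall(y, n)
        expected = [Fraction(ni) * th for ni, th in zip(n, theta)]
        total = sum(expected)
        amap = AreaMap(
            ("A", "B", "C"), np.array([[0.0, 0], [1, 0], [2, 0]]), np.array(n)
        )
        sm = marshall_global(CaseVector(np.array(y)), amap)
        p = smoothed_probabilities(sm, amap)
        np.testing.assert_allclose(p, [float(e / total) for e in expected], rtol=1e-13)
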