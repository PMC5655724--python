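"""Analytic translog evaluation against independent oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hospcost as hc
from hospcost.params import (HEDONICS, IDX_ADMISSIONS, INPUTS, OUTPUTS,
                             ModelDomainError)

from conftest import random_point, random_translog_params


def oracle_log_cost(params, point, norm):
    """Term-by-term summation of the translog polynomial, coded independently
    of the vectorized implementation."""
    yh = [np.log(point.y[m] / norm.outputs[m]) for m in range(len(OUTPUTS))]
    wh = [np.log(point.w[i] / norm.prices[i]) for i in range(len(INPUTS))]
    zc = [point.z[k] - norm.hedonics[k] for k in range(len(HEDONICS))]
    t = (point.year - norm.base_year) / norm.trend_span
    total = params.alpha0 + params.year_effects.get(point.year, 0.0)
    for m in range(len(OUTPUTS)):
        total += params.beta[m] * yh[m]
        for n in range(len(OUTPUTS)):
            total += 0.5 * params.B[m, n] * yh[m] * yh[n]
    for i in range(len(INPUTS)):
        total += params.gamma[i] * wh[i]
        for j in range(len(INPUTS)):
            total += 0.5 * params.G[i, j] * wh[i] * wh[j]
    for m in range(len(OUTPUTS)):
        for i in range(len(INPUTS)):
            total += params.delta[m, i] * yh[m] * wh[i]
    for i in range(len(INPUTS)):
        total += t * params.tau[i] * wh[i]
    for k in range(len(HEDONICS)):
        total += yh[IDX_ADMISSIONS] * params.theta[k] * zc[k]
    return total


def fd_gradient(f, x, rel_step=1e-6):
    g = np.empty_like(x)
    for j in range(len(x)):
        h = rel_step * x[j]
        up, dn = x.copy(), x.copy()
        up[j] += h
        dn[j] -= h
        g[j] = (f(up) - f(dn)) / (2 * h)
    return g


def test_log_cost_matches_term_enumeration_oracle(norm):
    rng = np.random.default_rng(7)
    for _ in range(25):
        params = random_translog_params(rng)
        pt = random_point(rng, norm)
        expected = oracle_log_cost(params, pt, norm)
        got = hc.log_cost(params, pt.y, pt.w, pt.z, pt.year, norm)
        assert got == pytest.approx(expected, abs=1e-12)


def test_log_cost_at_means_is_the_constant(stage2_params, stage1_params, norm):
    pt = hc.Point.mean(norm)
    assert hc.log_cost(stage2_params, pt.y, pt.w, pt.z, pt.year, norm) \
        == pytest.approx(0.191, abs=1e-12)
    assert hc.log_cost(stage1_params, pt.y, pt.w, pt.z, pt.year, norm) \
        == pytest.approx(0.203, abs=1e-12)


def test_cobb_douglas_reduction_with_outputs_at_means(norm):
    """With all second-order and interaction terms zero and outputs at their
    means, log cost is the Cobb-Douglas form alpha0 + gamma'what."""
    rng = np.random.default_rng(3)
    p = random_translog_params(rng)
    p.B[:] = 0.0
    p.G[:] = 0.0
    p.delta[:] = 0.0
    p.tau[:] = 0.0
    p.theta[:] = 0.0
    w = norm.prices * np.exp(rng.uniform(-0.4, 0.4, len(INPUTS)))
    got = hc.log_cost(p, norm.outputs, w, norm.hedonics, norm.base_year, norm)
    assert got == pytest.approx(
        p.alpha0 + np.log(w / norm.prices) @ p.gamma, abs=1e-12)


def test_elasticities_and_shares_match_numeric_gradients(norm):
    """Analytic output elasticities and Shephard shares equal central finite
    differences of the log-cost evaluator."""
    rng = np.random.default_rng(11)
    for _ in range(30):
        params = random_translog_params(rng)
        pt = random_point(rng, norm)

        def lc_y(y):
            return hc.log_cost(params, y, pt.w, pt.z, pt.year, norm)

        def lc_w(w):
            return hc.log_cost(params, pt.y, w, pt.z, pt.year, norm)

        eps = hc.cost_elasticities(params, pt.y, pt.w, pt.z, pt.year, norm)
        num_eps = fd_gradient(lc_y, pt.y) * pt.y       # dlogc/dlogy
        assert np.allclose(eps, num_eps, atol=1e-6)

        shares = hc.predicted_shares(params, pt.y, pt.w, pt.z, pt.year, norm)
        num_shares = fd_gradient(lc_w, pt.w) * pt.w    # dlogc/dlogw
        assert np.allclose(shares, num_shares, atol=1e-6)


def test_elasticity_at_mean_equals_first_order_coefficient(norm):
    rng = np.random.default_rng(5)
    params = random_translog_params(rng)
    pt = hc.Point.mean(norm)
    eps = hc.cost_elasticities(params, pt.y, pt.w, pt.z, pt.year, norm)
    np.testing.assert_array_equal(eps, params.beta)


def test_homogeneous_shares_sum_to_one_and_price_doubling_adds_log2(norm):
    rng = np.random.default_rng(13)
    for _ in range(10):
        params = random_translog_params(rng)
        pt = random_point(rng, norm)
        shares = hc.predicted_shares(params, pt.y, pt.w, pt.z, pt.year, norm)
        assert shares.sum() == pytest.approx(1.0, abs=1e-10)
        base = hc.log_cost(params, pt.y, pt.w, pt.z, pt.year, norm)
        doubled = hc.log_cost(params, pt.y, 2.0 * pt.w, pt.z, pt.year, norm)
        assert doubled - base == pytest.approx(np.log(2.0), abs=1e-10)


def test_marginal_cost_arithmetic_and_level_space_fd(norm):
    # elasticity 0.5, cost 100, y = 25 -> MC = 2
    assert 0.5 * 100.0 / 25.0 == 2.0
    rng = np.random.default_rng(17)
    params = random_translog_params(rng)
    pt = random_point(rng, norm)
    mc = hc.marginal_costs(params, pt.y, pt.w, pt.z, pt.year, norm)
    for m in range(len(OUTPUTS)):
        h = 1e-5 * pt.y[m]
        up = pt.replace_output(m, pt.y[m] + h)
        dn = pt.replace_output(m, pt.y[m] - h)
        fd = (hc.total_cost(params, up.y, up.w, up.z, up.year, norm)
              - hc.total_cost(params, dn.y, dn.w, dn.z, dn.year, norm)) / (2 * h)
        assert mc[m] == pytest.approx(fd, rel=1e-3)
    # explicit observed-cost version: MC scales linearly in the cost level
    mc2 = hc.marginal_cost(params, pt.y, pt.w, pt.z, pt.year, norm,
                           "admissions", total_cost_level=100.0)
    eps = hc.cost_elasticity(params, pt.y, pt.w, pt.z, pt.year, norm,
                             "admissions")
    assert mc2 == pytest.approx(eps * 100.0 / pt.y[0], abs=1e-12)


@given(
    k=st.floats(min_value=0.1, max_value=10.0,
                allow_nan=False, allow_infinity=False),
    seed=st.integers(min_value=0, max_value=2**16),
)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_price_scaling_shifts_log_cost_by_log_k(norm, k, seed):
    """Linear price homogeneity: scaling every input price by k adds exactly
    log k to log cost and leaves predicted shares unchanged."""
    rng = np.random.default_rng(seed)
    params = random_translog_params(rng)
    pt = random_point(rng, norm)
    base = hc.log_cost(params, pt.y, pt.w, pt.z, pt.year, norm)
    scaled = hc.log_cost(params, pt.y, k * pt.w, pt.z, pt.year, norm)
    assert scaled - base == pytest.approx(np.log(k), abs=1e-9)
    s0 = hc.predicted_shares(params, pt.y, pt.w, pt.z, pt.year, norm)
    s1 = hc.predicted_shares(params, pt.y, k * pt.w, pt.z, pt.year, norm)
    assert np.allclose(s0, s1, atol=1e-9)


def test_domain_errors_name_the_offending_field(norm):
    rng = np.random.default_rng(19)
    params = random_translog_params(rng)
    pt = random_point(rng, norm)
    bad = pt.y.copy()
    bad[2] = -5.0
    with pytest.raises(ModelDomainError, match="other_revenues"):
        hc.log_cost(params, bad, pt.w, pt.z, pt.year, norm)
    badw = pt.w.copy()
    badw[1] = 0.0
    with pytest.raises(ModelDomainError, match="price_nursing"):
        hc.log_cost(params, pt.y, badw, pt.z, pt.year, norm)
    with pytest.raises(KeyError):
        hc.cost_elasticity(params, pt.y, pt.w, pt.z, pt.year, norm, "dialysis")
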