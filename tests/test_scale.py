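"""Scale, product-specific and chain elasticities against closed forms."""

import numpy as np
import pytest

import hospcost as hc
from hospcost import scale
from hospcost.params import OUTPUTS

from conftest import random_point, random_translog_params


class PolynomialCost(scale.LevelCost):
    """Closed-form level-space cost for oracle checks."""

    def __init__(self, fn):
        self.fn = fn

    def cost(self, y):
        return float(self.fn(np.asarray(y, dtype=float)))


def test_linear_cost_gives_unit_elasticities_everywhere():
    """Average incremental equals marginal for a linear cost, so both the
    product-specific and the chain elasticity are exactly one."""
    a = np.array([3.0, 1.5, 0.2, 0.8])
    lc = PolynomialCost(lambda y: a @ y)
    y = np.array([100.0, 200.0, 50.0, 80.0])
    for m in range(4):
        v = scale.product_specific_scale_elasticity_lc(lc, y, m, y[m] / 5)
        assert v == pytest.approx(1.0, rel=1e-7)
    v12 = scale.chain_scale_elasticity_lc(lc, y, 3, 0, 30.0)
    assert v12 == pytest.approx(1.0, rel=1e-7)


def test_quadratic_cost_matches_closed_forms():
    # c = a y_m^2: product-specific elasticity = (y + y_min) / (2 y) < 1
    lc = PolynomialCost(lambda y: 2.0 * y[0] ** 2 + 5.0 * y[1])
    y = np.array([40.0, 10.0, 1.0, 1.0])
    for y_min in (5.0, 20.0):
        v = scale.product_specific_scale_elasticity_lc(lc, y, 0, y_min)
        assert v == pytest.approx((y[0] + y_min) / (2 * y[0]), rel=1e-7)
    # decreasing-marginal-cost quadratic in both services: chain economies,
    # closed form v12 = [a1 - b1(2y1 - y12) + a2 - b2(2y2 - y12)] / [MC1 + MC2]
    a1, b1, a2, b2 = 10.0, 0.01, 6.0, 0.004
    lc2 = PolynomialCost(
        lambda y: a1 * y[0] - b1 * y[0] ** 2 + a2 * y[1] - b2 * y[1] ** 2)
    y = np.array([300.0, 400.0, 1.0, 1.0])
    y12 = 120.0
    num = a1 - b1 * (2 * y[0] - y12) + a2 - b2 * (2 * y[1] - y12)
    den = a1 - 2 * b1 * y[0] + a2 - 2 * b2 * y[1]
    v12 = scale.chain_scale_elasticity_lc(lc2, y, 0, 1, y12)
    assert v12 == pytest.approx(num / den, rel=1e-7)
    assert v12 > 1.0


def test_chain_elasticity_tends_to_one_as_joint_volume_vanishes(norm, truth):
    pt = hc.Point.mean(norm)
    tiny = 1e-6 * pt.y[OUTPUTS.index("er_visits")]
    link = hc.ChainLink("er_visits", "admissions", tiny)
    v12 = hc.chain_scale_elasticity(truth, pt, norm, link)
    assert v12 == pytest.approx(1.0, abs=1e-4)


def test_cobb_douglas_overall_elasticity_is_inverse_beta_sum(norm):
    rng = np.random.default_rng(5)
    p = random_translog_params(rng)
    p.B[:] = 0.0
    p.delta[:] = 0.0
    p.theta[:] = 0.0
    for _ in range(5):
        pt = random_point(rng, norm)
        v = hc.overall_scale_elasticity(p, pt, norm)
        assert v == pytest.approx(1.0 / p.beta.sum(), rel=1e-10)
    # constant returns: beta summing to one gives v = 1 everywhere
    p.beta = p.beta / p.beta.sum()
    pt = random_point(rng, norm)
    assert hc.overall_scale_elasticity(p, pt, norm) == pytest.approx(1.0)


def test_overall_elasticity_definitional_forms_agree(norm, truth):
    """The inverse elasticity sum and the cost-over-weighted-marginal-cost
    ratio are asserted equal inside the implementation; exercise both."""
    rng = np.random.default_rng(7)
    for _ in range(10):
        pt = random_point(rng, norm)
        v = hc.overall_scale_elasticity(truth, pt, norm)
        eps = hc.cost_elasticities(truth, pt.y, pt.w, pt.z, pt.year, norm)
        assert v == pytest.approx(1.0 / eps.sum(), abs=1e-12)


def test_product_specific_elasticity_matches_composition_oracle(norm):
    """Brute-force composition: level costs from exp(log cost) x mean cost at
    both points, level-space numeric marginal cost."""
    rng = np.random.default_rng(9)
    for _ in range(10):
        p = random_translog_params(rng)
        pt = random_point(rng, norm)
        m = int(rng.integers(0, 4))
        y_min = pt.y[m] * rng.uniform(0.2, 0.8)
        got = hc.product_specific_scale_elasticity(p, pt, norm, m, y_min)

        def levels(y):
            return np.exp(hc.log_cost(p, y, pt.w, pt.z, pt.year, norm)) \
                * norm.total_cost

        y_cf = pt.y.copy()
        y_cf[m] = y_min
        h = 1e-6 * pt.y[m]
        up, dn = pt.y.copy(), pt.y.copy()
        up[m] += h
        dn[m] -= h
        mc = (levels(up) - levels(dn)) / (2 * h)
        expected = (levels(pt.y) - levels(y_cf)) / (pt.y[m] - y_min) / mc
        assert got == pytest.approx(expected, rel=1e-3)


def test_chain_elasticity_matches_composition_oracle(norm, truth):
    rng = np.random.default_rng(10)
    pt = random_point(rng, norm)
    link = hc.ChainLink("er_visits", "outpatients",
                        0.25 * pt.y[OUTPUTS.index("er_visits")])
    got = hc.chain_scale_elasticity(truth, pt, norm, link)

    def levels(y):
        return np.exp(hc.log_cost(truth, y, pt.w, pt.z, pt.year, norm)) \
            * norm.total_cost

    y_cf = pt.y.copy()
    y_cf[OUTPUTS.index("er_visits")] -= link.y12
    y_cf[OUTPUTS.index("outpatients")] -= link.y12
    mc = 0.0
    for m in (OUTPUTS.index("er_visits"), OUTPUTS.index("outpatients")):
        h = 1e-6 * pt.y[m]
        up, dn = pt.y.copy(), pt.y.copy()
        up[m] += h
        dn[m] -= h
        mc += (levels(up) - levels(dn)) / (2 * h)
    expected = (levels(pt.y) - levels(y_cf)) / link.y12 / mc
    assert got == pytest.approx(expected, rel=1e-3)


def test_conditional_derivative_sign_and_slope_oracle():
    """For c = (y1 + y2)^k with k < 1, increasing returns of service 2
    diminish as service 1 grows: dv(y2|y1)/dy1 < 0, matching the slope of a
    5-point local polynomial fit."""
    k = 0.8
    lc = PolynomialCost(lambda y: (y[0] + y[1]) ** k + 0.0 * y[2])
    y0 = np.array([200.0, 150.0, 1.0, 1.0])
    y_min = 30.0

    def v_of_y1(y1):
        y = y0.copy()
        y[0] = y1
        return scale.product_specific_scale_elasticity_lc(lc, y, 1, y_min)

    h = 1e-4 * y0[0]
    deriv = (v_of_y1(y0[0] + h) - v_of_y1(y0[0] - h)) / (2 * h)
    assert deriv < 0.0
    grid = y0[0] + np.linspace(-2, 2, 5) * 2.0
    poly = np.polyfit(grid, [v_of_y1(g) for g in grid], 2)
    slope = np.polyval(np.polyder(poly), y0[0])
    assert deriv == pytest.approx(slope, rel=1e-3)
    # linear cost: the derivative vanishes
    lin = PolynomialCost(lambda y: 3.0 * y[0] + 2.0 * y[1])
    def v_lin(y1):
        y = y0.copy()
        y[0] = y1
        return scale.product_specific_scale_elasticity_lc(lin, y, 1, y_min)
    dlin = (v_lin(y0[0] + h) - v_lin(y0[0] - h)) / (2 * h)
    assert dlin == pytest.approx(0.0, abs=1e-10)


def test_conditional_derivative_translog_interface(norm, truth):
    d = hc.conditional_elasticity_derivative(
        truth, hc.Point.mean(norm), norm, "er_visits", "admissions",
        y_min=8000.0)
    assert np.isfinite(d)
    with pytest.raises(ValueError, match="differ"):
        hc.conditional_elasticity_derivative(
            truth, hc.Point.mean(norm), norm, "er_visits", "er_visits", 8000.0)


def test_guardrails():
    with pytest.raises(ValueError):
        hc.ChainLink("er_visits", "er_visits", 10.0)
    with pytest.raises(KeyError):
        hc.ChainLink("er_visits", "radiology", 10.0)
    with pytest.raises(ValueError):
        hc.ChainLink("er_visits", "admissions", -1.0)
    lc = PolynomialCost(lambda y: y.sum())
    y = np.array([10.0, 10.0, 10.0, 10.0])
    with pytest.raises(ValueError, match="y_min"):
        scale.product_specific_scale_elasticity_lc(lc, y, 0, 12.0)
    with pytest.raises(scale.RegularityError, match="y12"):
        scale.chain_scale_elasticity_lc(lc, y, 0, 1, 10.0)


def test_quartile_report_single_hospital_and_labels(truth, small_panel):
    panel, norm = small_panel
    one = panel[panel["hospital"] == panel["hospital"].iloc[0]]
    one = one[one["year"] == one["year"].iloc[0]]
    rep = hc.quartile_report(truth, one, norm,
                             y_min={o: 0.5 * float(one[o].iloc[0])
                                    for o in OUTPUTS})
    assert (rep["q1"] == rep["median"]).all()
    assert (rep["median"] == rep["q3"]).all()
    full = hc.quartile_report(truth, panel, norm)
    for label in ["mc_admissions", "overall", "product_specific_er_visits",
                  "chain_er_visits_admissions", "chain_er_visits_outpatients"]:
        assert label in full.index
    assert (full.loc["overall", "q1"] <= full.loc["overall", "median"]
            <= full.loc["overall", "q3"])
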