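"""IER relative risk, trade attribution, mortality and ensemble CIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tradeair as ta
from tradeair.health import HealthError, _IncrementGrid
from tradeair.synthetic import IERParameterDraws


PARAMS = dict(C0=6.9, alpha=1.4, gamma=0.035, delta=0.8)


class TestRelativeRisk:
    def test_unity_below_counterfactual(self):
        C = np.array([0.0, 3.0, 6.9])
        np.testing.assert_array_equal(
            ta.relative_risk(C, **PARAMS), np.ones(3))

    def test_hand_value(self):
        # C0=5, alpha=1, gamma=0.01, delta=1 at C=105: 1 + (1 - e^-1)
        rr = ta.relative_risk(105.0, 5.0, 1.0, 0.01, 1.0)
        assert rr == pytest.approx(1 + (1 - np.exp(-1)), rel=1e-12)

    def test_plateau_at_high_concentration(self):
        rr = ta.relative_risk(PARAMS["C0"] + 1e4, **PARAMS)
        assert abs(rr - (1 + PARAMS["alpha"])) < 1e-9

    def test_invalid_parameters_rejected(self):
        with pytest.raises(HealthError):
            ta.relative_risk(10.0, 5.0, -1.0, 0.01, 1.0)


class TestRROfTrade:
    def test_zero_increment_exactly_one(self):
        assert ta.rr_of_trade(0.0, 80.0, **PARAMS) == 1.0

    def test_flat_region_below_counterfactual(self):
        assert ta.rr_of_trade(2.0, 3.0, **PARAMS) == 1.0

    def test_degenerate_distribution(self):
        # C_noTRE = 0: every term is RR(C_TRE)/RR(0) = RR(C_TRE)
        assert ta.rr_of_trade(50.0, 0.0, **PARAMS) == pytest.approx(
            ta.relative_risk(50.0, **PARAMS))

    @settings(max_examples=25, deadline=None)
    @given(ct=st.floats(-30, 60), cn=st.floats(0, 150))
    def test_negative_increment_never_raises_risk(self, ct, cn):
        rr = ta.rr_of_trade(ct, cn, **PARAMS)
        if ct <= 0:
            assert rr <= 1.0 + 1e-12
        else:
            assert rr >= 1.0 - 1e-12

    def test_monotone_in_increment(self):
        cts = np.linspace(-30, 60, 40)
        rr = ta.rr_of_trade(cts, np.full_like(cts, 70.0), **PARAMS)
        assert (np.diff(rr) >= -1e-12).all()

    def test_negative_distribution_rejected(self):
        with pytest.raises(HealthError):
            ta.rr_of_trade(1.0, -5.0, **PARAMS)

    def test_table_fast_path_matches_direct(self):
        rng = np.random.default_rng(1)
        ct = rng.uniform(-20, 50, 200)
        cn = rng.uniform(0, 120, 200)
        direct = ta.rr_of_trade(ct, cn, **PARAMS)
        grid = _IncrementGrid(ct, cn, N=1000)
        row = np.array([[PARAMS["C0"], PARAMS["alpha"], PARAMS["gamma"],
                         PARAMS["delta"]]])
        table = grid.rr_cells(row)[0]
        np.testing.assert_allclose(table, direct, atol=2e-5)


class TestAttributableFraction:
    def test_reference_values(self):
        assert np.all(ta.attributable_fraction(np.ones(5)) == 0)
        assert ta.attributable_fraction(np.array([2.0]))[0] == pytest.approx(0.5)
        af = ta.attributable_fraction(np.array([1.0, 3.0]), pop=np.array([1.0, 1.0]))
        assert af == pytest.approx(0.5)  # (0 + 2) / (1 + 3)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        rr = rng.uniform(1.0, 10.0, 100)
        af = ta.attributable_fraction(rr)
        assert ((af >= 0) & (af < 1)).all()
        assert ta.attributable_fraction(np.array([0.5]))[0] < 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(HealthError):
            ta.attributable_fraction(np.array([0.0]))
        with pytest.raises(HealthError):
            ta.attributable_fraction(np.array([2.0]), pop=np.array([0.0]))


class TestMortality:
    def test_product_and_sign(self):
        assert ta.mortality(0.1, 0.005, 1_000_000) == pytest.approx(500.0)
        assert ta.mortality(0.0, 0.005, 1e6) == 0.0
        assert ta.mortality(-0.1, 0.005, 1e6) == pytest.approx(-500.0)
        with pytest.raises(HealthError):
            ta.mortality(0.1, -0.005, 1e6)


def constant_draws(n_draws=10, **params):
    rows = []
    for ep in ("IHD", "COPD", "stroke", "LC"):
        for d in range(n_draws):
            rows.append({"endpoint": ep, "draw": d, **params})
    return IERParameterDraws(table=pd.DataFrame(rows))


@pytest.fixture(scope="module")
def exposure():
    rng = np.random.default_rng(2)
    shape = (12, 12)
    ct = rng.uniform(-5, 25, shape)
    cn = rng.uniform(10, 80, shape)
    pop = rng.uniform(1e3, 1e5, shape)
    rmap = (np.arange(144) % 3).reshape(shape)
    return ct, cn, pop, rmap


class TestMonteCarloCI:
    def test_identical_draws_collapse_interval(self, exposure):
        ct, cn, pop, rmap = exposure
        draws = constant_draws(10, **PARAMS)
        inc = {"IHD": 1e-3, "COPD": 1e-3, "stroke": 1e-3, "LC": 1e-3}
        res = ta.monte_carlo_ci(ct, cn, pop, rmap, ["a", "b", "c"], draws, inc)
        np.testing.assert_allclose(res.lower95, res.central, rtol=1e-12)
        np.testing.assert_allclose(res.upper95, res.central, rtol=1e-12)

    def test_interval_brackets_central_and_is_deterministic(
            self, exposure, small_world):
        ct, cn, pop, rmap = exposure
        w = small_world
        res1 = ta.monte_carlo_ci(ct, cn, pop, rmap, ["a", "b", "c"],
                                 w.ier_draws, w.incidence)
        res2 = ta.monte_carlo_ci(ct, cn, pop, rmap, ["a", "b", "c"],
                                 w.ier_draws, w.incidence)
        np.testing.assert_array_equal(res1.central, res2.central)
        np.testing.assert_array_equal(res1.upper95, res2.upper95)
        assert (res1.lower95 <= res1.central + 1e-9).all()
        assert (res1.central <= res1.upper95 + 1e-9).all()
        med = np.median(res1.draw_totals)
        assert res1.total_lower95 <= med <= res1.total_upper95

    def test_region_totals_sum_cells(self, exposure, small_world):
        ct, cn, pop, rmap = exposure
        w = small_world
        res = ta.monte_carlo_ci(ct, cn, pop, rmap, ["a", "b", "c"],
                                w.ier_draws, w.incidence)
        assert res.cell_central.shape == ct.shape
        assert res.cell_central.sum() == pytest.approx(res.total_central, rel=1e-9)
        per_region, national = ta.health.aggregate(res.cell_central, rmap, 3)
        np.testing.assert_allclose(per_region, res.central.sum(1), rtol=1e-9)
        assert national == pytest.approx(res.total_central, rel=1e-12)

    def test_too_few_draws_rejected(self, exposure, small_world):
        ct, cn, pop, rmap = exposure
        with pytest.raises(HealthError, match="at least 2"):
            ta.monte_carlo_ci(ct, cn, pop, rmap, ["a", "b", "c"],
                              small_world.ier_draws, small_world.incidence,
                              draw_slice=slice(0, 1))


class TestAggregate:
    def test_partition_sums_and_empty_region(self):
        deaths = np.array([[1.0, 2.0], [3.0, 4.0]])
        rmap = np.array([[0, 0], [1, 1]])
        per_region, national = ta.health.aggregate(deaths, rmap, 3)
        np.testing.assert_allclose(per_region, [3.0, 7.0, 0.0])
        assert national == pytest.approx(10.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(HealthError):
            ta.health.aggregate(np.ones(4), np.zeros(5, dtype=int), 1)
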