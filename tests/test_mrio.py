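"""Unit tests for the linked-MRIO algebra."""

import numpy as np
import pandas as pd
import pytest

import tradeair as ta
from tradeair.mrio import MRIOError

from conftest import make_autarkic_table


def one_sector_table(Z, Y, regions=None, n_domestic=1):
    Z = np.asarray(Z, float)
    Y = np.asarray(Y, float)
    R = Z.shape[0]
    regions = regions or [f"r{i}" for i in range(R)]
    return ta.LinkedMRIOTable(
        regions=regions, n_domestic=n_domestic, sectors=["s"],
        Z=Z, Y=Y, x=Z.sum(1) + Y.sum(1),
    )


class TestTechnicalCoefficients:
    def test_no_intermediates_gives_identity_inverse(self):
        t = one_sector_table(np.zeros((2, 2)), np.eye(2) * 5.0, n_domestic=2)
        c = ta.technical_coefficients(t)
        assert np.all(c.A == 0)
        np.testing.assert_allclose(c.L, np.eye(2), atol=1e-14)

    def test_scalar_geometric_series(self):
        # one sector, A = 0.2 => multiplier 1/(1-0.2) = 1.25
        t = one_sector_table([[0.2]], [[0.8]])
        c = ta.technical_coefficients(t)
        assert c.A[0, 0] == pytest.approx(0.2)
        assert c.L[0, 0] == pytest.approx(1.25, rel=1e-12)

    def test_leontief_identity_and_output_recovery(self, small_world):
        t = small_world.economy
        c = ta.technical_coefficients(t)
        n = t.n_flat
        assert np.abs(c.L @ (np.eye(n) - c.A) - np.eye(n)).max() < 1e-8
        np.testing.assert_allclose((c.L @ t.Y).sum(1), t.x, rtol=1e-8)

    def test_zero_output_sector_column_zeroed(self):
        t = one_sector_table([[0.2, 0], [0, 0]], [[0.8, 0], [0, 0]], n_domestic=2)
        c = ta.technical_coefficients(t)
        assert np.all(c.A[:, 1] == 0)

    def test_nonproductive_economy_rejected(self):
        t = one_sector_table([[2.0]], [[0.1]])
        t.x = np.array([1.0])  # force A = 2 > 1
        with pytest.raises(MRIOError, match="spectral radius"):
            ta.technical_coefficients(t)


class TestEmbodiedEmissions:
    def test_hand_example_single_region(self):
        # F = 2 g/$, L = 1.25, Y = 10 => 25 g embodied
        t = one_sector_table([[2.5]], [[10.0]])  # x = 12.5, A = 0.2
        c = ta.technical_coefficients(t)
        tensor = ta.embodied_emissions(np.array([[2.0]]), c, t, ["SO2"])
        assert tensor.values[0, 0, 0, 0] == pytest.approx(25.0, rel=1e-12)

    def test_zero_intensity_zero_tensor(self, small_world):
        t = small_world.economy
        c = ta.technical_coefficients(t)
        F = np.zeros((1, t.n_flat))
        tensor = ta.embodied_emissions(F, c, t, ["SO2"])
        assert np.all(tensor.values == 0)

    def test_consumer_sum_recovers_production(self, small_world):
        w = small_world
        c = ta.technical_coefficients(w.economy)
        tensor = ta.embodied_emissions(w.intensities, c, w.economy, w.pollutants)
        prod = tensor.values.sum(axis=3).reshape(len(w.pollutants), -1)
        np.testing.assert_allclose(
            prod, w.intensities * w.economy.x[None, :], rtol=1e-8
        )

    def test_homogeneity_in_final_demand(self, small_world):
        w = small_world
        t = w.economy
        c = ta.technical_coefficients(t)
        t1 = ta.embodied_emissions(w.intensities, c, t, w.pollutants)
        doubled = ta.LinkedMRIOTable(
            regions=t.regions, n_domestic=t.n_domestic, sectors=t.sectors,
            Z=t.Z, Y=2 * t.Y, x=t.x,
        )
        t2 = ta.embodied_emissions(w.intensities, c, doubled, w.pollutants)
        np.testing.assert_array_equal(t2.values, 2 * t1.values)

    def test_dimension_mismatch_rejected(self, small_world):
        w = small_world
        c = ta.technical_coefficients(w.economy)
        with pytest.raises(MRIOError, match="dimension"):
            ta.embodied_emissions(np.ones((1, 3)), c, w.economy, ["SO2"])


class TestAccounts:
    def test_autarky_production_equals_consumption(self):
        t = make_autarkic_table(3, 2)
        c = ta.technical_coefficients(t)
        F = np.ones((1, 3)) * 1e-3
        acc = ta.accounts(ta.embodied_emissions(F, c, t, ["SO2"]))
        np.testing.assert_allclose(acc.E_p, acc.E_c, rtol=1e-12)
        assert np.all(acc.domestic_out == 0) and np.all(acc.foreign_in == 0)

    def test_global_conservation(self, small_world):
        w = small_world
        c = ta.technical_coefficients(w.economy)
        acc = ta.accounts(ta.embodied_emissions(w.intensities, c, w.economy,
                                                w.pollutants))
        tot_p = acc.E_p.sum(1)
        tot_c = acc.E_c.sum(1)
        np.testing.assert_allclose(tot_p, tot_c, rtol=1e-9)

    def test_complete_outsourcing(self):
        # region 0 produces everything; region 1 is the only consumer
        Z = np.zeros((2, 2))
        Y = np.array([[0.0, 10.0], [0.0, 0.0]])
        t = one_sector_table(Z, Y, n_domestic=2)
        c = ta.technical_coefficients(t)
        acc = ta.accounts(ta.embodied_emissions(np.array([[1.0, 1.0]]), c, t, ["p"]))
        assert acc.E_p[0, 0] == pytest.approx(acc.E_c[0, 1])
        assert acc.E_c[0, 0] == 0 and acc.E_p[0, 1] == 0

    def test_decomposition_partitions_exactly(self, small_world):
        w = small_world
        c = ta.technical_coefficients(w.economy)
        acc = ta.accounts(ta.embodied_emissions(w.intensities, c, w.economy,
                                                w.pollutants))
        np.testing.assert_array_equal(
            acc.E_p, acc.local + acc.domestic_out + acc.foreign_out
        )
        np.testing.assert_array_equal(
            acc.E_c, acc.local + acc.domestic_in + acc.foreign_in
        )


class TestEmissionIntensity:
    def test_simple_ratio_and_roundtrip(self):
        F = ta.emission_intensity(np.array([[10.0, 0.0]]), np.array([2.0, 0.0]))
        np.testing.assert_array_equal(F, [[5.0, 0.0]])
        x = np.array([2.0, 3.0])
        E = np.array([[4.0, 9.0]])
        np.testing.assert_allclose(ta.emission_intensity(E, x) * x, E, rtol=1e-12)

    def test_negative_emissions_rejected(self):
        with pytest.raises(MRIOError):
            ta.emission_intensity(np.array([[-1.0]]), np.array([1.0]))


class TestSectorMap:
    def test_identity_split_and_conservation(self):
        raw = pd.DataFrame({"category": ["a", "b"], "region": ["r", "r"],
                            "value": [10.0, 4.0]})
        out = ta.sector_map(raw, {"a": {"s1": 0.6, "s2": 0.4}, "b": {"s1": 1.0}})
        got = dict(zip(out.sector, out.value)) if len(out) == 2 else \
            out.groupby("sector")["value"].sum().to_dict()
        assert got["s1"] == pytest.approx(10.0)  # 6 + 4
        assert got["s2"] == pytest.approx(4.0)
        assert out.value.sum() == pytest.approx(raw.value.sum(), rel=1e-12)

    def test_unmapped_category_and_bad_weights_rejected(self):
        raw = pd.DataFrame({"category": ["a"], "value": [1.0]})
        with pytest.raises(MRIOError, match="unmapped"):
            ta.sector_map(raw, {})
        with pytest.raises(MRIOError, match="sum"):
            ta.sector_map(raw, {"a": {"s1": 0.5, "s2": 0.4}})


class TestLinkTables:
    def _toy_pair(self):
        dom = one_sector_table([[1.0, 0.5], [0.5, 1.0]], np.eye(2) * 10 + 2,
                               regions=["d1", "d2"], n_domestic=2)
        foreign = one_sector_table([[3.0]], [[2.0]], regions=["f1"])
        return dom, foreign

    def test_zero_trade_preserves_blocks(self):
        dom, foreign = self._toy_pair()
        linked = ta.link_tables(dom, foreign, np.zeros((2, 1)), np.zeros((1, 2)))
        np.testing.assert_array_equal(linked.Z[:2, :2], dom.Z)
        np.testing.assert_array_equal(linked.Z[2:, 2:], foreign.Z)
        np.testing.assert_array_equal(linked.Y[:2, :2], dom.Y)
        assert np.all(linked.Z[:2, 2:] == 0) and np.all(linked.Y[:2, 2:] == 0)

    def test_proportional_idm_fdm_split(self):
        # destination absorbs 3:2 intermediate:final => exports of 5 split 3/2
        dom, foreign = self._toy_pair()
        exports = np.array([[5.0], [0.0]])
        linked = ta.link_tables(dom, foreign, exports, np.zeros((1, 2)))
        assert linked.Z[0, 2] == pytest.approx(3.0)
        assert linked.Y[0, 2] == pytest.approx(2.0)

    def test_trade_matrices_recovered(self):
        dom, foreign = self._toy_pair()
        exports = np.array([[5.0], [1.5]])
        imports = np.array([[2.0, 0.7]])
        linked = ta.link_tables(dom, foreign, exports, imports)
        idm_plus_fdm_exp = linked.Z[:2, 2:].sum(1, keepdims=True) + linked.Y[:2, 2:]
        np.testing.assert_allclose(idm_plus_fdm_exp, exports, rtol=1e-9)
        np.testing.assert_allclose(
            linked.Z[2:, :2].sum(1) + linked.Y[2:, :2].sum(1),
            imports.sum(1), rtol=1e-9,
        )
        linked.validate()

    def test_infeasible_destination_rejected(self):
        dom = one_sector_table([[1.0]], [[9.0]], regions=["d1"])
        dead = one_sector_table([[0.0]], [[0.0]], regions=["f1"])
        with pytest.raises(MRIOError, match="infeasible"):
            ta.link_tables(dom, dead, np.array([[5.0]]), np.zeros((1, 1)))
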