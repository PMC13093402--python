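"""Flow-network assembly and whole-system indices."""

import numpy as np
import pytest

import limnoweb as lw
from conftest import make_chain_model
from limnoweb.network import total_system_throughput


class TestFlowNetwork:
    def test_phytoplankton_to_zooplankton_flow(self, kaptai, network):
        i, j = kaptai.index("Phytoplankton"), kaptai.index("Zooplankton")
        assert network.flows[i, j] == pytest.approx(12.85 * 140 * 0.8, rel=1e-9)

    def test_exports_are_catch_plus_detritus_surplus(self, balanced, network):
        det = balanced.model.index("Detritus")
        catch = balanced.exports.sum()
        surplus = network.exports[det] - balanced.exports[det]
        inflow = balanced.flow_to_detritus.sum()
        consumed = network.flows[det, :].sum()
        assert surplus == pytest.approx(inflow - consumed, rel=1e-9)
        assert network.exports.sum() == pytest.approx(catch + surplus, rel=1e-9)

    def test_producer_only_web(self):
        model = make_chain_model(diet_on_producer=1.0)
        model.groups[1].biomass = 1e-12  # vanishing consumer: effectively producers only
        b = lw.solve(model)
        net = lw.build_flow_network(b)
        i = model.index("algae")
        assert net.exports[model.index("detritus")] == pytest.approx(
            b.flow_to_detritus.sum(), rel=1e-9
        )
        assert b.flow_to_detritus[i] == pytest.approx(
            (1 - b.ee[i]) * b.production[i]
        )

    def test_all_flows_nonnegative(self, network):
        assert np.all(network.flows >= 0)
        assert np.all(network.respiration >= 0)
        assert not network.negative_export_groups


class TestSummary:
    def test_tst_additivity_exact(self, balanced, network):
        s = lw.system_summary(network, balanced)
        assert s.tst == s.total_consumption + s.total_exports + s.total_respiration + s.total_flows_to_detritus
        assert s.tst == pytest.approx(total_system_throughput(network), rel=1e-9)

    def test_nsp_equals_exports_on_closed_web(self, balanced, network):
        # no imports: net system production must leave as exports
        s = lw.system_summary(network, balanced)
        assert s.nsp == pytest.approx(s.total_exports, rel=1e-6)

    def test_mtlc_weighted_by_landings(self, balanced, network):
        s = lw.system_summary(network, balanced)
        w = balanced.exports
        expected = float((w * balanced.trophic_level).sum() / w.sum())
        assert s.mtlc == pytest.approx(expected)

    def test_zero_catch_gives_absent_mtlc(self):
        model = make_chain_model(landings=0.0)
        b = lw.solve(model)
        s = lw.system_summary(lw.build_flow_network(b), b)
        assert s.mtlc is None
        assert s.gross_efficiency is None


class TestShannon:
    def test_equal_biomasses_maximal(self):
        assert lw.shannon_diversity(np.ones(8)) == pytest.approx(np.log(8))

    def test_single_group_zero(self):
        assert lw.shannon_diversity(np.array([5.0])) == 0.0

    def test_below_maximum_when_uneven(self):
        assert lw.shannon_diversity(np.array([10.0, 1.0, 1.0])) < np.log(3)


class TestConnectance:
    def test_fixture_link_count_convention(self, balanced):
        links = np.count_nonzero(balanced.model.diet.entries)
        assert lw.connectance_index(balanced) == pytest.approx(links / 14**2)
        assert lw.connectance_index(balanced, "n_n_minus_1") == pytest.approx(
            links / (14 * 13)
        )


class TestFinnCycling:
    def test_acyclic_web_has_zero_fci(self):
        web, _ = lw.generate_web(
            lw.SyntheticWebSpec(n_consumers=5, has_detritus=False, cannibalism_prob=0.0, seed=3)
        )
        b = lw.solve(web)
        fci, cycled, _ = lw.finn_cycling(lw.build_flow_network(b))
        assert fci == pytest.approx(0.0, abs=1e-12)
        assert cycled == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_flow_rescaling(self, balanced, network):
        fci, _, _ = lw.finn_cycling(network)
        scaled = lw.FlowNetwork(
            names=network.names,
            flows=network.flows * 7.0,
            imports=network.imports * 7.0,
            exports=network.exports * 7.0,
            respiration=network.respiration * 7.0,
            living=network.living,
            detritus=network.detritus,
        )
        fci2, _, _ = lw.finn_cycling(scaled)
        assert fci2 == pytest.approx(fci, rel=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_walk_sum_oracle(self, seed):
        """Leontief diagonal vs explicit walk enumeration by path length."""
        web, _ = lw.generate_web(
            lw.SyntheticWebSpec(n_consumers=3, tl_layers=2, cannibalism_prob=0.5, seed=seed)
        )
        b = lw.solve(web)
        net = lw.build_flow_network(b)
        inflow = net.compartment_inflow()
        n = net.n
        G = np.zeros((n, n))
        nz = inflow > 0
        G[:, nz] = net.flows[:, nz] / inflow[nz]
        # oracle: L = sum_k G^k accumulated walk by walk until convergence
        L = np.eye(n)
        term = np.eye(n)
        for _ in range(2000):
            term = term @ G
            L += term
            if np.abs(term).max() < 1e-14:
                break
        cycled_oracle = float(((np.diag(L) - 1) / np.diag(L) * inflow).sum())
        fci, cycled, _ = lw.finn_cycling(net)
        assert cycled == pytest.approx(cycled_oracle, abs=1e-8, rel=1e-8)

    def test_fmpl_definition(self, balanced, network):
        _, _, fmpl = lw.finn_cycling(network)
        s = lw.system_summary(network, balanced)
        assert fmpl == pytest.approx(s.tst / (s.total_exports + s.total_respiration), rel=1e-9)


class TestAscendancy:
    def test_single_flow_fully_determined(self):
        net = lw.FlowNetwork(
            names=["a", "b"],
            flows=np.array([[0.0, 5.0], [0.0, 0.0]]),
            imports=np.zeros(2),
            exports=np.zeros(2),
            respiration=np.zeros(2),
            living=np.array([True, True]),
            detritus=np.array([False, False]),
        )
        a, o, _ = lw.ascendancy(net)
        assert a == pytest.approx(100.0)
        assert o == pytest.approx(0.0, abs=1e-9)

    def test_percentages_partition_capacity(self, network):
        a, o, c = lw.ascendancy(network)
        assert a + o == pytest.approx(100.0, rel=1e-9)
        assert c > 0

    def test_scale_invariance(self, network):
        a, o, _ = lw.ascendancy(network)
        scaled = lw.FlowNetwork(
            names=network.names,
            flows=network.flows * 3.5,
            imports=network.imports * 3.5,
            exports=network.exports * 3.5,
            respiration=network.respiration * 3.5,
            living=network.living,
            detritus=network.detritus,
        )
        a2, o2, _ = lw.ascendancy(scaled)
        assert a2 == pytest.approx(a, rel=1e-12)
        assert o2 == pytest.approx(o, rel=1e-12)


class TestPedigreeScaffold:
    def test_mean_and_fit(self):
        p, t = lw.pedigree_index([0.5, 0.7, 0.6, 0.8])
        assert p == pytest.approx(0.65)
        assert t == pytest.approx(0.65 * np.sqrt(2) / np.sqrt(1 - 0.65**2))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            lw.pedigree_index([1.2])
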