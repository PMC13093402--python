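"""Mass-balance solver: unknown recovery, conservation, derived statistics."""

import numpy as np
import pytest
from scipy.optimize import fsolve

import limnoweb as lw
from conftest import make_chain_model


class TestSingleLink:
    def test_producer_and_consumer_ee(self):
        model = make_chain_model(producer_b=1, producer_pb=10, consumer_b=0.1, consumer_qb=10)
        b = lw.solve(model)
        assert b.ee[model.index("algae")] == pytest.approx(0.1)
        assert b.ee[model.index("grazer")] == pytest.approx(0.0)

    def test_full_ee_consumer_sends_only_egestion_to_detritus(self):
        # all grazer production is removed by the fishery -> EE = 1 and
        # the flow to detritus is exactly the unassimilated intake
        model = make_chain_model(consumer_pb=2.0, consumer_b=0.1, landings=0.2)
        b = lw.solve(model)
        i = model.index("grazer")
        assert b.ee[i] == pytest.approx(1.0)
        assert b.flow_to_detritus[i] == pytest.approx(0.2 * b.consumption[i])


class TestConservation:
    def test_balance_residuals_vanish(self, balanced):
        res = balanced.residuals()
        scale = np.where(np.isnan(balanced.production), 1.0, np.abs(balanced.production)) + 1.0
        assert np.all(np.abs(res) < 1e-9 * scale)

    def test_production_partition(self, balanced):
        """P = predation + landings + (1 - EE) P for every living group."""
        for i, g in enumerate(balanced.model.groups):
            if not g.is_living:
                continue
            lhs = balanced.production[i]
            rhs = (
                balanced.predation_mortality_flow[i]
                + balanced.exports[i]
                + (1 - balanced.ee[i]) * balanced.production[i]
            )
            assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_total_flow_to_detritus(self, balanced):
        assert balanced.flow_to_detritus.sum() == pytest.approx(1550.573, abs=0.5)

    def test_all_ee_within_unit_interval(self, balanced):
        assert balanced.unbalanced_groups == []
        living = [g.is_living for g in balanced.model.groups]
        assert np.all(balanced.ee[living] >= 0)
        assert np.all(balanced.ee[living] <= 1)


class TestDerivedStatistics:
    def test_zooplankton_flow_to_detritus(self, balanced):
        i = balanced.model.index("Zooplankton")
        q, p, ee = balanced.consumption[i], balanced.production[i], balanced.ee[i]
        assert balanced.flow_to_detritus[i] == pytest.approx(0.2 * q + (1 - ee) * p)

    def test_minnow_respiration_ratio(self, balanced):
        i = balanced.model.index("Minnow")
        assert balanced.ra[i] == pytest.approx(1 - 3.26 / (0.8 * 76.2), rel=1e-9)

    def test_ratio_identities(self, balanced):
        cons = balanced.model.consumer_indices()
        np.testing.assert_allclose(
            balanced.assimilation[cons], 0.8 * balanced.consumption[cons]
        )
        np.testing.assert_allclose(
            balanced.respiration[cons],
            balanced.assimilation[cons] - balanced.production[cons],
        )
        np.testing.assert_allclose(
            balanced.net_efficiency[cons] + balanced.ra[cons], 1.0, rtol=1e-12
        )

    def test_no_negative_respiration_on_fixture(self, balanced):
        assert balanced.negative_respiration_groups == []


class TestDetritusEE:
    def test_fixture_value(self, balanced):
        det = balanced.model.index("Detritus")
        assert balanced.ee[det] == pytest.approx(353.9 / 1550.573, abs=0.005)

    def test_no_detritivores_gives_zero(self):
        model = make_chain_model()
        b = lw.solve(model)
        assert b.ee[model.index("detritus")] == 0.0


class TestSolverStructure:
    def test_idempotent_on_complete_model(self, kaptai, balanced):
        complete = kaptai.copy()
        for i, g in enumerate(complete.groups):
            g.biomass = float(balanced.biomass[i])
            if g.is_living:
                g.ee = float(balanced.ee[i])
        again = lw.solve(complete)
        np.testing.assert_allclose(again.biomass, balanced.biomass, rtol=1e-12)
        np.testing.assert_allclose(again.ee, balanced.ee, rtol=1e-12)
        assert np.all(np.abs(again.residuals()) < 1e-9)

    def test_order_independent(self, kaptai, balanced):
        perm = list(reversed(range(kaptai.n)))
        groups = [kaptai.copy().groups[i] for i in perm]
        entries = kaptai.diet.entries[np.ix_(perm, perm)]
        diet = lw.DietMatrix(group_names=[g.name for g in groups], entries=entries)
        model = lw.FoodWebModel(groups=groups, diet=diet)
        b = lw.solve(model)
        np.testing.assert_allclose(b.biomass, balanced.biomass[perm], rtol=1e-10)
        np.testing.assert_allclose(b.ee, balanced.ee[perm], rtol=1e-10)

    def test_singular_system_reports_groups(self):
        # cannibal whose production demand exactly equals its self-predation:
        # the unknown-biomass equation degenerates to 0 * B = landings
        groups = [
            lw.FunctionalGroup("algae", lw.GroupType.PRODUCER, biomass=1.0, pb=10.0),
            lw.FunctionalGroup(
                "cannibal", lw.GroupType.CONSUMER, biomass=None, pb=10.0, qb=50.0, ee=0.5
            ),
            lw.FunctionalGroup("detritus", lw.GroupType.DETRITUS, biomass=1.0, unassimilated=0.0),
        ]
        entries = np.zeros((3, 3))
        entries[1, 1] = 0.1  # self-predation 50 * 0.1 = 5 = pb * ee
        entries[0, 1] = 0.9
        diet = lw.DietMatrix(group_names=[g.name for g in groups], entries=entries)
        model = lw.FoodWebModel(groups=groups, diet=diet)
        with pytest.raises(lw.balance.UnsolvableModelError, match="cannibal"):
            lw.solve(model)


class TestOracleEquivalence:
    """The linear solver must agree with a brute-force nonlinear root find."""

    @pytest.mark.parametrize("seed", range(8))
    def test_masked_unknowns_match_fsolve(self, seed):
        spec = lw.SyntheticWebSpec(n_consumers=5, tl_layers=2, seed=seed, cannibalism_prob=0.3)
        web, _ = lw.generate_web(spec)
        masked = lw.mask_parameter(web, "consumer_1", "biomass")
        masked = lw.mask_parameter(masked, "consumer_4", "biomass")
        b = lw.solve(masked)

        unknown = [masked.index("consumer_1"), masked.index("consumer_4")]
        dc = masked.diet.entries

        def residual(x):
            biomass = np.array(
                [g.biomass if g.biomass is not None else np.nan for g in masked.groups]
            )
            for k, i in enumerate(unknown):
                biomass[i] = x[k]
            out = []
            for k, i in enumerate(unknown):
                g = masked.groups[i]
                predation = sum(
                    biomass[j] * masked.groups[j].qb * dc[i, j]
                    for j in masked.consumer_indices()
                )
                out.append(biomass[i] * g.pb * g.ee - predation - g.landings)
            return out

        root = fsolve(residual, np.ones(len(unknown)), full_output=False)
        np.testing.assert_allclose(b.biomass[unknown], root, rtol=1e-8)
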