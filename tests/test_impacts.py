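"""Mixed trophic impacts, keystone statistics, and Pianka niche overlap."""

import numpy as np
import pytest

import limnoweb as lw
from conftest import make_chain_model
from limnoweb.impacts import _net_impact_matrix


class TestMTI:
    def test_predation_sign_structure(self):
        model = make_chain_model(landings=0.01)
        res = lw.mti_matrix(lw.solve(model), include_fleet=False)
        f = res.frame()
        assert f.loc["algae", "grazer"] > 0  # food benefits the consumer
        assert f.loc["grazer", "algae"] < 0  # predation harms the prey

    def test_equals_truncated_path_sum_on_chain(self):
        """(I-q)^-1 - I equals the convergent sum of impact paths q^k."""
        # some non-predation mortality on the producer keeps the predation
        # feedback loop below unit gain, so the path sum converges
        model = make_chain_model(landings=0.05, diet_on_producer=0.7)
        model.groups[0].landings = 0.05
        b = lw.solve(model)
        q, _ = _net_impact_matrix(b, include_fleet=False)
        assert max(abs(np.linalg.eigvals(q))) < 1.0
        path_sum = np.zeros_like(q)
        term = np.eye(q.shape[0])
        for _ in range(5000):
            term = term @ q
            path_sum += term
            if np.abs(term).max() < 1e-15:
                break
        res = lw.mti_matrix(b, include_fleet=False)
        np.testing.assert_allclose(res.mti, path_sum, atol=1e-12)

    def test_equals_truncated_path_sum_on_synthetic_webs(self):
        # the equivalence holds whenever the impact matrix has spectral
        # radius below 1; skip the (valid) webs where the series diverges
        checked = 0
        for seed in range(12):
            web, _ = lw.generate_web(
                lw.SyntheticWebSpec(n_consumers=5, tl_layers=3, seed=seed)
            )
            b = lw.solve(web)
            q, _ = _net_impact_matrix(b, include_fleet=False)
            if max(abs(np.linalg.eigvals(q))) >= 1.0:
                continue
            checked += 1
            path_sum = np.zeros_like(q)
            term = np.eye(q.shape[0])
            for _ in range(20000):
                term = term @ q
                path_sum += term
                if np.abs(term).max() < 1e-15:
                    break
            res = lw.mti_matrix(b, include_fleet=False)
            np.testing.assert_allclose(res.mti, path_sum, atol=1e-9)
        assert checked >= 3

    def test_fleet_neutral_without_landings(self):
        model = make_chain_model(landings=0.0)
        b = lw.solve(model)
        with_fleet = lw.mti_matrix(b, include_fleet=True)
        without = lw.mti_matrix(b, include_fleet=False)
        n = model.n
        np.testing.assert_allclose(with_fleet.mti[:n, :n], without.mti, atol=1e-12)

    def test_diagonal_bounded(self, balanced):
        res = lw.mti_matrix(balanced)
        d = np.diag(res.mti)
        assert np.all(d >= -1 - 1e-9)
        assert np.all(d <= 1 + 1e-9)


class TestKeystone:
    def test_relative_impact_has_unique_maximum(self, balanced):
        res = lw.mti_matrix(balanced)
        rel = res.relative_total_impact[: balanced.model.n]
        assert np.sum(rel == 1.0) == 1

    def test_inert_group_scores_zero(self):
        model = make_chain_model()
        b = lw.solve(model)
        res = lw.mti_matrix(b, include_fleet=False)
        det = model.index("detritus")
        # the inert detritus pool (nobody eats it, it eats nobody) has no impact
        assert res.epsilon[det] == pytest.approx(0.0, abs=1e-12)
        assert res.relative_total_impact[det] == pytest.approx(0.0, abs=1e-12)

    def test_keystoneness_penalises_biomass(self, balanced):
        res = lw.mti_matrix(balanced)
        names = balanced.model.names
        eps = res.epsilon
        ks = res.keystoneness
        living = np.array([g.is_living for g in balanced.model.groups])
        b = np.where(living, balanced.biomass, 0.0)
        p = b / b.sum()
        for i, name in enumerate(names):
            if eps[i] > 0:
                assert ks[i] == pytest.approx(np.log10(eps[i] * (1 - p[i])))

    def test_rank_variant_runs(self, balanced):
        res = lw.mti_matrix(balanced)
        frame = lw.keystone_analysis(res, balanced, variant="rank")
        ks = frame["keystoneness"].iloc[: balanced.model.n]
        # the biomass rank-1 group has penalty 0, hence undefined keystoneness
        assert ks.notna().sum() == balanced.model.n - 1


class TestNicheOverlap:
    def test_identical_diets_overlap_fully(self):
        groups = [
            lw.FunctionalGroup("algae", lw.GroupType.PRODUCER, biomass=1.0, pb=10.0),
            lw.FunctionalGroup("g1", lw.GroupType.CONSUMER, biomass=0.1, pb=1.0, qb=10.0),
            lw.FunctionalGroup("g2", lw.GroupType.CONSUMER, biomass=0.1, pb=1.0, qb=10.0),
            lw.FunctionalGroup("detritus", lw.GroupType.DETRITUS, biomass=1.0, unassimilated=0.0),
        ]
        names = [g.name for g in groups]
        entries = np.zeros((4, 4))
        entries[0, 1] = entries[0, 2] = 0.5
        entries[3, 1] = entries[3, 2] = 0.5
        model = lw.FoodWebModel(groups=groups, diet=lw.DietMatrix(group_names=names, entries=entries))
        ov = lw.niche_overlap(lw.solve(model))
        assert ov.prey_frame().loc["g1", "g2"] == pytest.approx(1.0)

    def test_disjoint_diets_do_not_overlap(self):
        groups = [
            lw.FunctionalGroup("algae", lw.GroupType.PRODUCER, biomass=1.0, pb=10.0),
            lw.FunctionalGroup("g1", lw.GroupType.CONSUMER, biomass=0.1, pb=1.0, qb=10.0),
            lw.FunctionalGroup("g2", lw.GroupType.CONSUMER, biomass=0.1, pb=1.0, qb=10.0),
            lw.FunctionalGroup("detritus", lw.GroupType.DETRITUS, biomass=1.0, unassimilated=0.0),
        ]
        names = [g.name for g in groups]
        entries = np.zeros((4, 4))
        entries[0, 1] = 1.0  # herbivore
        entries[3, 2] = 1.0  # detritivore
        model = lw.FoodWebModel(groups=groups, diet=lw.DietMatrix(group_names=names, entries=entries))
        ov = lw.niche_overlap(lw.solve(model))
        assert ov.prey_frame().loc["g1", "g2"] == 0.0

    def test_symmetry_unit_diagonal_and_range(self, balanced):
        ov = lw.niche_overlap(balanced)
        for mat in (ov.prey_overlap, ov.predator_overlap):
            np.testing.assert_allclose(mat, mat.T, atol=1e-12)
            assert np.all(mat >= -1e-12)
            assert np.all(mat <= 1 + 1e-12)
        for j in balanced.model.consumer_indices():
            assert ov.prey_overlap[j, j] == pytest.approx(1.0)

    def test_invariant_to_profile_rescaling(self, balanced):
        # Pianka overlap depends only on profile direction, not magnitude
        dc = balanced.model.diet.entries
        from limnoweb.impacts import _pianka

        scaled = dc * np.linspace(1, 5, dc.shape[1])[np.newaxis, :]
        np.testing.assert_allclose(_pianka(dc), _pianka(scaled), atol=1e-12)
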