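"""Exact label propagation, turn dynamics and the Monte-Carlo oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tracefate import (IsotopomerDist, Metabolite, PoolState,
                       SimulationConfig, build_topology, collapse_to_mid,
                       condense, monte_carlo, simulate, step_turn,
                       symmetrize, transform)
from tracefate.errors import ContractError
from tracefate.isotope_sim import (CO2PoolState, bitrev_table,
                                   labeled_carbon_balance, propagate)
from tracefate.network import _PDH, _reductive_reactions


def reaction(topology_name, reaction_name):
    t = build_topology(topology_name)
    return t, {r.name: r for r in t.reactions}[reaction_name]


def random_dist(met, rng):
    return IsotopomerDist(met, rng.dirichlet(np.ones(2 ** met.n_carbons)))


PC = _reductive_reactions(True)[0]
PYR = Metabolite("PYR", 3)
FUM = Metabolite("FUM", 4, symmetric=True)


class TestCondense:
    def test_labeled_acetyl_plus_unlabeled_oaa_gives_m2_citrate(self):
        t, cs = reaction("oxidative_tca", "CS")
        cit = condense(IsotopomerDist.fully_labeled(t.metabolite("ACA")),
                       IsotopomerDist.unlabeled(t.metabolite("OAA")), cs)
        mid = collapse_to_mid(cit).fractions
        assert mid[2] == pytest.approx(1.0)

    def test_unlabeled_substrates_give_unlabeled_product(self):
        t, cs = reaction("oxidative_tca", "CS")
        cit = condense(IsotopomerDist.unlabeled(t.metabolite("ACA")),
                       IsotopomerDist.unlabeled(t.metabolite("OAA")), cs)
        assert cit.weights[0] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self, rng):
        t, cs = reaction("oxidative_tca", "CS")
        a = random_dist(t.metabolite("ACA"), rng)
        b = random_dist(t.metabolite("OAA"), rng)
        got = condense(a, b, cs).weights
        expected = np.zeros(64)
        for pa in range(4):
            for pb in range(16):
                pat = 0
                for ci, (slot, carbon) in enumerate(cs.product_sources[0]):
                    sub = pa if slot == 0 else pb
                    pat |= ((sub >> (carbon - 1)) & 1) << ci
                expected[pat] += a.weights[pa] * b.weights[pb]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_slot_mismatch_rejected(self, rng):
        t, cs = reaction("oxidative_tca", "CS")
        b = random_dist(t.metabolite("OAA"), rng)
        with pytest.raises(ContractError):
            condense(b, b, cs)


class TestTransform:
    def test_decarboxylation_of_fully_labeled_pyruvate(self):
        aca, co2 = transform(IsotopomerDist.fully_labeled(PYR), _PDH)
        assert collapse_to_mid(aca).fractions[2] == pytest.approx(1.0)
        assert co2 == pytest.approx(1.0)

    def test_unlabeled_pyruvate(self):
        aca, co2 = transform(IsotopomerDist.unlabeled(PYR), _PDH)
        assert aca.weights[0] == pytest.approx(1.0)
        assert co2 == pytest.approx(0.0)

    def test_carboxyl_only_label_leaves_with_co2(self):
        d = IsotopomerDist.from_patterns(PYR, {0b001: 1.0})  # C1 labeled
        aca, co2 = transform(d, _PDH)
        assert aca.weights[0] == pytest.approx(1.0)
        assert co2 == pytest.approx(1.0)

    def test_carboxylation_with_labeled_co2_pool(self):
        oaa, _ = transform(IsotopomerDist.fully_labeled(PYR), PC,
                           co2_labeled_p=1.0)
        assert collapse_to_mid(oaa).fractions[4] == pytest.approx(1.0)

    def test_no_co2_release_returns_none(self):
        t, fh = reaction("oxidative_tca", "FH")
        _, co2 = transform(IsotopomerDist.unlabeled(t.metabolite("FUM")), fh)
        assert co2 is None


class TestSymmetrize:
    def test_half_labeled_pattern_splits_evenly(self):
        d = IsotopomerDist.from_patterns(FUM, {0b0011: 1.0})
        s = symmetrize(d)
        assert s.weights[0b0011] == pytest.approx(0.5)
        assert s.weights[0b1100] == pytest.approx(0.5)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_mid_invariant_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        d = random_dist(FUM, rng)
        s = symmetrize(d)
        np.testing.assert_allclose(collapse_to_mid(s).fractions,
                                   collapse_to_mid(d).fractions, atol=1e-12)
        np.testing.assert_allclose(symmetrize(s).weights, s.weights,
                                   atol=1e-12)

    def test_rejects_asymmetric_metabolite(self):
        with pytest.raises(ContractError):
            symmetrize(IsotopomerDist.unlabeled(Metabolite("MAL", 4)))

    def test_bitrev_is_involution(self):
        rev = bitrev_table(5)
        np.testing.assert_array_equal(rev[rev], np.arange(32))


class TestStepTurn:
    def test_one_oxidative_turn_yields_m2_fumarate(self):
        t = build_topology("oxidative_tca")
        s = PoolState.for_topology(t, labeled={"ACA"})
        cfg = SimulationConfig(n_turns=1, mixing_fraction=1.0)
        s2, _ = step_turn(t, s, CO2PoolState(), cfg)
        mid = collapse_to_mid(s2.dists["FUM"]).fractions
        assert mid[2] == pytest.approx(1.0)

    def test_zero_label_state_is_fixed_in_label_space(self, preset_name):
        t = build_topology(preset_name)
        s = PoolState.for_topology(t)
        cfg = SimulationConfig(n_turns=1, mixing_fraction=0.6)
        s2, c2 = step_turn(t, s, CO2PoolState(), cfg)
        for name, d in s2.dists.items():
            assert d.weights[0] == pytest.approx(1.0), name
        assert c2.labeled_fraction == pytest.approx(0.0)

    def test_empty_substrate_pool_rejected(self):
        t = build_topology("oxidative_tca")
        s = PoolState.for_topology(t, labeled={"ACA"})
        s.sizes["OAA"] = 0.0
        with pytest.raises(ContractError, match="empty pool"):
            step_turn(t, s, CO2PoolState(), SimulationConfig(n_turns=1))

    def test_all_distributions_stay_normalized(self, preset_name, rng):
        t = build_topology(preset_name)
        s = PoolState.for_topology(t, labeled=set(t.inputs))
        for name in s.dists:
            s.dists[name] = random_dist(t.metabolite(name), rng)
        cfg = SimulationConfig(n_turns=1, mixing_fraction=0.5)
        c = CO2PoolState(0.4)
        for _ in range(3):
            s, c = step_turn(t, s, c, cfg)
            for name, d in s.dists.items():
                assert d.weights.sum() == pytest.approx(1.0, abs=1e-9)
            assert 0.0 <= c.labeled_fraction <= 1.0

    def test_per_reaction_label_balance(self, preset_name, rng):
        t = build_topology(preset_name)
        for r in t.reactions:
            subs = [random_dist(t.metabolite(n), rng) for n in r.substrates]
            label_in, label_out = labeled_carbon_balance(
                r, subs, co2_labeled_p=0.37)
            assert label_in == pytest.approx(label_out, abs=1e-9)


class TestSimulate:
    def test_repeated_oxidative_turns_build_m4_fumarate(self):
        t = build_topology("oxidative_tca")
        init = PoolState.for_topology(t, labeled={"ACA"})
        tc = simulate(t, init, SimulationConfig(n_turns=5, mixing_fraction=1.0))
        assert tc.mid("FUM", 1).fractions[4] == pytest.approx(0.0, abs=1e-12)
        assert tc.mid("FUM", 5).fractions[4] > 0.0

    def test_reductive_branch_yields_m3_fumarate(self):
        t = build_topology("reductive_branch", recycle_fraction=0.0)
        init = PoolState.for_topology(t, labeled={"PYR"})
        tc = simulate(t, init, SimulationConfig(n_turns=1, mixing_fraction=1.0))
        assert tc.mid("FUM", 1).labeled_shifts() == [3]

    def test_recycled_bicarbonate_builds_m4_aspartate(self):
        t = build_topology("bifurcated_tca", recycle_fraction=1.0)
        init = PoolState.for_topology(t, labeled={"PYR"})
        tc = simulate(t, init, SimulationConfig(n_turns=3, mixing_fraction=1.0))
        # turn 1 carboxylates with the still-unlabeled pool (M+3 only);
        # once decarboxylations have charged the pool, M+4 appears
        assert tc.mid("ASP", 1).fractions[4] == pytest.approx(0.0, abs=1e-12)
        assert tc.mid("ASP", 3).fractions[4] > 0.1

    def test_timecourse_records_every_turn(self):
        t = build_topology("glycolysis")
        init = PoolState.for_topology(t, labeled={"GLC"})
        tc = simulate(t, init, SimulationConfig(n_turns=3))
        assert tc.turns() == [0, 1, 2, 3]
        assert set(tc.metabolites()) == {m.name for m in t.metabolites}

    def test_deterministic_given_inputs(self):
        t = build_topology("bifurcated_tca")
        init = PoolState.for_topology(t, labeled={"PYR"})
        cfg = SimulationConfig(n_turns=3, mixing_fraction=0.5)
        a = simulate(t, init, cfg).frame
        b = simulate(t, init, cfg).frame
        assert a.equals(b)

    def test_mixing_fraction_one_converges_to_fixed_point(self):
        t = build_topology("oxidative_tca")
        init = PoolState.for_topology(t, labeled={"ACA"})
        tc = simulate(t, init, SimulationConfig(n_turns=40,
                                                mixing_fraction=1.0))
        late = tc.mid("FUM", 40).fractions
        later = tc.mid("FUM", 39).fractions
        np.testing.assert_allclose(late, later, atol=1e-6)


class TestMonteCarlo:
    def test_agrees_with_deterministic_within_4se(self, preset_name):
        t = build_topology(preset_name)
        init = PoolState.for_topology(t, labeled=set(t.inputs))
        cfg = SimulationConfig(n_turns=3, mixing_fraction=0.7, seed=11,
                               n_molecules=100_000)
        tc = simulate(t, init, cfg)
        est = monte_carlo(t, init, cfg)
        for name, e in est.items():
            det = tc.mid(name, 3).fractions
            bound = 4 * np.sqrt(det * (1 - det) / cfg.n_molecules) + 1e-9
            assert np.all(np.abs(det - e.mid) <= bound), name

    def test_unlabeled_input_stays_unlabeled(self):
        t = build_topology("oxidative_tca")
        init = PoolState.for_topology(t)
        cfg = SimulationConfig(n_turns=2, seed=1, n_molecules=2000)
        est = monte_carlo(t, init, cfg)
        for name, e in est.items():
            assert e.mid[0] == pytest.approx(1.0), name

    def test_same_seed_reproduces_estimates(self):
        t = build_topology("reductive_branch")
        init = PoolState.for_topology(t, labeled={"PYR"})
        cfg = SimulationConfig(n_turns=2, seed=42, n_molecules=5000)
        a = monte_carlo(t, init, cfg)
        b = monte_carlo(t, init, cfg)
        for name in a:
            np.testing.assert_array_equal(a[name].mid, b[name].mid)

    def test_requires_enough_molecules(self):
        t = build_topology("glycolysis")
        init = PoolState.for_topology(t, labeled={"GLC"})
        with pytest.raises(ContractError):
            monte_carlo(t, init, SimulationConfig(n_molecules=10))


class TestRestrictedEquivalence:
    def test_bifurcated_without_oxidative_flux_matches_reductive(self):
        from tracefate import restrict_topology
        bif = build_topology("bifurcated_tca", recycle_fraction=0.0)
        red_only = restrict_topology(bif, {"PC", "MDHr", "FHr", "FR"})
        red = build_topology("reductive_branch", recycle_fraction=0.0)
        cfg = SimulationConfig(n_turns=3, mixing_fraction=0.8)
        tc_bif = simulate(red_only,
                          PoolState.for_topology(red_only, labeled={"PYR"}),
                          cfg)
        tc_red = simulate(red,
                          PoolState.for_topology(red, labeled={"PYR"}), cfg)
        np.testing.assert_allclose(tc_bif.mid("FUM", 3).fractions,
                                   tc_red.mid("FUM", 3).fractions, atol=1e-12)


class TestStereospecificity:
    def test_first_turn_fumarate_never_exceeds_m2(self):
        t = build_topology("oxidative_tca")
        s = PoolState.for_topology(t, labeled={"ACA"})
        s2, _ = step_turn(t, s, CO2PoolState(),
                          SimulationConfig(n_turns=1, mixing_fraction=1.0))
        mid = collapse_to_mid(s2.dists["FUM"]).fractions
        assert np.all(mid[3:] == pytest.approx(0.0, abs=1e-12))
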