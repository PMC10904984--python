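import itertools

import numpy as np
import pytest

from wildgut import (
    MetabolicNetwork,
    Reaction,
    SubstrateProfile,
    minimal_communities,
    module_abundance_test,
    producible_targets,
    scope,
    wp_module,
)
from wildgut.types import ValidationError
from conftest import random_table


def net(species, *reactions):
    return MetabolicNetwork(species, {Reaction.make(s, p) for s, p in reactions})


def naive_scope_reference(networks, species_subset, seeds):
    """Repeat-until-stable reference: rescan every reaction each pass."""
    pool = [r for n in networks if n.species_id in species_subset
            for r in n.reactions]
    reachable = set(seeds)
    while True:
        new = set(reachable)
        for r in pool:
            if set(r.substrates) <= reachable:
                new |= set(r.products)
        if new == reachable:
            return frozenset(reachable)
        reachable = new


def random_networks(rng, n_species=5, n_metabolites=20, n_reactions=30):
    mets = [f"M{i}" for i in range(n_metabolites)]
    nets = {f"sp{i}": MetabolicNetwork(f"sp{i}", set()) for i in range(n_species)}
    for _ in range(n_reactions):
        subs = frozenset(rng.choice(mets, size=int(rng.integers(1, 4)), replace=False))
        prods = frozenset(rng.choice(mets, size=int(rng.integers(1, 3)), replace=False)) - subs
        if not prods:
            continue
        sp = f"sp{int(rng.integers(n_species))}"
        nets[sp].reactions.add(Reaction(subs, prods))
    return list(nets.values()), mets


def exhaustive_key_species(networks, profile):
    """Classification by brute-force enumeration over all 2^n subsets."""
    species = [n.species_id for n in networks]
    targets = producible_targets(networks, species, profile)
    covers = [
        frozenset(sub)
        for r in range(1, len(species) + 1)
        for sub in itertools.combinations(species, r)
        if targets
        and targets <= scope(networks, sub, profile.seed_metabolites).reachable_metabolites
    ]
    minimal = [c for c in covers if not any(o < c for o in covers)]
    essential = frozenset.intersection(*minimal) if minimal else frozenset()
    alternative = (frozenset.union(*minimal) - essential) if minimal else frozenset()
    return targets, essential, alternative, set(minimal)


class TestScope:
    def test_no_reactions_fixpoint_is_seeds(self):
        res = scope([net("a")], {"a"}, {"X"})
        assert res.reachable_metabolites == {"X"}

    def test_blocked_reaction_never_fires(self):
        n = net("a", ({"A"}, {"B"}), ({"B", "C"}, {"D"}))
        res = scope([n], {"a"}, {"A"})
        assert res.reachable_metabolites == {"A", "B"}

    def test_unknown_species_rejected(self):
        with pytest.raises(ValidationError):
            scope([net("a")], {"ghost"}, {"X"})

    def test_matches_naive_reference_on_random_networks(self, rng):
        for _ in range(25):
            nets, mets = random_networks(rng)
            subset = {n.species_id for n in nets if rng.random() < 0.7}
            seeds = set(rng.choice(mets, size=3, replace=False))
            got = scope(nets, subset, seeds).reachable_metabolites
            assert got == naive_scope_reference(nets, subset, seeds)

    def test_monotone_in_species_and_idempotent(self, rng):
        nets, mets = random_networks(rng)
        seeds = set(mets[:3])
        all_sp = [n.species_id for n in nets]
        small = scope(nets, all_sp[:2], seeds).reachable_metabolites
        big = scope(nets, all_sp, seeds).reachable_metabolites
        assert small <= big
        again = scope(nets, all_sp, big).reachable_metabolites
        assert again == big


class TestProducibleTargets:
    def test_empty_community_produces_nothing(self):
        profile = SubstrateProfile("p", {"S"}, {"T"})
        assert producible_targets([net("a", ({"S"}, {"T"}))], set(), profile) == frozenset()

    def test_planted_chain_reaches_exactly_its_targets(self):
        nets = [net("a", ({"S"}, {"I"})), net("b", ({"I"}, {"T"})),
                net("c", ({"S"}, {"J"}))]
        profile = SubstrateProfile("p", {"S"}, {"T", "U"})
        assert producible_targets(nets, {"a", "b", "c"}, profile) == {"T"}

    def test_overlapping_seed_target_rejected_upstream(self):
        with pytest.raises(ValidationError):
            SubstrateProfile("p", {"S"}, {"S", "T"})


class TestMinimalCommunities:
    profile = SubstrateProfile("plant", {"S"}, {"T"})

    def test_single_degrader_is_essential(self):
        nets = [net("solo", ({"S"}, {"T"})), net("bystander", ({"X"}, {"Y"}))]
        res = minimal_communities(nets, self.profile)
        assert res.minimal_communities == [frozenset({"solo"})]
        assert res.essential_species == {"solo"}

    def test_interchangeable_degraders_are_alternative(self):
        nets = [net("a", ({"S"}, {"T"})), net("b", ({"S"}, {"T"}))]
        res = minimal_communities(nets, self.profile)
        assert res.essential_species == frozenset()
        assert res.alternative_species == {"a", "b"}
        assert set(res.minimal_communities) == {frozenset({"a"}), frozenset({"b"})}

    def test_cross_feeding_pair_both_essential(self):
        nets = [net("a", ({"S"}, {"I"})), net("b", ({"I"}, {"T"}))]
        res = minimal_communities(nets, self.profile)
        assert res.minimal_communities == [frozenset({"a", "b"})]
        assert res.essential_species == {"a", "b"}

    def test_unreachable_targets_reported_empty(self):
        res = minimal_communities([net("a", ({"X"}, {"Y"}))], self.profile)
        assert res.producible_targets == frozenset()
        assert res.minimal_communities == []

    def test_matches_exhaustive_subset_enumeration(self, rng):
        for _ in range(15):
            nets, mets = random_networks(rng, n_species=5, n_metabolites=12,
                                         n_reactions=15)
            seeds = frozenset(mets[:2])
            targets = frozenset(mets[-3:]) - seeds
            profile = SubstrateProfile("p", seeds, targets)
            res = minimal_communities(nets, profile, max_size=5)
            t, ess, alt, minimal = exhaustive_key_species(nets, profile)
            assert res.producible_targets == t
            assert res.essential_species == ess
            assert res.alternative_species == alt
            assert set(res.minimal_communities) == minimal

    def test_greedy_route_matches_exhaustive_on_guild_instances(self):
        from wildgut.simulate import NetworkSpec, gen_networks

        for seed in range(8):
            nets, profiles, _ = gen_networks(
                NetworkSpec(n_species=10, guild_sizes=(2, 2, 1), seed=seed)
            )
            for profile in profiles:
                ex = minimal_communities(nets, profile)
                gr = minimal_communities(nets, profile, exhaustive_cutoff=0)
                assert ex.exhaustive and not gr.exhaustive
                assert gr.essential_species == ex.essential_species
                assert gr.alternative_species == ex.alternative_species

    def test_every_minimal_community_passes_minimality_audit(self, rng):
        nets, mets = random_networks(rng, n_species=6, n_metabolites=15,
                                     n_reactions=20)
        seeds = frozenset(mets[:2])
        profile = SubstrateProfile("p", seeds, frozenset(mets[-3:]) - seeds)
        res = minimal_communities(nets, profile, max_size=6)
        for community in res.minimal_communities:
            for sp in community:
                sub = community - {sp}
                reach = scope(nets, sub, seeds).reachable_metabolites if sub else seeds
                assert not res.producible_targets <= reach


class TestWpModule:
    def test_empty_results_give_empty_module(self):
        results = [
            minimal_communities([net("a", ({"X"}, {"Y"}))],
                                SubstrateProfile(f"p{i}", {"S"}, {"T"}))
            for i in range(5)
        ]
        assert wp_module(results) == frozenset()

    def test_union_of_disjoint_essential_sets(self):
        r1 = minimal_communities([net("X", ({"S"}, {"T"}))],
                                 SubstrateProfile("p1", {"S"}, {"T"}))
        r2 = minimal_communities([net("Y", ({"S"}, {"U"}))],
                                 SubstrateProfile("p2", {"S"}, {"U"}))
        assert wp_module([r1, r2]) == {"X", "Y"}

    def test_essential_only_flag_drops_alternatives(self):
        nets = [net("a", ({"S"}, {"T"})), net("b", ({"S"}, {"T"}))]
        res = minimal_communities(nets, SubstrateProfile("p", {"S"}, {"T"}))
        assert wp_module([res]) == {"a", "b"}
        assert wp_module([res], essential_only=True) == frozenset()


class TestModuleAbundanceTest:
    def test_full_module_sums_equal_column_totals(self, three_group_table):
        sums, _ = module_abundance_test(three_group_table, three_group_table.sgb_ids)
        np.testing.assert_allclose(sums.to_numpy(), three_group_table.values.sum(axis=0))

    def test_empty_module_rejected(self, three_group_table):
        with pytest.raises(ValidationError):
            module_abundance_test(three_group_table, [])

    def test_planted_shift_orders_group_medians(self):
        from wildgut.simulate import CohortSpec, gen_cohort

        table, _, truth = gen_cohort(
            CohortSpec(n_sgbs=50, n_samples_per_group=(10, 8, 10),
                       n_gradient_sgbs=0, n_module_sgbs=8, seed=3)
        )
        sums, tests = module_abundance_test(table, truth["module_sgbs"])
        row = tests[(tests.group_a == "baka_forest")
                    & (tests.group_b == "nzime_village")].iloc[0]
        assert row.median_a > row.median_b
        assert row.p_value < 0.05
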