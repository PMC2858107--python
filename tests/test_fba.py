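import itertools

import numpy as np
import pytest

import viaspace as vs
from viaspace.fixtures import reachability_viable, subset_viable_lp


def ids(universe, *names):
    return vs.Genotype.from_ids(names, universe)


class TestMaximizeBiomass:
    def test_full_genotype_grows(self, toy):
        universe, env, biomass = toy
        sol = vs.maximize_biomass(universe, vs.Genotype.full(9), env, biomass)
        assert sol.status == "optimal" and sol.objective > 1e-6
        # steady state holds on the reaction fluxes the solver returned
        assert np.all(np.isfinite(sol.fluxes))

    def test_without_biomass_reaction_zero(self, toy):
        universe, env, biomass = toy
        g = vs.Genotype.full(9).with_bit(universe.index_of("R7"), False)
        sol = vs.maximize_biomass(universe, g, env, biomass)
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_empty_genotype_zero(self, toy):
        universe, env, biomass = toy
        sol = vs.maximize_biomass(universe, vs.Genotype.empty(9), env, biomass)
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_uptake_limit_caps_growth(self, toy):
        universe, env, biomass = toy
        sol = vs.maximize_biomass(universe, vs.Genotype.full(9), env, biomass)
        # one carbon in -> at most half a biomass unit out (P1 + P2 both drawn
        # from the same carbon pool)
        assert sol.objective <= env.carbon_uptake_limit


class TestIsViable:
    def test_examples(self, toy):
        universe, env, biomass = toy
        assert vs.is_viable(universe, ids(universe, "R1", "R2", "R5", "R7"), env, biomass).viable
        assert not vs.is_viable(universe, ids(universe, "R1", "R2", "R5"), env, biomass).viable

    def test_at_least_mode_boundary(self, toy):
        universe, env, biomass = toy
        full = vs.Genotype.full(9)
        ref = vs.maximize_biomass(universe, full, env, biomass).objective
        res = vs.is_viable(universe, full, env, biomass, mode="at_least",
                           reference_flux=ref)
        assert res.viable and res.threshold_used == ref
        sub = ids(universe, "R1", "R2", "R5", "R7")
        # the minimal genotype achieves the same optimum here (no redundancy
        # bonus in flux), so stringent viability still holds
        assert vs.is_viable(universe, sub, env, biomass, "at_least",
                            reference_flux=ref).viable

    def test_monotonicity_under_reaction_addition(self, toy):
        universe, env, biomass = toy
        model = vs.FbaModel(universe, env, biomass)
        rng = np.random.default_rng(2)
        for _ in range(25):
            small_idx = rng.choice(9, size=4, replace=False)
            small = vs.Genotype.from_indices(small_idx, 9)
            extra = rng.choice([i for i in range(9) if i not in small_idx], size=2,
                               replace=False)
            big = vs.Genotype.from_indices(list(small_idx) + list(extra), 9)
            assert model.biomass_flux(big) >= model.biomass_flux(small) - 1e-9


class TestEssential:
    def test_full_genotype(self, toy):
        universe, env, biomass = toy
        assert vs.essential_reactions(universe, vs.Genotype.full(9), env, biomass) == {
            "R1",
            "R7",
        }

    def test_minimal_genotype_all_essential(self, toy):
        universe, env, biomass = toy
        g = ids(universe, "R1", "R2", "R5", "R7")
        assert vs.essential_reactions(universe, g, env, biomass) == {
            "R1", "R2", "R5", "R7",
        }

    def test_non_viable_input_rejected(self, toy):
        universe, env, biomass = toy
        with pytest.raises(vs.NonViableError):
            vs.essential_reactions(universe, ids(universe, "R1"), env, biomass)

    def test_super_essential_subset_of_every_essential_set(self, toy, toy_viable):
        universe, env, biomass = toy
        se = vs.super_essential_reactions(universe, env, biomass)
        assert se == {"R1", "R7"}
        for g in toy_viable[5]:
            assert se <= vs.essential_reactions(universe, g, env, biomass)

    def test_single_linear_pathway_all_super_essential(self):
        chain = vs.ReactionUniverse(
            (
                vs.Reaction("U", {"C_ext": -1, "A": 1}),
                vs.Reaction("S1", {"A": -1, "B": 1}),
                vs.Reaction("S2", {"B": -1, "BM_ext": 1}),
            ),
            id="chain",
        )
        env = vs.Environment(id="chain_env", carbon_source="C_ext")
        biomass = vs.BiomassObjective({"BM_ext": 1.0})
        assert vs.super_essential_reactions(chain, env, biomass) == {"U", "S1", "S2"}

    def test_two_carbon_variant_second_environment(self, two_carbon):
        universe, _, env2, biomass = two_carbon
        assert vs.super_essential_reactions(universe, env2, biomass) == {
            "R7", "R8", "R10", "R11",
        }


class TestBlocked:
    def test_full_genotype_decoy_blocked(self, toy):
        universe, env, biomass = toy
        assert vs.blocked_reactions(universe, vs.Genotype.full(9), env, biomass) == {"R8"}

    def test_minimal_genotype_nothing_blocked(self, toy):
        universe, env, biomass = toy
        g = ids(universe, "R1", "R2", "R5", "R7")
        assert vs.blocked_reactions(universe, g, env, biomass) == set()

    def test_disjoint_from_essential(self, toy, toy_viable):
        universe, env, biomass = toy
        for g in toy_viable[6]:
            ess = vs.essential_reactions(universe, g, env, biomass)
            blk = vs.blocked_reactions(universe, g, env, biomass)
            assert ess.isdisjoint(blk)
            assert blk <= set(g.to_ids(universe))


class TestRobustness:
    def test_full_genotype(self, toy):
        universe, env, biomass = toy
        r = vs.mutational_robustness(universe, vs.Genotype.full(9), env, biomass)
        assert r == pytest.approx(7 / 9)

    def test_minimal_genotype_zero(self, toy):
        universe, env, biomass = toy
        g = ids(universe, "R1", "R2", "R5", "R7")
        assert vs.mutational_robustness(universe, g, env, biomass) == 0.0

    def test_duplicate_environment_idempotent(self, toy):
        universe, env, biomass = toy
        full = vs.Genotype.full(9)
        one = vs.mutational_robustness(universe, full, env, biomass)
        two = vs.mutational_robustness(universe, full, [env, env], biomass)
        assert one == two


class TestOracleEquivalence:
    def test_all_toy9_subsets_match_independent_oracles(self, toy, toy_evaluator):
        """Streamlined bound-zeroing LP vs fresh column-removal LP vs boolean
        reachability, across the entire 2^9 subset lattice."""
        universe, env, biomass = toy
        for r in range(2**9):
            g = vs.Genotype(r, 9)
            fast = toy_evaluator.viable(g)
            fresh = subset_viable_lp(universe, g.present_indices, env, biomass)
            logic = reachability_viable(universe, g, env, biomass)
            assert fast == fresh == logic, f"disagreement on mask {r:09b}"
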