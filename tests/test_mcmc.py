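import math

import numpy as np
import pytest

import viaspace as vs


def config(env, **kw):
    base = dict(n=5, environments=[env], total_steps=2000, burn_in=200,
                thinning=10, seed=1)
    base.update(kw)
    return vs.McmcConfig(**base)


class TestInitialGenotype:
    def test_full_n_forced(self, toy):
        universe, env, biomass = toy
        g = vs.initial_viable_genotype(universe, env, biomass, n=9, seed=0)
        assert g.mask == vs.Genotype.full(9).mask

    def test_member_of_viable_space(self, toy, toy_viable):
        universe, env, biomass = toy
        masks5 = {g.mask for g in toy_viable[5]}
        for seed in range(20):
            g = vs.initial_viable_genotype(universe, env, biomass, n=5, seed=seed)
            assert g.mask in masks5

    def test_n_below_support_rejected(self, toy):
        universe, env, biomass = toy
        with pytest.raises(vs.NonViableError):
            vs.initial_viable_genotype(universe, env, biomass, n=3, seed=0)


class TestRunChain:
    def test_bookkeeping(self, toy, toy_evaluator):
        universe, env, biomass = toy
        cfg = config(env, total_steps=50, burn_in=0, thinning=1)
        sample, _ = vs.run_chain(universe, biomass, cfg, evaluator=toy_evaluator)
        assert len(sample.genotypes) == 50

    def test_determinism(self, toy, toy_evaluator):
        universe, env, biomass = toy
        a, _ = vs.run_chain(universe, biomass, config(env), evaluator=toy_evaluator)
        b, _ = vs.run_chain(universe, biomass, config(env), evaluator=toy_evaluator)
        assert [g.mask for g in a.genotypes] == [g.mask for g in b.genotypes]
        assert a.acceptance == b.acceptance

    def test_all_kept_states_viable_with_exact_n(self, toy, toy_evaluator, toy_viable):
        universe, env, biomass = toy
        masks5 = {g.mask for g in toy_viable[5]}
        sample, _ = vs.run_chain(universe, biomass, config(env),
                                 evaluator=toy_evaluator)
        for g in sample.genotypes:
            assert g.n == 5 and g.mask in masks5

    def test_frozen_super_essential_always_present(self, toy, toy_evaluator):
        universe, env, biomass = toy
        sample, _ = vs.run_chain(universe, biomass, config(env),
                                 evaluator=toy_evaluator)
        i1, i7 = universe.index_of("R1"), universe.index_of("R7")
        assert all(i1 in g and i7 in g for g in sample.genotypes)

    def test_acceptance_and_tau_heuristic(self, toy, toy_evaluator):
        universe, env, biomass = toy
        cfg = config(env, total_steps=20000, burn_in=1000, thinning=5)
        sample, diag = vs.run_chain(universe, biomass, cfg,
                                    evaluator=toy_evaluator)
        assert 0 < sample.acceptance < 1
        assert diag.converged and diag.tau is not None
        # the n/A rule of thumb holds within a small factor on the fixture
        assert diag.expected_tau / 3 <= max(diag.tau, 1.0) <= diag.expected_tau * 3


class TestAutocorrelationTime:
    def test_closed_form_saturating_trace(self):
        steps = np.arange(0, 20000, 10.0)
        d = 6.0 * (1 - np.exp(-steps / 1000.0))
        res = vs.autocorrelation_time(np.column_stack([steps, d]))
        assert res.converged
        assert res.tau == pytest.approx(1000, rel=0.05)

    def test_flat_zero_trace_not_converged(self):
        steps = np.arange(0, 100, 1.0)
        res = vs.autocorrelation_time(np.column_stack([steps, np.zeros_like(steps)]))
        assert not res.converged and res.tau is None

    def test_non_saturating_trace_flagged(self):
        steps = np.arange(0, 1000, 1.0)
        res = vs.autocorrelation_time(np.column_stack([steps, steps / 10.0]))
        assert not res.converged


class TestJackknife:
    def test_iid_standard_normal(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000)
        res = vs.jackknife_error(x, [1])
        assert res.errors[1] == pytest.approx(1 / math.sqrt(1000), rel=0.1)

    def test_constant_series_zero_error(self):
        res = vs.jackknife_error(np.full(400, 3.14), [1, 5, 20])
        assert all(e == pytest.approx(0.0, abs=1e-12) for e in res.errors.values())

    def test_ar1_plateau_matches_effective_sample_size(self):
        rho, m = 0.8, 40000
        rng = np.random.default_rng(7)
        x = np.empty(m)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(m) * math.sqrt(1 - rho**2)
        for t in range(1, m):
            x[t] = rho * x[t - 1] + eps[t]
        res = vs.jackknife_error(x, [1, 10, 50, 200, 1000])
        n_eff = m * (1 - rho) / (1 + rho)
        expected = x.std(ddof=1) / math.sqrt(n_eff)
        assert res.plateau == pytest.approx(expected, rel=0.2)
        # small windows underestimate the error of a correlated series
        assert res.errors[1] < res.plateau

    def test_window_too_large_rejected(self):
        with pytest.raises(ValueError):
            vs.jackknife_error(np.zeros(20), [10])


class TestTwoHeadedWalk:
    def test_recovers_exhaustive_diameter(self, toy, toy_evaluator, toy_viable):
        universe, env, biomass = toy
        truth = vs.diameter_of(toy_viable[5])
        est = vs.two_headed_walk(
            universe, biomass, config(env, total_steps=4000), replicates=5,
            evaluator=toy_evaluator,
        )
        assert est.max_distance == truth == 6
        assert est.max_distance == max(est.replicate_values)

    def test_single_genotype_space_gives_zero(self, toy, toy_evaluator):
        universe, env, biomass = toy
        est = vs.two_headed_walk(
            universe, biomass, config(env, n=9, total_steps=100, burn_in=0),
            replicates=2,
            evaluator=toy_evaluator,
        )
        assert est.max_distance == 0

    def test_never_exceeds_omega_bound(self, toy, toy_evaluator):
        universe, env, biomass = toy
        for n in (5, 6, 7):
            est = vs.two_headed_walk(
                universe, biomass, config(env, n=n, total_steps=1500),
                replicates=3, evaluator=toy_evaluator,
            )
            assert est.max_distance <= vs.max_hamming_omega(n, 9)
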