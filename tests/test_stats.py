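import numpy as np
import pandas as pd
import pytest

import viaspace as vs


class TestRobustness:
    def test_binomial_normal_variance_formula(self):
        # s = 0 collapses to the plain binomial variance r(1-r)/n
        r, n = 0.6, 100
        assert vs.binomial_robustness_variance(r, n, 0) == pytest.approx(
            r * (1 - r) / n
        )

    def test_exhaustive_sample_statistics(self, toy, toy_viable):
        universe, env, biomass = toy
        rs = vs.robustness_stats(universe, toy_viable[5], env, biomass)
        # direct average of per-genotype knockout screens
        expected = np.mean(
            [
                vs.mutational_robustness(universe, g, env, biomass)
                for g in toy_viable[5]
            ]
        )
        assert rs.mean == pytest.approx(expected)
        assert rs.s == 2 and rs.n == 5
        assert rs.variance >= 0

    def test_reference_genotype_p_value(self, toy, toy_viable):
        universe, env, biomass = toy
        full = vs.Genotype.full(9)
        rs = vs.robustness_stats(universe, toy_viable[5], env, biomass,
                                 reference=full)
        # the full genotype is more robust than every size-5 member
        assert rs.reference_value == pytest.approx(7 / 9)
        assert rs.reference_p_value == pytest.approx(1 / (len(toy_viable[5]) + 1))

    def test_multi_environment_union(self, two_carbon):
        universe, env1, env2, biomass = two_carbon
        full = vs.Genotype.full(universe.N)
        rs = vs.robustness_stats(universe, [full, full], [env1, env2], biomass)
        union = vs.mutational_robustness(universe, full, [env1, env2], biomass)
        assert rs.mean == pytest.approx(union)


class TestDistances:
    def test_identical_genotypes(self):
        g = vs.Genotype.from_indices([0, 2, 4], 9)
        ds = vs.distance_stats([g, g, g])
        assert ds.mean == ds.max == 0 and ds.pair_count == 3

    def test_exhaustive_viable_space(self, toy_viable):
        ds = vs.distance_stats(toy_viable[5])
        assert ds.max == 6
        assert ds.pair_count == len(toy_viable[5]) * (len(toy_viable[5]) - 1) // 2
        # viability constrains similarity below the unconstrained expectation
        assert ds.mean <= vs.expected_hamming_omega(5, 9)

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            vs.distance_stats([vs.Genotype.from_indices([0], 3)])


class TestOccurrence:
    def test_exhaustive_counts(self, toy, toy_viable):
        universe, env, biomass = toy
        table = vs.occurrence_table(universe, toy_viable[5], env, biomass)
        occ = dict(zip(table.reaction_id, table.occurrence))
        m = len(toy_viable[5])
        counts = {
            r: sum(universe.index_of(r) in g for g in toy_viable[5])
            for r in universe.reaction_ids
        }
        for r, c in counts.items():
            assert occ[r] == pytest.approx(c / m)
        assert occ["R1"] == occ["R7"] == 1.0
        assert sorted(table["rank"]) == list(range(1, 10))

    def test_decoy_blocked_whenever_present(self, toy, toy_viable):
        universe, env, biomass = toy
        table = vs.occurrence_table(universe, toy_viable[5], env, biomass).set_index(
            "reaction_id"
        )
        assert table.loc["R8", "blocked_freq"] == pytest.approx(
            table.loc["R8", "occurrence"]
        )
        assert table.loc["R8", "essential_freq"] == 0.0

    def test_occurrence_dominates_component_frequencies(self, toy, toy_viable):
        universe, env, biomass = toy
        table = vs.occurrence_table(universe, toy_viable[6], env, biomass)
        assert (table.occurrence + 1e-12 >= table.essential_freq).all()
        assert (table.occurrence + 1e-12 >= table.blocked_freq).all()


class TestRankFits:
    @staticmethod
    def _table(f):
        ranks = np.arange(1, 301, dtype=float)
        return pd.DataFrame({"rank": ranks, "occurrence": f(ranks),
                             "reaction_id": [f"R{i}" for i in range(300)]})

    def test_noiseless_exponential_recovery(self):
        table = self._table(lambda r: 0.2 + 1.3 * np.exp(-0.007 * r))
        exp_fit, _ = vs.fit_rank_histogram(table)
        assert exp_fit.converged
        assert exp_fit.a == pytest.approx(0.2, rel=1e-3)
        assert exp_fit.b == pytest.approx(1.3, rel=1e-3)
        assert exp_fit.c == pytest.approx(0.007, rel=1e-3)
        assert exp_fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_power_law_data_prefers_power_model(self):
        rng = np.random.default_rng(0)
        table = self._table(lambda r: 0.2 + 458.9 * np.power(r, -1.375))
        table["occurrence"] += rng.normal(0, 0.002, size=len(table))
        exp_fit, pow_fit = vs.fit_rank_histogram(table)
        assert pow_fit.converged
        assert pow_fit.r_squared > exp_fit.r_squared

    def test_constant_occurrence_flagged(self):
        table = self._table(lambda r: np.full_like(r, 0.5))
        exp_fit, pow_fit = vs.fit_rank_histogram(table)
        assert not exp_fit.converged and not pow_fit.converged
        assert np.isnan(exp_fit.r_squared)


class TestPca:
    def test_identical_rows(self):
        res = vs.pca(np.ones((5, 8)))
        assert np.allclose(res.scores, 0) and np.allclose(
            res.explained_variance_ratio, 0
        )

    def test_two_clusters_separate_on_first_component(self):
        rng = np.random.default_rng(3)
        base_a = (rng.random(30) < 0.5).astype(float)
        base_b = base_a.copy()
        flip = rng.choice(30, size=12, replace=False)  # 40% of bits differ
        base_b[flip] = 1 - base_b[flip]
        rows, labels = [], []
        for _ in range(20):
            for base, lab in ((base_a, 0), (base_b, 1)):
                row = base.copy()
                noise = rng.choice(30, size=2, replace=False)
                row[noise] = 1 - row[noise]
                rows.append(row)
                labels.append(lab)
        res = vs.pca(np.array(rows))
        labels = np.array(labels)
        pc1 = res.scores[:, 0]
        assert res.explained_variance_ratio[0] > 0.5
        assert (pc1[labels == 0].mean() - pc1[labels == 1].mean()) ** 2 > (
            pc1.var()
        )

    def test_spectral_properties_and_sign_convention(self, toy_viable):
        res = vs.pca(toy_viable[5])
        evr = res.explained_variance_ratio
        assert evr.sum() <= 1 + 1e-9
        assert all(a >= b - 1e-12 for a, b in zip(evr, evr[1:]))
        for comp in res.loadings:
            assert comp[np.argmax(np.abs(comp))] >= 0


class TestHierarchicalClustering:
    def test_two_identical_points_merge_at_zero(self):
        g = vs.Genotype.from_indices([0, 1], 8)
        Z = vs.hierarchical_clustering([g, g])
        assert Z.shape == (1, 4) and Z[0, 2] == 0.0

    def test_average_linkage_height_hand_computed(self):
        # pairwise distances d(a,b)=2, d(a,c)=6, d(b,c)=6
        a = vs.Genotype.from_indices([0, 1, 2], 8)
        b = vs.Genotype.from_indices([0, 1, 3], 8)
        c = vs.Genotype.from_indices([4, 5, 6], 8)
        Z = vs.hierarchical_clustering([a, b, c])
        assert Z[0, 2] == pytest.approx(2.0)  # a with b
        assert Z[1, 2] == pytest.approx(6.0)  # mean of the two cross distances

    def test_monotone_heights(self, toy_viable):
        Z = vs.hierarchical_clustering(toy_viable[6])
        heights = Z[:, 2]
        assert all(x <= y + 1e-12 for x, y in zip(heights, heights[1:]))


class TestPermutationTest:
    def test_disjoint_supports_minimum_p(self):
        # clouds large enough that no shuffle recreates the exact split
        a = np.zeros((12, 10))
        a[:, :5] = 1
        b = np.zeros((12, 10))
        b[:, 5:] = 1
        res = vs.permutation_test([a, b], num_permutations=200, seed=0)
        assert res.p_value == pytest.approx(1 / 201)

    def test_identical_points_p_one(self):
        cloud = np.ones((4, 6))
        res = vs.permutation_test([cloud, cloud.copy()], num_permutations=100, seed=0)
        assert res.p_value == 1.0

    def test_pca_plane_variant_runs(self):
        rng = np.random.default_rng(1)
        clouds = [(rng.random((10, 12)) < 0.5).astype(float) for _ in range(2)]
        res = vs.permutation_test(clouds, num_permutations=100, seed=2,
                                  pca_plane=True)
        assert 0 < res.p_value <= 1


class TestViabilityProfile:
    def test_own_environment_all_viable(self, toy, toy_viable):
        universe, env, biomass = toy
        counts, hist = vs.viability_profile(universe, toy_viable[5], [env], biomass)
        assert (counts == 1).all()
        assert hist.tolist() == [0, len(toy_viable[5])]

    def test_two_carbon_membership(self, two_carbon):
        universe, env1, env2, biomass = two_carbon
        V1 = vs.enumerate_viable(universe, env1, biomass, 7)
        counts, hist = vs.viability_profile(universe, V1, [env1, env2], biomass)
        V2_masks = {g.mask for g in vs.enumerate_viable(universe, env2, biomass, 7)}
        expected = np.array([1 + (g.mask in V2_masks) for g in V1])
        assert (counts == expected).all()
        assert set(counts) == {1, 2}

    def test_empty_sample_empty_histogram(self, toy):
        universe, env, biomass = toy
        counts, hist = vs.viability_profile(universe, [], [env], biomass)
        assert len(counts) == 0 and hist.sum() == 0
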