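import dataclasses

import numpy as np
import pytest

from conftest import make_cohort
from cpmkit.cohort import AlignedCohort, PhenotypeTable
from cpmkit.connectome import CohortEdgeMatrix
from cpmkit.cpm import screen_edges
from cpmkit.simulate import (null_benchmark, planted_benchmark,
                             simulate_cohort)
from cpmkit.validation import (CVConfig, _CVEngine, _make_splits,
                               alpha_sweep, consensus_network,
                               permutation_test, run_cv, split_half_sites)


class TestSplitHalfSites:
    def test_twentyone_sites_partition_eleven_ten(self):
        rng = np.random.default_rng(0)
        sites = np.repeat([f"s{i:02d}" for i in range(21)], 10)
        split = split_half_sites(sites, rng)
        assert len(split.train_sites) == 11
        assert len(split.test_sites) == 10
        assert set(split.train_sites) | set(split.test_sites) == set(sites)
        assert set(split.train_sites) & set(split.test_sites) == set()
        assert np.intersect1d(split.train_idx, split.test_idx).size == 0
        assert split.train_idx.size + split.test_idx.size == sites.size

    def test_two_sites_split_whole_sites(self):
        sites = np.array(["a"] * 5 + ["b"] * 7)
        split = split_half_sites(sites, 3)
        got = {tuple(sorted(split.train_sites)), tuple(sorted(split.test_sites))}
        assert got == {("a",), ("b",)}

    def test_fixed_seed_reproduces_split(self):
        sites = np.repeat([f"s{i}" for i in range(7)], 4)
        a = split_half_sites(sites, 42)
        b = split_half_sites(sites, 42)
        assert a.train_sites == b.train_sites
        np.testing.assert_array_equal(a.train_idx, b.train_idx)

    def test_single_site_directs_to_participant_split(self):
        with pytest.raises(ValueError, match="participant_split"):
            split_half_sites(np.array(["s0"] * 10), 0)


class TestRunCV:
    def test_engine_screening_equals_public_screen_on_train_half(self):
        sim = simulate_cohort(null_benchmark(n_participants=200,
                                             n_regions=12, seed=5))
        cohort = sim.cohort
        cfg = CVConfig(n_iterations=1, seed=5, alpha=0.5)
        splits = _make_splits(cohort, cfg, 1)
        tr = splits[0].train_idx
        sub = AlignedCohort(
            edges=CohortEdgeMatrix(
                X=cohort.edges.X[tr],
                participant_ids=[cohort.participant_ids[i] for i in tr],
                edge_map=cohort.edges.edge_map),
            phenotypes=PhenotypeTable(
                df=cohort.phenotypes.df.iloc[tr].reset_index(drop=True)))
        for adjust in (False, True):
            ref = screen_edges(sub, alpha=0.5, adjust=adjust)
            engine = _CVEngine(cohort)
            _, masks = engine.run(splits, np.arange(cohort.n)[None, :],
                                  [0.5], adjust, collect_masks=True)
            np.testing.assert_array_equal(masks[0][0],
                                          np.flatnonzero(ref.mask))

    def test_same_seed_gives_identical_results(self, planted_sim):
        cfg = CVConfig(n_iterations=5, seed=3)
        a = run_cv(planted_sim.cohort, cfg)
        b = run_cv(planted_sim.cohort, cfg)
        np.testing.assert_array_equal(a.rhos, b.rhos)
        assert a.splits[0].train_sites == b.splits[0].train_sites

    def test_planted_signal_is_predictive(self, planted_sim):
        cv = run_cv(planted_sim.cohort, CVConfig(n_iterations=10, seed=1))
        assert cv.mean_rho > 0.1
        assert cv.n_zero_edge == 0

    def test_null_cohort_predicts_nothing(self):
        sim = simulate_cohort(null_benchmark(n_participants=2000, seed=8))
        cv = run_cv(sim.cohort, CVConfig(n_iterations=10, seed=8))
        assert abs(cv.mean_rho) < 0.05

    def test_zero_edge_iterations_excluded_with_count(self):
        sim = simulate_cohort(null_benchmark(seed=9))
        cv = run_cv(sim.cohort, CVConfig(n_iterations=8, seed=9, alpha=1e-9))
        assert cv.n_zero_edge == 8
        assert np.isnan(cv.mean_rho)

    def test_train_test_site_disjointness_every_iteration(self, planted_sim):
        cv = run_cv(planted_sim.cohort, CVConfig(n_iterations=5, seed=2))
        sites = planted_sim.cohort.sites
        fams = planted_sim.cohort.phenotypes.families
        for split in cv.splits:
            assert not set(sites[split.train_idx]) & set(sites[split.test_idx])
            assert not set(fams[split.train_idx]) & set(fams[split.test_idx])

    def test_mean_rho_nondecreasing_in_planted_effect(self):
        means = []
        for gamma in [0.0, 0.04, 0.08, 0.16]:
            cfg = dataclasses.replace(
                planted_benchmark(n_participants=1000, seed=12), gamma=gamma)
            cv = run_cv(simulate_cohort(cfg).cohort,
                        CVConfig(n_iterations=8, seed=12))
            means.append(0.0 if np.isnan(cv.mean_rho) else cv.mean_rho)
        assert means[-1] > means[0] + 0.1
        assert all(means[i + 1] > means[i] - 0.05 for i in range(3))


class TestPermutationTest:
    def test_strong_signal_beats_every_permutation(self, planted_sim):
        cfg = CVConfig(n_iterations=5, seed=4, n_permutations=30)
        cv = run_cv(planted_sim.cohort, cfg)
        perm = permutation_test(planted_sim.cohort, cfg, cv)
        assert perm.p_perm == 0.0
        assert perm.null_rhos.size == 30
        assert np.nanmax(np.abs(perm.null_rhos)) < cv.mean_rho

    def test_p_perm_is_strict_proportion_greater(self, planted_sim):
        cfg = CVConfig(n_iterations=3, seed=5, n_permutations=20)
        cv = run_cv(planted_sim.cohort, cfg)
        perm = permutation_test(planted_sim.cohort, cfg, cv)
        expect = np.nansum(perm.null_rhos > cv.mean_rho) / 20
        assert perm.p_perm == pytest.approx(expect)

    def test_zero_permutations_rejected(self, planted_sim):
        cfg = CVConfig(n_iterations=3, seed=5, n_permutations=0)
        cv = run_cv(planted_sim.cohort, cfg)
        with pytest.raises(ValueError, match="positive"):
            permutation_test(planted_sim.cohort, cfg, cv)


class TestConsensusNetwork:
    def test_recovers_planted_edges(self, planted_sim):
        mask = consensus_network(planted_sim.cohort, alpha=1e-3, adjust=True)
        em = planted_sim.cohort.edges.edge_map
        selected = set(mask.edge_indices(em))
        planted = set(planted_sim.planted_edge_indices)
        assert len(planted - selected) <= 2     # at most 2 false negatives
        assert mask.provenance["alpha"] == 1e-3

    def test_null_cohort_selects_few(self):
        sim = simulate_cohort(null_benchmark(seed=14))
        mask = consensus_network(sim.cohort, alpha=1e-3, adjust=False)
        assert len(mask) <= 8

    def test_alpha_one_selects_everything(self):
        sim = simulate_cohort(null_benchmark(n_participants=60,
                                             n_regions=8, seed=15))
        mask = consensus_network(sim.cohort, alpha=1.0, adjust=False)
        assert len(mask) == sim.cohort.edges.edge_map.n_edges


class TestAlphaSweep:
    def test_sweep_matches_individual_runs(self, planted_sim):
        cfg = CVConfig(n_iterations=4, seed=6)
        sweep = alpha_sweep(planted_sim.cohort, cfg, [0.01, 0.001])
        single = run_cv(planted_sim.cohort,
                        dataclasses.replace(cfg, alpha=0.01))
        np.testing.assert_allclose(sweep[0.01].rhos, single.rhos,
                                   equal_nan=True)
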