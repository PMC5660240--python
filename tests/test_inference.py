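"""Permutation inference: BH-FDR, clustering, conjunction, ISC contrasts."""

import numpy as np
import pytest
from scipy import stats

from natisc.inference import (bh_fdr, build_contrast_design, cluster_filter,
                              conjunction_max_p, design_from_tensors,
                              isc_condition_contrast, isc_one_group_test)
from natisc.isc import enumerate_pairs, pairwise_isc
from natisc.synthetic import (CohortSpec, EffectRegion, simulate_bold_cohort,
                              weight_for_isc)

from conftest import make_run


def brute_force_bh(p, q):
    """Independent step-up oracle: check every k by hand."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    k_best = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_best = k
    mask = np.zeros(m, bool)
    mask[order[:k_best]] = True
    return mask


class TestBhFdr:
    def test_hand_worked_example(self):
        mask, cutoff = bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]), q=0.05)
        assert mask.tolist() == [True, True, True, False]
        assert cutoff == 0.03

    def test_all_ones_reject_nothing(self):
        mask, cutoff = bh_fdr(np.ones(10), q=0.05)
        assert not mask.any()
        assert np.isnan(cutoff)

    def test_single_p_reduces_to_threshold(self):
        mask, _ = bh_fdr(np.array([0.04]), q=0.05)
        assert mask.all()

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            m = rng.integers(1, 51)
            p = rng.uniform(size=m) ** rng.uniform(0.3, 3)
            q = rng.uniform(0.01, 0.2)
            mask, _ = bh_fdr(p, q)
            np.testing.assert_array_equal(mask, brute_force_bh(p, q))

    def test_nan_entries_ignored(self):
        p = np.array([0.001, np.nan, 0.002])
        mask, _ = bh_fdr(p, 0.05)
        assert mask.tolist() == [True, False, True]


class TestClusterFilter:
    def test_small_cluster_removed_at_default_extent(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[:3, :3, :3] = True  # 27 voxels < 64
        assert not cluster_filter(mask).any()

    def test_4x4x4_block_is_retained(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[2:6, 2:6, 2:6] = True
        np.testing.assert_array_equal(cluster_filter(mask), mask)

    def test_size_selection_matches_component_labelling(self):
        mask = np.zeros((12, 12, 6), bool)
        mask[0:2, 0:5, 0:1] = True            # 10 voxels
        mask[5:10, 5:10, 1:5] = True          # 100 voxels
        out = cluster_filter(mask, min_extent_voxels=64)
        assert out.sum() == 100
        assert not out[0:2].any()

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        mask = rng.random((12, 12, 8)) > 0.6
        once = cluster_filter(mask, min_extent_voxels=10)
        np.testing.assert_array_equal(
            cluster_filter(once, min_extent_voxels=10), once)

    def test_diagonal_touching_blocks_merge_only_at_26_connectivity(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[0:2, 0:2, 0:2] = True
        mask[2:4, 2:4, 2:4] = True  # shares only a corner
        assert not cluster_filter(mask, min_extent_voxels=10,
                                  connectivity=6).any()
        assert cluster_filter(mask, min_extent_voxels=10,
                              connectivity=26).sum() == 16

    def test_non_3d_rejected(self):
        with pytest.raises(ValueError):
            cluster_filter(np.zeros((4, 4), bool))


class TestConjunction:
    def test_max_p_definition(self):
        conj, _ = conjunction_max_p(np.array([0.01]), np.array([0.04]), 0.05)
        assert conj[0] == 0.04

    def test_null_map_empties_the_conjunction(self):
        rng = np.random.default_rng(2)
        pa = rng.uniform(size=50) * 1e-4
        _, mask = conjunction_max_p(pa, np.ones(50), 0.05)
        assert not mask.any()

    def test_conjunction_mask_subset_of_individual_masks(self):
        rng = np.random.default_rng(3)
        pa, pb = rng.uniform(size=(2, 200)) ** 3
        conj, mask = conjunction_max_p(pa, pb, 0.05)
        assert np.all(conj >= pa) and np.all(conj >= pb)
        mask_a, _ = bh_fdr(pa, 0.05)
        mask_b, _ = bh_fdr(pb, 0.05)
        assert np.all(~mask | (mask_a & mask_b))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conjunction_max_p(np.zeros(3), np.zeros(4))


def _contrast_cohort(c_gen, c_non, n_subjects=6, n_trs=120, seed=0,
                     grid=(4, 4, 2), box=((0, 2), (0, 4), (0, 2))):
    sd = 0.8
    regions = []
    if c_gen > 0:
        regions.append(EffectRegion(box=box, condition="genetic",
                                    weight=weight_for_isc(c_gen, sd)))
    if c_non > 0:
        regions.append(EffectRegion(box=box, condition="nongenetic",
                                    weight=weight_for_isc(c_non, sd)))
    spec = CohortSpec(n_subjects=n_subjects, n_trs=n_trs, grid_shape=grid,
                      noise_sd=sd, effect_regions=regions, seed=seed)
    runs, truth = simulate_bold_cohort(spec)
    return runs, truth


class TestConditionContrast:
    def test_identical_tensors_give_null_map(self):
        rng = np.random.default_rng(4)
        pairs = enumerate_pairs(5, 2, "genetic")
        z = rng.normal(size=(20, len(pairs)))
        from natisc.isc import PairCorrelationTensor
        ta = PairCorrelationTensor(z=z, pairs=pairs)
        tb = PairCorrelationTensor(z=z.copy(),
                                   pairs=enumerate_pairs(5, 2, "nongenetic"))
        sm = isc_condition_contrast(design_from_tensors(ta, tb),
                                    n_permutations=200, seed=0)
        np.testing.assert_allclose(sm.stat, 0.0, atol=1e-12)
        assert np.all(sm.p > 0.9)
        assert not sm.mask.any()

    def test_t_flips_sign_when_conditions_swap(self):
        runs, _ = _contrast_cohort(0.4, 0.1, seed=5)
        d_ab = build_contrast_design(runs, "genetic", "nongenetic")
        d_ba = build_contrast_design(runs, "nongenetic", "genetic")
        sm_ab = isc_condition_contrast(d_ab, n_permutations=100, seed=1)
        sm_ba = isc_condition_contrast(d_ba, n_permutations=100, seed=1)
        np.testing.assert_allclose(sm_ab.stat, -sm_ba.stat, atol=1e-10)

    def test_planted_difference_recovered(self):
        runs, truth = _contrast_cohort(0.5, 0.1, n_subjects=10, n_trs=250,
                                       seed=6)
        design = build_contrast_design(runs)
        sm = isc_condition_contrast(design, n_permutations=500, seed=2)
        planted = truth.difference_mask
        assert sm.mask[planted].mean() > 0.9
        false_pos = sm.mask & ~planted
        assert false_pos.sum() <= max(1, 0.05 * (~planted).sum())

    def test_recorded_threshold_reproduces_mask(self):
        runs, _ = _contrast_cohort(0.5, 0.1, n_subjects=8, n_trs=150, seed=7)
        sm = isc_condition_contrast(build_contrast_design(runs),
                                    n_permutations=300, seed=3)
        np.testing.assert_array_equal(sm.mask, sm.p <= sm.p_cutoff)
        assert np.all(np.abs(sm.stat[sm.mask]) >= sm.stat_threshold)

    def test_null_p_values_roughly_uniform(self):
        # pooled voxelwise p over a handful of belief-null cohorts (one
        # stimulus course common to all viewings, as for a single movie)
        ps = []
        for seed in range(5):
            spec = CohortSpec(
                n_subjects=6, n_trs=100, grid_shape=(4, 4, 1), noise_sd=0.8,
                effect_regions=[EffectRegion(
                    box=((0, 4), (0, 4), (0, 1)), condition="both",
                    weight=weight_for_isc(0.3, 0.8))], seed=seed)
            runs, _ = simulate_bold_cohort(spec)
            sm = isc_condition_contrast(build_contrast_design(runs),
                                        n_permutations=200, seed=seed)
            ps.append(sm.p)
        ps = np.concatenate(ps)
        rate = float(np.mean(ps < 0.05))
        assert 0.01 < rate < 0.12
        assert stats.kstest(ps, "uniform").pvalue > 1e-4

    def test_too_few_permutations_rejected(self):
        runs, _ = _contrast_cohort(0.3, 0.3, n_subjects=3, n_trs=60, seed=9)
        with pytest.raises(ValueError):
            isc_condition_contrast(build_contrast_design(runs),
                                   n_permutations=50, seed=0)


class TestOneGroupTest:
    def test_planted_region_significant(self):
        spec = CohortSpec(
            n_subjects=10, n_trs=200, grid_shape=(4, 4, 2), noise_sd=0.8,
            effect_regions=[EffectRegion(box=((0, 2), (0, 4), (0, 2)),
                                         condition="genetic",
                                         weight=weight_for_isc(0.5, 0.8))],
            seed=10)
        runs, truth = simulate_bold_cohort(spec)
        genetic = [r for r in runs if r.condition == "genetic"]
        pairs = enumerate_pairs(10, 2, "genetic")
        sm = isc_one_group_test(genetic, pairs, n_permutations=500, seed=4)
        region = truth.isc["genetic"] > 0
        assert sm.mask[region].all()
        assert sm.mask[~region].mean() < 0.10

    def test_identical_runs_saturate_at_resolution_floor(self):
        rng = np.random.default_rng(11)
        data = rng.normal(size=(6, 80))
        runs = [make_run(data.copy(), subject=i) for i in range(3)]
        pairs = enumerate_pairs(3, 1, "genetic")
        sm = isc_one_group_test(runs, pairs, n_permutations=100, seed=5)
        np.testing.assert_allclose(sm.p, 1.0 / 101.0)

    def test_pure_noise_controls_false_positives(self):
        sig = []
        for seed in range(20):
            spec = CohortSpec(n_subjects=5, n_trs=100, grid_shape=(4, 4, 1),
                              seed=seed)
            runs, _ = simulate_bold_cohort(spec)
            genetic = [r for r in runs if r.condition == "genetic"]
            pairs = enumerate_pairs(5, 2, "genetic")
            sm = isc_one_group_test(genetic, pairs, n_permutations=100,
                                    seed=seed)
            sig.append(sm.mask.mean())
        # FDR at q=0.05 on null data: mean significant fraction stays tiny
        assert np.mean(sig) < 0.05 + 2 * np.sqrt(0.05 / 20)
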