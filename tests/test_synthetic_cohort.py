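"""Phantom construction, lesion simulation and planted behavioral effects."""

import numpy as np
import pytest

import lesioncpm as lc
import lesioncpm.behavior as bhv
from lesioncpm.synthetic_cohort import (
    _stroop_counts_for,
    _tube,
    _coordinate_grid,
    make_phantom,
    simulate_behavior,
    simulate_bold,
    simulate_lesions,
)


class TestPhantom:
    def test_ac_maps_nonnegative_and_masked(self, small_phantom):
        mask = small_phantom.brain_mask.data > 0
        for m in small_phantom.atlas_ac.maps:
            assert np.all(m.data >= 0)
            assert np.all(m.data[~mask] == 0)

    def test_parcellation_balanced_across_hemispheres(self, small_cfg, small_phantom):
        p = small_phantom.parcellation
        assert len(p.rois_in_hemisphere("L")) == small_cfg.n_rois // 2
        assert len(p.rois_in_hemisphere("R")) == small_cfg.n_rois // 2

    def test_deterministic_given_config(self, small_cfg, small_phantom):
        again = make_phantom(small_cfg)
        np.testing.assert_array_equal(
            again.brain_mask.data, small_phantom.brain_mask.data
        )
        assert again.network_subset == small_phantom.network_subset
        for m1, m2 in zip(again.atlas_ac.maps, small_phantom.atlas_ac.maps):
            np.testing.assert_array_equal(m1.data, m2.data)

    def test_partnerless_rois_have_zero_ac_maps(self):
        cfg = lc.SyntheticConfig(
            shape=(20, 20, 20), n_rois=8, network_size=4, n_partners=0,
            n_shared=1, n_task_specific=1, n_subjects=(10, 10, 10), seed=3,
        )
        ph = make_phantom(cfg)
        for m in ph.atlas_ac.maps:
            np.testing.assert_array_equal(m.data, 0.0)

    def test_edge_density_equals_naive_tube_sum(self, small_cfg, small_phantom):
        # recompute the normalized union of pair tubes with a naive loop
        grid = _coordinate_grid(tuple(small_cfg.shape))
        mask = small_phantom.brain_mask.data > 0
        sigma = small_cfg.tract_sigma_mm / small_cfg.voxel_mm
        pairs = set()
        for rid, ps in small_phantom.partners.items():
            for p in ps:
                pairs.add((min(rid, p), max(rid, p)))
        total = np.zeros(tuple(small_cfg.shape))
        for r1, r2 in pairs:
            a = small_phantom.roi_centers[r1 - 1]
            b = small_phantom.roi_centers[r2 - 1]
            total += _tube(grid, a, b, sigma) * mask
        if total.max() > 0:
            total /= total.max()
        np.testing.assert_allclose(
            small_phantom.edge_density.data, total * mask, atol=1e-10
        )


class TestLesions:
    def test_lesions_inside_brain_mask(self, small_cfg, small_phantom):
        rng = np.random.default_rng(0)
        lesions = simulate_lesions(small_cfg, 30, rng, small_phantom.brain_mask)
        mask = small_phantom.brain_mask.data > 0
        for les in lesions:
            assert not np.any((les.mask.data > 0) & ~mask)
            assert les.n_voxels >= 1

    def test_volumes_reproducible_with_fixed_seed(self, small_cfg, small_phantom):
        v1 = [
            l.n_voxels
            for l in simulate_lesions(
                small_cfg, 15, np.random.default_rng(5), small_phantom.brain_mask
            )
        ]
        v2 = [
            l.n_voxels
            for l in simulate_lesions(
                small_cfg, 15, np.random.default_rng(5), small_phantom.brain_mask
            )
        ]
        assert v1 == v2

    def test_size_law_shifts_lesion_volumes(self, small_cfg, small_phantom):
        base = dict(vars(small_cfg))
        big_cfg = lc.SyntheticConfig(**{**base, "lesion_log_radius_mean": 1.6})
        small_vols = [
            l.n_voxels
            for l in simulate_lesions(
                small_cfg, 200, np.random.default_rng(1), small_phantom.brain_mask
            )
        ]
        big_vols = [
            l.n_voxels
            for l in simulate_lesions(
                big_cfg, 200, np.random.default_rng(1), small_phantom.brain_mask
            )
        ]
        assert np.mean(big_vols) > 1.5 * np.mean(small_vols)


class TestBehaviorGeneration:
    def test_noiseless_tmt_scores_match_ground_truth_exactly(
        self, small_cfg, small_phantom
    ):
        cfg = lc.SyntheticConfig(**{**vars(small_cfg), "noise_sd": 0.0})
        rng = np.random.default_rng(2)
        lesions = simulate_lesions(cfg, 20, rng, small_phantom.brain_mask)
        recs, gt = simulate_behavior(
            lesions, small_phantom.atlas_ac, cfg, "task1", rng,
            planted_shared=small_phantom.network_subset[:2],
            planted_specific=small_phantom.network_subset[2:3],
        )
        for rec in recs:
            got = lc.tmt_score(rec.tmt_a_s, rec.tmt_b_s)
            assert got == pytest.approx(gt.noiseless_scores[rec.subject_id], abs=1e-9)

    def test_stroop_rounding_within_tolerance(self, small_cohort, small_cfg):
        gt = small_cohort.ground_truth["group3"]
        assert gt.max_rounding_error <= small_cfg.stroop_tolerance
        for rec in small_cohort.behavior["group3"]:
            score = lc.stroop_interference(
                rec.stroop_c_correct, rec.stroop_w_correct, rec.stroop_cw_correct
            )
            assert score == pytest.approx(gt.latent_scores[rec.subject_id], abs=1e-9)

    def test_noiseless_single_roi_loo_is_near_perfect(self, small_phantom, small_cfg):
        # sigma = 0, one planted ROI, strict selection threshold: the
        # perfect predictor alone enters the model and LOO recovers y
        cfg = lc.SyntheticConfig(
            **{**vars(small_cfg), "noise_sd": 0.0, "n_shared": 1, "n_task_specific": 0}
        )
        rng = np.random.default_rng(4)
        lesions = simulate_lesions(cfg, 40, rng, small_phantom.brain_mask)
        recs, gt = simulate_behavior(
            lesions, small_phantom.atlas_ac, cfg, "task1", rng,
            planted_shared=small_phantom.network_subset[:1], planted_specific=[],
        )
        vec = bhv.score_records(recs, "TMT")
        X = lc.disconnection_matrix(lesions, small_phantom.atlas_ac).scores
        pred = lc.crossval_cpm(X, vec.values, alpha=1e-10)
        r = np.corrcoef(pred.y, pred.y_hat)[0, 1]
        assert r > 0.999

    def test_zero_weight_selection_rate_near_alpha(self, small_phantom, small_cfg):
        # no planted effect: selection fires at roughly the nominal rate
        cfg = lc.SyntheticConfig(
            **{**vars(small_cfg), "effect_weight": 0.0, "noise_sd": 1.0}
        )
        rates = []
        for rep in range(30):
            rng = np.random.default_rng(100 + rep)
            lesions = simulate_lesions(cfg, 50, rng, small_phantom.brain_mask)
            recs, _ = simulate_behavior(
                lesions, small_phantom.atlas_ac, cfg, "task1", rng,
                planted_shared=small_phantom.network_subset[:2],
                planted_specific=small_phantom.network_subset[2:3],
            )
            vec = bhv.score_records(recs, "TMT")
            X = lc.disconnection_matrix(lesions, small_phantom.atlas_ac).scores
            sel = lc.select_features(X, vec.values, alpha=0.01,
                                     sign_policy="two_sided")
            rates.append(sel.selected.mean())
        assert np.mean(rates) < 0.06

    def test_stroop_count_search_hits_target(self):
        for y in (-2.0, -0.5, 0.3, 1.2, 2.4):
            c, w, cw, err = _stroop_counts_for(y, 45.0, 0.02)
            assert err <= 0.02
            got = lc.stroop_interference(c, w, cw, 45.0)
            assert got == pytest.approx(y, abs=0.02)


class TestCohort:
    def test_group_sizes_and_disjoint_subjects(self, small_cfg, small_cohort):
        ids = []
        for g, n in zip(("group1", "group2", "group3"), small_cfg.n_subjects):
            assert len(small_cohort.lesions[g]) == n
            ids.extend(l.subject_id for l in small_cohort.lesions[g])
        assert len(ids) == len(set(ids))

    def test_planted_sets_nested_in_network(self, small_cohort, small_phantom):
        net = set(small_phantom.network_subset)
        assert set(small_cohort.planted_shared) <= net
        assert set(small_cohort.planted_task1) <= net
        assert set(small_cohort.planted_task2) <= net
        assert not set(small_cohort.planted_task1) & set(small_cohort.planted_task2)

    def test_cohort_deterministic(self, small_cfg, small_phantom, small_cohort):
        again = lc.simulate_cohort(small_cfg, phantom=small_phantom)
        for g in ("group1", "group2", "group3"):
            for l1, l2 in zip(again.lesions[g], small_cohort.lesions[g]):
                np.testing.assert_array_equal(l1.mask.data, l2.mask.data)
            assert again.behavior[g] == small_cohort.behavior[g]


class TestBold:
    def test_deterministic(self, small_cfg):
        ts1, nuis1, _ = simulate_bold(
            small_cfg, np.random.default_rng(9), shape=(6, 6, 6), n_timepoints=80
        )
        ts2, nuis2, _ = simulate_bold(
            small_cfg, np.random.default_rng(9), shape=(6, 6, 6), n_timepoints=80
        )
        np.testing.assert_array_equal(ts1.data, ts2.data)
        np.testing.assert_array_equal(nuis1, nuis2)

    def test_latent_coupling_visible_in_fc_map(self, small_cfg):
        ts, nuisance, info = simulate_bold(
            small_cfg, np.random.default_rng(10), shape=(8, 8, 8),
            n_timepoints=240, noise_sd=0.3,
        )
        loadings = info["loadings"][0]
        seed_vox = np.unravel_index(np.argmax(loadings), loadings.shape)
        roi = np.zeros((8, 8, 8))
        roi[seed_vox] = 1.0
        fc = lc.build_fc_map(ts, lc.Volume3D(roi, ts.affine), nuisance=nuisance)
        # voxels loading on the same latent correlate with the seed
        partner = np.unravel_index(
            np.argsort(loadings.ravel())[-2], loadings.shape
        )
        assert fc.zmap.data[partner] > 0.2
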