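"""Synthetic cohort generators: moments, determinism, planted structure."""

import numpy as np
import pandas as pd
import pytest

from msprofiler.dconn import affected_connectome, healthy_connectome, regional_disconnection
from msprofiler.synth import (
    CohortConfig,
    generate_clinical,
    generate_label_volume,
    generate_lesions,
    generate_regional_volumes,
    generate_tractogram,
    simulate_cohort,
)


class TestConfigValidation:
    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="proportions"):
            CohortConfig(proportions=(0.5, 0.4, 0.2))

    def test_negative_sd_rejected(self):
        sds = CohortConfig().score_sds
        sds["sdmt"] = (-1.0, 1.0, 1.0)
        with pytest.raises(ValueError, match="SD"):
            CohortConfig(score_sds=sds)

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=-1)


class TestClinical:
    def test_empty_cohort(self):
        clin, truth = generate_clinical(CohortConfig(n_subjects=0))
        assert len(clin) == 0 and len(truth.true_profile) == 0

    def test_determinism(self):
        a, _ = generate_clinical(CohortConfig(seed=5))
        b, _ = generate_clinical(CohortConfig(seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_sdmt_profile_means_match_configuration(self):
        """Empirical per-profile SDMT means within 3 SE of the configured
        values (motor ~56.5, cognitive ~36.8, global ~39.2)."""
        cfg = CohortConfig(n_subjects=5000, seed=2)
        clin, truth = generate_clinical(cfg)
        for k in range(3):
            sel = truth.true_profile == k
            target = cfg.score_means["sdmt"][k]
            se = cfg.score_sds["sdmt"][k] / np.sqrt(sel.sum())
            assert abs(clin.loc[sel, "sdmt"].mean() - target) < 3 * se + 0.15

    def test_profile_proportions_converge(self):
        cfg = CohortConfig(n_subjects=5000, seed=3)
        _, truth = generate_clinical(cfg)
        counts = np.bincount(truth.true_profile, minlength=3)
        for k in range(3):
            p = cfg.proportions[k]
            ci = 3 * np.sqrt(p * (1 - p) / 5000)
            assert abs(counts[k] / 5000 - p) < ci

    def test_legal_ranges_and_edss_grid(self):
        clin, _ = generate_clinical(CohortConfig(n_subjects=2000, seed=4))
        assert ((clin["edss"] * 2) % 1 == 0).all()
        assert clin["edss"].between(0, 10).all()
        assert (clin["t25fw"] > 0.5 - 1e-9).all()
        assert (clin["sdmt"] >= 0).all()
        assert clin["bvmtr"].between(0, 36).all()

    def test_global_profile_spms_enriched(self):
        clin, truth = generate_clinical(CohortConfig(n_subjects=4000, seed=5))
        frac = [
            (clin.loc[truth.true_profile == k, "phenotype"] == "SPMS").mean()
            for k in range(3)
        ]
        assert frac[2] > frac[0] and frac[2] > frac[1]


class TestLabelVolume:
    def test_two_regions_tiny_grid(self):
        lv = generate_label_volume(2, (4, 4, 4), region_size=4, seed=0)
        assert {1, 2} <= set(np.unique(lv.data))

    def test_histogram_exactly_covers_labels(self):
        lv = generate_label_volume(12, (32, 32, 32), region_size=40, seed=1)
        assert set(np.unique(lv.data)) == set(range(13))

    def test_regions_connected(self):
        from scipy.ndimage import label as cc_label

        lv = generate_label_volume(6, (16, 16, 16), region_size=25, seed=2)
        for lab in range(1, 7):
            _, ncomp = cc_label(lv.data == lab)
            assert ncomp == 1

    def test_determinism(self):
        a = generate_label_volume(12, seed=3)
        b = generate_label_volume(12, seed=3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            generate_label_volume(10, (2, 2, 2), region_size=10)


class TestTractogram:
    def test_zero_streamlines(self, small_labels):
        trk = generate_tractogram(small_labels, 0, seed=0)
        assert len(trk) == 0

    def test_pair_coverage_forces_connectome_entry(self):
        lv = generate_label_volume(2, (8, 8, 8), region_size=10, seed=4)
        trk = generate_tractogram(lv, 7, seed=0)
        HC = healthy_connectome(trk)
        assert HC[0, 1] == 7 and HC[1, 0] == 7

    def test_paths_inside_grid_and_endpoints_labelled(self, small_labels, small_tractogram):
        shape = np.array(small_tractogram.grid_shape)
        for sl, (a, b) in zip(small_tractogram.streamlines, small_tractogram.endpoints):
            assert (sl >= 0).all() and (sl < shape).all()
            assert small_labels.data[tuple(sl[0])] == a
            assert small_labels.data[tuple(sl[-1])] == b
            # digital line: consecutive voxels differ by <= 1 per axis
            assert np.abs(np.diff(sl, axis=0)).max(initial=0) <= 1

    def test_determinism(self, small_labels):
        a = generate_tractogram(small_labels, 3, seed=9)
        b = generate_tractogram(small_labels, 3, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a.streamlines, b.streamlines))


class TestLesions:
    def test_zero_mean_profile_gets_empty_masks(self, small_labels):
        cfg = CohortConfig(n_subjects=60, seed=6, lesion_ml_mean=(0.0, 5.0, 5.0))
        clin, truth = generate_clinical(cfg)
        masks = generate_lesions(clin, truth, small_labels, seed=0)
        for s, mask in enumerate(masks):
            if truth.true_profile[s] == 0:
                assert mask.sum() == 0

    def test_masks_binary_and_volume_ordering(self):
        cfg = CohortConfig(n_subjects=600, seed=7)
        clin, truth = generate_clinical(cfg)
        lv = generate_label_volume(cfg.n_regions, cfg.grid_shape, seed=1)
        masks = generate_lesions(clin, truth, lv, seed=2)
        vols = np.array([m.sum() for m in masks])
        assert all(np.isin(m, (0, 1)).all() for m in masks)
        means = [vols[truth.true_profile == k].mean() for k in range(3)]
        # printed per-profile lesion burdens: cognitive > global > motor
        assert means[1] > means[2] > means[0]

    def test_misaligned_inputs_rejected(self, small_labels):
        clin, truth = generate_clinical(CohortConfig(n_subjects=10, seed=8))
        with pytest.raises(ValueError):
            generate_lesions(clin.iloc[:5], truth, small_labels, seed=0)


class TestRegionalVolumes:
    def test_noiseless_single_component_rank(self):
        cfg = CohortConfig(
            n_subjects=50, seed=9, n_planted_components=1,
            planted_shifts=((0.0,), (1.0,), (-1.0,)),
        )
        clin, truth = generate_clinical(cfg)
        vols = generate_regional_volumes(clin, truth, noise_sd=0.0, seed=0)
        X = vols.drop(columns="subject_id").to_numpy()
        centered = X - X.mean(axis=0)
        assert np.linalg.matrix_rank(centered, tol=1e-8) <= 1

    def test_planted_shift_separates_groups_on_truth_scores(self):
        cfg = CohortConfig(n_subjects=2000, seed=10)
        _, truth = generate_clinical(cfg)
        shifts = np.asarray(cfg.planted_shifts)
        for comp in range(cfg.n_planted_components):
            group_means = [
                truth.planted_scores[truth.true_profile == k, comp].mean()
                for k in range(3)
            ]
            for a in range(3):
                for b in range(3):
                    if shifts[a, comp] < shifts[b, comp]:
                        assert group_means[a] < group_means[b]

    def test_negative_noise_rejected(self):
        clin, truth = generate_clinical(CohortConfig(n_subjects=5, seed=11))
        with pytest.raises(ValueError):
            generate_regional_volumes(clin, truth, noise_sd=-1.0)

    def test_positive_and_deterministic(self):
        clin, truth = generate_clinical(CohortConfig(n_subjects=30, seed=12))
        a = generate_regional_volumes(clin, truth, seed=1)
        b = generate_regional_volumes(clin, truth, seed=1)
        pd.testing.assert_frame_equal(a, b)
        assert (a.drop(columns="subject_id").to_numpy() > 0).all()


def test_whole_cohort_bundle_consistency():
    cohort = simulate_cohort(CohortConfig(n_subjects=40, seed=13))
    assert len(cohort.clinical) == len(cohort.lesions) == 40
    assert cohort.regional_volumes.shape == (40, 13)
    assert cohort.tractogram.n_regions == cohort.labels.n_regions


def test_disconnection_ordering_across_profiles():
    """Whole-brain disconnection mirrors the published profile ordering
    (cognitive > global > motor) on the default generator."""
    cohort = simulate_cohort(CohortConfig(n_subjects=300, seed=14))
    HC = healthy_connectome(cohort.tractogram)
    wb = np.array(
        [
            regional_disconnection(HC, affected_connectome(cohort.tractogram, m)).whole_brain
            for m in cohort.lesions
        ]
    )
    prof = cohort.truth.true_profile
    means = [wb[prof == k].mean() for k in range(3)]
    assert means[1] > means[2] > means[0]
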