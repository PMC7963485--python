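import numpy as np
import pytest

from xenassay.synthetic import (StackSimParams, make_assay_cohort,
                                make_realtime_series, make_stack_pair)
from xenassay.trogo import (MicrogliaROI, TectumMeasurement, assay_correlations,
                            assemble_assay, green_mode_background,
                            hybrid_median_3d, link_microglia, measure_rois,
                            realtime_roi_trace, register_series,
                            segment_microglia)


def brute_force_hybrid_median(vol):
    """Per-voxel oracle: reflect-pad, then median of the three plane medians
    and the center value."""
    v = np.pad(np.asarray(vol, float), 1, mode="reflect")
    out = np.empty_like(np.asarray(vol, float))
    nz, ny, nx = vol.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                zc, yc, xc = z + 1, y + 1, x + 1
                m_xy = np.median(v[zc, yc - 1:yc + 2, xc - 1:xc + 2])
                m_xz = np.median(v[zc - 1:zc + 2, yc, xc - 1:xc + 2])
                m_yz = np.median(v[zc - 1:zc + 2, yc - 1:yc + 2, xc])
                out[z, y, x] = np.median([m_xy, m_xz, m_yz, v[zc, yc, xc]])
    return out


class TestHybridMedian:
    def test_constant_volume_unchanged(self):
        vol = np.full((5, 6, 7), 42.0)
        assert np.array_equal(hybrid_median_3d(vol), vol)

    def test_single_hot_voxel_rejected(self):
        vol = np.full((5, 5, 5), 10.0)
        vol[2, 2, 2] = 1000.0
        out = hybrid_median_3d(vol)
        assert out[2, 2, 2] == 10.0

    def test_matches_brute_force_oracle_on_random_volume(self):
        rng = np.random.default_rng(0)
        vol = rng.integers(0, 255, (8, 8, 8)).astype(float)
        assert np.array_equal(hybrid_median_3d(vol), brute_force_hybrid_median(vol))

    def test_2d_input_rejected(self):
        with pytest.raises(ValueError):
            hybrid_median_3d(np.zeros((10, 10)))


class TestRegistration:
    def _blob_volume(self, seed=0, shape=(24, 32, 32)):
        rng = np.random.default_rng(seed)
        zz, yy, xx = np.mgrid[0:shape[0], 0:shape[1], 0:shape[2]].astype(float)
        vol = 50.0 + 200.0 * np.exp(-(((zz - 12) / 4) ** 2 + ((yy - 16) / 6) ** 2
                                      + ((xx - 16) / 6) ** 2))
        return vol

    def test_known_shift_recovered(self):
        vol = self._blob_volume()
        moved = np.roll(vol, (-3, 2, -1), axis=(0, 1, 2))
        shifts, aligned = register_series([vol, moved])
        assert shifts[0] == (3, -2, 1)
        assert np.allclose(aligned[1], vol)

    def test_identical_volumes_zero_shift(self):
        vol = self._blob_volume()
        shifts, _ = register_series([vol, vol.copy()])
        assert shifts[0] == (0, 0, 0)

    def test_shift_recovered_under_noise_across_seeds(self):
        vol = self._blob_volume()
        for seed in range(10):
            rng = np.random.default_rng(seed)
            moved = np.roll(vol, (2, -1, 3), axis=(0, 1, 2))
            noisy = moved + rng.normal(0, 20.0, vol.shape)  # 10% of signal
            shifts, _ = register_series([vol, noisy])
            assert shifts[0] == (-2, 1, -3)


class TestSegmentMicroglia:
    def test_single_bright_blob_gives_one_label(self):
        rng = np.random.default_rng(1)
        vol = rng.normal(100, 10, (30, 40, 40))
        vol[10:20, 10:28, 10:28] = 400.0  # ~3240 voxels
        labels = segment_microglia(vol, min_size=1500)
        assert labels.max() == 1
        assert (labels == 1).sum() >= 3000

    def test_min_size_rule_boundary(self):
        vol = np.random.default_rng(2).normal(100, 5, (40, 40, 40))
        vol[2:9, 2:12, 2:22] = 400.0    # 7*10*20 = 1400 voxels -> discarded
        vol[20:28, 20:30, 18:38] = 400.0  # 8*10*20 = 1600 voxels -> kept
        labels = segment_microglia(vol, min_size=1500)
        assert labels.max() == 1
        assert labels[24, 24, 24] == 1
        assert labels[5, 5, 5] == 0

    def test_uniform_volume_yields_no_labels(self):
        labels = segment_microglia(np.full((10, 10, 10), 7.0), min_size=10)
        assert labels.max() == 0

    def test_intensity_offset_invariance(self):
        rng = np.random.default_rng(3)
        vol = rng.normal(100, 10, (20, 30, 30))
        vol[5:15, 5:20, 5:20] = 300.0
        l1 = segment_microglia(vol, min_size=100)
        l2 = segment_microglia(vol + 57.0, min_size=100)
        assert np.array_equal(l1, l2)

    def test_labels_ordered_by_descending_size(self):
        vol = np.zeros((30, 30, 30))
        vol[2:6, 2:6, 2:6] = 100.0      # 64 voxels
        vol[20:28, 20:28, 20:28] = 100.0  # 512 voxels
        labels = segment_microglia(vol, k_sd=1.0, min_size=10)
        assert labels[24, 24, 24] == 1
        assert labels[3, 3, 3] == 2


class TestModeBackground:
    def test_dominant_value_is_mode(self):
        vol = np.full((10, 10, 10), 100.0)
        vol[:1] = 250.0
        assert green_mode_background(vol) == 100.0

    def test_tie_broken_by_lowest_value(self):
        vol = np.array([[[100.0] * 5 + [130.0] * 5]])
        assert green_mode_background(vol) == 100.0

    def test_recovers_programmed_offset(self, small_stack):
        params, pair, truth = small_stack
        mode = green_mode_background(pair.green)
        assert abs(mode - truth["green_offset"]) <= 1.0


class TestMeasureRois:
    def _one_roi(self):
        labels = np.zeros((10, 10, 10), dtype=int)
        labels[3:7, 3:7, 3:7] = 1
        green = np.full((10, 10, 10), 150.0)
        return labels, green

    def test_uniform_roi_mean_minus_mode(self):
        labels, green = self._one_roi()
        rois, summary = measure_rois(labels, green, mode_bg=100.0)
        assert rois[0].mean_green_corrected == pytest.approx(50.0)
        assert summary == pytest.approx(50.0)

    def test_negative_corrected_mean_clamped_at_zero(self):
        labels, green = self._one_roi()
        rois, summary = measure_rois(labels, green, mode_bg=200.0)
        assert rois[0].mean_green_corrected == 0.0

    def test_single_voxel_axon_overlap_excludes_roi(self):
        labels, green = self._one_roi()
        labels[0:2, 0:2, 0:2] = 2
        axon = np.zeros_like(labels, dtype=bool)
        axon[3, 3, 3] = True  # one voxel shared with ROI 1
        rois, summary = measure_rois(labels, green, 100.0, axon_mask=axon)
        by_label = {r.label: r for r in rois}
        assert by_label[1].excluded and by_label[1].exclusion_reason == "axon_overlap"
        assert not by_label[2].excluded

    def test_manual_exclusion(self):
        labels, green = self._one_roi()
        labels[0:2, 0:2, 0:2] = 2
        rois, _ = measure_rois(labels, green, 100.0, manual_exclusions=[2])
        by_label = {r.label: r for r in rois}
        assert by_label[2].exclusion_reason == "manual"

    def test_all_excluded_raises(self):
        labels, green = self._one_roi()
        with pytest.raises(ValueError):
            measure_rois(labels, green, 100.0, manual_exclusions=[1])

    def test_summary_invariant_to_label_renumbering_and_outside_voxels(self):
        labels, green = self._one_roi()
        labels[0:2, 0:2, 0:2] = 2
        green2 = green.copy()
        green2[labels == 0] = 999.0  # outside-ROI voxels must not matter
        relabeled = np.where(labels == 1, 5, np.where(labels == 2, 3, 0))
        _, s1 = measure_rois(labels, green, 100.0)
        _, s2 = measure_rois(relabeled, green2, 100.0)
        assert s1 == pytest.approx(s2)

    def test_programmed_means_recovered_from_stack(self, small_stack):
        params, pair, truth = small_stack
        from xenassay.synthetic import _min_size_for
        labels = segment_microglia(pair.red, min_size=_min_size_for(params))
        mode = green_mode_background(pair.green)
        rois, _ = measure_rois(labels, pair.green, mode)
        for r in rois:
            tol = 3 * params.noise_sigma / np.sqrt(r.n_voxels) + 1.5
            assert r.mean_green_corrected == pytest.approx(
                truth["green_content"], abs=tol)


class TestAssembleAssay:
    def _meas(self, animal, day, count, bleb=False, green=10.0):
        return TectumMeasurement(animal_id=animal, day=day, axon_count=count,
                                 blebbing=bleb, mean_microglial_green=green,
                                 n_rois=3)

    def test_axon_count_drop_excludes_animal(self):
        table = assemble_assay([self._meas("a", 4, 5), self._meas("a", 5, 4)])
        assert table.data["excluded"].iloc[0]
        assert table.data["exclusion_reason"].iloc[0] == "axon_loss"

    def test_rule_disabled_retains_animal(self):
        table = assemble_assay([self._meas("a", 4, 5), self._meas("a", 5, 4)],
                               exclusion_rule_enabled=False)
        assert not table.data["excluded"].iloc[0]

    def test_blebbing_on_either_day_excludes(self):
        t1 = assemble_assay([self._meas("a", 4, 3, bleb=True), self._meas("a", 5, 3)])
        t2 = assemble_assay([self._meas("b", 4, 3), self._meas("b", 5, 3, bleb=True)])
        assert t1.data["excluded"].iloc[0] and t2.data["excluded"].iloc[0]
        assert t1.data["exclusion_reason"].iloc[0] == "blebbing"

    def test_missing_day_drops_animal(self):
        table = assemble_assay([self._meas("a", 4, 3)])
        assert len(table.data) == 0

    def test_enabling_rule_never_retains_more_animals(self):
        meas, _ = make_assay_cohort(n_animals=20, frac_blebbing=0.1,
                                    frac_axon_loss=0.1, seed=5)
        on = assemble_assay(meas, exclusion_rule_enabled=True)
        off = assemble_assay(meas, exclusion_rule_enabled=False)
        assert len(on.included) <= len(off.included)
        assert len(off.included) == len(off.data)


class TestAssayCorrelations:
    def test_zero_slope_gives_small_r_over_replicates(self):
        rs = []
        for seed in range(30):
            meas, _ = make_assay_cohort(n_animals=47, slope_day4=0.0,
                                        slope_day5=0.0, seed=seed)
            res = assay_correlations(assemble_assay(meas))
            rs.append(res["day5"].r)
        assert abs(np.mean(rs)) < 0.08
        # p-values roughly uniform: around half should exceed 0.5
        ps = [assay_correlations(assemble_assay(
            make_assay_cohort(n_animals=47, slope_day4=0.0, slope_day5=0.0,
                              seed=s)[0]))["day5"].p for s in range(30)]
        assert 0.2 < np.mean(np.array(ps) > 0.5) < 0.8

    def test_identical_conditions_center_fisher_z_on_zero(self):
        zs = []
        for seed in range(30):
            m1, _ = make_assay_cohort(n_animals=40, seed=1000 + seed)
            m2, _ = make_assay_cohort(n_animals=40, seed=2000 + seed,
                                      condition="other")
            res = assay_correlations(assemble_assay(m1), assemble_assay(m2))
            zs.append(res["fisher_z_delta"].z)
        assert abs(np.mean(zs)) < 0.5

    def test_too_few_animals_rejected(self):
        meas, _ = make_assay_cohort(n_animals=8, seed=0)
        table = assemble_assay(meas[:6])  # only 3 complete animals
        with pytest.raises(ValueError):
            assay_correlations(table)


class TestRealtimeTrace:
    def test_step_trace_fold_change(self):
        reds, greens, truth = make_realtime_series(n_frames=20, fold=3.0,
                                                   event_frame=16, noise_sigma=0.0)
        trace = realtime_roi_trace(reds, greens, fixed_threshold=250.0)
        assert trace.baseline == pytest.approx(truth["base_level"], rel=0.01)
        assert trace.fold_change[-1] == pytest.approx(3.0, rel=0.02)

    def test_interaction_truncates_baseline(self):
        reds, greens, _ = make_realtime_series(n_frames=20, fold=3.0,
                                               event_frame=10, noise_sigma=0.0)
        trace = realtime_roi_trace(reds, greens, fixed_threshold=250.0,
                                   interaction_frame=10)
        # baseline from frames 0..9 only, all pre-step
        assert trace.baseline == pytest.approx(20.0, rel=0.01)
        assert trace.fold_change[-1] == pytest.approx(3.0, rel=0.02)

    def test_early_interaction_rejected(self):
        reds, greens, _ = make_realtime_series(n_frames=20, noise_sigma=0.0)
        with pytest.raises(ValueError):
            realtime_roi_trace(reds, greens, 250.0, interaction_frame=1)

    def test_noisy_fold_recovered_across_seeds(self):
        folds = []
        for seed in range(10):
            reds, greens, _ = make_realtime_series(n_frames=20, fold=2.0,
                                                   event_frame=16,
                                                   noise_sigma=2.0, seed=seed)
            trace = realtime_roi_trace(reds, greens, fixed_threshold=250.0)
            folds.append(np.nanmean(trace.fold_change[16:]))
        assert np.allclose(folds, 2.0, atol=0.2)


class TestMobility:
    def test_programmed_step_speed(self):
        pts = [np.array([[0.0, 0.0, 9.0 * k]]) for k in range(8)]
        tracks, cohort = link_microglia(pts, interval_s=360.0)
        assert len(tracks) == 1
        assert tracks[0].mean_speed_um_min == pytest.approx(1.5)
        assert cohort == pytest.approx(1.5)

    def test_stationary_cells_zero_speed(self):
        pts = [np.array([[0.0, 0.0, 0.0], [0.0, 50.0, 50.0]])] * 6
        tracks, cohort = link_microglia(pts)
        assert cohort == pytest.approx(0.0)

    def test_well_separated_programmed_speeds_recovered(self):
        rng = np.random.default_rng(0)
        speeds = [1.0, 2.0, 3.0]  # µm/min at 6-min intervals
        origins = np.array([[0, 0, 0], [0, 200, 0], [0, 0, 200]], float)
        pts = []
        for k in range(10):
            frame = []
            for o, s in zip(origins, speeds):
                frame.append(o + [0, 0, s * 6.0 * k])
            pts.append(np.array(frame))
        tracks, _ = link_microglia(pts, max_displacement_um=40.0)
        got = sorted(t.mean_speed_um_min for t in tracks if len(t.timepoints) >= 5)
        assert np.allclose(got, speeds, rtol=0.05)

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError):
            link_microglia([np.zeros((2, 3))])
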