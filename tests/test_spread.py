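"""Decay-constant pipeline: amplitude maps, binning, distances, fitting."""

import numpy as np
import pytest

from scartools.spread import (
    AmplitudeBin,
    AmplitudeMap,
    RegionAnnotation,
    VoltageMovie,
    bin_amplitudes,
    compute_amplitude_map,
    fit_exponential,
    normalize_to_control,
    percent_decrease,
    pipeline_decay_constant,
    radial_distances,
    select_matched_uninjured_region,
)
from scartools.spread.types import GroupSummary
from scartools.synth import generate_amplitude_map, generate_voltage_movie

from .conftest import make_sector_spec
from .oracles import brute_bin_members


class TestComputeAmplitudeMap:
    def test_constant_movie_gives_zero_map(self):
        movie = VoltageMovie(frames=np.full((20, 5, 5), 3.0), frame_rate=1000.0, pixel_pitch=0.1)
        amap = compute_amplitude_map(movie, (10, 20), (0, 10))
        np.testing.assert_array_equal(amap.values, 0.0)

    def test_default_baseline_precedes_pulse(self):
        frames = np.zeros((20, 4, 4))
        frames[:5] = 1.0  # baseline offset
        frames[10:15] = 5.0
        movie = VoltageMovie(frames=frames, frame_rate=1000.0, pixel_pitch=0.1)
        amap = compute_amplitude_map(movie, (10, 15))  # baseline = frames 0..9, mean 0.5
        np.testing.assert_allclose(amap.values, 4.5)

    def test_zero_length_window_raises(self):
        movie = VoltageMovie(frames=np.zeros((10, 2, 2)), frame_rate=1000.0, pixel_pitch=0.1)
        with pytest.raises(ValueError, match="pulse_window"):
            compute_amplitude_map(movie, (5, 5), (0, 5))

    def test_overlapping_windows_raise(self):
        movie = VoltageMovie(frames=np.zeros((10, 2, 2)), frame_rate=1000.0, pixel_pitch=0.1)
        with pytest.raises(ValueError, match="overlap"):
            compute_amplitude_map(movie, (4, 8), (0, 5))

    def test_negative_clipped_to_zero(self):
        frames = np.zeros((10, 2, 2))
        frames[0:5] = 2.0  # baseline above pulse
        movie = VoltageMovie(frames=frames, frame_rate=1000.0, pixel_pitch=0.1)
        amap = compute_amplitude_map(movie, (5, 10), (0, 5))
        np.testing.assert_array_equal(amap.values, 0.0)

    def test_noisy_recovery_bounded_by_max_of_n_statistics(self):
        """Monte-Carlo oracle: with n pulse frames the per-pixel error is the
        max of n gaussians minus a baseline mean; its spread is set by
        sigma * sqrt(2 ln n)."""
        spec = make_sector_spec(noise_sd=0.2, seed=123, shape=(100, 100))
        movie, _ = generate_voltage_movie(spec, frames=30, pulse_window=(10, 30))
        noiseless, _ = generate_amplitude_map(
            spec.model_copy(update={"noise_sd": 0.0})
        )
        amap = compute_amplitude_map(movie, (10, 30), (0, 10))
        err = amap.values - noiseless.values
        sigma, n = 0.2, 20
        expected_mean = sigma * np.sqrt(2 * np.log(n))  # ~ E[max of n N(0,s)]
        assert 0.5 * expected_mean < err.mean() < 1.5 * expected_mean
        # max over all pixels of max-of-n: generous 6-sigma cap
        assert np.abs(err).max() < 6 * sigma


class TestRadialDistances:
    def test_single_pixel_mask_is_zero(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 4] = True
        d = radial_distances(mask, (2.0, 0.0), 0.1)
        assert d[2, 4] == 0.0

    def test_pitch_scaling_printed_value(self):
        # pixels at 10 and 20 px from the electrode, pitch 0.0928 mm
        mask = np.zeros((1, 30), dtype=bool)
        mask[0, 10] = True
        mask[0, 20] = True
        d = radial_distances(mask, (0.0, 0.0), 0.0928)
        assert d[0, 10] == 0.0
        assert d[0, 20] == pytest.approx(0.928)

    def test_translation_invariance(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:15, 20:30] = True
        d1 = radial_distances(mask, (10.0, 10.0), 0.05)
        mask2 = np.roll(mask, (7, 3), axis=(0, 1))
        d2 = radial_distances(mask2, (17.0, 13.0), 0.05)
        np.testing.assert_allclose(d1[mask], d2[mask2])

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            radial_distances(np.zeros((5, 5), dtype=bool), (0.0, 0.0), 0.1)

    def test_outside_mask_is_nan(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1, 1] = True
        d = radial_distances(mask, (0.0, 0.0), 0.1)
        assert np.isnan(d[0, 0])


class TestBinAmplitudes:
    def _uniform_map(self):
        # 10x10 map with amplitudes 0..99 inside mask, distances irrelevant
        values = np.arange(100, dtype=float).reshape(10, 10)
        return AmplitudeMap(values=values, pixel_pitch=0.1)

    def test_equal_width_boundaries(self):
        amap = self._uniform_map()
        mask = np.ones((10, 10), dtype=bool)
        mask[0, 0] = True
        bins = bin_amplitudes(amap, mask, (0.0, 0.0), n_bins=5)
        lows = sorted(b.amplitude_range[0] for b in bins)
        highs = sorted(b.amplitude_range[1] for b in bins)
        np.testing.assert_allclose(lows, [0.0, 19.8, 39.6, 59.4, 79.2])
        np.testing.assert_allclose(highs, [19.8, 39.6, 59.4, 79.2, 99.0])

    def test_partition_property(self):
        amap = self._uniform_map()
        mask = np.ones((10, 10), dtype=bool)
        bins = bin_amplitudes(amap, mask, (0.0, 0.0), n_bins=5)
        assert sum(b.pixel_count for b in bins) == int(mask.sum())

    def test_matches_brute_force_grouping(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 50, size=(20, 20))
        amap = AmplitudeMap(values=values, pixel_pitch=0.1)
        mask = np.zeros((20, 20), dtype=bool)
        mask[4:18, 3:17] = True
        bins = bin_amplitudes(amap, mask, (0.0, 0.0), n_bins=5, min_pixels=1)
        oracle = brute_bin_members(values, mask, 5)
        for b, members in zip(bins, oracle):
            assert b.pixel_count == len(members)
            amps = [values[idx] for idx in members]
            assert b.mean_amplitude == pytest.approx(np.mean(amps))

    def test_monotone_means_for_exponential_map(self, sector_spec, sector_annotation):
        amap, _ = generate_amplitude_map(sector_spec)
        bins = bin_amplitudes(
            amap, sector_spec.scar_mask, sector_spec.electrode_center, n_bins=5
        )
        amps = [b.mean_amplitude for b in bins]
        dists = [b.mean_distance for b in bins]
        assert all(a1 > a2 for a1, a2 in zip(amps, amps[1:]))
        assert all(d1 < d2 for d1, d2 in zip(dists, dists[1:]))

    def test_underfilled_bins_merge_downward(self):
        values = np.zeros((1, 20))
        values[0, :16] = np.linspace(0, 10, 16)  # bulk in low bins
        values[0, 16:] = 100.0  # 4 pixels alone at the top
        amap = AmplitudeMap(values=values, pixel_pitch=0.1)
        mask = np.ones((1, 20), dtype=bool)
        bins = bin_amplitudes(amap, mask, (0.0, 0.0), n_bins=5, min_pixels=5)
        assert bins[0].merged
        assert sum(b.pixel_count for b in bins) == 20

    def test_constant_map_raises(self):
        amap = AmplitudeMap(values=np.full((5, 5), 2.0), pixel_pitch=0.1)
        with pytest.raises(ValueError, match="constant"):
            bin_amplitudes(amap, np.ones((5, 5), dtype=bool), (0.0, 0.0), n_bins=5)

    def test_too_few_bins_rejected(self):
        amap = self._uniform_map()
        with pytest.raises(ValueError, match="n_bins"):
            bin_amplitudes(amap, np.ones((10, 10), dtype=bool), (0.0, 0.0), n_bins=1)


def exact_bins(v0: float, dc: float, distances) -> list[AmplitudeBin]:
    return [
        AmplitudeBin(
            index=i + 1,
            amplitude_range=(0.0, 1.0),
            mean_amplitude=v0 * np.exp(-d / dc),
            mean_distance=d,
            pixel_count=10,
        )
        for i, d in enumerate(distances)
    ]


class TestFitExponential:
    @pytest.mark.parametrize("v0,dc", [(10.0, 0.48), (7.0, 0.57)])
    def test_exact_points_recovered(self, v0, dc):
        fit = fit_exponential(exact_bins(v0, dc, [0.0, 0.3, 0.6, 0.9, 1.2]))
        assert fit.converged
        assert fit.decay_constant == pytest.approx(dc, rel=1e-6)
        assert fit.v_edge == pytest.approx(v0, rel=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_self_consistency_at_one_decay_constant(self):
        fit = fit_exponential(exact_bins(5.0, 0.4, [0.0, 0.2, 0.5, 0.8]))
        assert fit.predict(fit.decay_constant) == pytest.approx(
            fit.v_edge * np.exp(-1.0), rel=1e-12
        )

    def test_duplicate_distances_rejected(self):
        bins = exact_bins(10.0, 0.5, [0.1, 0.1, 0.1, 0.1])
        with pytest.raises(ValueError, match="distinct"):
            fit_exponential(bins)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="3"):
            fit_exponential(exact_bins(10.0, 0.5, [0.0, 0.5]))

    def test_flat_data_flagged_not_silent(self):
        bins = exact_bins(10.0, 1e9, [0.0, 0.01, 0.02, 0.03])  # essentially constant
        fit = fit_exponential(bins)
        assert not fit.converged
        assert fit.message != "ok"


class TestMatchedRegion:
    def test_rotation_match_properties(self, sector_spec, sector_annotation):
        amap, _ = generate_amplitude_map(sector_spec)
        matched = select_matched_uninjured_region(amap, sector_annotation)
        scar = sector_spec.scar_mask
        er, ec = sector_spec.electrode_center
        assert not np.any(matched & scar)
        assert abs(int(matched.sum()) - int(scar.sum())) <= 0.02 * scar.sum()
        sr, sc = np.nonzero(scar)
        mr, mc = np.nonzero(matched)
        r_scar = np.hypot(sr - er, sc - ec).min()
        r_match = np.hypot(mr - er, mc - ec).min()
        assert abs(r_scar - r_match) <= 0.5

    def test_full_field_scar_errors(self):
        mask = np.ones((50, 50), dtype=bool)
        mask[0, 0] = False  # electrode pixel
        ann = RegionAnnotation(scar_mask=mask, electrode_center=(0.0, 0.0))
        amap = AmplitudeMap(values=np.random.default_rng(0).uniform(size=(50, 50)), pixel_pitch=0.1)
        with pytest.raises(ValueError, match="manual"):
            select_matched_uninjured_region(amap, ann)

    def test_provided_mask_validated(self, sector_spec):
        amap, _ = generate_amplitude_map(sector_spec)
        bad = np.zeros_like(sector_spec.scar_mask)
        bad[0, 0] = True  # wrong size and wrong distance
        ann = RegionAnnotation(
            scar_mask=sector_spec.scar_mask,
            electrode_center=sector_spec.electrode_center,
            uninjured_mask=bad,
        )
        with pytest.raises(ValueError):
            select_matched_uninjured_region(amap, ann)


class TestPipeline:
    def test_noiseless_scar_recovery(self, sector_spec, sector_annotation):
        amap, _ = generate_amplitude_map(sector_spec)
        fit = pipeline_decay_constant(amap, sector_annotation, region="scar")
        assert fit.converged
        assert abs(fit.decay_constant - 0.48) / 0.48 < 0.05

    def test_equal_lambdas_symmetric_regions(self):
        spec = make_sector_spec(lambda_scar=0.5, lambda_uninjured=0.5)
        amap, _ = generate_amplitude_map(spec)
        ann = RegionAnnotation(scar_mask=spec.scar_mask, electrode_center=spec.electrode_center)
        f_scar = pipeline_decay_constant(amap, ann, region="scar")
        f_unj = pipeline_decay_constant(amap, ann, region="uninjured")
        assert abs(f_scar.decay_constant - f_unj.decay_constant) / f_scar.decay_constant < 0.05

    def test_movie_source_end_to_end(self):
        spec = make_sector_spec()
        movie, _ = generate_voltage_movie(spec, frames=40, pulse_window=(10, 30))
        ann = RegionAnnotation(scar_mask=spec.scar_mask, electrode_center=spec.electrode_center)
        fit = pipeline_decay_constant(movie, ann, region="scar", pulse_window=(10, 30))
        assert abs(fit.decay_constant - 0.48) / 0.48 < 0.05

    def test_noisy_recovery_over_seeds(self):
        errs = []
        for seed in range(20):
            spec = make_sector_spec(noise_sd=0.1, seed=seed)
            amap, _ = generate_amplitude_map(spec)
            ann = RegionAnnotation(
                scar_mask=spec.scar_mask, electrode_center=spec.electrode_center
            )
            fit = pipeline_decay_constant(amap, ann, region="scar")
            errs.append(abs(fit.decay_constant - 0.48) / 0.48)
        assert max(errs) < 0.15

    def test_scale_equivariance(self, sector_spec, sector_annotation):
        amap, _ = generate_amplitude_map(sector_spec)
        fit1 = pipeline_decay_constant(amap, sector_annotation, region="scar")
        scaled = AmplitudeMap(values=3.0 * amap.values, pixel_pitch=amap.pixel_pitch)
        fit2 = pipeline_decay_constant(scaled, sector_annotation, region="scar")
        assert fit2.decay_constant == pytest.approx(fit1.decay_constant, rel=1e-9)
        assert fit2.v_edge == pytest.approx(3.0 * fit1.v_edge, rel=1e-9)

    def test_pixel_pitch_doubling_doubles_dc(self, sector_spec, sector_annotation):
        amap, _ = generate_amplitude_map(sector_spec)
        fit1 = pipeline_decay_constant(amap, sector_annotation, region="scar")
        doubled = AmplitudeMap(values=amap.values, pixel_pitch=2 * amap.pixel_pitch)
        fit2 = pipeline_decay_constant(doubled, sector_annotation, region="scar")
        assert fit2.decay_constant == pytest.approx(2 * fit1.decay_constant, rel=1e-6)

    @pytest.mark.parametrize("lam", np.round(np.arange(0.2, 1.01, 0.1), 2).tolist())
    def test_lambda_grid_recovery(self, lam):
        spec = make_sector_spec(lambda_scar=float(lam), shape=(300, 300))
        amap, _ = generate_amplitude_map(spec)
        ann = RegionAnnotation(scar_mask=spec.scar_mask, electrode_center=spec.electrode_center)
        fit = pipeline_decay_constant(amap, ann, region="scar")
        assert abs(fit.decay_constant - lam) / lam < 0.05

    def test_bad_region_rejected(self, sector_spec, sector_annotation):
        amap, _ = generate_amplitude_map(sector_spec)
        with pytest.raises(ValueError, match="region"):
            pipeline_decay_constant(amap, sector_annotation, region="border")


class TestGroupStatistics:
    def test_normalize_basic(self):
        groups = [
            GroupSummary(label="bmpCTL", decay_constants=[0.5, 0.5]),
            GroupSummary(label="bmpKO", decay_constants=[0.25, 0.25]),
        ]
        normalize_to_control(groups, "bmpCTL")
        assert groups[0].normalized_mean == pytest.approx(1.0)
        assert groups[1].normalized_mean == pytest.approx(0.5)

    def test_single_group_identity(self):
        groups = [GroupSummary(label="only", decay_constants=[0.4, 0.6])]
        normalize_to_control(groups, "only")
        assert groups[0].normalized_mean == pytest.approx(1.0)
        assert groups[0].percent_change_vs_control == pytest.approx(0.0)

    def test_printed_style_decrease(self):
        groups = [
            GroupSummary(label="ctl", decay_constants=[0.48]),
            GroupSummary(label="ko", decay_constants=[0.30]),
        ]
        normalize_to_control(groups, "ctl")
        assert groups[1].normalized_mean == pytest.approx(0.625)
        assert groups[1].percent_change_vs_control == pytest.approx(37.5)

    def test_percent_decrease_values(self):
        assert percent_decrease(0.30, 0.48) == pytest.approx(37.5)
        assert percent_decrease(0.7, 0.7) == 0.0
        assert percent_decrease(0.404, 0.57) == pytest.approx(29.12, abs=0.01)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            percent_decrease(0.3, 0.0)

    def test_missing_control_group(self):
        with pytest.raises(ValueError, match="not found"):
            normalize_to_control([GroupSummary(label="a", decay_constants=[1.0])], "b")

    def test_sem_definition(self):
        g = GroupSummary(label="g", decay_constants=[0.4, 0.5, 0.6])
        assert g.mean == pytest.approx(0.5)
        assert g.sem == pytest.approx(np.std([0.4, 0.5, 0.6], ddof=1) / np.sqrt(3))
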