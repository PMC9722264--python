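"""Wide-field analysis: df/f movies, triggered averages, latency maps,
response areas, velocity fields, activation distributions."""

import numpy as np
import pytest

from cortexwave import (
    ActivationHistogram,
    FieldGeometry,
    GroundTruth,
    LatencyMap,
    Movie,
    SimConfig,
    activation_distribution,
    compare_distributions_permutation,
    dff_movie,
    generate_spontaneous_events,
    generate_stimulus_train,
    mean_velocity_vector,
    onset_latency_map,
    render_widefield,
    response_area,
    stimulus_triggered_average,
    velocity_field,
)
from cortexwave.widefield import (
    DegenerateFieldError,
    DegenerateMapError,
    DegenerateNormalizationError,
    TriggeredAverage,
    VelocityField,
)


def small_geometry(n=48, pitch=0.1):
    return FieldGeometry(fov_ap_mm=n * pitch, fov_ml_mm=n * pitch,
                         pixel_pitch_mm=pitch, sites={})


def make_sta(frames, rate=20.0, geometry=None, n_pre=20):
    geometry = geometry or small_geometry(frames.shape[1])
    t = (np.arange(frames.shape[0]) - n_pre) / rate
    return TriggeredAverage(frames=frames, t_s=t, frame_rate_hz=rate,
                            geometry=geometry, n_stimuli=1)


class TestDffMovie:
    def test_arithmetic(self):
        geom = small_geometry(4)
        frames = np.full((10, 4, 4), 100.0)
        frames[5:] = 110.0
        mv = Movie(frames=frames, frame_rate_hz=20.0, geometry=geom)
        out = dff_movie(mv, stimulus_onset_s=0.25)
        assert np.allclose(out.frames[5:], 10.0)
        assert np.allclose(out.frames[:5], 0.0)

    def test_static_movie_zero(self):
        geom = small_geometry(4)
        mv = Movie(frames=np.full((10, 4, 4), 7.0), frame_rate_hz=20.0,
                   geometry=geom)
        assert np.allclose(dff_movie(mv, 0.3).frames, 0.0)

    def test_pa_disc_supra_zero_pixels(self, geometry):
        cfg = SimConfig(state="PA", duration_s=6, seed=0, noise_sd=0.0,
                        pa_fluct_amplitude=0.0, frame_rate_hz=20.0)
        gt = GroundTruth(config=cfg, geometry=geometry)
        gt.stim_onset_s = np.array([2.0])
        gt.stim_modality = np.array(["visual"], dtype=object)
        mv = render_widefield(gt, geometry, cfg)
        out = dff_movie(mv, 2.0)
        active = out.frames.max(axis=0) > 1e-9
        expected = geometry.disc_mask(*geometry.site_position("V1"), 6.9)
        assert np.array_equal(active, expected)


class TestTriggeredAverage:
    def test_identical_segments_average(self):
        geom = small_geometry(4)
        rng = np.random.default_rng(0)
        base = rng.uniform(50, 100, size=(40, 4, 4))
        frames = np.concatenate([base] * 3, axis=0)
        mv = Movie(frames=frames, frame_rate_hz=20.0, geometry=geom)
        onsets = np.array([0.5, 2.5, 4.5])  # same phase in each repeat
        sta = stimulus_triggered_average(mv, onsets, window_s=(-0.25, 1.0))
        single = stimulus_triggered_average(mv, onsets[:1], window_s=(-0.25, 1.0))
        assert sta.n_stimuli == 3
        assert np.allclose(sta.frames, single.frames)

    def test_noise_shrinks_as_sqrt_n(self):
        geom = small_geometry(8)
        rng = np.random.default_rng(1)
        frames = 100.0 + rng.standard_normal((4000, 8, 8))
        mv = Movie(frames=frames, frame_rate_hz=20.0, geometry=geom)
        on_few = np.arange(2.0, 12.0, 2.0)
        on_many = np.arange(2.0, 162.0, 2.0)
        sd_few = stimulus_triggered_average(mv, on_few, (-0.5, 1.0)).frames.std()
        sd_many = stimulus_triggered_average(mv, on_many, (-0.5, 1.0)).frames.std()
        ratio = sd_few / sd_many
        expected = np.sqrt(len(on_many) / len(on_few))
        assert abs(ratio - expected) / expected < 0.25

    def test_no_usable_stimulus_raises(self):
        geom = small_geometry(4)
        mv = Movie(frames=np.ones((10, 4, 4)), frame_rate_hz=20.0, geometry=geom)
        with pytest.raises(ValueError):
            stimulus_triggered_average(mv, np.array([100.0]), (-0.5, 1.0))


class TestOnsetLatencyMap:
    def _step_sta(self, step_frame=4, rate=20.0):
        rng = np.random.default_rng(0)
        frames = 0.01 * rng.standard_normal((60, 8, 8))
        frames[20 + step_frame:, :, :] += 5.0
        return make_sta(frames, rate=rate, geometry=small_geometry(8))

    def test_step_crossing_frame_quantized(self):
        # step above threshold at frame +4 at 20 Hz -> 200 ms
        sta = self._step_sta()
        lm = onset_latency_map(sta, interpolate=False)
        assert np.allclose(lm.latency_s, 0.200)

    def test_interpolation_stays_within_frame(self):
        sta = self._step_sta()
        lm = onset_latency_map(sta, interpolate=True)
        assert np.all(lm.latency_s <= 0.200 + 1e-9)
        assert np.all(lm.latency_s > 0.150)

    def test_flat_pixel_missing(self):
        # responding pixels get latencies; flat pixels are missing
        frames = np.zeros((60, 8, 8))
        frames[:, :4, :] = 0.01 * (-1.0) ** np.arange(60)[:, None, None]
        frames[24:, :4, :] += 5.0
        sta = make_sta(frames, geometry=small_geometry(8))
        lm = onset_latency_map(sta)
        assert np.isfinite(lm.latency_s[:4]).all()
        assert np.isnan(lm.latency_s[4:]).all()

    def test_noiseless_ramp_from_generator(self, geometry):
        # a rendered plane wave yields an affine latency ramp along AP
        cfg = SimConfig(duration_s=14, seed=0, frame_rate_hz=40.0,
                        noise_sd=0.002)
        gt = GroundTruth(
            config=cfg, geometry=geometry,
            event_time_s=np.array([6.0]),
            origin_ap_mm=np.array([-0.2]), origin_ml_mm=np.array([2.5]),
            speed_mm_s=np.array([30.0]), direction_rad=np.array([np.pi]),
            evoked=np.zeros(1, bool), merged=np.zeros(1, bool),
            stim_index=np.full(1, -1), event_modality=np.array([None]))
        mv = render_widefield(gt, geometry, cfg)
        sta = stimulus_triggered_average(mv, np.array([6.0]), (-1.0, 1.0))
        lm = onset_latency_map(sta)
        row_lat = np.nanmean(lm.latency_s, axis=1)
        rows = np.arange(len(row_lat))
        slope = np.polyfit(rows, row_lat, 1)[0]  # s per row
        # 0.1 mm per row at 30 mm/s -> 3.33 ms per row
        assert abs(slope - 0.1 / 30.0) / (0.1 / 30.0) < 0.15


class TestResponseArea:
    def test_pixel_count_arithmetic(self):
        # 400 active pixels at 0.1 mm pitch -> 4.0 mm^2
        frames = 0.01 * (-1.0) ** np.arange(80)[:, None, None] \
            * np.ones((80, 48, 48))
        mask = np.zeros((48, 48), bool)
        mask.flat[:400] = True
        frames[40:, mask] += 5.0
        sta = make_sta(frames, geometry=small_geometry(48))
        area = response_area(sta, window_s=(0.5, 1.5))
        assert np.isclose(area, 4.0)

    def test_noise_only_area_bounded_by_threshold_tail(self):
        rng = np.random.default_rng(3)
        frames = 0.01 * rng.standard_normal((80, 48, 48))
        sta = make_sta(frames, geometry=small_geometry(48))
        area = response_area(sta, window_s=(1.0, 2.0))
        fov = 48 * 48 * 0.01
        # 3.5-SD one-sided tail ~2.3e-4; allow estimation slack
        assert area < 0.01 * fov

    def test_monotone_in_true_footprint(self):
        rng = np.random.default_rng(1)
        areas = []
        for n_active in (100, 400, 900):
            frames = 0.001 * rng.standard_normal((80, 48, 48))
            mask = np.zeros((48, 48), bool)
            mask.flat[:n_active] = True
            frames[40:, mask] += 5.0
            sta = make_sta(frames, geometry=small_geometry(48))
            areas.append(response_area(sta, window_s=(0.5, 1.5)))
        assert areas[0] < areas[1] < areas[2]

    def test_cumulative_mode_at_least_simultaneous(self):
        rng = np.random.default_rng(2)
        frames = 0.01 * rng.standard_normal((80, 16, 16))
        frames[30:50, :8] += 5.0
        frames[50:70, 8:] += 5.0
        sta = make_sta(frames, geometry=small_geometry(16))
        sim = response_area(sta, window_s=(0.0, 2.0), mode="simultaneous")
        cum = response_area(sta, window_s=(0.0, 2.0), mode="cumulative")
        assert cum >= sim


class TestVelocityField:
    def _ramp_map(self, speed=30.0, n=32, pitch=0.1):
        geom = small_geometry(n, pitch)
        ap, _ = geom.pixel_grid()
        lat = (-ap) / speed  # wave travelling posteriorly (direction pi)
        return LatencyMap(latency_s=lat, geometry=geom), geom

    def test_exact_on_synthetic_ramp(self):
        lm, geom = self._ramp_map(speed=30.0)
        vf = velocity_field(lm, smooth_px=1)
        _, spd = vf.vectors()
        assert np.allclose(spd, 30.0, rtol=1e-9)
        ms, md = mean_velocity_vector(vf)
        assert np.isclose(ms, 30.0)
        assert np.isclose(abs(md), np.pi)  # posterior

    def test_constant_map_all_invalid(self):
        geom = small_geometry(16)
        lm = LatencyMap(latency_s=np.full((16, 16), 0.5), geometry=geom)
        with pytest.raises(DegenerateMapError):
            velocity_field(lm, smooth_px=1)

    def test_rotation_equivariance(self):
        # rotating the latency map 90 deg rotates direction, keeps speed
        lm, geom = self._ramp_map(speed=25.0)
        vf = velocity_field(lm, smooth_px=1)
        lm_rot = LatencyMap(latency_s=np.rot90(lm.latency_s).copy(),
                            geometry=geom)
        vf_rot = velocity_field(lm_rot, smooth_px=1)
        s0, d0 = mean_velocity_vector(vf)
        s1, d1 = mean_velocity_vector(vf_rot)
        assert np.isclose(s0, s1, rtol=1e-6)
        diff = np.angle(np.exp(1j * (d1 - d0)))
        assert np.isclose(abs(diff), np.pi / 2, atol=1e-6)

    def test_mean_vector_uniform_and_cancelling(self):
        geom = small_geometry(4)
        ones = np.ones((4, 4))
        vf = VelocityField(speed_mm_s=30 * ones, direction_rad=0 * ones,
                           valid=ones.astype(bool), geometry=geom)
        assert mean_velocity_vector(vf) == (30.0, 0.0)
        direction = np.where(np.arange(16).reshape(4, 4) % 2 == 0, 0.0, np.pi)
        vf2 = VelocityField(speed_mm_s=30 * ones, direction_rad=direction,
                            valid=ones.astype(bool), geometry=geom)
        s, _ = mean_velocity_vector(vf2)
        assert s < 1e-9

    def test_no_valid_pixels_raises(self):
        geom = small_geometry(4)
        vf = VelocityField(speed_mm_s=np.ones((4, 4)),
                           direction_rad=np.zeros((4, 4)),
                           valid=np.zeros((4, 4), bool), geometry=geom)
        with pytest.raises(DegenerateFieldError):
            mean_velocity_vector(vf)

    def test_recovers_default_speed_from_movies(self, geometry):
        # full pipeline on generator waves at default speed, 10% tolerance
        speeds = []
        for seed in (100, 101, 102):
            cfg = SimConfig(duration_s=210, seed=seed, frame_rate_hz=40.0)
            gt = generate_spontaneous_events(cfg, geometry)
            stim = generate_stimulus_train("visual", n_stimuli=20,
                                           isi_s=10.0, start_s=5.0)
            g2 = __import__("cortexwave").apply_stimulus_gating(stim, gt, cfg)
            mv = render_widefield(g2, geometry, cfg)
            sta = stimulus_triggered_average(mv, stim, window_s=(-1.0, 3.0))
            vf = velocity_field(onset_latency_map(sta), smooth_mean_px=7)
            _, spd = vf.vectors()
            speeds.append(spd)
            _, md = mean_velocity_vector(vf)
            # visual waves propagate anterolaterally: within 30 deg of anterior
            assert abs(np.degrees(md)) < 60.0
        pooled = np.median(np.concatenate(speeds))
        assert abs(pooled - 30.5) / 30.5 < 0.10


class TestActivationDistribution:
    def _movie_from_trace(self, trace, n=8):
        geom = small_geometry(n)
        frames = np.tile(trace[:, None, None], (1, n, n))
        return Movie(frames=frames, frame_rate_hz=20.0, geometry=geom)

    def test_square_wave_mass_at_extremes(self):
        trace = np.tile(np.repeat([0.0, 1.0], 20), 20)
        hist = activation_distribution(self._movie_from_trace(trace))
        assert np.isclose(hist.mass[0], 0.5)
        assert np.isclose(hist.mass[-1], 0.5)
        assert np.isclose(hist.mass.sum(), 1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        trace = rng.uniform(0, 1, 400)
        h1 = activation_distribution(self._movie_from_trace(trace))
        h2 = activation_distribution(self._movie_from_trace(3.7 * trace + 11.0))
        assert np.allclose(h1.mass, h2.mass)

    def test_constant_trace_degenerate(self):
        with pytest.raises(DegenerateNormalizationError):
            activation_distribution(self._movie_from_trace(np.full(400, 2.0)))

    def test_swa_mass_concentrates_low(self, geometry):
        cfg = SimConfig(duration_s=120, seed=0, frame_rate_hz=20.0)
        gt = generate_spontaneous_events(cfg, geometry)
        mv = render_widefield(gt, geometry, cfg)
        hist = activation_distribution(mv)
        assert int(np.argmax(hist.mass)) == 0


class TestPermutationComparison:
    def test_identical_groups_p_one(self):
        h = np.tile(np.linspace(0.0, 0.1, 20) / np.linspace(0, 0.1, 20).sum(),
                    (3, 1))
        p_raw, p_adj = compare_distributions_permutation(h, h.copy(),
                                                         n_perm=500, seed=0)
        assert np.all(p_adj == 1.0)

    def test_p_value_floor(self):
        rng = np.random.default_rng(0)
        a = rng.dirichlet(np.ones(20), size=5)
        b = rng.dirichlet(np.ones(20) * 10, size=5)
        n_perm = 500
        p_raw, _ = compare_distributions_permutation(a, b, n_perm=n_perm, seed=0)
        assert np.all(p_raw >= 1.0 / (n_perm + 1))

    def test_swa_vs_pa_extreme_bins_significant(self, geometry):
        hists_swa, hists_pa = [], []
        for seed in range(7):
            cfg = SimConfig(duration_s=120, seed=seed, frame_rate_hz=20.0)
            gt = generate_spontaneous_events(cfg, geometry)
            hists_swa.append(activation_distribution(
                render_widefield(gt, geometry, cfg)))
            cfgp = SimConfig(state="PA", duration_s=120, seed=seed,
                             frame_rate_hz=20.0)
            hists_pa.append(activation_distribution(
                render_widefield(GroundTruth(config=cfgp, geometry=geometry),
                                 geometry, cfgp)))
        _, p_adj = compare_distributions_permutation(hists_swa, hists_pa,
                                                     n_perm=4000, seed=1)
        # silent-period bin dominates SWA, mid-activation bins dominate PA
        assert p_adj[0] < 0.05
        assert (p_adj[8:12] < 0.05).any()
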