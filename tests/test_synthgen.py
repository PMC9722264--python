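"""Generator tests: stimulus trains, spontaneous waves, gating, rendering."""

import numpy as np
import pytest

from cortexwave import (
    FieldGeometry,
    GroundTruth,
    SimConfig,
    apply_stimulus_gating,
    generate_spontaneous_events,
    generate_stimulus_train,
    render_lfp,
    render_photometry,
    render_widefield,
)
from cortexwave.geometry import unit_vector
from cortexwave.synthgen import calcium_kernel, kernel_peak_delay


def event_site_onsets(gt, geometry, site):
    """Per-event (unsorted) onsets at a site, aligned with event arrays."""
    p = geometry.site_position(site)
    u = unit_vector(gt.direction_rad)
    o = np.stack([gt.origin_ap_mm, gt.origin_ml_mm], axis=1)
    return gt.event_time_s + ((p - o) * u).sum(axis=1) / gt.speed_mm_s


class TestStimulusTrain:
    def test_regular_spacing(self):
        st = generate_stimulus_train("somatosensory", n_stimuli=3, isi_s=10.0)
        assert np.allclose(st.onsets_s, [0.0, 10.0, 20.0])

    def test_block_paradigm_pulse_count(self):
        # a 3 Hz x 4 s train contains 12 pulses
        st = generate_stimulus_train("somatosensory", n_stimuli=1,
                                     train_spec=(3.0, 4.0))
        assert len(st) == 12
        assert np.allclose(np.diff(st.onsets_s), 1 / 3)

    def test_jittered_isi_deterministic_and_bounded(self):
        a = generate_stimulus_train("visual", n_stimuli=100, isi_s=(2, 4), seed=5)
        b = generate_stimulus_train("visual", n_stimuli=100, isi_s=(2, 4), seed=5)
        assert np.array_equal(a.onsets_s, b.onsets_s)
        gaps = np.diff(a.onsets_s)
        assert gaps.min() >= 2.0 and gaps.max() <= 4.0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_stimulus_train("visual", n_stimuli=2, isi_s=-1.0)
        with pytest.raises(ValueError):
            generate_stimulus_train("visual", train_spec=(0.0, 4.0))
        with pytest.raises(ValueError):
            generate_stimulus_train("auditory")


class TestSpontaneousEvents:
    def test_hard_refractory_per_site(self, swa_ground_truth, geometry):
        tau_r = swa_ground_truth.config.refractory_s
        for site in ("S1", "V1"):
            onsets = swa_ground_truth.site_onsets(site)
            assert np.diff(onsets).min() >= tau_r

    def test_anterior_origin_forces_s1_lead(self, geometry):
        cfg = SimConfig(duration_s=400, seed=1, anterior_origin_prob=1.0)
        gt = generate_spontaneous_events(cfg, geometry)
        s1 = event_site_onsets(gt, geometry, "S1")
        v1 = event_site_onsets(gt, geometry, "V1")
        assert np.all(s1 < v1)

    def test_s1_leading_fraction_near_default(self, geometry):
        # anterior-origin probability 0.6 -> ~60% of waves reach S1 first
        lead = []
        n_tot = 0
        for seed in range(10):
            cfg = SimConfig(duration_s=600, seed=seed)
            gt = generate_spontaneous_events(cfg, geometry)
            s1 = event_site_onsets(gt, geometry, "S1")
            v1 = event_site_onsets(gt, geometry, "V1")
            lead.append((s1 < v1).sum())
            n_tot += gt.n_events
        frac = sum(lead) / n_tot
        assert abs(frac - 0.6) < 3 * np.sqrt(0.6 * 0.4 / n_tot)

    def test_geometry_consistency(self, swa_ground_truth, geometry):
        # V1 onset - S1 onset equals the signed projected path / speed
        gt = swa_ground_truth
        s1 = event_site_onsets(gt, geometry, "S1")
        v1 = event_site_onsets(gt, geometry, "V1")
        u = unit_vector(gt.direction_rad)
        rel = geometry.site_position("V1") - geometry.site_position("S1")
        expected = (rel * u).sum(axis=1) / gt.speed_mm_s
        assert np.allclose(v1 - s1, expected, atol=1e-12)

    def test_too_short_duration_warns(self, geometry):
        cfg = SimConfig(duration_s=1e-3, seed=0)
        with pytest.warns(UserWarning):
            gt = generate_spontaneous_events(cfg, geometry)
        assert gt.n_events == 0 and gt.warning is not None

    def test_requires_swa_state(self, geometry):
        with pytest.raises(ValueError):
            generate_spontaneous_events(SimConfig(state="PA"), geometry)


class TestStimulusGating:
    def test_certain_evocation_outside_refractory(self, geometry):
        cfg = SimConfig(duration_s=400, seed=2, p_evoke=1.0)
        gt = generate_spontaneous_events(cfg, geometry)
        stim = generate_stimulus_train("somatosensory", n_stimuli=30,
                                       isi_s=12.0, start_s=8.0)
        out = apply_stimulus_gating(stim, gt, cfg)
        outside = ~out.stim_refractory
        assert out.stim_success[outside].all()

    def test_hard_gate_inside_refractory(self, geometry):
        cfg = SimConfig(duration_s=400, seed=2, p_refractory=0.0)
        gt = generate_spontaneous_events(cfg, geometry)
        stim = generate_stimulus_train("somatosensory", n_stimuli=30,
                                       isi_s=12.0, start_s=8.0)
        out = apply_stimulus_gating(stim, gt, cfg)
        assert not out.stim_success[out.stim_refractory].any()

    def test_success_rate_near_default(self, geometry):
        succ = fail = 0
        for seed in range(5):
            cfg = SimConfig(duration_s=1010, seed=seed)
            gt = generate_spontaneous_events(cfg, geometry)
            stim = generate_stimulus_train("somatosensory", n_stimuli=100,
                                           isi_s=10.0, start_s=8.0)
            out = apply_stimulus_gating(stim, gt, cfg)
            outside = ~out.stim_refractory
            succ += out.stim_success[outside].sum()
            fail += (~out.stim_success[outside]).sum()
        n = succ + fail
        assert abs(succ / n - 0.9) < 3 * np.sqrt(0.9 * 0.1 / n)

    def test_every_success_has_matching_event(self, geometry):
        cfg = SimConfig(duration_s=600, seed=4)
        gt = generate_spontaneous_events(cfg, geometry)
        stim = generate_stimulus_train("visual", n_stimuli=50,
                                       isi_s=10.0, start_s=8.0)
        out = apply_stimulus_gating(stim, gt, cfg)
        onsets = out.site_onsets("V1")
        for k in np.flatnonzero(out.stim_success):
            s = out.stim_onset_s[k]
            lat = out.stim_latency_ms[k] / 1000.0
            assert np.isfinite(lat)
            assert np.any(np.abs(onsets - (s + lat)) < 1e-9)


class TestRenderPhotometry:
    def test_noiseless_peak_at_kernel_peak(self, geometry):
        cfg = SimConfig(duration_s=30, seed=0, noise_sd=0.0)
        gt = GroundTruth(
            config=cfg, geometry=geometry,
            event_time_s=np.array([10.0]),
            origin_ap_mm=np.array([geometry.site_position("S1")[0]]),
            origin_ml_mm=np.array([geometry.site_position("S1")[1]]),
            speed_mm_s=np.array([30.5]), direction_rad=np.array([np.pi]),
            evoked=np.zeros(1, bool), merged=np.zeros(1, bool),
            stim_index=np.full(1, -1), event_modality=np.array([None]))
        tr = render_photometry(gt, geometry, cfg)["S1"]
        t_peak = np.argmax(tr.samples) / tr.fs_hz
        expected = 10.0 + kernel_peak_delay(cfg.tau_rise_s, cfg.tau_decay_s)
        assert abs(t_peak - expected) < 2 / tr.fs_hz

    def test_silent_periods_dominate(self, swa_traces, swa_ground_truth):
        # SWA is bimodal: most samples sit near baseline
        from helpers import preprocess
        dff = preprocess(swa_traces["S1"])
        cfg = swa_ground_truth.config
        frac = np.mean(np.abs(dff.samples) < 0.05 * cfg.amplitude)
        assert frac > 0.5

    def test_bit_identical_under_seed(self, swa_ground_truth, geometry, swa_config):
        a = render_photometry(swa_ground_truth, geometry, swa_config)["S1"]
        b = render_photometry(swa_ground_truth, geometry, swa_config)["S1"]
        assert np.array_equal(a.samples, b.samples)


class TestRenderWidefield:
    def test_plane_wave_timing_across_field(self, geometry):
        # 3 mm along AP at 30 mm/s -> 100 ms activation difference
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
        col = geometry.site_pixel("S1")[1]
        r0, r1 = 5, 35  # 30 rows = 3.0 mm along AP
        t = mv.frame_times()
        act0 = t[np.argmax(mv.frames[:, r0, col] > 1.5)]
        act1 = t[np.argmax(mv.frames[:, r1, col] > 1.5)]
        assert abs((act1 - act0) - 0.100) <= 1.5 / cfg.frame_rate_hz

    def test_pa_disc_pixel_count(self, geometry):
        # 6.9 mm^2 at 0.1 mm pitch -> exactly 690 supra-baseline pixels
        cfg = SimConfig(state="PA", duration_s=6, seed=0, noise_sd=0.0,
                        pa_fluct_amplitude=0.0, frame_rate_hz=20.0)
        gt = GroundTruth(config=cfg, geometry=geometry)
        gt.stim_onset_s = np.array([2.0])
        gt.stim_modality = np.array(["visual"], dtype=object)
        mv = render_widefield(gt, geometry, cfg)
        active = (mv.frames.max(axis=0) > 1.0 + 1e-9)
        assert active.sum() == 690

    def test_swa_wave_spans_field(self, geometry):
        cfg = SimConfig(duration_s=20, seed=1, noise_sd=0.0,
                        frame_rate_hz=20.0)
        gt = generate_spontaneous_events(
            SimConfig(duration_s=20, seed=1), geometry)
        gt.config = cfg
        mv = render_widefield(gt, geometry, cfg)
        if gt.n_events:
            assert (mv.frames.max(axis=0) > 1.5).all()

    def test_bit_identical_under_seed(self, geometry):
        cfg = SimConfig(duration_s=30, seed=9, frame_rate_hz=20.0)
        gt = generate_spontaneous_events(cfg, geometry)
        a = render_widefield(gt, geometry, cfg)
        b = render_widefield(gt, geometry, cfg)
        assert np.array_equal(a.frames, b.frames)


class TestRenderLFP:
    def test_silence_vs_event_power_gating(self, geometry):
        cfg = SimConfig(duration_s=300, seed=4)
        gt = generate_spontaneous_events(cfg, geometry)
        lfp = render_lfp(gt, cfg, site="V1")
        x, fs = lfp.samples, lfp.fs_hz
        on = gt.site_onsets("V1")
        ev = np.zeros(len(x), bool)
        sil = np.ones(len(x), bool)
        for o in on:
            ev[int(o * fs):int((o + 0.3) * fs)] = True
            sil[int((o - 0.5) * fs):int((o + 2.5) * fs)] = False
        assert x[sil].std() <= 0.1 * x[ev].std()

    def test_pa_narrowband_peak(self, geometry):
        from cortexwave import multitaper_spectrogram
        cfg = SimConfig(state="PA", duration_s=60, seed=4)
        lfp = render_lfp(GroundTruth(config=cfg, geometry=geometry), cfg)
        sg = multitaper_spectrogram(lfp.samples, lfp.fs_hz, window_s=1.0,
                                    tw=2, k=3, fpass=(1, 40))
        assert abs(sg.peak_frequency() - cfg.pa_band_hz) <= 2.0

    def test_evoked_gamma_packet(self, geometry):
        from cortexwave.spectral import _bandpass
        cfg = SimConfig(state="PA", duration_s=40, seed=2)
        gt = GroundTruth(config=cfg, geometry=geometry)
        stim = generate_stimulus_train("visual", n_stimuli=3, isi_s=10.0,
                                       start_s=5.0)
        gt.stim_onset_s = stim.onsets_s
        gt.stim_modality = np.array(["visual"] * 3, dtype=object)
        lfp = render_lfp(gt, cfg, site="V1")
        g = _bandpass(lfp.samples, lfp.fs_hz, (35, 200))
        fs = lfp.fs_hz
        for s in stim.onsets_s:
            post = g[int(s * fs):int((s + 0.1) * fs)]
            pre = g[int((s - 0.1) * fs):int(s * fs)]
            assert (post**2).mean() > (pre**2).mean()
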