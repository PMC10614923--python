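"""Simulator contracts: determinism, breath statistics, the two intonation
mechanisms, register jumps, audio rendering, and EMG ground truth."""
import numpy as np
import pytest
from scipy.signal import hilbert

import intonate as it
from intonate.sim import _TEMPLATES


def _phonation_r(rec):
    m = np.isfinite(rec["f_khz"])
    return np.corrcoef(rec["f_khz"][m], rec["Q"][m])[0, 1]


class TestBreathTrain:
    def test_fixed_seed_is_byte_identical_and_seeds_differ(self):
        cfg = it.SimConfig(duration_s=10.0, seed=4)
        t1, _ = it.generate_breath_train(cfg)
        t2, _ = it.generate_breath_train(it.SimConfig(duration_s=10.0, seed=4))
        t3, _ = it.generate_breath_train(it.SimConfig(duration_s=10.0, seed=5))
        assert np.array_equal(t1.samples, t2.samples)
        assert not np.array_equal(t1.samples, t3.samples)

    def test_periodic_quiet_train_has_identical_cycles(self):
        # fixed Ti = Te = 67 ms, no jitter or noise: a strictly periodic train
        cfg = it.SimConfig(duration_s=40.2, vocal_fraction=0.0,
                           sniff_bout_prob=0.0, airflow_noise=0.0,
                           flow_wiggle=0.0, amp_jitter=0.0, breath_jitter=0.0,
                           ti_s=0.067, te_s=0.067, emg_lag_ms=0.0, seed=0)
        _, truth = it.generate_breath_train(cfg)
        period = truth.breaths.Ti.iloc[0] + truth.breaths.Te.iloc[0]
        assert len(truth.breaths) == int(cfg.duration_s / period)
        assert truth.breaths.Ti.nunique() == 1
        assert truth.breaths.Te.nunique() == 1

    def test_mean_instantaneous_frequency_recovers_breath_rate(self):
        cfg = it.SimConfig(duration_s=120.0, vocal_fraction=0.0,
                           sniff_bout_prob=0.0, seed=2)
        _, truth = it.generate_breath_train(cfg)
        assert truth.breaths.f_inst.mean() == pytest.approx(7.5, rel=0.02)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            it.generate_breath_train(it.SimConfig(duration_s=0.05))

    def test_ground_truth_conservation_laws(self, default_session):
        # Q = P * a**beta and v = Q / a hold sample-wise
        _, _, truth = default_session
        s = truth.signals
        m = s["a"] > 0
        assert np.allclose(s["Q"][m], s["P"][m] * s["a"][m] ** 0.5, atol=1e-12)
        assert np.allclose(s["v"][m], s["Q"][m] / s["a"][m], atol=1e-12)

    def test_syllables_lie_within_their_breath_expiration(self, default_session):
        _, _, truth = default_session
        for _, syl in truth.syllables.iterrows():
            b = truth.breaths.iloc[int(syl.breath_index)]
            assert b.exp_onset - 1e-9 <= syl.onset
            assert syl.offset <= b.end + 1e-9

    def test_phonation_has_positive_flow_in_band(self, default_session):
        _, _, truth = default_session
        s = truth.signals
        m = np.isfinite(s["f"])
        assert np.all(s["Q"][m] > 0)
        assert np.all((s["f"][m] >= 40.0) & (s["f"][m] <= 120.0))


class TestVocalBreath:
    def test_model1_pitch_is_exactly_affine_in_flow(self):
        cfg = it.SimConfig(airflow_noise=0.0, pitch_jitter_khz=0.0, seed=3)
        for ty in ("down fm", "complex", "chevron"):
            _, _, rec = it.generate_vocal_breath(ty, "model1", cfg)
            assert _phonation_r(rec) == pytest.approx(1.0, abs=1e-9)

    def test_model2_strongly_anticorrelated(self):
        # f is a convex monotone (not affine) function of Q under the
        # power-law convention, so clean r approaches but never reaches -1
        for seed in range(10):
            cfg = it.SimConfig(airflow_noise=0.0, pitch_jitter_khz=0.0,
                               aperture_wiggle=0.0, flow_wiggle=0.0, seed=seed)
            _, _, rec = it.generate_vocal_breath("up fm", "model2", cfg)
            assert _phonation_r(rec) <= -0.97

    def test_invalid_mechanism_pairing_rejected(self):
        cfg = it.SimConfig()
        with pytest.raises(ValueError, match="mechanism"):
            it.generate_vocal_breath("up fm", "model1", cfg)
        with pytest.raises(ValueError, match="mechanism"):
            it.generate_vocal_breath("down fm", "model2", cfg)

    def test_register_jumps_move_pitch_not_flow(self):
        # register steps exceed the jump threshold in f with Q continuous
        cfg = it.SimConfig(airflow_noise=0.0, pitch_jitter_khz=0.0, seed=8)
        for ty in ("step down", "multi"):
            _, _, rec = it.generate_vocal_breath(ty, "model1", cfg)
            fs = cfg.airflow_rate_hz
            q = rec["Q"]
            dq_typ = np.median(np.abs(np.diff(q)))
            assert len(rec["jumps"]) == len(_TEMPLATES[ty]["jumps"])
            for j in rec["jumps"]:
                assert j["kind"] == "register"
                assert abs(j["size_khz"]) > 10.0
                k = int(round(j["time"] * fs))
                assert abs(q[k] - q[k - 1]) < 20 * dq_typ + 1e-6

    def test_mini_breath_count_matches_cycles_per_expiration(self):
        cfg = it.SimConfig(seed=0)
        counts = []
        for _, _, rec in it.simulate_usv_dataset(500, ["complex"], "model1",
                                                 cfg, seed=31):
            counts.append(len(rec["mini_times"]))
        assert np.mean(counts) == pytest.approx(1.5, abs=0.1)


class TestAudio:
    def test_pure_tone_spectrogram_peak(self):
        cfg = it.SimConfig()
        t = np.arange(0, 0.05, 1e-3)
        pc = it.PitchContour(times=t, f_peak=np.full(t.size, 75e3),
                             peak_power=np.ones(t.size),
                             valid=np.ones(t.size, bool))
        w = it.synthesize_audio(pc, cfg, duration_s=0.05)
        spec = it.multitaper_spectrogram(w, cfg.audio_rate_hz)
        binw = spec.freqs[1] - spec.freqs[0]
        active = spec.power.max(axis=1) > 0.25 * spec.power.max()
        peaks = spec.freqs[np.argmax(spec.power[active], axis=1)]
        assert np.all(np.abs(peaks - 75e3) <= binw)

    def test_empty_contour_is_silence_of_requested_length(self):
        cfg = it.SimConfig()
        pc = it.PitchContour(times=np.array([0.0, 0.001]),
                             f_peak=np.array([np.nan, np.nan]),
                             peak_power=np.zeros(2), valid=np.zeros(2, bool))
        w = it.synthesize_audio(pc, cfg, duration_s=0.02)
        assert w.size == int(0.02 * cfg.audio_rate_hz)
        assert np.all(w == 0)

    def test_chirp_matches_analytic_instantaneous_frequency(self):
        # phase-derivative oracle on the rendered FM waveform
        cfg = it.SimConfig()
        fs = cfg.audio_rate_hz
        t = np.arange(0, 0.05, 1e-3)
        fk = 60e3 + 20e3 * t / t[-1]
        pc = it.PitchContour(times=t, f_peak=fk, peak_power=np.ones(t.size),
                             valid=np.ones(t.size, bool))
        w = it.synthesize_audio(pc, cfg, duration_s=0.05)
        phase = np.unwrap(np.angle(hilbert(w)))
        f_inst = np.diff(phase) / (2 * np.pi) * fs
        tt = np.arange(1, w.size) / fs
        mid = (tt > 0.01) & (tt < 0.04)
        f_true = np.interp(tt, t, fk)
        assert np.median(np.abs(f_inst[mid] - f_true[mid]) / f_true[mid]) < 0.01

    def test_contour_above_nyquist_rejected(self):
        cfg = it.SimConfig(audio_rate_hz=100_000.0)
        t = np.arange(0, 0.01, 1e-3)
        pc = it.PitchContour(times=t, f_peak=np.full(t.size, 75e3),
                             peak_power=np.ones(t.size),
                             valid=np.ones(t.size, bool))
        with pytest.raises(ValueError, match="Nyquist"):
            it.synthesize_audio(pc, cfg, duration_s=0.01)


class TestEmgSynthesis:
    def test_laryngeal_truth_peaks_at_phi_of_diaphragm_interval(self):
        mix = {t: 0.0 for t in it.SYLLABLE_TYPES}
        mix["complex"] = 1.0
        cfg = it.SimConfig(duration_s=20.0, vocal_fraction=0.8,
                           syllable_mix=mix, sniff_bout_prob=0.0, seed=6)
        _, truth = it.generate_breath_train(cfg)
        it.synthesize_emg(truth, cfg)
        dia = np.sort(truth.emg_bursts.query(
            "channel == 'diaphragm'").peak_time.to_numpy())
        for lp in truth.emg_bursts.query("channel == 'laryngeal'").peak_time:
            k = np.searchsorted(dia, lp) - 1
            if 0 <= k < dia.size - 1:
                phase = (lp - dia[k]) / (dia[k + 1] - dia[k])
                assert phase == pytest.approx(0.69, abs=1e-9)

    def test_ecg_spike_count_is_rate_times_duration(self):
        cfg = it.SimConfig(duration_s=10.0, ecg_rate_hz=10.0, seed=1)
        _, truth = it.generate_breath_train(cfg)
        it.synthesize_emg(truth, cfg)
        assert len(truth.ecg_times) == 100

    def test_quiet_diaphragm_peaks_only_in_inspirations(self):
        cfg = it.SimConfig(duration_s=10.0, vocal_fraction=0.0,
                           sniff_bout_prob=0.0, ecg_rate_hz=0.0,
                           emg_noise=0.0, seed=2)
        _, truth = it.generate_breath_train(cfg)
        dia, _ = it.synthesize_emg(truth, cfg)
        env = it.rectify_integrate(dia)
        lag = cfg.emg_lag_ms / 1000.0
        for b in it.detect_bursts(env, channel="diaphragm"):
            row = truth.breaths[
                (truth.breaths.insp_onset - lag <= b.peak_time + 0.005)
                & (truth.breaths.exp_onset - lag >= b.peak_time - 0.005)]
            assert len(row) == 1
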