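"""Airflow-pitch pairing, Pearson statistic, shuffle nulls, intonation calls."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import intonate as it
from conftest import oracle_pearson, events_from_dataset


def _contour(times, f_hz, valid=None):
    f = np.asarray(f_hz, float)
    valid = np.ones(f.size, bool) if valid is None else valid
    return it.PitchContour(times=np.asarray(times, float),
                           f_peak=np.where(valid, f, np.nan),
                           peak_power=valid.astype(float), valid=valid)


def _event(times, f_hz, valid=None):
    c = _contour(times, f_hz, valid)
    return it.UsvEvent(id=0, onset=float(times[0]),
                       offset=float(times[-1]) + 1e-6,
                       syllables=[(float(times[0]), float(times[-1]) + 1e-6)],
                       contour=c)


class TestAlignment:
    def test_bins_on_airflow_samples_interpolate_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        tr = it.AirflowTrace(samples=x, rate=1000.0)
        times = np.arange(10, 30) / 1000.0
        ev = _event(times, np.linspace(60e3, 80e3, 20))
        q, f = it.align_airflow_to_pitch(tr, ev.contour, ev)
        assert np.array_equal(q, x[10:30])

    def test_flat_zero_airflow_gives_zero_pairs(self):
        tr = it.AirflowTrace(samples=np.zeros(100), rate=1000.0)
        times = np.arange(10, 30) / 1000.0
        ev = _event(times, np.linspace(60e3, 80e3, 20))
        q, _ = it.align_airflow_to_pitch(tr, ev.contour, ev)
        assert np.all(q == 0)

    def test_too_few_valid_bins_yields_empty_pairing(self):
        tr = it.AirflowTrace(samples=np.ones(100), rate=1000.0)
        times = np.arange(10, 13) / 1000.0
        ev = _event(times, np.full(3, 70e3))
        q, f = it.align_airflow_to_pitch(tr, ev.contour, ev)
        assert q.size == 0 and f.size == 0

    def test_simulated_pairing_matches_ground_truth_flow(self):
        cfg = it.SimConfig(airflow_noise=0.0, seed=5)
        trace, contour, rec = it.generate_vocal_breath("complex", "model1", cfg)
        ev = _event(contour.times[contour.valid],
                    contour.f_peak[contour.valid])
        q, _ = it.align_airflow_to_pitch(trace, ev.contour, ev)
        truth_q = rec["Q"][np.isfinite(rec["f_khz"])]
        rms = np.sqrt(np.mean((q - truth_q) ** 2)) / np.sqrt(np.mean(truth_q ** 2))
        assert rms <= 0.01


class TestPearson:
    def test_affine_pairs_are_exactly_plus_minus_one(self):
        q = np.linspace(0.1, 1.0, 25)
        assert it.intonation_correlation((q, 2 * q + 1)) == \
            pytest.approx(1.0, abs=1e-12)
        assert it.intonation_correlation((q, -q)) == \
            pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_five_point_pairing(self):
        # Q = 1..5, f = (2,1,4,3,5): covariance 1.6, variances 2, 2 -> r = 0.8
        r = it.intonation_correlation((np.arange(1.0, 6.0),
                                       np.array([2.0, 1, 4, 3, 5])))
        assert r == pytest.approx(0.8, abs=1e-12)

    def test_degenerate_inputs_are_indeterminate_not_nan(self):
        assert it.intonation_correlation((np.ones(10), np.arange(10.0))) is None
        assert it.intonation_correlation((np.arange(10.0), np.ones(10))) is None
        assert it.intonation_correlation((np.arange(3.0), np.arange(3.0))) is None

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(5, 10), st.integers(0, 10_000))
    def test_matches_from_scratch_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        q = rng.standard_normal(n)
        f = rng.standard_normal(n)
        r = it.intonation_correlation((q, f))
        assert r == pytest.approx(oracle_pearson(q, f), abs=1e-12)

    def test_sign_flip_of_airflow_flips_r_exactly(self):
        rng = np.random.default_rng(3)
        q, f = rng.standard_normal(40), rng.standard_normal(40)
        assert it.intonation_correlation((-q, f)) == \
            pytest.approx(-it.intonation_correlation((q, f)), abs=1e-15)

    def test_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(4)
        q, f = rng.standard_normal(40), rng.standard_normal(40)
        r0 = it.intonation_correlation((q, f))
        assert it.intonation_correlation((3.2 * q + 11, 0.5 * f - 2)) == \
            pytest.approx(r0, abs=1e-12)


class TestShuffleNull:
    def _identical_pair(self):
        times = np.arange(20) / 1000.0
        f = np.linspace(60e3, 80e3, 20)
        x = np.linspace(1.0, 0.4, 30)
        tr = it.AirflowTrace(samples=x, rate=1000.0)
        events = []
        for i in range(2):
            ev = _event(times, f)
            ev.id = i
            events.append(ev)
        return events, [tr, tr]

    def test_identical_usvs_null_equals_observed(self):
        events, airs = self._identical_pair()
        obs = it.intonation_correlation(
            it.align_airflow_to_pitch(airs[0], events[0].contour, events[0]))
        null = it.build_shuffle_null(events, airs, n_perm=10, seed=0)
        assert np.allclose(null.r_values, obs, atol=1e-9)

    def test_fixed_seed_reproducible(self):
        cfg = it.SimConfig()
        ds = it.simulate_usv_dataset(10, ["complex"], "model1", cfg, seed=9)
        events, airs = events_from_dataset(ds)
        a = it.build_shuffle_null(events, airs, n_perm=20, seed=3)
        b = it.build_shuffle_null(events, airs, n_perm=20, seed=3)
        assert np.array_equal(a.r_values, b.r_values)

    def test_single_usv_or_zero_perms_rejected(self):
        events, airs = self._identical_pair()
        with pytest.raises(ValueError):
            it.build_shuffle_null(events[:1], airs[:1], n_perm=10)
        with pytest.raises(ValueError):
            it.build_shuffle_null(events, airs, n_perm=0)

    def test_null_nearly_centered_under_independence(self):
        cfg = it.SimConfig()
        ds = it.simulate_usv_dataset(150, ["complex"], "none", cfg, seed=40)
        events, airs = events_from_dataset(ds)
        null = it.build_shuffle_null(events, airs, n_perm=60, seed=8)
        assert abs(null.r_values.mean()) < 0.05


class TestCalls:
    def test_mixed_mechanism_is_intermediate(self):
        cfg = it.SimConfig()
        meds = {}
        for key, ty, mech, sd in (("m1", "down fm", "model1", 11),
                                  ("mix", "two step", "mixed", 12),
                                  ("m2", "up fm", "model2", 13)):
            events, airs = events_from_dataset(
                it.simulate_usv_dataset(40, [ty], mech, cfg, seed=sd))
            rs = [it.intonation_correlation(
                it.align_airflow_to_pitch(airs[i], events[i].contour,
                                          events[i]))
                for i in range(len(events))]
            meds[key] = np.median([r for r in rs if r is not None])
        assert meds["m2"] < meds["mix"] < meds["m1"]

    def test_pitch_jitter_degrades_correlation_monotonically(self):
        meds = []
        for jit in (0.5, 3.0, 8.0):
            cfg = it.SimConfig(pitch_jitter_khz=jit)
            events, airs = events_from_dataset(
                it.simulate_usv_dataset(40, ["complex"], "model1", cfg,
                                        seed=21))
            rs = [abs(it.intonation_correlation(
                it.align_airflow_to_pitch(airs[i], events[i].contour,
                                          events[i])))
                for i in range(len(events))]
            meds.append(np.median(rs))
        assert meds[0] > meds[1] > meds[2]

    def test_missing_null_gives_indeterminate_with_warning(self, caplog):
        res = [it.IntonationResult(usv_id=0, r=0.9, n_bins=30)]
        import logging
        with caplog.at_level(logging.WARNING):
            it.classify_intonation(res, {})
        assert res[0].call == "indeterminate"
        assert any("null" in rec.message for rec in caplog.records)

    def test_near_degenerate_contours_called_indeterminate(self):
        cfg = it.SimConfig(pitch_jitter_khz=0.0)
        events, airs = events_from_dataset(
            it.simulate_usv_dataset(6, ["flat"], "model1",
                                    it.SimConfig(pitch_jitter_khz=0.0,
                                                 aperture_wiggle=0.0,
                                                 flow_wiggle=0.0,
                                                 airflow_noise=0.0), seed=2))
        # constant-pitch flat syllables: zero pitch variance
        for ev, tr in zip(events, airs):
            ev.contour.f_peak[ev.contour.valid] = 70e3
            r = it.intonation_correlation(
                it.align_airflow_to_pitch(tr, ev.contour, ev))
            assert r is None
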