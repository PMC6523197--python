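"""Generator contracts: IPFM beat process, waveform synthesis, EDA model,
cohort structure and reproducibility."""

import numpy as np
import pytest

import taskphysio as tp
from oracles import dense_ipfm_beats, plain_lf_hf_ratio


def profile(**kw) -> tp.ConditionProfile:
    return tp.ConditionProfile(condition_label=kw.pop("condition_label", "BL"),
                               **kw)


class TestGenerateRR:
    def test_unmodulated_60bpm_gives_constant_1000ms(self):
        rr, _ = tp.generate_rr(profile(mean_hr=60, lf_mod_amp=0,
                                       hf_mod_amp=0), 240, seed=3)
        assert np.allclose(rr.rr_ms, 1000.0, atol=1e-6)
        assert rr.beat_times.size == 240

    def test_same_seed_bitwise_identical(self):
        p = profile(mean_hr=70, lf_mod_amp=0.08, hf_mod_amp=0.05)
        rr1, _ = tp.generate_rr(p, 240, seed=11)
        rr2, _ = tp.generate_rr(p, 240, seed=11)
        assert np.array_equal(rr1.beat_times, rr2.beat_times)
        rr3, _ = tp.generate_rr(p, 240, seed=12)
        assert not np.array_equal(rr1.beat_times, rr3.beat_times)

    def test_lf_hf_power_ratio_matches_dense_oracle(self):
        """amp ratio 2 -> power ratio ~4, as measured by both the package
        chain and an independent dense-grid IPFM + raw periodogram oracle."""
        p = profile(mean_hr=65, lf_mod_amp=0.1, hf_mod_amp=0.05)
        oracle = plain_lf_hf_ratio(
            dense_ipfm_beats(65, 0.1, 0.05, p.f_LF, p.f_HF, 240))
        rr, _ = tp.generate_rr(p, 240, seed=5)
        idx = tp.hrv_band_indices(
            tp.averaged_spectrum(tp.uniform_rr(rr.beat_times)))
        assert idx.HRVLF / idx.HRVHF == pytest.approx(oracle, rel=0.25)

    def test_lf_power_is_monotone_in_modulation_depth(self):
        """Spectral LF power scales with the square of the modulation depth;
        rank order across depths must be exact."""
        amps = [0.02, 0.05, 0.08, 0.12]
        powers = []
        for a in amps:
            vals = []
            for seed in range(3):
                rr, _ = tp.generate_rr(profile(mean_hr=65, lf_mod_amp=a,
                                               hf_mod_amp=0.03), 240, seed)
                idx = tp.hrv_band_indices(
                    tp.averaged_spectrum(tp.uniform_rr(rr.beat_times)))
                vals.append(idx.HRVLF)
            powers.append(np.mean(vals))
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_rejects_modulation_reaching_zero_rate(self):
        with pytest.raises(tp.ConfigError):
            profile(mean_hr=60, lf_mod_amp=0.6, hf_mod_amp=0.5)

    def test_rejects_short_segment(self):
        with pytest.raises(tp.ConfigError):
            tp.generate_rr(profile(), 120, seed=0)


class TestSynthesizeECG:
    def test_sample_count_matches_duration_times_rate(self):
        rr, _ = tp.generate_rr(profile(mean_hr=60), 240, seed=0)
        ecg = tp.synthesize_ecg(rr, fs=256, seed=0, duration=240)
        assert ecg.samples.size == 61440

    def test_clean_signal_peaks_at_beat_times(self):
        rr, _ = tp.generate_rr(profile(mean_hr=65, lf_mod_amp=0.05,
                                       hf_mod_amp=0.03), 240, seed=1)
        ecg = tp.synthesize_ecg(rr, fs=256, seed=1, noise_sd=0.0,
                                wander_amp=0.0, duration=240)
        fs = ecg.fs
        for bt in rr.beat_times[1:-1]:
            idx = int(round(bt * fs))
            win = ecg.samples[idx - 13: idx + 14]  # +-50 ms
            assert abs(int(np.argmax(win)) - 13) <= 1

    def test_detector_recovers_beats_through_noise(self):
        """At 0.05 mV noise, detection vs ground truth stays >= 99% in both
        sensitivity and precision (10 ms tolerance)."""
        rr, truth = tp.generate_rr(profile(mean_hr=70, lf_mod_amp=0.08,
                                           hf_mod_amp=0.04), 240, seed=2)
        ecg = tp.synthesize_ecg(rr, fs=256, seed=2, noise_sd=0.05,
                                duration=240)
        beats = tp.detect_r_peaks(ecg)
        d = np.abs(beats[:, None] - truth.beat_times[None, :])
        precision = (d.min(axis=1) < 0.010).mean()
        sensitivity = (d.min(axis=0) < 0.010).mean()
        assert precision >= 0.99 and sensitivity >= 0.99


class TestSynthesizeEDA:
    def test_bare_tonic_is_constant(self):
        p = profile(condition_label="PVT", tonic_level=3.5, scr_rate=0,
                    tonic_drift_slope=0, noise_sd_eda=0)
        eda, _ = tp.synthesize_eda(p, 120, seed=0, slow_amp=0.0)
        assert np.allclose(eda.samples, 3.5)

    def test_tonic_level_difference_between_conditions(self):
        """SS vs BL tonic levels differ by the published SCL gap (~5.4 µS)."""
        profs = tp.default_profiles()
        ss, _ = tp.synthesize_eda(profs["SS"], 120, seed=3, slow_amp=0.0)
        bl, _ = tp.synthesize_eda(profs["BL"], 120, seed=3, slow_amp=0.0)
        diff = ss.samples.mean() - bl.samples.mean()
        assert diff == pytest.approx(5.6 - 0.19, abs=0.3)

    def test_seeded_poisson_process_reproducible_and_seed_sensitive(self):
        p = profile(scr_rate=4.0)
        _, t1 = tp.synthesize_eda(p, 120, seed=9)
        _, t2 = tp.synthesize_eda(p, 120, seed=9)
        _, t3 = tp.synthesize_eda(p, 120, seed=10)
        assert np.array_equal(t1.scr_event_times, t2.scr_event_times)
        assert not np.array_equal(t1.scr_event_times, t3.scr_event_times)

    def test_event_count_calibrated_to_rate(self):
        """Mean SCR count over 100 seeded runs within 3 SE of rate*minutes."""
        p = profile(scr_rate=3.0)
        counts = [tp.synthesize_eda(p, 120, seed=s)[1].scr_event_times.size
                  for s in range(100)]
        expected = 3.0 * 2.0
        se = np.sqrt(expected / 100)
        assert abs(np.mean(counts) - expected) < 3 * se


class TestCohort:
    def test_16_subjects_one_trial_yields_64_recordings(self):
        cohort = tp.generate_cohort(16, 1, tp.default_profiles(), seed=0,
                                    duration_ecg=240, duration_eda=120)
        assert len(cohort) == 64
        labels = {(r.subject_id, r.trial, r.condition) for r in cohort}
        assert len(labels) == 64

    def test_label_balance_across_trials(self):
        cohort = tp.generate_cohort(2, 12, tp.default_profiles(), seed=0)
        assert len(cohort) == 96
        per_cond = {c: sum(r.condition == c for r in cohort)
                    for c in tp.CONDITIONS}
        assert set(per_cond.values()) == {24}

    def test_minimum_cohort_size_enforced(self):
        with pytest.raises(tp.ConfigError):
            tp.generate_cohort(1, 1, tp.default_profiles(), seed=0)

    def test_missing_condition_profile_rejected(self):
        profs = tp.default_profiles()
        del profs["SS"]
        with pytest.raises(tp.ConfigError):
            tp.generate_cohort(2, 1, profs, seed=0)

    def test_attenuation_shrinks_condition_gaps(self):
        profs = tp.default_profiles()
        shrunk = tp.simulate.attenuate_separation(profs, 0.5)
        tonic = [p.tonic_level for p in profs.values()]
        tonic_s = [p.tonic_level for p in shrunk.values()]
        assert np.ptp(tonic_s) == pytest.approx(0.5 * np.ptp(tonic), rel=1e-6)
        same = tp.simulate.attenuate_separation(profs, 1.0)
        assert all(same[c].tonic_level == profs[c].tonic_level for c in profs)

    def test_cohort_directory_roundtrip(self, tmp_path):
        cohort = tp.generate_cohort(2, 1, tp.default_profiles(), seed=4)
        tp.write_cohort(cohort, tmp_path / "cohort")
        assert (tmp_path / "cohort" / "manifest.csv").exists()
        back = tp.read_cohort(tmp_path / "cohort")
        assert len(back) == len(cohort)
        orig = {(r.subject_id, r.trial, r.condition): r for r in cohort}
        for r in back:
            o = orig[(r.subject_id, r.trial, r.condition)]
            assert r.ecg.fs == o.ecg.fs
            assert np.allclose(r.eda.samples, o.eda.samples, atol=1e-5)
            assert r.seed == o.seed
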