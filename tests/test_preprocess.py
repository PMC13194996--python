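import numpy as np
import pytest
from scipy import signal as sps

from seegstate.channels import make_channel_spec
from seegstate.containers import Recording, Trial, TrialAnnotation
from seegstate.preprocess import (PreprocConfig, audio_neural_independence_check,
                                  compute_zscore_stats, count_windows,
                                  downsample, filter_signal, label_and_segment,
                                  zscore_standardize)

FS = 2000.0


def tone(freq, duration=4.0, fs=FS, n_channels=1):
    t = np.arange(int(duration * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    return Recording(signal=np.tile(x, (n_channels, 1)),
                     sampling_rate=fs,
                     channels=[make_channel_spec(f"c{i}", "STG")
                               for i in range(n_channels)])


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestFiltering:
    def test_broadband_stopband(self):
        rec = tone(300.0)
        out = filter_signal(rec, PreprocConfig(signal_mode="broadband"))
        assert rms(out.signal) < 0.05 * rms(rec.signal)

    def test_notch_removes_line_frequency(self):
        # steady-state attenuation: skip the filter's edge transients
        rec = tone(50.0, duration=8.0)
        out = filter_signal(rec, PreprocConfig(signal_mode="broadband"))
        assert rms(out.signal[0, 4000:-4000]) < 0.05 * rms(rec.signal[0, 4000:-4000])

    def test_hga_passband_matches_designed_response(self):
        """A pass-band tone away from the notches passes nearly unattenuated.

        The empirical gain is cross-checked against the designed filter's
        frequency response evaluated independently with sosfreqz.
        """
        rec = tone(110.0)
        cfg = PreprocConfig(signal_mode="hga")
        out = filter_signal(rec, cfg)
        # zero-phase application squares the magnitude response
        sos = sps.butter(4, cfg.hga_band, btype="bandpass", fs=FS, output="sos")
        _, h = sps.sosfreqz(sos, worN=[110.0], fs=FS)
        expected_gain = np.abs(h[0]) ** 2
        measured = rms(out.signal[0, 2000:-2000]) / rms(rec.signal[0, 2000:-2000])
        assert measured >= 0.90
        assert abs(measured - expected_gain) < 0.05

    def test_hga_mode_still_notches_100hz(self):
        rec = tone(100.0, duration=8.0)
        out = filter_signal(rec, PreprocConfig(signal_mode="hga"))
        assert rms(out.signal[0, 4000:-4000]) < 0.05 * rms(rec.signal[0, 4000:-4000])

    def test_linearity(self, rng):
        rec = Recording(signal=rng.standard_normal((2, 8000)),
                        sampling_rate=FS,
                        channels=[make_channel_spec("a", "STG"),
                                  make_channel_spec("b", "Tha")])
        cfg = PreprocConfig()
        a = filter_signal(rec, cfg).signal
        scaled = Recording(signal=3.5 * rec.signal, sampling_rate=FS,
                           channels=rec.channels)
        b = filter_signal(scaled, cfg).signal
        assert np.allclose(b, 3.5 * a, rtol=1e-5, atol=1e-5)

    def test_band_edges_above_nyquist_rejected(self):
        rec = tone(10.0, fs=300.0)
        with pytest.raises(ValueError):
            filter_signal(rec, PreprocConfig(signal_mode="broadband"))

    def test_causal_mode_does_not_use_future(self, rng):
        """An impulse at sample k leaves samples < k untouched under causal filtering."""
        sig = np.zeros((1, 8000))
        sig[0, 4000] = 1.0
        rec = Recording(signal=sig, sampling_rate=FS,
                        channels=[make_channel_spec("a", "STG")])
        out = filter_signal(rec, PreprocConfig(), causal=True)
        assert np.allclose(out.signal[0, :4000], 0.0, atol=1e-12)


class TestZScore:
    def test_self_standardization(self, rng):
        x = rng.normal(5.0, 3.0, size=(1, 100_000))
        rec = Recording(signal=x, sampling_rate=FS,
                        channels=[make_channel_spec("a", "STG")])
        out, stats = zscore_standardize(rec)
        assert abs(out.signal.mean()) < 0.01
        assert 0.99 < out.signal.std() < 1.01

    def test_constant_channel_flagged_and_dropped(self, rng):
        x = np.vstack([np.full(4000, 7.0), rng.standard_normal(4000)])
        rec = Recording(signal=x, sampling_rate=FS,
                        channels=[make_channel_spec("flat", "STG"),
                                  make_channel_spec("ok", "Tha")])
        out, stats = zscore_standardize(rec)
        assert stats.excluded == ["flat"]
        assert out.channel_names() == ["ok"]

    def test_provided_stats_identity(self, rng):
        x = rng.standard_normal((1, 4000))
        rec = Recording(signal=x, sampling_rate=FS,
                        channels=[make_channel_spec("a", "STG")])
        stats = compute_zscore_stats(rec)
        stats.mean[:] = 0.0
        stats.sd[:] = 1.0
        out, _ = zscore_standardize(rec, stats)
        assert np.allclose(out.signal, x, atol=1e-6)


class TestDownsample:
    def test_2000_to_500_quarters_samples(self, rng):
        rec = Recording(signal=rng.standard_normal((2, 8000)), sampling_rate=FS,
                        channels=[make_channel_spec("a", "STG"),
                                  make_channel_spec("b", "Tha")])
        out = downsample(rec, 500.0)
        assert out.n_samples == 2000
        assert out.sampling_rate == 500.0

    def test_factor_one_identity(self, rng):
        rec = Recording(signal=rng.standard_normal((1, 4000)), sampling_rate=FS,
                        channels=[make_channel_spec("a", "STG")])
        assert downsample(rec, FS) is rec

    def test_non_integer_factor_rejected(self, rng):
        rec = Recording(signal=rng.standard_normal((1, 4000)), sampling_rate=FS,
                        channels=[make_channel_spec("a", "STG")])
        with pytest.raises(ValueError):
            downsample(rec, 600.0)

    def test_low_frequency_content_survives(self):
        """10 Hz tone keeps >=99% amplitude; agrees with a polyphase oracle."""
        rec = filter_signal(tone(10.0), PreprocConfig())
        out = downsample(rec, 500.0)
        assert rms(out.signal) >= 0.99 * rms(rec.signal)
        oracle = sps.resample_poly(rec.signal[0], 1, 4)
        assert abs(rms(out.signal) - rms(oracle)) < 0.01


def two_trial_annotation():
    """Trial 0: prep exactly 2.0 s; speech contains a 0.4 s pause."""
    t0 = Trial(trial_id=0, sentence_id=0, repetition=0,
               prep=(0.0, 2.0),
               syllables=[(2.0, 2.5), (2.9, 3.4), (3.4, 4.0)],
               rest=(4.0, 6.0))
    t1 = Trial(trial_id=1, sentence_id=1, repetition=0,
               prep=(6.0, 7.65),
               syllables=[(7.65, 9.0)],
               rest=(9.0, 11.0))
    return TrialAnnotation(trials=[t0, t1])


class TestSegmentation:
    @pytest.fixture()
    def rec500(self, rng):
        ann = two_trial_annotation()
        n = int(11.5 * 500)
        return Recording(signal=rng.standard_normal((2, n)), sampling_rate=500.0,
                         channels=[make_channel_spec("a", "STG"),
                                   make_channel_spec("b", "Tha")]), ann

    def test_window_has_50_samples(self, rec500):
        rec, ann = rec500
        segs = label_and_segment(rec, ann, PreprocConfig())
        assert segs and all(s.data.shape == (2, 50) for s in segs)

    def test_rest_windows_before_first_onset(self, rec500):
        rec, ann = rec500
        segs = label_and_segment(rec, ann, PreprocConfig())
        t0_rest_pre = [s for s in segs if s.trial_id == 0 and s.label == 0
                       and s.window_start < 2.0]
        assert len(t0_rest_pre) == 20  # 2.0 s of prep / 100 ms

    def test_pause_window_labeled_speech(self, rec500):
        rec, ann = rec500
        segs = label_and_segment(rec, ann, PreprocConfig())
        # window [2.5, 2.6) lies wholly inside the 2.5-2.9 s pause
        pause = [s for s in segs if s.trial_id == 0
                 and abs(s.window_start - 2.5) < 1e-9]
        assert len(pause) == 1 and pause[0].label == 1

    def test_boundary_straddling_windows_dropped(self, rng):
        tr = Trial(trial_id=0, sentence_id=0, repetition=0,
                   prep=(0.0, 1.95), syllables=[(1.95, 3.93)], rest=(3.93, 6.0))
        ann = TrialAnnotation(trials=[tr])
        rec = Recording(signal=rng.standard_normal((1, 3200)),
                        sampling_rate=500.0,
                        channels=[make_channel_spec("a", "STG")])
        segs = label_and_segment(rec, ann, PreprocConfig())
        starts = {round(s.window_start, 3) for s in segs}
        assert 1.9 not in starts  # [1.9, 2.0) straddles onset 1.95
        assert 3.9 not in starts  # [3.9, 4.0) straddles offset 3.93

    def test_window_count_conservation(self, rec500):
        rec, ann = rec500
        cfg = PreprocConfig()
        segs = label_and_segment(rec, ann, cfg)
        n_dropped = count_windows(ann, cfg.window_length) - len(segs)
        # recompute dropped windows directly: those straddling a boundary
        expected_dropped = 0
        for tr in ann.trials:
            n_windows = int(np.floor((tr.end - tr.start) / cfg.window_length))
            for w in range(n_windows):
                a = tr.start + w * cfg.window_length
                b = a + cfg.window_length
                in_rest = b <= tr.first_onset + 1e-9 or a >= tr.last_offset - 1e-9
                in_speech = (a >= tr.first_onset - 1e-9
                             and b <= tr.last_offset + 1e-9)
                expected_dropped += not (in_rest or in_speech)
        assert n_dropped == expected_dropped

    def test_trial_without_syllables_skipped(self, rng, caplog):
        tr = Trial(trial_id=0, sentence_id=0, repetition=0,
                   prep=(0.0, 2.0), syllables=[], rest=(4.0, 6.0))
        ann = TrialAnnotation(trials=[tr])
        rec = Recording(signal=rng.standard_normal((1, 3200)),
                        sampling_rate=500.0,
                        channels=[make_channel_spec("a", "STG")])
        with caplog.at_level("WARNING"):
            segs = label_and_segment(rec, ann, PreprocConfig())
        assert segs == []
        assert "no syllables" in caplog.text


class TestIndependenceCheck:
    def test_independent_signals_pass(self, rng):
        n = int(120 * FS)
        rec = Recording(signal=rng.standard_normal((3, n)), sampling_rate=FS,
                        channels=[make_channel_spec(f"c{i}", "STG")
                                  for i in range(3)])
        audio = rng.standard_normal(n)
        for seed in range(5):
            out = audio_neural_independence_check(rec, audio, epoch_length=60.0,
                                                  n_epochs=4, seed=seed)
            assert (out.max_abs_r < 0.05).all()

    def test_copied_envelope_flagged(self, rng):
        n = int(120 * FS)
        audio = rng.standard_normal(n)
        sig = rng.standard_normal((2, n))
        sig[1] = audio
        rec = Recording(signal=sig, sampling_rate=FS,
                        channels=[make_channel_spec("a", "STG"),
                                  make_channel_spec("leak", "STG")])
        out = audio_neural_independence_check(rec, audio, epoch_length=60.0,
                                              n_epochs=3, seed=0)
        assert not out.independent[1]
        assert out.max_abs_r[1] > 0.99

    def test_weak_leak_has_cohort_max_correlation(self, rng):
        n = int(120 * FS)
        audio = rng.standard_normal(n)
        sig = rng.standard_normal((4, n))
        sig[2] += 0.1 * audio
        rec = Recording(signal=sig, sampling_rate=FS,
                        channels=[make_channel_spec(f"c{i}", "STG")
                                  for i in range(4)])
        out = audio_neural_independence_check(rec, audio, epoch_length=60.0,
                                              n_epochs=4, seed=1)
        assert out.max_abs_r.idxmax() == 2

    def test_epoch_longer_than_recording_rejected(self, rng):
        rec = Recording(signal=rng.standard_normal((1, 4000)), sampling_rate=FS,
                        channels=[make_channel_spec("a", "STG")])
        with pytest.raises(ValueError):
            audio_neural_independence_check(rec, np.zeros(4000),
                                            epoch_length=10.0, n_epochs=2)
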