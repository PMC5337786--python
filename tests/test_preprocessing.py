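import numpy as np
import pytest

from conftest import make_events, make_recording
from hybridbci.core import (BoundaryError, ContinuousRecording, ParameterError)
from hybridbci.preprocessing import (bandpass, extract_flash_epochs,
                                     extract_mi_segments, resample)


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


def _sine_recording(freq, rate=250.0, seconds=20.0):
    t = np.arange(int(seconds * rate)) / rate
    samples = np.tile(np.sin(2 * np.pi * freq * t), (15, 1))
    events = make_events(n_trials=1, rate_hz=rate)
    from hybridbci.core import CHANNELS
    return ContinuousRecording(samples, rate, list(CHANNELS), events)


class TestBandpass:
    def test_stop_band_attenuation_50hz_in_erp_band(self):
        # the 0.1 Hz low edge rings for seconds: judge the steady state,
        # well away from the onset/offset transients
        rec = _sine_recording(50.0, seconds=60.0)
        out = bandpass(rec, 0.1, 20.0)
        mid = slice(5000, -5000)
        assert _rms(out.samples[:, mid]) < 0.01 * _rms(rec.samples[:, mid])

    def test_pass_band_12hz_in_mi_band(self):
        rec = _sine_recording(12.0)
        out = bandpass(rec, 8.0, 30.0)
        mid = slice(500, -500)
        assert abs(_rms(out.samples[:, mid]) - _rms(rec.samples[:, mid])) \
            < 0.05 * _rms(rec.samples[:, mid])

    def test_zero_input_gives_zero_output(self):
        rec = make_recording(n_trials=1)
        rec.samples[:] = 0.0
        out = bandpass(rec, 0.1, 20.0)
        assert np.all(out.samples == 0)

    def test_high_edge_at_or_above_nyquist_rejected(self):
        rec = make_recording(n_trials=1)
        with pytest.raises(ParameterError):
            bandpass(rec, 0.1, 125.0)

    def test_zero_phase_time_reversal_symmetry(self):
        rec = make_recording(n_trials=2, seed=3)
        fwd = bandpass(rec, 8.0, 30.0).samples
        rev_rec = ContinuousRecording(rec.samples[:, ::-1], rec.rate_hz,
                                      rec.channel_names, rec.events)
        rev = bandpass(rev_rec, 8.0, 30.0).samples[:, ::-1]
        mid = slice(500, -500)
        assert _rms(fwd[:, mid] - rev[:, mid]) < 1e-8 * max(_rms(fwd), 1.0)


class TestResample:
    def test_250_to_60_sample_count(self):
        rec = _sine_recording(5.0, seconds=10.0)
        out = resample(rec, 60.0)
        assert out.n_samples == 600
        assert out.rate_hz == 60.0

    def test_250_to_100_sample_count(self):
        rec = _sine_recording(5.0, seconds=4.0)
        out = resample(rec, 100.0)
        assert out.n_samples == 400

    def test_dc_preserved(self):
        rec = make_recording(n_trials=1)
        rec.samples[:] = 3.25
        out = resample(rec, 60.0)
        mid = out.samples[:, 50:-50]
        # anti-aliasing FIR leaves ~1e-5 pass-band ripple
        assert np.allclose(mid, 3.25, rtol=1e-4)

    def test_event_onsets_rescaled(self):
        rec = make_recording(n_trials=1)
        out = resample(rec, 60.0)
        orig = rec.events.df["onset_sample"].to_numpy()
        scaled = out.events.df["onset_sample"].to_numpy()
        assert np.array_equal(scaled, np.rint(orig * 60.0 / 250.0).astype(int))

    def test_upsampling_rejected(self):
        rec = make_recording(n_trials=1)
        with pytest.raises(ParameterError):
            resample(rec, 500.0)


def _recording_at_60hz(n_trials=1, seed=0):
    """Recording constructed directly at 60 Hz (unit spacing arithmetic)."""
    from hybridbci.core import CHANNELS
    rng = np.random.default_rng(seed)
    events = make_events(n_trials, rate_hz=60.0, rng=rng)
    n = int(n_trials * 12.0 * 60) + 60
    samples = rng.standard_normal((15, n))
    return ContinuousRecording(samples, 60.0, list(CHANNELS), events)


class TestFlashEpochs:
    def test_four_epochs_per_trial_shape_37x15(self):
        rec = _recording_at_60hz()
        epochs = extract_flash_epochs(rec)
        assert len(epochs) == 4
        assert all(e.data.shape == (37, 15) for e in epochs)
        assert [e.repeat_index for e in epochs] == [1, 2, 3, 4]

    def test_window_starts_at_flash_onset(self):
        rec = _recording_at_60hz(seed=2)
        target = rec.events.flashes.query("button_id == 1")
        onsets = sorted(target["onset_sample"])
        epochs = extract_flash_epochs(rec)
        for e, s in zip(epochs, onsets):
            assert np.array_equal(e.data[0], rec.samples[:, s])
            assert np.array_equal(e.data, rec.samples[:, s:s + 37].T)

    def test_translation_equivariance(self):
        rec = _recording_at_60hz(seed=5)
        k = 17
        shifted = ContinuousRecording(
            np.concatenate([np.zeros((15, k)), rec.samples], axis=1),
            60.0, rec.channel_names, rec.events.scaled(1.0))
        shifted.events.df["onset_sample"] += k
        e0 = extract_flash_epochs(rec)
        e1 = extract_flash_epochs(shifted)
        for a, b in zip(e0, e1):
            assert np.array_equal(a.data, b.data)

    def test_epoch_past_end_names_trial(self):
        rec = _recording_at_60hz()
        rec2 = ContinuousRecording(rec.samples[:, :280], 60.0,
                                   rec.channel_names, rec.events)
        with pytest.raises(BoundaryError, match="trial 0"):
            extract_flash_epochs(rec2)

    def test_rate_checked(self):
        rec = make_recording(n_trials=1)
        with pytest.raises(ParameterError):
            extract_flash_epochs(rec)


def _recording_at_100hz(n_trials=1, seed=0):
    from hybridbci.core import CHANNELS
    rng = np.random.default_rng(seed)
    events = make_events(n_trials, rate_hz=100.0, rng=rng)
    n = int(n_trials * 12.0 * 100) + 100
    samples = rng.standard_normal((15, n))
    return ContinuousRecording(samples, 100.0, list(CHANNELS), events)


class TestMISegments:
    def test_segment_covers_cue_plus_4s(self):
        rec = _recording_at_100hz()
        segs = extract_mi_segments(rec)
        assert len(segs) == 1
        assert segs[0].data.shape == (15, 400)
        assert np.array_equal(segs[0].data, rec.samples[:, 400:800])

    def test_one_segment_per_trial(self):
        rec = _recording_at_100hz(n_trials=5)
        assert len(extract_mi_segments(rec)) == 5

    def test_overlapping_cue_windows_rejected(self):
        rec = _recording_at_100hz(n_trials=2)
        df = rec.events.df
        second = df[(df.trial_id == 1) & (df.kind == "cue")].index[0]
        df.loc[second, "onset_sample"] = 500  # inside trial 0's window
        with pytest.raises(BoundaryError, match="overlap"):
            extract_mi_segments(rec)
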