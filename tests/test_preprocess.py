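"""Filtering, ocular artifact removal, epoching and rejection."""

import numpy as np
import pytest

from mmnstudy.paradigm import DeviantKind, TrialEvent
from mmnstudy.preprocess import (bandpass, drop_warmup_standards,
                                 extract_epochs, load_epochs, reject_epochs,
                                 remove_ocular, save_epochs)
from mmnstudy.synthetic_eeg import (ZERO_NOISE, NoiseModel, RawRecording,
                                    simulate_subject)

from conftest import SMALL_LAYOUT

FS = 1024.0


def _sine_recording(freq_hz, n_s=8192, amp=10.0, layout=SMALL_LAYOUT,
                    offset=0.0):
    t = np.arange(n_s) / FS
    data = np.tile(amp * np.sin(2 * np.pi * freq_hz * t) + offset,
                   (len(layout.labels), 1))
    return RawRecording(data, FS, layout, [])


def _events(onsets, kind=DeviantKind.STANDARD, warmup=False):
    return [TrialEvent(o, kind, 1, i + 1, warmup) for i, o in enumerate(onsets)]


class TestBandpass:
    def test_stopband_50hz(self):
        rec = _sine_recording(50.0)
        out = bandpass(rec)
        core = slice(1024, -1024)  # steady state, past onset transients
        ratio = out.data[0, core].std() / rec.data[0, core].std()
        assert ratio < 0.01

    def test_passband_10hz(self):
        rec = _sine_recording(10.0)
        out = bandpass(rec)
        core = slice(1024, -1024)  # ignore edge transients
        assert out.data[0, core].std() == pytest.approx(
            rec.data[0, core].std(), rel=0.05)

    def test_dc_removed(self):
        rec = _sine_recording(10.0, amp=0.0, offset=100.0)
        out = bandpass(rec)
        assert abs(out.data[0].mean()) < 1.0

    def test_linearity(self):
        r1 = _sine_recording(5.0)
        r2 = _sine_recording(12.0)
        combo = r1.copy()
        combo.data = 2.0 * r1.data + 0.5 * r2.data
        lhs = bandpass(combo).data
        rhs = 2.0 * bandpass(r1).data + 0.5 * bandpass(r2).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_invalid_band(self):
        rec = _sine_recording(10.0)
        with pytest.raises(ValueError):
            bandpass(rec, low_hz=20.0, high_hz=1.0)


@pytest.fixture(scope="module")
def blinky(meanfixed_profile, small_events):
    """Recording with blinks plus light pink noise (full-rank mixture)."""
    noise = NoiseModel(pink_rms_uV=2.0, alpha_rms_uV=0.0,
                       blink_rate_per_min=20.0, blink_amp_uV=150.0)
    rec = simulate_subject(meanfixed_profile, small_events, noise=noise)
    return bandpass(rec)


class TestOcularRemoval:
    def _blink_windows(self, rec):
        eog = rec.data[rec.layout.index("EOG_lower")]
        return np.abs(eog) > 30.0

    @pytest.mark.parametrize("method", ["ica", "regression"])
    def test_frontal_blink_power_reduced(self, blinky, method):
        """Blink-window RMS on frontal channels drops by >= 70%."""
        mask = self._blink_windows(blinky)
        assert mask.sum() > 1000  # the fixture actually contains blinks
        out = remove_ocular(blinky, method=method)
        i_fp = blinky.layout.index("FP1")
        before = blinky.data[i_fp, mask].std()
        after = out.data[i_fp, mask].std()
        assert after < 0.3 * before

    def test_zero_eog_is_noop(self, meanfixed_profile, small_events):
        rec = simulate_subject(meanfixed_profile, small_events,
                               noise=ZERO_NOISE)
        out = remove_ocular(rec)
        rms = np.sqrt(np.mean((out.data - rec.data) ** 2))
        assert rms < 1.0

    def test_mmn_preserved_after_removal(self, meanfixed_profile,
                                         small_events):
        """Blink removal keeps the MMN within 10% of the blink-free truth."""
        from mmnstudy.pipeline import PreprocessParams, process_recording

        kind = DeviantKind.FREQUENCY_HIGH
        clean = simulate_subject(meanfixed_profile, small_events,
                                 noise=ZERO_NOISE)
        fs_clean, _ = process_recording(
            clean, "s", "decompensated", PreprocessParams(ocular_method="none"))
        # light background keeps the mixture full rank without drowning the
        # few deviant trials this short paradigm provides
        noise = NoiseModel(pink_rms_uV=0.5, alpha_rms_uV=0.0,
                           blink_rate_per_min=20.0, blink_amp_uV=150.0)
        noisy = simulate_subject(meanfixed_profile, small_events, noise=noise)
        fs_noisy, _ = process_recording(
            noisy, "s", "decompensated", PreprocessParams(ocular_method="ica"))
        assert fs_noisy.amplitude_uV[kind] == pytest.approx(
            fs_clean.amplitude_uV[kind], rel=0.10)

    def test_unknown_method(self, blinky):
        with pytest.raises(ValueError):
            remove_ocular(blinky, method="magic")

    def test_missing_eog_channel(self, blinky):
        with pytest.raises(ValueError, match="EOG"):
            remove_ocular(blinky, eog_channels=("EOG_nope",))


class TestEpoching:
    def test_epoch_count_and_length(self, meanfixed_profile, default_events):
        rec = simulate_subject(meanfixed_profile, default_events,
                               noise=ZERO_NOISE)
        epochs = extract_epochs(rec)
        assert epochs.n_trials == 364
        assert epochs.data.shape[2] == round(0.95 * FS) + 1
        assert epochs.times_ms[0] == pytest.approx(-50.0, abs=1.0)
        assert epochs.times_ms[-1] == pytest.approx(900.0, abs=1.0)

    def test_constant_channel_zero_after_baseline(self):
        rec = _sine_recording(10.0, amp=0.0, offset=42.0)
        rec.events = _events([2.0, 4.0])
        epochs = extract_epochs(rec)
        np.testing.assert_allclose(epochs.data, 0.0, atol=1e-12)

    def test_edge_event_flagged_not_dropped(self):
        rec = _sine_recording(10.0, n_s=4096)
        rec.events = _events([0.01, 2.0])  # first has no prestim support
        epochs = extract_epochs(rec)
        assert epochs.n_trials == 2
        assert not epochs.keep[0] and epochs.reason[0] == "edge"
        assert epochs.keep[1]


class TestRejection:
    def _epochs(self, n_trials=5, layout=SMALL_LAYOUT):
        rec = _sine_recording(10.0, amp=0.0, n_s=int(FS) * 12, layout=layout)
        rec.events = _events(list(2.0 + np.arange(n_trials)))
        return rec

    def test_spike_trial_rejected(self):
        rec = self._epochs()
        i_cz = rec.layout.index("Cz")
        spike_at = int((2.0 + 2 + 0.3) * FS)  # 300 ms into the third epoch
        rec.data[i_cz, spike_at] = 60.0
        epochs = reject_epochs(extract_epochs(rec))
        assert not epochs.keep[2] and epochs.reason[2] == "amplitude"
        assert epochs.keep.sum() == 4

    def test_eog_excluded_from_criterion(self):
        rec = self._epochs()
        i_eog = rec.layout.index("EOG_lower")
        rec.data[i_eog, int(2.3 * FS)] = 200.0
        epochs = reject_epochs(extract_epochs(rec))
        assert epochs.keep.all()

    def test_all_zero_none_rejected(self):
        epochs = reject_epochs(extract_epochs(self._epochs()))
        assert epochs.keep.all()

    def test_matches_bruteforce_scan(self, meanfixed_profile, small_events):
        rec = simulate_subject(meanfixed_profile, small_events,
                               noise=NoiseModel(pink_rms_uV=25.0,
                                                blink_rate_per_min=0,
                                                alpha_rms_uV=0))
        epochs = extract_epochs(bandpass(rec))
        rejected = ~reject_epochs(epochs, 50.0).keep
        scalp = epochs.layout.indices(epochs.layout.scalp)
        brute = np.array([
            np.abs(epochs.data[i][scalp]).max() > 50.0
            for i in range(epochs.n_trials)
        ])
        np.testing.assert_array_equal(rejected, brute)
        assert 0 < rejected.sum() < epochs.n_trials

    def test_permutation_equivariance(self, meanfixed_profile, small_events):
        rec = simulate_subject(meanfixed_profile, small_events,
                               noise=NoiseModel(pink_rms_uV=25.0,
                                                blink_rate_per_min=0,
                                                alpha_rms_uV=0))
        epochs = extract_epochs(bandpass(rec))
        perm = np.random.default_rng(0).permutation(epochs.n_trials)
        shuffled = epochs.copy()
        shuffled.data = epochs.data[perm]
        shuffled.kinds = [epochs.kinds[i] for i in perm]
        shuffled.blocks = epochs.blocks[perm]
        shuffled.trials = epochs.trials[perm]
        shuffled.is_warmup = epochs.is_warmup[perm]
        shuffled.keep = epochs.keep[perm]
        shuffled.reason = [epochs.reason[i] for i in perm]
        np.testing.assert_array_equal(reject_epochs(shuffled).keep,
                                      reject_epochs(epochs).keep[perm])

    def test_all_rejected_raises(self):
        rec = self._epochs()
        rec.data += 100.0 * np.sin(2 * np.pi * 3 * np.arange(rec.n_samples) / FS)
        with pytest.raises(ValueError, match="threshold"):
            reject_epochs(extract_epochs(rec))


class TestWarmupExclusion:
    def test_default_paradigm_flags_forty(self, meanfixed_profile,
                                          default_events):
        rec = simulate_subject(meanfixed_profile, default_events,
                               noise=ZERO_NOISE)
        epochs = drop_warmup_standards(extract_epochs(rec))
        assert sum(r == "warmup" for r in epochs.reason) == 40

    def test_idempotent(self, meanfixed_profile, small_events):
        rec = simulate_subject(meanfixed_profile, small_events,
                               noise=ZERO_NOISE)
        once = drop_warmup_standards(extract_epochs(rec))
        twice = drop_warmup_standards(once)
        np.testing.assert_array_equal(once.keep, twice.keep)
        assert once.reason == twice.reason

    def test_no_warmup_no_change(self):
        rec = _sine_recording(10.0, amp=0.0, n_s=int(FS) * 8)
        rec.events = _events([2.0, 3.0, 4.0])
        epochs = extract_epochs(rec)
        out = drop_warmup_standards(epochs)
        np.testing.assert_array_equal(out.keep, epochs.keep)


class TestEpochIO:
    def test_roundtrip(self, tmp_path, meanfixed_profile, small_events):
        rec = simulate_subject(meanfixed_profile, small_events[:6],
                               noise=ZERO_NOISE)
        epochs = drop_warmup_standards(extract_epochs(rec))
        path = tmp_path / "epochs.npz"
        save_epochs(epochs, path)
        back = load_epochs(path)
        np.testing.assert_array_equal(back.data, epochs.data)
        assert back.kinds == epochs.kinds
        assert back.reason == epochs.reason
        np.testing.assert_array_equal(back.keep, epochs.keep)
        assert back.layout.labels == epochs.layout.labels
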