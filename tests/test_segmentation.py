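import numpy as np
import pytest

import fetmov as fm
from fetmov.preprocess import FilteredTrace
from fetmov.segmentation import (
    PEAK_POS,
    WINDOW_LEN,
    MovementClass,
    adaptive_threshold,
    build_training_set,
    detect_candidate_peaks,
    extract_window,
    locate_annotated_peak,
)

FS = 280.0


def _trace(z):
    return FilteredTrace(fs=FS, z=np.asarray(z, dtype=float))


class TestLocateAnnotatedPeak:
    def test_single_impulse_found(self):
        z = np.zeros(3000)
        z[1000] = 5.0
        assert locate_annotated_peak(_trace(z), 1500, 5.0) == 1000

    def test_flat_trace_falls_back_to_press(self):
        with pytest.warns(UserWarning):
            assert locate_annotated_peak(_trace(np.zeros(3000)), 1500, 5.0) == 1500

    def test_tie_breaks_toward_latest(self):
        z = np.zeros(3000)
        z[900] = 4.0
        z[1100] = 4.0
        got = locate_annotated_peak(_trace(z), 1500, 5.0)
        # brute-force oracle: last index attaining the max of |z| in window
        lo = 1500 - int(5.0 * FS)
        window = np.abs(z[lo:1501])
        best = lo + max(i for i, v in enumerate(window) if v == window.max())
        assert got == best == 1100

    def test_press_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            locate_annotated_peak(_trace(np.zeros(100)), 500)


class TestExtractWindow:
    def test_boundary_arithmetic(self):
        z = np.arange(300, dtype=float)
        r = extract_window(_trace(z), 100)
        assert r.samples.tolist() == list(range(0, 200))
        assert r.origin_idx == 100 and r.peak_pos == PEAK_POS

    def test_edge_peak_rejected(self):
        with pytest.raises(IndexError):
            extract_window(_trace(np.zeros(300)), 99)
        with pytest.raises(IndexError):
            extract_window(_trace(np.zeros(300)), 200)

    def test_peak_lands_at_index_100_over_grid(self):
        n = 1000
        for peak_idx in range(PEAK_POS, n - PEAK_POS, 37):
            z = np.zeros(n)
            z[peak_idx] = 3.0
            r = extract_window(_trace(z), peak_idx)
            assert r.samples.shape == (WINDOW_LEN,)
            assert int(np.argmax(np.abs(r.samples))) == PEAK_POS


class TestDetectCandidatePeaks:
    def test_all_zero_trace_gives_empty(self):
        assert detect_candidate_peaks(_trace(np.zeros(4000)), 1.0).size == 0

    def test_close_peaks_larger_wins(self):
        z = np.zeros(4000)
        z[1000] = 2.0
        z[1050] = 3.0
        got = detect_candidate_peaks(_trace(z), threshold=1.0,
                                     min_separation=200)
        # brute-force oracle: enumerate supra-threshold local maxima,
        # keep greedily by magnitude under the separation constraint
        mag = np.abs(z)
        cands = [i for i in range(1, z.size - 1)
                 if mag[i] >= 1.0 and mag[i] > mag[i - 1] and mag[i] >= mag[i + 1]]
        keep: list[int] = []
        for i in sorted(cands, key=lambda k: -mag[k]):
            if all(abs(i - j) >= 200 for j in keep):
                keep.append(i)
        assert sorted(keep) == got.tolist() == [1050]

    def test_high_snr_kicks_recovered(self):
        # drift off: a high-pass-filtered posture step is itself a genuine
        # above-threshold transient, so specificity is defined against the
        # respiration+noise background
        cfg = fm.SynthConfig(duration_s=300.0, kick_rate=2.0, laugh_rate=0.0,
                             kick_amp=20.0, noise_sigma=0.5, drift_step_amp=0.0,
                             count_mode="expected", seed=17)
        sess, truth = fm.synth_session(cfg)
        filt = fm.highpass_filter(fm.select_z_axis(sess))
        peaks = detect_candidate_peaks(filt)
        assert len(truth) == 10
        assert peaks.size == 10
        for ev in truth:
            sl = slice(ev.onset_idx, ev.onset_idx + int(ev.duration_s * FS))
            true_peak = ev.onset_idx + int(np.argmax(np.abs(filt.z[sl])))
            assert np.min(np.abs(peaks - true_peak)) <= 20

    def test_event_free_session_yields_no_candidates(self):
        cfg = fm.SynthConfig(duration_s=300.0, kick_rate=0, laugh_rate=0,
                             drift_step_amp=0.0, seed=23)
        sess, _ = fm.synth_session(cfg)
        filt = fm.highpass_filter(fm.select_z_axis(sess))
        assert detect_candidate_peaks(filt).size == 0

    def test_threshold_is_robust_scale(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 2.0, size=100_000)
        thr = adaptive_threshold(z)
        assert 10.0 < thr < 20.0  # approx (median|z| + 7 sigma) for sigma=2


class TestBuildTrainingSet:
    def _session(self, seed=31):
        cfg = fm.SynthConfig(duration_s=300.0, seed=seed)
        sess, truth = fm.synth_session(cfg)
        filt = fm.highpass_filter(fm.select_z_axis(sess))
        return sess, filt, truth

    def test_count_bookkeeping(self):
        sess, filt, _ = self._session()
        ds = build_training_set([(sess, filt)], n_respiratory_per_session=3,
                                seed=0)
        counts = ds.class_counts
        assert counts[MovementClass.FETAL] == sess.btn1_idx.size
        assert counts[MovementClass.LAUGH] == sess.btn2_idx.size
        assert counts[MovementClass.RESPIRATORY] == 3

    def test_window_centred_on_event_not_press(self):
        sess, filt, truth = self._session()
        ds = build_training_set([(sess, filt)], n_respiratory_per_session=0,
                                seed=0)
        kicks = [r for r in ds.realizations if r.label == MovementClass.FETAL]
        events = [e for e in truth if e.kind == "kick"]
        assert len(kicks) == len(events)
        hits = 0
        for r in kicks:
            d = min(abs(r.origin_idx - e.onset_idx) for e in events)
            if d <= int(1.0 * FS):  # within the event, far from the press lag
                hits += 1
        assert hits >= 0.95 * len(kicks)

    def test_zero_presses_only_respiratory(self):
        cfg = fm.SynthConfig(duration_s=60.0, kick_rate=0, laugh_rate=0, seed=2)
        sess, _ = fm.synth_session(cfg)
        filt = fm.highpass_filter(fm.select_z_axis(sess))
        ds = build_training_set([(sess, filt)], n_respiratory_per_session=4,
                                seed=1)
        assert ds.class_counts[MovementClass.RESPIRATORY] == len(ds) == 4

    def test_all_windows_are_200_samples_peak_at_100(self):
        sess, filt, _ = self._session(seed=37)
        ds = build_training_set([(sess, filt)], n_respiratory_per_session=5,
                                seed=0)
        for r in ds.realizations:
            assert r.samples.shape == (WINDOW_LEN,)
            if r.label != MovementClass.RESPIRATORY:
                assert int(np.argmax(np.abs(r.samples))) == PEAK_POS

    def test_truth_kick_peaks_recovered_high_snr(self):
        """>= 95% of truth kicks are re-centred within +-20 samples."""
        cfg = fm.SynthConfig(duration_s=600.0, kick_amp=20.0, noise_sigma=0.5,
                             laugh_rate=0.0, seed=41)
        sess, truth = fm.synth_session(cfg)
        filt = fm.highpass_filter(fm.select_z_axis(sess))
        ds = build_training_set([(sess, filt)], n_respiratory_per_session=0,
                                seed=0)
        recovered = 0
        events = [e for e in truth if e.kind == "kick"]
        for ev in events:
            sl = slice(ev.onset_idx, ev.onset_idx + int(ev.duration_s * FS))
            true_peak = ev.onset_idx + int(np.argmax(np.abs(filt.z[sl])))
            if any(abs(r.origin_idx - true_peak) <= 20 for r in ds.realizations):
                recovered += 1
        assert recovered >= 0.95 * len(events)
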