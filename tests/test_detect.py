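import itertools

import numpy as np
import pytest

from specd.detect import (
    DetectorPostprocessConfig,
    binary_trace_events,
    build_detection_labels,
    causal_moving_average,
    extract_events,
    fit_detector,
    recognition_latency,
    stream_probabilities,
)
from specd.session import CLASS_INDEX, DetectedEvent, TrialRecord, TrueEvent


def oracle_events(b, t_on, t_off, sr=200.0):
    """Independent run-length oracle for the event state machine.

    Works on the run-length encoding of the binary trace: an event starts at
    the first run of >= t_on consecutive ones reached from the idle state,
    stays active across zero-gaps shorter than t_off, and ends at the last
    one-sample before a zero-gap of >= t_off (or the end of the trace).
    """
    runs = [(k, len(list(g))) for k, g in itertools.groupby(np.asarray(b, dtype=bool))]
    events = []
    pos = 0
    active = False
    onset = last_one = None
    for value, length in runs:
        if value:
            if not active and length >= t_on:
                active = True
                onset = pos
            if active:
                last_one = pos + length - 1
        else:
            if active and length >= t_off:
                events.append((onset, last_one))
                active = False
        pos += length
    if active:
        events.append((onset, last_one))
    return [
        DetectedEvent(
            onset_s=a / sr,
            offset_s=z / sr,
            onset_recognized_s=(a + t_on) / sr,
            offset_recognized_s=(z + t_off) / sr,
        )
        for a, z in events
    ]


def _same_events(a, b):
    if len(a) != len(b):
        return False
    return all(
        x.onset_s == y.onset_s
        and x.offset_s == y.offset_s
        and x.onset_recognized_s == y.onset_recognized_s
        and x.offset_recognized_s == y.offset_recognized_s
        for x, y in zip(a, b)
    )


class TestExtractEvents:
    def test_clean_step_recognized_after_time_threshold(self):
        sr = 200.0
        b = np.zeros(1400, dtype=bool)
        b[400:1001] = True  # high exactly on [2.0, 5.0] s
        events = binary_trace_events(b, t_on=100, t_off=100, sample_rate_hz=sr)
        assert len(events) == 1
        e = events[0]
        assert e.onset_s == pytest.approx(2.0)
        assert e.onset_recognized_s == pytest.approx(2.5)
        assert e.offset_s == pytest.approx(5.0)
        assert e.offset_recognized_s == pytest.approx(5.5)

    def test_short_run_produces_no_event(self):
        b = np.zeros(1000, dtype=bool)
        b[100:160] = True  # 0.3 s < 0.5 s time threshold
        assert binary_trace_events(b, 100, 100) == []

    def test_trace_shorter_than_t_on_gives_no_events(self):
        assert binary_trace_events(np.ones(50, dtype=bool), 100, 100) == []

    def test_zero_gap_shorter_than_t_off_merges(self):
        b = np.ones(500, dtype=bool)
        b[200:250] = False  # 50-sample gap < t_off=100
        events = binary_trace_events(b, 100, 100)
        assert len(events) == 1
        assert events[0].offset_s == pytest.approx(499 / 200.0)

    def test_probability_trace_path(self):
        trace = np.zeros((1500, 5))
        trace[:, CLASS_INDEX["silence"]] = 1.0
        trace[500:1100, CLASS_INDEX["silence"]] = 0.0
        trace[500:1100, CLASS_INDEX["speech"]] = 1.0
        events = extract_events(trace, DetectorPostprocessConfig(smooth_width=1))
        assert len(events) == 1
        assert events[0].onset_s == pytest.approx(2.5)

    def test_matches_oracle_on_random_long_traces(self):
        rng = np.random.default_rng(0)
        for i in range(100):
            b = rng.random(2000) < rng.uniform(0.2, 0.8)
            t_on = int(rng.integers(1, 30))
            t_off = int(rng.integers(1, 30))
            assert _same_events(
                binary_trace_events(b, t_on, t_off), oracle_events(b, t_on, t_off)
            )

    def test_matches_oracle_exhaustive_short(self):
        for L in range(1, 13):
            for m in range(2**L):
                b = np.array([(m >> i) & 1 for i in range(L)], dtype=bool)
                for t_on, t_off in ((1, 1), (2, 3), (3, 2)):
                    assert _same_events(
                        binary_trace_events(b, t_on, t_off), oracle_events(b, t_on, t_off)
                    )

    def test_event_count_monotone_in_threshold_on_bump_traces(self):
        # on unimodal, well-separated bumps raising the probability
        # threshold can only shrink or drop events, never split them
        rng = np.random.default_rng(1)
        t = np.arange(4000) / 200.0
        trace = np.zeros((4000, 5))
        p = np.zeros(4000)
        for c in (4.0, 9.0, 15.0):
            p += rng.uniform(0.5, 1.0) * np.exp(-((t - c) ** 2) / 0.5)
        trace[:, CLASS_INDEX["speech"]] = np.clip(p, 0, 1)
        trace[:, CLASS_INDEX["silence"]] = 1 - trace[:, CLASS_INDEX["speech"]]
        counts = []
        for theta in (0.1, 0.3, 0.5, 0.7, 0.9):
            cfg = DetectorPostprocessConfig(smooth_width=20, prob_threshold=theta)
            counts.append(len(extract_events(trace, cfg)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DetectorPostprocessConfig(prob_threshold=0.0)
        with pytest.raises(ValueError):
            DetectorPostprocessConfig(t_on=0)


def test_causal_moving_average():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    out = causal_moving_average(x, 2)
    assert np.allclose(out, [1.0, 1.5, 2.5, 3.5])


class TestBuildLabels:
    def _speech_trial(self, pres=3.0, cue=5.0, end=9.0):
        return TrialRecord("speech", 0, pres, cue, end, cue + 0.2, cue + 2.0)

    def test_scheme_a_extent(self):
        labels, mask = build_detection_labels([self._speech_trial()], 2200)
        sp = CLASS_INDEX["speech"]
        assert labels[1000] == sp  # 5.0 s
        assert labels[1549] == sp  # just before 7.75 s
        assert labels[1551] != sp
        assert np.all(labels[600:1000] == CLASS_INDEX["preparation"])
        # ambiguous tail masked out
        assert not mask[1600]
        assert mask[500]

    def test_scheme_b_85_percent(self):
        t = self._speech_trial(cue=5.0, end=9.0)  # 4 s post-cue duration
        labels, _ = build_detection_labels([t], 2200, scheme="B")
        sp = CLASS_INDEX["speech"]
        assert labels[int(200 * (5.0 + 3.39))] == sp
        assert labels[int(200 * (5.0 + 3.41))] != sp

    def test_rest_is_all_silence_unmasked(self):
        labels, mask = build_detection_labels([], 1000)
        assert np.all(labels == CLASS_INDEX["silence"])
        assert np.all(mask)

    def test_perceptual_trials(self):
        trials = [
            TrialRecord("listening", 1, 2.0, 2.0, 6.0, stimulus_end_s=4.0),
            TrialRecord("reading", 2, 8.0, 8.0, 12.0, stimulus_end_s=10.0),
        ]
        labels, _ = build_detection_labels(trials, 2600)
        assert np.all(labels[400:800] == CLASS_INDEX["listening"])
        assert np.all(labels[1600:2000] == CLASS_INDEX["reading"])
        assert np.all(labels[800:1600] == CLASS_INDEX["silence"])

    def test_overlapping_trials_error(self):
        trials = [self._speech_trial(3.0, 5.0, 9.0), self._speech_trial(8.0, 10.0, 14.0)]
        with pytest.raises(ValueError):
            build_detection_labels(trials, 4000)

    def test_self_paced_trial_labels_attempt_span(self):
        t = TrialRecord("speech", 0, 2.0, 2.0, 12.0, 6.0, 8.0)
        labels, _ = build_detection_labels([t], 2600)
        assert np.all(labels[1200:1600] == CLASS_INDEX["speech"])
        assert labels[1000] == CLASS_INDEX["silence"]


class TestRecognitionLatency:
    def test_additivity(self):
        true = TrueEvent(10.0, 12.0)
        det = DetectedEvent(10.2, 12.1, 10.7, 12.6)
        out = recognition_latency([(true, det)])
        assert out["median_onset_latency_s"] == pytest.approx(0.7)
        assert out["median_offset_latency_s"] == pytest.approx(0.6)

    def test_empty_matches(self):
        assert recognition_latency([]) == {}


class TestDetectorTraining:
    def test_determinism(self, train_sessions):
        from specd.detect import DetectorHyper

        tiny = DetectorHyper(hidden=8, epochs=2, chunk_s=2.0, seed=3)
        subset = ("silence", "preparation", "speech")
        a = fit_detector([train_sessions["speech"]], tiny, class_subset=subset)
        b = fit_detector([train_sessions["speech"]], tiny, class_subset=subset)
        for pa, pb in zip(a.net.params, b.net.params):
            assert np.array_equal(pa, pb)

    def test_probabilities_row_stochastic_and_causal(self, detector_full, eval_sessions):
        s = eval_sessions["rest"]
        p = stream_probabilities(detector_full, s)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
        # rest block: silence dominates
        assert np.all(p.mean(axis=0)[CLASS_INDEX["silence"]] >= p.mean(axis=0))

    def test_held_out_frame_accuracy(self, detector_full, eval_sessions):
        accs = []
        for s in eval_sessions.values():
            p = stream_probabilities(detector_full, s)
            m = s.train_mask
            accs.append(np.mean(p.argmax(1)[m] == s.labels[m]))
        assert np.mean(accs) > 0.7

    def test_ablated_model_keeps_5_way_head(self, detector_speech_only, eval_sessions):
        p = stream_probabilities(detector_speech_only, eval_sessions["rest"])
        assert p.shape[1] == 5

    def test_feature_width_mismatch_errors(self, detector_full):
        from specd.simulate import SimConfig, simulate_session

        bad = simulate_session(SimConfig(n_electrodes=5, n_trials=2, seed=0))
        with pytest.raises(ValueError):
            stream_probabilities(detector_full, bad)

    def test_missing_class_errors(self, train_sessions):
        with pytest.raises(ValueError):
            fit_detector([train_sessions["rest"]], class_subset=("silence", "speech"))
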