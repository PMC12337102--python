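"""Streaming 5-class speech detection and event extraction.

The detector is a stack of unidirectional LSTM layers with a per-frame
linear read-out over {silence, preparation, speech, reading, listening},
run causally over the 200 Hz feature streams.  The continuous speech-class
probability is smoothed with a causal moving average, binarized with a
probability threshold, and turned into discrete events by a time-threshold
state machine: an onset is declared once the binary signal has been high
for T_on consecutive samples (and is recorded at the first sample of that
run); the offset is the last high sample before the signal stays low for
T_off consecutive samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FEATURE_RATE_HZ
from .nets import SequenceNet, fit_sequence_net
from .session import (
    CLASS_INDEX,
    CLASS_NAMES,
    DetectedEvent,
    NeuralSession,
    TrialRecord,
    TrueEvent,
)

SPEECH_EXTENT_A_S = 2.75  # post-go-cue speech label extent, scheme A
SPEECH_EXTENT_B_FRAC = 0.85  # fraction of post-go-cue trial duration, scheme B


@dataclass
class DetectorPostprocessConfig:
    smooth_width: int = 40  # samples, causal moving average
    prob_threshold: float = 0.5
    t_on: int = 100  # samples
    t_off: int = 100

    def __post_init__(self):
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("probability threshold must lie in (0, 1)")
        if self.t_on < 1 or self.t_off < 1:
            raise ValueError("time thresholds must be >= 1 sample")
        if self.smooth_width < 1:
            raise ValueError("smoothing width must be >= 1 sample")


@dataclass
class DetectorHyper:
    hidden: int = 64
    n_layers: int = 3
    epochs: int = 30
    learning_rate: float = 1e-3
    chunk_s: float = 10.0
    batch_size: int = 8
    seed: int = 0


def build_detection_labels(
    trials: list[TrialRecord],
    n_samples: int,
    sample_rate_hz: float = FEATURE_RATE_HZ,
    scheme: str = "A",
) -> tuple[np.ndarray, np.ndarray]:
    """Frame labels per the five-class convention; returns (labels, train_mask).

    Speech trials with a countdown: [presentation, go_cue) -> preparation,
    [go_cue, go_cue + extent) -> speech where the extent is 2.75 s (scheme
    "A") or 85% of the post-go-cue trial duration (scheme "B"); the
    ambiguous tail up to the trial end is masked out of training.  Speech
    trials without a countdown (self-paced blocks) label the annotated
    attempt span directly.  Listening/reading trials label the stimulus
    span; everything else is silence.
    """
    if scheme not in ("A", "B"):
        raise ValueError(f"unknown label scheme {scheme!r}")
    labels = np.zeros(n_samples, dtype=np.int8)
    mask = np.ones(n_samples, dtype=bool)
    sr = sample_rate_hz

    def _idx(t: float) -> int:
        return min(max(int(round(t * sr)), 0), n_samples)

    ordered = sorted(trials, key=lambda t: t.presentation_s)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.presentation_s < prev.trial_end_s - 1e-9:
            raise ValueError("overlapping trials")

    for t in ordered:
        if t.task in ("speech", "nonspeech_motor"):
            if t.task == "nonspeech_motor":
                continue  # not a detector training class; stays silence
            if t.go_cue_s > t.presentation_s:
                labels[_idx(t.presentation_s) : _idx(t.go_cue_s)] = CLASS_INDEX["preparation"]
                if scheme == "A":
                    extent = SPEECH_EXTENT_A_S
                else:
                    extent = SPEECH_EXTENT_B_FRAC * (t.trial_end_s - t.go_cue_s)
                speech_end = min(t.go_cue_s + extent, t.trial_end_s)
                labels[_idx(t.go_cue_s) : _idx(speech_end)] = CLASS_INDEX["speech"]
                mask[_idx(speech_end) : _idx(t.trial_end_s)] = False
            else:
                # self-paced: annotated attempt span
                labels[_idx(t.attempt_onset_s) : _idx(t.attempt_offset_s)] = CLASS_INDEX["speech"]
        elif t.task in ("listening",):
            labels[_idx(t.presentation_s) : _idx(t.stimulus_end_s)] = CLASS_INDEX["listening"]
        elif t.task in ("reading", "reading_sentence", "false_font"):
            labels[_idx(t.presentation_s) : _idx(t.stimulus_end_s)] = CLASS_INDEX["reading"]
    return labels, mask


@dataclass
class DetectorModel:
    net: SequenceNet
    class_subset: tuple[str, ...] = CLASS_NAMES
    hyper: DetectorHyper = field(default_factory=DetectorHyper)

    @property
    def n_features(self) -> int:
        return self.net.in_dim


def _chunk_session(
    X: np.ndarray, y: np.ndarray, m: np.ndarray, chunk: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = (X.shape[0] // chunk) * chunk
    cx = X[:n].reshape(-1, chunk, X.shape[1])
    cy = y[:n].reshape(-1, chunk)
    cm = m[:n].reshape(-1, chunk)
    keep = cm.any(axis=1)
    return cx[keep], cy[keep], cm[keep]


def fit_detector(
    sessions: NeuralSession | list[NeuralSession],
    hyper: DetectorHyper | None = None,
    class_subset: tuple[str, ...] | None = None,
) -> DetectorModel:
    """Train the streaming detector on labeled sessions.

    ``class_subset`` restricts the training classes for ablations: frames of
    excluded classes are relabeled as silence, so the model keeps its 5-way
    output head and post-processing is unchanged.  A requested class absent
    from the labels raises.
    """
    hyper = hyper or DetectorHyper()
    if isinstance(sessions, NeuralSession):
        sessions = [sessions]
    subset = tuple(class_subset) if class_subset else CLASS_NAMES
    for c in subset:
        if c not in CLASS_NAMES:
            raise ValueError(f"unknown class {c!r}")
    chunk = int(round(hyper.chunk_s * FEATURE_RATE_HZ))
    xs, ys, ms = [], [], []
    for s in sessions:
        if s.labels is None:
            raise ValueError("session has no label track")
        X = s.features()
        y = np.asarray(s.labels, dtype=np.int64).copy()
        m = (
            np.ones(len(y), dtype=bool)
            if s.train_mask is None
            else np.asarray(s.train_mask, dtype=bool).copy()
        )
        for i, name in enumerate(CLASS_NAMES):
            if name not in subset:
                y[y == i] = CLASS_INDEX["silence"]
        cx, cy, cm = _chunk_session(X, y, m, chunk)
        xs.append(cx)
        ys.append(cy)
        ms.append(cm)
    cx = np.concatenate(xs)
    cy = np.concatenate(ys)
    cm = np.concatenate(ms)
    present = set(np.unique(cy[cm]))
    for c in subset:
        if CLASS_INDEX[c] not in present:
            raise ValueError(f"requested class {c!r} absent from training labels")
    net = SequenceNet(
        in_dim=cx.shape[-1],
        hidden=hyper.hidden,
        n_classes=len(CLASS_NAMES),
        n_layers=hyper.n_layers,
        seed=hyper.seed,
    )
    fit_sequence_net(
        net, cx, cy, cm,
        epochs=hyper.epochs, lr=hyper.learning_rate,
        batch_size=hyper.batch_size, seed=hyper.seed,
    )
    return DetectorModel(net=net, class_subset=subset, hyper=hyper)


def stream_probabilities(model: DetectorModel, session: NeuralSession) -> np.ndarray:
    """Causal (time, 5) probability trace at 200 Hz over the whole session."""
    X = session.features()
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1]} != trained width {model.n_features}"
        )
    # process in segments, carrying the recurrent state (strictly causal)
    seg = 4000
    out = np.empty((X.shape[0], len(CLASS_NAMES)))
    state = None
    for start in range(0, X.shape[0], seg):
        x = X[None, start : start + seg]
        logits, state = model.net.forward_logits(x, state)
        from .nets import softmax

        out[start : start + x.shape[1]] = softmax(logits[0])
    return out


def causal_moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Mean of the trailing ``width`` samples (growing prefix at the start)."""
    c = np.cumsum(np.concatenate([[0.0], x]))
    idx = np.arange(1, len(x) + 1)
    lo = np.maximum(idx - width, 0)
    return (c[idx] - c[lo]) / (idx - lo)


def extract_events(
    trace: np.ndarray,
    cfg: DetectorPostprocessConfig | None = None,
    sample_rate_hz: float = FEATURE_RATE_HZ,
) -> list[DetectedEvent]:
    """Discrete events from a probability trace (or a precomputed binary one).

    ``trace`` is either (time, 5) row-stochastic probabilities -- in which
    case the speech-class column is smoothed and thresholded -- or an
    already-binary 1-D array, which skips smoothing/thresholding.
    """
    cfg = cfg or DetectorPostprocessConfig()
    trace = np.asarray(trace)
    if trace.ndim == 2:
        p = trace[:, CLASS_INDEX["speech"]]
        b = causal_moving_average(p, cfg.smooth_width) > cfg.prob_threshold
    else:
        b = trace.astype(bool)
    return binary_trace_events(b, cfg.t_on, cfg.t_off, sample_rate_hz)


def binary_trace_events(
    b: np.ndarray, t_on: int, t_off: int, sample_rate_hz: float = FEATURE_RATE_HZ
) -> list[DetectedEvent]:
    """Time-threshold state machine over a binary trace (vectorized scan)."""
    sr = sample_rate_hz
    events: list[DetectedEvent] = []
    active = False
    ones = 0
    zeros = 0
    onset_idx = -1
    last_one = -1
    for t, v in enumerate(np.asarray(b, dtype=bool)):
        if not active:
            if v:
                ones += 1
                if ones >= t_on:
                    active = True
                    onset_idx = t - t_on + 1
                    last_one = t
                    zeros = 0
            else:
                ones = 0
        else:
            if v:
                last_one = t
                zeros = 0
            else:
                zeros += 1
                if zeros >= t_off:
                    events.append(_make_event(onset_idx, last_one, t_on, t_off, sr))
                    active = False
                    ones = 0
                    zeros = 0
    if active:
        events.append(_make_event(onset_idx, last_one, t_on, t_off, sr))
    return events


def _make_event(onset_idx: int, last_one: int, t_on: int, t_off: int, sr: float) -> DetectedEvent:
    return DetectedEvent(
        onset_s=onset_idx / sr,
        offset_s=last_one / sr,
        onset_recognized_s=(onset_idx + t_on) / sr,
        offset_recognized_s=(last_one + t_off) / sr,
    )


def recognition_latency(
    matched: list[tuple[TrueEvent, DetectedEvent]],
) -> dict[str, float]:
    """Median onset/offset recognition latencies over matched event pairs."""
    if not matched:
        return {}
    onset = [d.onset_recognized_s - t.onset_s for t, d in matched]
    offset = [d.offset_recognized_s - t.offset_s for t, d in matched]
    return {
        "median_onset_latency_s": float(np.median(onset)),
        "median_offset_latency_s": float(np.median(offset)),
        "n": len(matched),
    }
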