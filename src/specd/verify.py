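"""Verification gate: attempted speech vs reading vs listening around d*.

A fixed window around each detected onset (4 s total by default) is
downsampled to 33.3 Hz and scored by an ensemble of conv+GRU classifiers;
an event is accepted as attempted speech only when the ensemble mean speech
probability strictly exceeds the acceptance threshold (0.65 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FEATURE_RATE_HZ
from .nets import WindowNet, fit_window_net
from .session import NeuralSession

VERIFIER_CLASSES = ("speech", "reading", "listening")
VERIFIER_CLASSES_MOTOR = ("speech", "reading", "listening", "nonspeech_motor")
DEFAULT_ACCEPT_THRESHOLD = 0.65


@dataclass
class EventWindowSpec:
    start_offset_s: float = -1.0
    end_offset_s: float = 3.0
    downsample_factor: int = 6

    def __post_init__(self):
        if not self.end_offset_s > self.start_offset_s:
            raise ValueError("window end must exceed start")
        if self.downsample_factor < 1:
            raise ValueError("downsample factor must be >= 1")

    @property
    def duration_s(self) -> float:
        return self.end_offset_s - self.start_offset_s

    @property
    def effective_rate_hz(self) -> float:
        return FEATURE_RATE_HZ / self.downsample_factor

    def n_steps(self, duration_s: float | None = None) -> int:
        dur = self.duration_s if duration_s is None else duration_s
        return int(round(dur * FEATURE_RATE_HZ)) // self.downsample_factor


@dataclass
class VerifierHyper:
    hidden: int = 64
    conv_width: int = 5
    n_gru_layers: int = 2
    n_members: int = 10
    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 32
    weight_decay: float = 0.0
    seed: int = 0


def downsample_window(window: np.ndarray, factor: int) -> np.ndarray:
    """Average non-overlapping blocks of ``factor`` samples along time."""
    n = (window.shape[0] // factor) * factor
    return window[:n].reshape(-1, factor, window.shape[1]).mean(axis=1)


def event_window(
    session: NeuralSession,
    d_star_s: float,
    spec: EventWindowSpec | None = None,
    electrode_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Downsampled feature window around a detected onset, (time, 2E)."""
    spec = spec or EventWindowSpec()
    sr = session.sample_rate_hz
    start = int(round((d_star_s + spec.start_offset_s) * sr))
    n_src = int(round(spec.duration_s * sr))
    if start < 0 or start + n_src > session.n_samples:
        raise ValueError(f"window for event at {d_star_s:.3f} s out of session bounds")
    feats = session.features(electrode_mask)
    return downsample_window(feats[start : start + n_src], spec.downsample_factor)


@dataclass
class VerifierEnsemble:
    members: list[WindowNet]
    classes: tuple[str, ...]
    spec: EventWindowSpec
    accept_threshold: float = DEFAULT_ACCEPT_THRESHOLD

    def probabilities(self, windows: np.ndarray) -> np.ndarray:
        """Ensemble-mean class probabilities; windows (n, time, features)."""
        windows = np.asarray(windows)
        if windows.ndim == 2:
            windows = windows[None]
        return np.mean([m.probabilities(windows) for m in self.members], axis=0)


def fit_verifier(
    windows: np.ndarray,
    task_labels: np.ndarray,
    hyper: VerifierHyper | None = None,
    include_motor: bool = False,
    spec: EventWindowSpec | None = None,
) -> VerifierEnsemble:
    """Train K randomly initialized members on (n, time, feature) windows.

    ``task_labels`` are integer indices into ``VERIFIER_CLASSES`` (or the
    4-class variant when ``include_motor``).  Classes with very few examples
    emit a warning, not an error.
    """
    import warnings

    hyper = hyper or VerifierHyper()
    spec = spec or EventWindowSpec()
    classes = VERIFIER_CLASSES_MOTOR if include_motor else VERIFIER_CLASSES
    y = np.asarray(task_labels, dtype=np.int64)
    present = np.unique(y)
    if len(present) < 2:
        raise ValueError("need at least 2 classes to train the verifier")
    counts = np.bincount(y, minlength=len(classes))
    for ci in present:
        if counts[ci] < hyper.n_members:
            warnings.warn(
                f"class {classes[ci]!r} has only {counts[ci]} examples", stacklevel=2
            )
    members = []
    for k in range(hyper.n_members):
        net = WindowNet(
            in_dim=windows.shape[-1],
            n_classes=len(classes),
            hidden=hyper.hidden,
            conv_width=hyper.conv_width,
            n_gru_layers=hyper.n_gru_layers,
            seed=hyper.seed * 1000 + k,
        )
        fit_window_net(
            net, windows, y,
            epochs=hyper.epochs, lr=hyper.learning_rate,
            batch_size=hyper.batch_size, seed=hyper.seed * 1000 + k,
            weight_decay=hyper.weight_decay,
        )
        members.append(net)
    return VerifierEnsemble(members=members, classes=classes, spec=spec)


def verify(
    ensemble: VerifierEnsemble,
    window: np.ndarray,
    threshold: float | None = None,
) -> tuple[np.ndarray, bool]:
    """(class probabilities, accepted).  Accepted iff p(speech) > threshold."""
    threshold = ensemble.accept_threshold if threshold is None else threshold
    probs = ensemble.probabilities(window[None] if window.ndim == 2 else window)[0]
    return probs, bool(probs[0] > threshold)


def threshold_sweep(
    speech_probs: np.ndarray,
    is_speech: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FP and FN rates (proportions of all evaluation events) vs threshold.

    A false positive is a non-speech event accepted; a false negative is a
    speech event rejected.  FP is non-increasing and FN non-decreasing in
    the threshold.
    """
    speech_probs = np.asarray(speech_probs, dtype=float)
    if speech_probs.size == 0:
        raise ValueError("no events to sweep")
    is_speech = np.asarray(is_speech, dtype=bool)
    thresholds = np.linspace(0.0, 1.0, 101) if thresholds is None else np.asarray(thresholds)
    n = len(speech_probs)
    accept = speech_probs[None, :] > thresholds[:, None]
    fp = np.sum(accept & ~is_speech[None, :], axis=1) / n
    fn = np.sum(~accept & is_speech[None, :], axis=1) / n
    return thresholds, fp, fn


def optimal_threshold(
    speech_probs: np.ndarray, is_speech: np.ndarray
) -> float:
    """Threshold minimizing FP + FN on a validation split."""
    thr, fp, fn = threshold_sweep(speech_probs, is_speech)
    return float(thr[np.argmin(fp + fn)])


def context_curve(
    windows: np.ndarray,
    task_labels: np.ndarray,
    is_speech_eval: np.ndarray,
    context_lengths_s: list[float],
    spec: EventWindowSpec | None = None,
    hyper: VerifierHyper | None = None,
    val_fraction: float = 0.25,
    seed: int = 0,
) -> dict[float, float]:
    """Accept/reject accuracy vs post-onset context length.

    For each context length L one ensemble is retrained on windows truncated
    at d* + L; the accept threshold is chosen on a validation split to
    minimize FP + FN, and accuracy is reported on the held-out remainder.
    """
    spec = spec or EventWindowSpec()
    hyper = hyper or VerifierHyper()
    rng = np.random.default_rng(seed)
    n = windows.shape[0]
    order = rng.permutation(n)
    n_val = max(int(round(val_fraction * n)), 1)
    val_idx, train_idx = order[:n_val], order[n_val:]
    results: dict[float, float] = {}
    for L in context_lengths_s:
        if L > spec.end_offset_s + 1e-9:
            raise ValueError(f"context length {L} exceeds window end {spec.end_offset_s}")
        n_keep = int(round((L - spec.start_offset_s) * spec.effective_rate_hz))
        n_keep = max(n_keep, hyper.conv_width + 1)
        trunc = windows[:, :n_keep, :]
        ens = fit_verifier(trunc[train_idx], task_labels[train_idx], hyper=hyper, spec=spec)
        val_p = ens.probabilities(trunc[val_idx])[:, 0]
        thr = optimal_threshold(val_p, is_speech_eval[val_idx])
        probs = ens.probabilities(trunc)[:, 0]
        accepted = probs > thr
        results[L] = float(np.mean(accepted == is_speech_eval))
    return results
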