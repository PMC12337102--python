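"""Shared fixtures.

Training-based fixtures are session-scoped and deliberately small (few
electrodes, short sessions, small hidden sizes) so the whole suite stays
within a desk-scale CPU budget while exercising the real training paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from specd.classify import ClassifierHyper, fit_classifier
from specd.detect import DetectorHyper, fit_detector
from specd.session import trial_windows
from specd.simulate import SimConfig, simulate_session
from specd.verify import VerifierHyper, downsample_window, fit_verifier

N_ELECTRODES = 12
SNR = 1.5


def make_task_sessions(seed: int, n_trials: int = 10, **kw):
    """One isolated-target session per task plus a rest block."""
    base = dict(n_electrodes=N_ELECTRODES, snr=SNR, **kw)
    out = {
        task: simulate_session(SimConfig(**base, n_trials=n_trials, task=task, seed=seed + i))
        for i, task in enumerate(("speech", "reading", "listening"))
    }
    out["rest"] = simulate_session(
        SimConfig(**base, schedule="rest", longform_s=30.0, seed=seed + 9)
    )
    return out


def downsampled_trial_windows(session, align="go_cue", window=(-1.0, 3.0), factor=6):
    w = trial_windows(session, align=align, window=window)
    return np.stack([downsample_window(x, factor) for x in w])


SMALL_DETECTOR_HYPER = DetectorHyper(
    hidden=24, epochs=12, learning_rate=3e-3, chunk_s=3.0, batch_size=16, seed=0
)
SMALL_VERIFIER_HYPER = VerifierHyper(
    hidden=24, n_members=3, epochs=12, learning_rate=3e-3, seed=0
)
SMALL_CLASSIFIER_HYPER = ClassifierHyper(
    hidden=24, n_members=3, epochs=20, learning_rate=3e-3, seed=0
)


@pytest.fixture(scope="session")
def train_sessions():
    return make_task_sessions(seed=10)


@pytest.fixture(scope="session")
def eval_sessions():
    return make_task_sessions(seed=50)


@pytest.fixture(scope="session")
def detector_full(train_sessions):
    return fit_detector(list(train_sessions.values()), SMALL_DETECTOR_HYPER)


@pytest.fixture(scope="session")
def detector_speech_only(train_sessions):
    return fit_detector(
        [train_sessions["speech"], train_sessions["rest"]],
        SMALL_DETECTOR_HYPER,
        class_subset=("silence", "preparation", "speech"),
    )


@pytest.fixture(scope="session")
def verifier_data():
    """Onset-aligned downsampled windows for 3 tasks, 30 trials each."""
    wins, labels = [], []
    for ci, task in enumerate(("speech", "reading", "listening")):
        s = simulate_session(
            SimConfig(n_electrodes=N_ELECTRODES, snr=SNR, n_trials=30, task=task, seed=20 + ci)
        )
        wins.append(downsampled_trial_windows(s, align="onset"))
        labels.append(np.full(30, ci))
    return np.concatenate(wins), np.concatenate(labels)


@pytest.fixture(scope="session")
def verifier_split(verifier_data):
    X, y = verifier_data
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(y))
    return X, y, idx[:60], idx[60:]


@pytest.fixture(scope="session")
def trained_verifier(verifier_split):
    X, y, tr, _ = verifier_split
    return fit_verifier(X[tr], y[tr], SMALL_VERIFIER_HYPER)


@pytest.fixture(scope="session")
def classifier_session():
    """High-SNR 10-word speech session with strong word tuning."""
    return simulate_session(
        SimConfig(
            n_electrodes=N_ELECTRODES, n_trials=150, task="speech",
            seed=30, word_tuning_sigma=0.5, snr=SNR,
        )
    )


@pytest.fixture(scope="session")
def classifier_split(classifier_session):
    X = downsampled_trial_windows(classifier_session)
    y = np.array([t.word for t in classifier_session.trials])
    return X, y, np.arange(120), np.arange(120, 150)


@pytest.fixture(scope="session")
def trained_classifier(classifier_split):
    X, y, tr, _ = classifier_split
    return fit_classifier(X[tr], y[tr], SMALL_CLASSIFIER_HYPER)
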