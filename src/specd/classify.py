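"""Closed-vocabulary word classification of verified event windows.

Ensembles of conv+GRU networks map a downsampled feature window to a
distribution over the vocabulary.  Also houses the time-window retraining
analysis (decoding from [-2,0], [-1,1] and [0,2] s around the go-cue with
electrode-set ablations) and cross-task transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nets import WindowNet, fit_window_net

DEFAULT_TIME_WINDOWS = ((-2.0, 0.0), (-1.0, 1.0), (0.0, 2.0))
ABLATION_CONDITIONS = ("all", "no_shared", "no_articulatory")


@dataclass
class ClassifierHyper:
    hidden: int = 64
    conv_width: int = 5
    n_gru_layers: int = 2
    n_members: int = 10
    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 32
    weight_decay: float = 0.0
    seed: int = 0


@dataclass
class WordClassifierEnsemble:
    members: list[WindowNet]
    vocab_size: int
    electrode_mask: np.ndarray | None = None

    def probabilities(self, windows: np.ndarray) -> np.ndarray:
        windows = np.asarray(windows)
        if windows.ndim == 2:
            windows = windows[None]
        return np.mean([m.probabilities(windows) for m in self.members], axis=0)


def apply_electrode_mask(windows: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    """Drop channels of masked-out electrodes from (n, time, 2E) windows."""
    if mask is None:
        return windows
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("electrode mask keeps no electrodes")
    if windows.shape[-1] != 2 * mask.size:
        raise ValueError("window feature width != 2 x electrode count")
    return windows[..., np.concatenate([mask, mask])]


def fit_classifier(
    windows: np.ndarray,
    word_labels: np.ndarray,
    hyper: ClassifierHyper | None = None,
    electrode_mask: np.ndarray | None = None,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> WordClassifierEnsemble:
    """Train an ensemble on (n, time, 2E) windows with integer word labels."""
    hyper = hyper or ClassifierHyper()
    y = np.asarray(word_labels, dtype=np.int64)
    vocab = int(y.max()) + 1
    counts = np.bincount(y, minlength=vocab)
    if np.any(counts < 2):
        raise ValueError("every vocabulary word needs >= 2 examples")
    X = apply_electrode_mask(windows, electrode_mask)
    X_val = y_val = None
    if validation is not None:
        X_val = apply_electrode_mask(validation[0], electrode_mask)
        y_val = np.asarray(validation[1], dtype=np.int64)
    members = []
    for k in range(hyper.n_members):
        net = WindowNet(
            in_dim=X.shape[-1],
            n_classes=vocab,
            hidden=hyper.hidden,
            conv_width=hyper.conv_width,
            n_gru_layers=hyper.n_gru_layers,
            seed=hyper.seed * 1000 + k,
        )
        fit_window_net(
            net, X, y,
            epochs=hyper.epochs, lr=hyper.learning_rate,
            batch_size=hyper.batch_size, seed=hyper.seed * 1000 + k,
            X_val=X_val, y_val=y_val, weight_decay=hyper.weight_decay,
        )
        members.append(net)
    return WordClassifierEnsemble(members=members, vocab_size=vocab, electrode_mask=electrode_mask)


def classify(
    ensemble: WordClassifierEnsemble, window: np.ndarray
) -> tuple[np.ndarray, int]:
    """(word distribution, top word).  Ties break to the lowest index."""
    X = window[None] if window.ndim == 2 else window
    X = apply_electrode_mask(X, ensemble.electrode_mask)
    dist = ensemble.probabilities(X)[0]
    return dist, int(np.argmax(dist))  # argmax returns the first (lowest) index on ties


def timewindow_retrain(
    session,
    shared_set: np.ndarray,
    articulatory_set: np.ndarray,
    window_specs: tuple[tuple[float, float], ...] = DEFAULT_TIME_WINDOWS,
    hyper: ClassifierHyper | None = None,
    folds: int = 10,
    members_per_fold: int = 5,
    seed: int = 0,
    speech_trials=None,
) -> dict[tuple[float, float], dict[str, object]]:
    """Per time window x ablation condition: CV accuracies and contributions.

    ``shared_set`` / ``articulatory_set`` are boolean electrode masks (from
    the mapping module or simulator ground truth); they must be disjoint.
    Returns ``{window: {condition: fold accuracies, "contributions": map}}``.
    """
    from .evaluate import crossval
    from .mapping import contributions
    from .session import trial_windows

    shared_set = np.asarray(shared_set, dtype=bool)
    articulatory_set = np.asarray(articulatory_set, dtype=bool)
    if np.any(shared_set & articulatory_set):
        raise ValueError("shared and articulatory electrode sets overlap")
    hyper = hyper or ClassifierHyper()
    trials = speech_trials or [t for t in session.trials if t.task == "speech"]
    words = np.array([t.word for t in trials])
    all_mask = np.ones(session.n_electrodes, dtype=bool)
    conditions = {
        "all": all_mask,
        "no_shared": all_mask & ~shared_set,
        "no_articulatory": all_mask & ~articulatory_set,
    }
    out: dict[tuple[float, float], dict[str, object]] = {}
    for win in window_specs:
        windows = trial_windows(session, trials, align="go_cue", window=win)
        from .verify import downsample_window

        windows = np.stack([downsample_window(w, 6) for w in windows])
        res: dict[str, object] = {}
        for name, mask in conditions.items():
            res[name] = crossval(
                windows, words,
                folds=folds, members_per_fold=members_per_fold,
                hyper=hyper, electrode_mask=mask, seed=seed,
            )
        ens = fit_classifier(windows, words, hyper=hyper)
        res["contributions"] = contributions(ens, windows, words)
        out[win] = res
    return out


def cross_task_transfer(
    ensembles_a: list[WordClassifierEnsemble],
    fold_windows_b: list[np.ndarray],
    fold_labels_b: list[np.ndarray],
) -> np.ndarray:
    """Accuracy of task-A-trained fold ensembles on task-B fold windows."""
    if len(ensembles_a) != len(fold_windows_b):
        raise ValueError("one ensemble per evaluation fold required")
    accs = []
    for ens, Xb, yb in zip(ensembles_a, fold_windows_b, fold_labels_b):
        if ens.vocab_size <= int(np.max(yb)):
            raise ValueError("vocabulary mismatch between tasks")
        X = apply_electrode_mask(Xb, ens.electrode_mask)
        pred = np.argmax(ens.probabilities(X), axis=1)
        accs.append(float(np.mean(pred == yb)))
    return np.asarray(accs)
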