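"""Offline neural analyses: responsiveness, contributions, band power.

Per-electrode task responsiveness uses one-sided rank-sum tests between
trial-mean HGA in a pre-stimulus baseline and a task-specific post-onset
window, Holm-corrected across electrodes.  Electrode contributions are the
time-wise L2 norm of the gradient of a model's loss with respect to its
inputs.  Theta/beta band power is estimated with a DPSS multitaper
(time-bandwidth 3, 5 tapers) and compared across tasks as z-scored
pseudo-block means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal.windows import dpss

from .evaluate import holm_bonferroni
from .features import FEATURE_RATE_HZ
from .session import NeuralSession, trial_windows

#: post-onset analysis window per task (seconds from go-cue/stimulus onset)
TASK_ANALYSIS_WINDOWS = {
    "speech": (0.0, 1.0),
    "reading": (0.0, 1.0),
    "listening": (0.5, 1.0),
    "nonspeech_motor": (0.0, 1.0),
}
BASELINE_WINDOW_S = (-1.0, 0.0)  # relative to stimulus presentation


@dataclass
class ResponsivenessMap:
    task: str
    z_statistic: np.ndarray  # per electrode
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray  # adjusted p < alpha
    alpha: float = 0.05

    @property
    def display_statistic(self) -> np.ndarray:
        """Z with negative values (higher baseline activity) set to 0."""
        return np.maximum(self.z_statistic, 0.0)


@dataclass
class SpectralConfig:
    theta_band: tuple[float, float] = (5.0, 12.0)
    beta_band: tuple[float, float] = (20.0, 30.0)
    analysis_window_s: tuple[float, float] = (0.0, 2.0)
    pseudo_block_trials: int = 60
    time_bandwidth: float = 3.0
    n_tapers: int = 5


def responsiveness(
    session: NeuralSession,
    task: str,
    alpha: float = 0.05,
    trials=None,
) -> ResponsivenessMap:
    """Per-electrode one-sided (post > pre) rank-sum test on trial-mean HGA."""
    if task not in TASK_ANALYSIS_WINDOWS:
        raise ValueError(f"unknown task {task!r}")
    trials = trials if trials is not None else [t for t in session.trials if t.task == task]
    if len(trials) < 2:
        raise ValueError("need at least 2 trials")
    E = session.n_electrodes
    pre = trial_windows(session, trials, align="presentation", window=BASELINE_WINDOW_S)
    anchor = "go_cue" if task in ("speech", "nonspeech_motor") else "presentation"
    post = trial_windows(session, trials, align=anchor, window=TASK_ANALYSIS_WINDOWS[task])
    pre_hga = pre[:, :, :E].mean(axis=1)  # (trials, electrodes)
    post_hga = post[:, :, :E].mean(axis=1)
    z = np.empty(E)
    p = np.empty(E)
    for e in range(E):
        res = stats.ranksums(post_hga[:, e], pre_hga[:, e], alternative="greater")
        z[e] = res.statistic
        p[e] = res.pvalue
    adj = holm_bonferroni(p)
    return ResponsivenessMap(
        task=task, z_statistic=z, p_raw=p, p_adjusted=adj,
        significant=adj < alpha, alpha=alpha,
    )


@dataclass
class ElectrodeSets:
    shared: np.ndarray  # bool mask
    articulatory: np.ndarray | None = None

    def __post_init__(self):
        if self.articulatory is not None and np.any(self.shared & self.articulatory):
            raise ValueError("shared and articulatory electrode sets overlap")


def shared_set(
    maps: dict[str, ResponsivenessMap],
    articulatory: np.ndarray | None = None,
) -> ElectrodeSets:
    """Electrodes significant for all of speech, reading and listening."""
    for task in ("speech", "reading", "listening"):
        if task not in maps:
            raise ValueError(f"missing responsiveness map for {task!r}")
    shared = (
        maps["speech"].significant
        & maps["reading"].significant
        & maps["listening"].significant
    )
    return ElectrodeSets(shared=shared, articulatory=articulatory)


@dataclass
class ContributionMap:
    total: np.ndarray  # per electrode, >= 0
    hga: np.ndarray
    lfs: np.ndarray
    provenance: str = ""


def contributions(model, inputs: np.ndarray, labels: np.ndarray, provenance: str = "") -> ContributionMap:
    """Gradient-based electrode contributions.

    ``model`` is a window-classifier ensemble (or anything exposing
    ``members`` of nets with ``input_gradient``) evaluated on
    (n, time, 2E) inputs with true integer labels.  Per time course the
    L2 norm over time of dLoss/dinput is taken per channel, averaged over
    time courses and ensemble members, and split into HGA/LFS sub-scores.
    """
    members = getattr(model, "members", None)
    if members is None:
        members = [model]
    X = np.asarray(inputs)
    y = np.asarray(labels, dtype=np.int64)
    mask = getattr(model, "electrode_mask", None)
    if mask is not None:
        from .classify import apply_electrode_mask

        X = apply_electrode_mask(X, mask)
    n_feat = X.shape[-1]
    if n_feat % 2:
        raise ValueError("feature width must be 2 x electrode count (HGA + LFS)")
    e_in = n_feat // 2
    score = np.zeros(n_feat)
    for net in members:
        if not hasattr(net, "input_gradient"):
            raise TypeError("model is not differentiable (no input_gradient)")
        grad = net.input_gradient(X, y)  # (n, time, 2E)
        score += np.linalg.norm(grad, axis=1).mean(axis=0)
    score /= len(members)
    if mask is not None:
        full = np.zeros(2 * mask.size)
        idx = np.flatnonzero(np.concatenate([mask, mask]))
        full[idx] = score
        score = full
        e_in = mask.size
    hga, lfs = score[:e_in], score[e_in:]
    return ContributionMap(total=hga + lfs, hga=hga, lfs=lfs, provenance=provenance)


def multitaper_band_power(
    x: np.ndarray,
    band: tuple[float, float],
    sample_rate_hz: float = FEATURE_RATE_HZ,
    time_bandwidth: float = 3.0,
    n_tapers: int = 5,
) -> float:
    """Mean multitaper PSD in ``band`` for a 1-D segment."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if band[1] >= sample_rate_hz / 2:
        raise ValueError("band exceeds Nyquist")
    tapers = dpss(n, time_bandwidth, Kmax=n_tapers)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    spec = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2
    psd = spec.mean(axis=0) * 2.0 / sample_rate_hz
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(psd[sel].mean())


def band_power(
    sessions_by_task: dict[str, NeuralSession],
    cfg: SpectralConfig | None = None,
    electrodes: np.ndarray | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Pseudo-blocked, z-scored theta/beta LFS power per task.

    Per trial the mean multitaper power in each band over the analysis
    window (go-cue-relative for attempted speech, onset-relative otherwise)
    is averaged over the selected electrodes; trials are pseudo-blocked into
    consecutive groups and block means are z-scored across the pooled task
    distribution per band.  Returns ``{band: {task: block z-scores}}``.
    """
    cfg = cfg or SpectralConfig()
    bands = {"theta": cfg.theta_band, "beta": cfg.beta_band}
    per_task_power: dict[str, dict[str, np.ndarray]] = {b: {} for b in bands}
    for task, session in sessions_by_task.items():
        E = session.n_electrodes
        sel = np.ones(E, dtype=bool) if electrodes is None else np.asarray(electrodes, dtype=bool)
        trials = [t for t in session.trials if t.task == task]
        anchor = "go_cue" if task in ("speech", "nonspeech_motor") else "presentation"
        wins = trial_windows(session, trials, align=anchor, window=cfg.analysis_window_s)
        lfs = wins[:, :, E:][:, :, sel]  # (trials, time, electrodes)
        for bname, brange in bands.items():
            p = np.array(
                [
                    np.mean(
                        [
                            multitaper_band_power(
                                lfs[i, :, e], brange, session.sample_rate_hz,
                                cfg.time_bandwidth, cfg.n_tapers,
                            )
                            for e in range(lfs.shape[2])
                        ]
                    )
                    for i in range(lfs.shape[0])
                ]
            )
            n_blocks = len(p) // cfg.pseudo_block_trials
            if n_blocks < 1:
                raise ValueError(
                    f"need >= {cfg.pseudo_block_trials} trials per task for one pseudo-block"
                )
            blocks = p[: n_blocks * cfg.pseudo_block_trials].reshape(n_blocks, -1).mean(axis=1)
            per_task_power[bname][task] = blocks
    # z-score across the pooled distribution per band
    out: dict[str, dict[str, np.ndarray]] = {}
    for bname, task_blocks in per_task_power.items():
        pooled = np.concatenate(list(task_blocks.values()))
        mu, sd = pooled.mean(), pooled.std()
        sd = sd if sd > 0 else 1.0
        out[bname] = {task: (v - mu) / sd for task, v in task_blocks.items()}
    return out


def longform_activation(
    longform: NeuralSession,
    baseline: NeuralSession,
    n_points: int = 100,
    window_s: float = 4.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> ResponsivenessMap:
    """Rank-sum test of mean HGA at random timepoints, longform vs baseline.

    ``n_points`` random timepoints are sampled in each session such that the
    centred ``window_s`` window fits; the mean HGA per window feeds a
    per-electrode rank-sum test, Holm-corrected.  When the session holds at
    least ``n_points`` non-overlapping windows, distinct window slots are
    sampled so the rank-sum independence assumption holds; otherwise
    sampling falls back to uniform with replacement (anticonservative on
    short autocorrelated blocks).
    """
    if n_points < 2:
        raise ValueError("need at least 2 sampled timepoints")
    rng = np.random.default_rng(seed)
    half = window_s / 2.0

    def _sample_means(session: NeuralSession) -> np.ndarray:
        sr = session.sample_rate_hz
        w = int(round(window_s * sr))
        lo = int(np.ceil(half * sr))
        hi = session.n_samples - lo
        if hi <= lo:
            raise ValueError("session shorter than the sampling window")
        n_slots = session.n_samples // w
        if n_slots >= n_points:
            slots = rng.choice(n_slots, size=n_points, replace=False)
            starts = slots * w
        else:
            starts = rng.integers(lo, hi, size=n_points) - w // 2
        return np.stack([session.hga[s : s + w].mean(axis=0) for s in starts])

    lf = _sample_means(longform)
    bl = _sample_means(baseline)
    E = longform.n_electrodes
    z = np.empty(E)
    p = np.empty(E)
    for e in range(E):
        res = stats.ranksums(lf[:, e], bl[:, e], alternative="greater")
        z[e] = res.statistic
        p[e] = res.pvalue
    adj = holm_bonferroni(p)
    return ResponsivenessMap(
        task="longform", z_statistic=z, p_raw=p, p_adjusted=adj,
        significant=adj < alpha, alpha=alpha,
    )
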