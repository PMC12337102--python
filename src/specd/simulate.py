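"""Seeded synthetic sensorimotor-ECoG sessions with known ground truth.

The simulator emits normalized (z-unit) HGA and LFS streams at 200 Hz for a
grid of electrodes drawn from five functional classes:

``shared``
    task-evoked in attempted speech, reading and listening (strongest for
    speech), with pre-go-cue ramping activity whose amplitude is
    word-selective (``pre_cue`` tuning) -- the planning-like profile.
``articulatory``
    speech-evoked only, word-selective after the go-cue.
``auditory``
    listening- and speech-evoked, word-selective after stimulus onset.
``visual``
    reading-evoked (false fonts at a reduced gain).
``silent``
    noise only.

LFS carries theta (8 Hz) and beta (25 Hz) oscillations whose amplitudes are
modulated per task (suppressed during attempted speech, elevated during
perception).  Every source of randomness flows from ``SimConfig.seed``, so
identical configs produce bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .features import FEATURE_RATE_HZ
from .session import NeuralSession, TrialRecord, TrueEvent

CLASSES = ("shared", "articulatory", "auditory", "visual", "silent")
TASKS = ("speech", "reading", "listening", "nonspeech_motor")

_CLASS_REGION = {
    "shared": "midPrCG",
    "articulatory": "PrCG",
    "auditory": "temporal",
    "visual": "frontal",
    "silent": "other",
}

_CLASS_GAINS = {
    "shared": {"speech": 3.0, "reading": 2.0, "listening": 1.0, "nonspeech_motor": 0.3},
    "articulatory": {"speech": 3.0, "reading": 0.0, "listening": 0.0, "nonspeech_motor": 2.5},
    "auditory": {"speech": 1.5, "reading": 0.0, "listening": 3.0, "nonspeech_motor": 0.0},
    "visual": {"speech": 0.0, "reading": 2.5, "listening": 0.0, "nonspeech_motor": 0.0},
    "silent": {"speech": 0.0, "reading": 0.0, "listening": 0.0, "nonspeech_motor": 0.0},
}

_CLASS_TUNING_PHASE = {
    "shared": "pre_cue",
    "articulatory": "post_cue",
    "auditory": "post_cue",
    "visual": "none",
    "silent": "none",
}

# signed LFS amplitude modulation: suppression for attempted speech,
# elevation for perception, at task-responsive electrodes
_CLASS_BAND_MOD = {
    "shared": {"speech": -0.5, "reading": 0.3, "listening": 0.3, "nonspeech_motor": -0.3},
    "articulatory": {"speech": -0.5, "reading": 0.0, "listening": 0.0, "nonspeech_motor": -0.4},
    "auditory": {"speech": 0.0, "reading": 0.0, "listening": 0.3, "nonspeech_motor": 0.0},
    "visual": {"speech": 0.0, "reading": 0.3, "listening": 0.0, "nonspeech_motor": 0.0},
    "silent": {"speech": 0.0, "reading": 0.0, "listening": 0.0, "nonspeech_motor": 0.0},
}

FALSE_FONT_GAIN_SCALE = 0.25
LISTENING_EXTRA_LATENCY_S = 0.35


@dataclass
class ElectrodeProfile:
    region: str
    klass: str
    gains: dict[str, float]
    latency_s: float = 0.1
    pre_cue_ramp: float = 0.0
    word_tuning: dict[str, np.ndarray] = field(default_factory=dict)
    tuning_phase: str = "none"
    theta_mod: dict[str, float] = field(default_factory=dict)
    beta_mod: dict[str, float] = field(default_factory=dict)
    ar1: float = 0.95
    noise_std: float = 1.0

    def __post_init__(self):
        if self.klass not in CLASSES:
            raise ValueError(f"unknown electrode class {self.klass!r}")
        if any(g < 0 for g in self.gains.values()):
            raise ValueError("evoked gains must be >= 0")
        if self.klass == "shared" and not all(
            self.gains.get(t, 0) > 0 for t in ("speech", "reading", "listening")
        ):
            raise ValueError("shared electrodes need positive speech/reading/listening gains")
        for m in self.word_tuning.values():
            if np.any(np.asarray(m) <= 0):
                raise ValueError("word-tuning multipliers must be positive")

    def responsive(self, task: str) -> bool:
        """Designed ground truth: does this electrode respond to `task`?"""
        return self.gains.get(task, 0.0) > 0.0


@dataclass
class SimConfig:
    n_electrodes: int = 24
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "shared": 0.15,
            "articulatory": 0.20,
            "auditory": 0.15,
            "visual": 0.10,
            "silent": 0.40,
        }
    )
    vocab_size: int = 10
    schedule: str = "isolated_target"  # isolated_target | online | longform | rest
    task: str = "speech"  # isolated_target task / longform task
    condition: str = "baseline"  # online: baseline | reading | listening
    n_trials: int = 50
    countdown_s: float = 2.0  # presentation -> go-cue (speech/motor)
    trial_s: float = 4.0  # go-cue/onset -> trial end
    iti_s: float = 2.0
    stim_s: float = 2.0
    attempt_dur_s: float = 2.5
    attempt_delay_range: tuple[float, float] = (2.0, 8.0)  # online, self-paced
    longform_s: float = 120.0
    snr: float = 1.0
    word_tuning_sigma: float = 0.25
    word_code_mode: str = "independent"  # or "shared" (speech/listening share codes)
    gain_jitter: float = 0.1
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, expected 1")
        for name, value in (
            ("countdown_s", self.countdown_s),
            ("trial_s", self.trial_s),
            ("iti_s", self.iti_s),
            ("stim_s", self.stim_s),
            ("attempt_dur_s", self.attempt_dur_s),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be > 0")


def _largest_remainder_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    raw = {k: f * n for k, f in fractions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - counts[k]), list(raw).index(k)))
    for k in order[:short]:
        counts[k] += 1
    return counts


def make_grid(config: SimConfig) -> list[ElectrodeProfile]:
    """Deterministic electrode profiles; class counts by largest remainder."""
    if config.n_electrodes < 4:
        raise ValueError("need at least 4 electrodes")
    rng = np.random.default_rng(config.seed)
    counts = _largest_remainder_counts(config.class_fractions, config.n_electrodes)
    profiles: list[ElectrodeProfile] = []
    for klass in CLASSES:
        for i in range(counts.get(klass, 0)):
            gains = {
                t: g * (1.0 + config.gain_jitter * rng.uniform(-1, 1)) if g > 0 else 0.0
                for t, g in _CLASS_GAINS[klass].items()
            }
            tuning: dict[str, np.ndarray] = {}
            phase = _CLASS_TUNING_PHASE[klass]
            sig = config.word_tuning_sigma
            if klass in ("shared", "articulatory"):
                tuning["speech"] = rng.lognormal(0.0, sig, size=config.vocab_size)
            elif klass == "auditory":
                tuning["speech"] = rng.lognormal(0.0, sig, size=config.vocab_size)
                if config.word_code_mode == "shared":
                    tuning["listening"] = tuning["speech"].copy()
                else:
                    tuning["listening"] = rng.lognormal(0.0, sig, size=config.vocab_size)
            region = _CLASS_REGION[klass]
            if klass == "articulatory" and i % 2:
                region = "PoCG"
            profiles.append(
                ElectrodeProfile(
                    region=region,
                    klass=klass,
                    gains=gains,
                    latency_s=0.1,
                    pre_cue_ramp=1.5 if klass == "shared" else 0.0,
                    word_tuning=tuning,
                    tuning_phase=phase,
                    theta_mod=dict(_CLASS_BAND_MOD[klass]),
                    beta_mod=dict(_CLASS_BAND_MOD[klass]),
                )
            )
    return profiles


def evoked_kernel(sample_rate_hz: float = FEATURE_RATE_HZ, scale_s: float = 0.15) -> np.ndarray:
    """Peak-normalized gamma-density bump (shape 2), ~1 s wide at scale 0.25."""
    t = np.arange(0, 10 * scale_s, 1.0 / sample_rate_hz)
    k = stats.gamma.pdf(t, a=2.0, scale=scale_s)
    return k / k.max()


def _build_trials(config: SimConfig, rng: np.random.Generator) -> tuple[list[TrialRecord], float]:
    trials: list[TrialRecord] = []
    t = 5.0
    if config.schedule == "isolated_target":
        words = np.concatenate(
            [rng.permutation(config.vocab_size) for _ in range(int(np.ceil(config.n_trials / config.vocab_size)))]
        )[: config.n_trials]
        for i in range(config.n_trials):
            task = config.task
            if task in ("speech", "nonspeech_motor"):
                go_cue = t + config.countdown_s
                onset = go_cue + rng.uniform(0.05, 0.25)
                offset = onset + config.attempt_dur_s
                end = go_cue + config.trial_s
                trials.append(
                    TrialRecord(task, int(words[i]), t, go_cue, end, onset, offset, np.nan, i // config.vocab_size)
                )
            else:
                end = t + config.trial_s
                trials.append(
                    TrialRecord(task, int(words[i]), t, t, end,
                                np.nan, np.nan, t + config.stim_s, i // config.vocab_size)
                )
            t = end + config.iti_s
    elif config.schedule == "online":
        words = np.concatenate(
            [rng.permutation(config.vocab_size) for _ in range(int(np.ceil(config.n_trials / config.vocab_size)))]
        )[: config.n_trials]
        for i in range(config.n_trials):
            onset = t + rng.uniform(*config.attempt_delay_range)
            offset = onset + config.attempt_dur_s
            end = offset + 4.0  # screen cleared for 4 s
            trials.append(
                TrialRecord("speech", int(words[i]), t, t, end, onset, offset, np.nan, 0, config.condition)
            )
            t = end
    elif config.schedule in ("longform", "rest"):
        t += config.longform_s
    else:
        raise ValueError(f"unknown schedule {config.schedule!r}")
    return trials, t + 5.0


def simulate_session(config: SimConfig) -> NeuralSession:
    """Generate one seeded synthetic session (see module docstring)."""
    if config.vocab_size < 2:
        raise ValueError("vocabulary size must be >= 2 for word tuning")
    profiles = make_grid(config)
    rng = np.random.default_rng(config.seed + 1)
    trials, duration_s = _build_trials(config, rng)
    sr = FEATURE_RATE_HZ
    T = int(round(duration_s * sr))
    E = len(profiles)
    kernel = evoked_kernel(sr)

    # perceptual background pulses: continuous stimulus stream for online
    # perceptual conditions and longform perceptual blocks
    background: list[tuple[str, float]] = []  # (task, onset_s)
    if config.schedule == "online" and config.condition in ("reading", "listening"):
        span = (2.0, duration_s - 5.0)
        t0 = span[0]
        while t0 < span[1]:
            background.append((config.condition, t0))
            t0 += rng.uniform(1.2, 2.2)
    elif config.schedule == "longform" and config.task in ("reading", "listening"):
        t0 = 5.0
        while t0 < duration_s - 5.0:
            background.append((config.task, t0))
            t0 += rng.uniform(1.2, 2.2)

    hga = np.empty((T, E))
    lfs = np.empty((T, E))
    tt = np.arange(T) / sr
    theta_base, beta_base = 0.7, 0.7

    # sustained evoked envelopes: boxcar over the response span convolved
    # with the unimodal kernel, peak-normalized (cached per duration)
    env_cache: dict[int, np.ndarray] = {}

    def _envelope(dur_s: float) -> np.ndarray:
        n = max(int(round(dur_s * sr)), 1)
        if n not in env_cache:
            env = signal.fftconvolve(np.ones(n), kernel)
            env_cache[n] = env / env.max()
        return env_cache[n]

    # per-trial modulation envelopes are shared across electrodes up to the
    # per-electrode signed modulation coefficients
    def _evoked_task(trial: TrialRecord) -> str:
        return {"false_font": "reading", "reading_sentence": "reading"}.get(trial.task, trial.task)

    # fraction of the evoked/ramp component mirrored into the LFS stream
    # (evoked potentials carry discriminative low-frequency content too)
    LFS_EVOKED_SCALE = 0.4

    for e, prof in enumerate(profiles):
        innov = rng.normal(size=T) * prof.noise_std * np.sqrt(1.0 - prof.ar1**2)
        noise = signal.lfilter([1.0], [1.0, -prof.ar1], innov)
        x = np.zeros(T)  # evoked component (shared between bands)
        mod_env = np.zeros(T)

        def _add_bump(onset_s: float, amp: float, dur_s: float | None = None) -> None:
            if amp == 0.0:
                return
            i0 = int(round(onset_s * sr))
            if i0 >= T:
                return
            shape = kernel if dur_s is None else _envelope(dur_s)
            seg = shape[: T - i0]
            x[i0 : i0 + len(seg)] += amp * seg

        for trial in trials:
            task = _evoked_task(trial)
            gain = prof.gains.get(task, 0.0) * config.snr
            if trial.task == "false_font":
                gain *= FALSE_FONT_GAIN_SCALE
            mult = 1.0
            if prof.tuning_phase == "post_cue" and task in prof.word_tuning:
                mult = float(prof.word_tuning[task][trial.word])
            latency = prof.latency_s + (LISTENING_EXTRA_LATENCY_S if task == "listening" else 0.0)
            if task in ("speech", "nonspeech_motor"):
                anchor = trial.attempt_onset_s
                dur = trial.attempt_offset_s - trial.attempt_onset_s
            else:
                anchor = trial.presentation_s
                dur = 0.3 if trial.task == "false_font" else config.stim_s
            if np.isfinite(anchor) and gain > 0:
                _add_bump(anchor + latency, gain * mult, dur)
            # pre-go-cue planning ramp, attempted speech only
            if task == "speech" and prof.pre_cue_ramp > 0 and trial.go_cue_s > trial.presentation_s:
                ramp_amp = prof.pre_cue_ramp * config.snr
                if prof.tuning_phase == "pre_cue" and "speech" in prof.word_tuning:
                    ramp_amp *= float(prof.word_tuning["speech"][trial.word])
                i0 = int(round(trial.presentation_s * sr))
                i1 = int(round(trial.go_cue_s * sr))
                i2 = min(int(round((trial.go_cue_s + 0.5) * sr)), T)
                up = np.linspace(0.0, 1.0, max(i1 - i0, 1), endpoint=False)
                x[i0:i1] += ramp_amp * up[: max(min(i1, T) - i0, 0)]
                down = np.linspace(1.0, 0.0, max(i2 - i1, 1))
                x[i1:i2] += ramp_amp * down[: max(i2 - i1, 0)]
            # LFS modulation over [anchor0, anchor0 + 2 s]
            mod = prof.theta_mod.get(task, 0.0)
            if mod != 0.0:
                m0 = trial.go_cue_s if task in ("speech", "nonspeech_motor") else trial.presentation_s
                j0, j1 = int(round(m0 * sr)), min(int(round((m0 + 2.0) * sr)), T)
                mod_env[j0:j1] += mod

        for task, onset_s in background:
            gain = prof.gains.get(task, 0.0) * config.snr
            _add_bump(onset_s + prof.latency_s
                      + (LISTENING_EXTRA_LATENCY_S if task == "listening" else 0.0), gain, 1.5)
            mod = prof.theta_mod.get(task, 0.0)
            if mod != 0.0:
                j0, j1 = int(round(onset_s * sr)), min(int(round((onset_s + 2.0) * sr)), T)
                mod_env[j0:j1] += mod

        hga[:, e] = noise + x
        np.clip(mod_env, -0.95, 2.0, out=mod_env)
        phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
        lfs[:, e] = (
            0.6 * rng.normal(size=T)
            + LFS_EVOKED_SCALE * x
            + theta_base * (1.0 + mod_env) * np.sin(2 * np.pi * 8.0 * tt + phase1)
            + beta_base * (1.0 + mod_env) * np.sin(2 * np.pi * 25.0 * tt + phase2)
        )

    true_events = [
        TrueEvent(tr.attempt_onset_s, tr.attempt_offset_s, tr.word)
        for tr in trials
        if tr.task == "speech" and np.isfinite(tr.attempt_onset_s)
    ]

    from .detect import build_detection_labels

    labels, mask = build_detection_labels(trials, T, sample_rate_hz=sr)
    if config.schedule == "longform" and config.task in ("reading", "listening"):
        from .session import CLASS_INDEX

        code = CLASS_INDEX[config.task]
        for _, onset_s in background:
            j0 = int(round(onset_s * sr))
            j1 = min(int(round((onset_s + config.stim_s) * sr)), T)
            labels[j0:j1] = code

    return NeuralSession(
        hga=hga,
        lfs=lfs,
        electrode_regions=[p.region for p in profiles],
        trials=trials,
        true_events=true_events,
        labels=labels,
        train_mask=mask,
        profiles=profiles,
        sample_rate_hz=sr,
    )
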