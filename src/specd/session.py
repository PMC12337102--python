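"""Session container: feature streams, trials, labels, events, HDF5 round-trip."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from .features import FEATURE_RATE_HZ

#: frame-label codes for the streaming detector
CLASS_NAMES = ("silence", "preparation", "speech", "reading", "listening")
CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}

SPEECH_TASKS = ("speech", "nonspeech_motor")
PERCEPTUAL_TASKS = ("reading", "listening", "false_font", "reading_sentence")


@dataclass
class TrialRecord:
    task: str
    word: int
    presentation_s: float
    go_cue_s: float
    trial_end_s: float
    attempt_onset_s: float = np.nan
    attempt_offset_s: float = np.nan
    stimulus_end_s: float = np.nan
    block_id: int = 0
    condition: str = ""

    def __post_init__(self):
        if self.go_cue_s < self.presentation_s:
            raise ValueError("go cue precedes presentation")
        if np.isfinite(self.attempt_onset_s) and self.attempt_onset_s < self.go_cue_s:
            raise ValueError("attempt onset precedes go cue")


@dataclass
class TrueEvent:
    onset_s: float
    offset_s: float
    word: int = -1

    def __post_init__(self):
        if not self.offset_s > self.onset_s:
            raise ValueError("event offset must exceed onset")


@dataclass
class DetectedEvent:
    onset_s: float
    offset_s: float  # time of the last above-threshold sample
    onset_recognized_s: float
    offset_recognized_s: float
    verified: bool | None = None
    speech_probability: float | None = None
    predicted_word: int | None = None

    def __post_init__(self):
        # equality occurs only for one-sample events (time threshold of 1)
        if not self.offset_s >= self.onset_s:
            raise ValueError("event offset precedes onset")


@dataclass
class NeuralSession:
    """Two feature streams plus task metadata and (optional) ground truth."""

    hga: np.ndarray  # (time, electrode), z-units, 200 Hz
    lfs: np.ndarray
    electrode_regions: list[str]
    trials: list[TrialRecord] = field(default_factory=list)
    true_events: list[TrueEvent] = field(default_factory=list)
    labels: np.ndarray | None = None  # int8 (time,)
    train_mask: np.ndarray | None = None  # bool (time,)
    profiles: list | None = None  # simulator ground truth (ElectrodeProfile)
    sample_rate_hz: float = FEATURE_RATE_HZ

    def __post_init__(self):
        self.hga = np.asarray(self.hga)
        self.lfs = np.asarray(self.lfs)
        if self.hga.shape != self.lfs.shape:
            raise ValueError("HGA and LFS streams must share shape")
        if len(self.electrode_regions) != self.hga.shape[1]:
            raise ValueError("electrode map length != electrode count")
        if self.labels is not None and len(self.labels) != self.hga.shape[0]:
            raise ValueError("label track length != stream length")

    @property
    def n_samples(self) -> int:
        return self.hga.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.hga.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def features(self, electrode_mask: np.ndarray | None = None) -> np.ndarray:
        """(time, 2E) feature matrix: HGA channels then LFS channels."""
        if electrode_mask is None:
            return np.concatenate([self.hga, self.lfs], axis=1)
        m = np.asarray(electrode_mask, dtype=bool)
        return np.concatenate([self.hga[:, m], self.lfs[:, m]], axis=1)


_TRIAL_DTYPE = np.dtype(
    [
        ("task", "S24"),
        ("word", "i4"),
        ("presentation_s", "f8"),
        ("go_cue_s", "f8"),
        ("trial_end_s", "f8"),
        ("attempt_onset_s", "f8"),
        ("attempt_offset_s", "f8"),
        ("stimulus_end_s", "f8"),
        ("block_id", "i4"),
        ("condition", "S24"),
    ]
)

_EVENT_DTYPE = np.dtype([("onset_s", "f8"), ("offset_s", "f8"), ("word", "i4")])


def save_session(session: NeuralSession, path) -> None:
    with h5py.File(path, "w") as f:
        for name, arr in (("hga", session.hga), ("lfs", session.lfs)):
            d = f.create_dataset(name, data=np.asarray(arr, dtype=np.float32))
            d.attrs["sample_rate_hz"] = session.sample_rate_hz
        if session.labels is not None:
            f.create_dataset("labels", data=np.asarray(session.labels, dtype=np.int8))
        if session.train_mask is not None:
            f.create_dataset("train_mask", data=np.asarray(session.train_mask, dtype=bool))
        f.create_dataset(
            "electrodes",
            data=np.array([r.encode() for r in session.electrode_regions], dtype="S16"),
        )
        trials = np.empty(len(session.trials), dtype=_TRIAL_DTYPE)
        for i, t in enumerate(session.trials):
            trials[i] = (
                t.task.encode(), t.word, t.presentation_s, t.go_cue_s, t.trial_end_s,
                t.attempt_onset_s, t.attempt_offset_s, t.stimulus_end_s,
                t.block_id, t.condition.encode(),
            )
        f.create_dataset("trials", data=trials)
        events = np.empty(len(session.true_events), dtype=_EVENT_DTYPE)
        for i, e in enumerate(session.true_events):
            events[i] = (e.onset_s, e.offset_s, e.word)
        f.create_dataset("events", data=events)
        if session.profiles is not None:
            f.attrs["profiles_json"] = json.dumps(
                [_profile_to_dict(p) for p in session.profiles]
            )


def load_session(path) -> NeuralSession:
    with h5py.File(path, "r") as f:
        hga = f["hga"][...].astype(np.float32)
        lfs = f["lfs"][...].astype(np.float32)
        sr = float(f["hga"].attrs["sample_rate_hz"])
        labels = f["labels"][...] if "labels" in f else None
        mask = f["train_mask"][...] if "train_mask" in f else None
        regions = [r.decode() for r in f["electrodes"][...]]
        trials = [
            TrialRecord(
                task=row["task"].decode(), word=int(row["word"]),
                presentation_s=float(row["presentation_s"]),
                go_cue_s=float(row["go_cue_s"]),
                trial_end_s=float(row["trial_end_s"]),
                attempt_onset_s=float(row["attempt_onset_s"]),
                attempt_offset_s=float(row["attempt_offset_s"]),
                stimulus_end_s=float(row["stimulus_end_s"]),
                block_id=int(row["block_id"]), condition=row["condition"].decode(),
            )
            for row in f["trials"][...]
        ]
        events = [
            TrueEvent(float(r["onset_s"]), float(r["offset_s"]), int(r["word"]))
            for r in f["events"][...]
        ]
        profiles = None
        if "profiles_json" in f.attrs:
            from .simulate import ElectrodeProfile

            profiles = [
                _profile_from_dict(d) for d in json.loads(f.attrs["profiles_json"])
            ]
    return NeuralSession(
        hga=hga, lfs=lfs, electrode_regions=regions, trials=trials,
        true_events=events, labels=labels, train_mask=mask,
        profiles=profiles, sample_rate_hz=sr,
    )


def _profile_to_dict(p) -> dict:
    d = asdict(p)
    for key in ("word_tuning",):
        d[key] = {k: np.asarray(v).tolist() for k, v in d[key].items()}
    return d


def _profile_from_dict(d: dict):
    from .simulate import ElectrodeProfile

    d = dict(d)
    d["word_tuning"] = {k: np.asarray(v) for k, v in d["word_tuning"].items()}
    return ElectrodeProfile(**d)


def trial_windows(
    session: NeuralSession,
    trials: list[TrialRecord] | None = None,
    align: str = "go_cue",
    window: tuple[float, float] = (-1.0, 3.0),
    electrode_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-trial feature windows, (n_trials, n_samples, 2E).

    ``align`` is one of ``presentation``, ``go_cue``, ``attempt`` or
    ``onset`` (= presentation for perceptual trials, attempt onset for
    speech trials).
    """
    trials = session.trials if trials is None else trials
    feats = session.features(electrode_mask)
    sr = session.sample_rate_hz
    a, b = window
    if not b > a:
        raise ValueError("window end must exceed start")
    n = int(round((b - a) * sr))
    out = np.empty((len(trials), n, feats.shape[1]))
    for i, t in enumerate(trials):
        if align == "presentation":
            anchor = t.presentation_s
        elif align == "go_cue":
            anchor = t.go_cue_s
        elif align == "attempt":
            anchor = t.attempt_onset_s
        elif align == "onset":
            anchor = t.attempt_onset_s if t.task in SPEECH_TASKS else t.presentation_s
        else:
            raise ValueError(f"unknown alignment {align!r}")
        if not np.isfinite(anchor):
            raise ValueError(f"trial {i} has no finite {align} anchor")
        start = int(round((anchor + a) * sr))
        if start < 0 or start + n > session.n_samples:
            raise ValueError(f"trial {i}: window outside session bounds")
        out[i] = feats[start : start + n]
    return out
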