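"""Signal processing: raw multichannel voltage -> normalized feature streams.

Two streams are produced per electrode at 200 Hz: the high-gamma amplitude
(HGA; envelope of the 70-150 Hz band) and the low-frequency signal
(LFS; band-limited 1-100 Hz by default).  Both are normalized with a causal
30 s sliding-window z-score before being consumed by any model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

FEATURE_RATE_HZ = 200.0
HGA_BAND = (70.0, 150.0)
DEFAULT_LFS_LOW = 1.0
LFS_HIGH = 100.0

REGIONS = ("midPrCG", "PrCG", "PoCG", "temporal", "frontal", "other")


@dataclass
class RawRecording:
    """Raw voltage, (time, electrode), with a per-electrode region map."""

    voltage: np.ndarray
    sample_rate_hz: float
    electrode_map: list[str]

    def __post_init__(self):
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.voltage.ndim != 2:
            raise ValueError("voltage must be (time, electrode)")
        if not np.all(np.isfinite(self.voltage)):
            raise ValueError("voltage contains non-finite values")
        if self.sample_rate_hz < 400:  # Nyquist margin for the 150 Hz band edge
            raise ValueError(f"sample rate {self.sample_rate_hz} Hz < 400 Hz")
        if len(self.electrode_map) != self.voltage.shape[1]:
            raise ValueError("electrode_map length != electrode count")

    @property
    def n_electrodes(self) -> int:
        return self.voltage.shape[1]

    @property
    def duration_s(self) -> float:
        return self.voltage.shape[0] / self.sample_rate_hz


@dataclass
class FeatureStream:
    values: np.ndarray  # (time, electrode), z-units
    band: str  # "HGA" or "LFS"
    sample_rate_hz: float = FEATURE_RATE_HZ

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.band not in ("HGA", "LFS"):
            raise ValueError(f"unknown band {self.band!r}")


@dataclass
class ArtifactReport:
    metric: np.ndarray  # per-timepoint aggregate (NaN at edges)
    flagged_trials: list[int]
    cutoff: float = 0.6


def common_average_reference(raw: RawRecording) -> RawRecording:
    """Subtract the instantaneous mean across electrodes.  Idempotent."""
    if raw.n_electrodes < 2:
        raise ValueError("common average reference requires >= 2 electrodes")
    v = raw.voltage - raw.voltage.mean(axis=1, keepdims=True)
    return RawRecording(v, raw.sample_rate_hz, list(raw.electrode_map))


def _bandpass_sos(low: float, high: float, fs: float, order: int = 4):
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def _resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    y = signal.resample_poly(x, frac.numerator, frac.denominator, axis=0)
    n_out = int(round(x.shape[0] / fs_in * fs_out))
    if y.shape[0] > n_out:
        y = y[:n_out]
    elif y.shape[0] < n_out:
        y = np.pad(y, ((0, n_out - y.shape[0]),) + ((0, 0),) * (y.ndim - 1), mode="edge")
    return y


def extract_feature_streams(
    raw: RawRecording,
    lfs_low: float = DEFAULT_LFS_LOW,
    causal: bool = False,
) -> tuple[FeatureStream, FeatureStream]:
    """Compute HGA (70-150 Hz envelope) and LFS streams at 200 Hz.

    Offline filtering is zero-phase (``sosfiltfilt``); ``causal=True``
    switches to a one-pass IIR for streaming use.  The envelope is the
    magnitude of the analytic signal of the band-passed trace.
    """
    fs = raw.sample_rate_hz
    if fs < 400:
        raise ValueError(f"sample rate {fs} Hz < 400 Hz (need Nyquist for 150 Hz)")
    if raw.duration_s < 1.0:
        raise ValueError("recording shorter than 1 s")
    filt = signal.sosfilt if causal else signal.sosfiltfilt

    hg = filt(_bandpass_sos(*HGA_BAND, fs), raw.voltage, axis=0)
    env = np.abs(signal.hilbert(hg, axis=0))
    hga = _resample_to(env, fs, FEATURE_RATE_HZ)

    lfs_high = min(LFS_HIGH, 0.99 * FEATURE_RATE_HZ / 2)
    lf = filt(_bandpass_sos(lfs_low, lfs_high, fs), raw.voltage, axis=0)
    lfs = _resample_to(lf, fs, FEATURE_RATE_HZ)

    return (
        FeatureStream(hga, "HGA", FEATURE_RATE_HZ),
        FeatureStream(lfs, "LFS", FEATURE_RATE_HZ),
    )


def sliding_zscore(
    values: np.ndarray,
    sample_rate_hz: float = FEATURE_RATE_HZ,
    window_s: float = 30.0,
    std_floor: float = 1e-6,
) -> np.ndarray:
    """Causal sliding-window z-score, per channel.

    The output at sample t is normalized by the mean and standard deviation
    of the trailing ``window_s`` seconds (samples (t - w, t]).  During the
    first window the statistics are computed on the growing prefix.
    Channels with (near-)zero variance in a window map to 0 via the
    standard-deviation floor.
    """
    x = np.asarray(values, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    T = x.shape[0]
    w = max(int(round(window_s * sample_rate_hz)), 1)
    csum = np.cumsum(x, axis=0)
    csq = np.cumsum(x * x, axis=0)
    idx = np.arange(T)
    lo = np.maximum(idx - w + 1, 0)
    n = (idx - lo + 1).astype(float)[:, None]
    s = csum - np.where(lo[:, None] > 0, csum[lo - 1], 0.0)
    sq = csq - np.where(lo[:, None] > 0, csq[lo - 1], 0.0)
    mean = s / n
    var = np.maximum(sq / n - mean**2, 0.0)
    std = np.sqrt(var)
    out = (x - mean) / np.maximum(std, std_floor)
    out[np.abs(std) <= std_floor] = 0.0
    return out[:, 0] if one_d else out


def trial_zscore(
    trial_features: np.ndarray,
    baseline: slice | tuple[int, int],
) -> np.ndarray:
    """Z-score a (time, channel) trial against its pre-stimulus baseline."""
    x = np.asarray(trial_features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if isinstance(baseline, tuple):
        baseline = slice(*baseline)
    base = x[baseline]
    if base.shape[0] == 0:
        raise ValueError("empty baseline window")
    if baseline.start is not None and baseline.start < 0:
        raise ValueError("baseline window outside trial")
    mu = base.mean(axis=0)
    sd = base.std(axis=0)
    bad = np.flatnonzero(sd <= 1e-10 * (1.0 + np.abs(mu)))
    if bad.size:
        raise ValueError(f"zero baseline variance on channel(s) {bad.tolist()}")
    out = (x - mu) / sd
    return out[:, 0] if trial_features.ndim == 1 else out


def _rolling_std(x: np.ndarray, w: int) -> np.ndarray:
    """Std over full windows of length w; output[t] covers samples [t, t+w)."""
    csum = np.cumsum(np.concatenate([np.zeros((1, x.shape[1])), x], axis=0), axis=0)
    csq = np.cumsum(np.concatenate([np.zeros((1, x.shape[1])), x * x], axis=0), axis=0)
    s = csum[w:] - csum[:-w]
    sq = csq[w:] - csq[:-w]
    var = np.maximum(sq / w - (s / w) ** 2, 0.0)
    return np.sqrt(var)


def artifact_scan(
    hga: np.ndarray,
    trial_spans: list[tuple[int, float, float]],
    sample_rate_hz: float = FEATURE_RATE_HZ,
    cutoff: float = 0.6,
    pre_s: float = 5.0,
    post_s: float = 10.0,
    sustain_s: float = 1.0,
    percentile: float = 30.0,
) -> ArtifactReport:
    """Flag trials with sustained variance suppression of the HGA.

    metric(t) = 30th percentile over electrodes of the HGA standard
    deviation in the window [t - 5 s, t + 10 s].  A trial (id, start_s,
    end_s) is flagged when the metric stays below ``cutoff`` for at least
    ``sustain_s`` inside the trial.  Timepoints whose window does not fit in
    the recording carry NaN and are excluded from trial decisions.
    """
    x = np.asarray(hga, dtype=float)
    T = x.shape[0]
    pre = int(round(pre_s * sample_rate_hz))
    post = int(round(post_s * sample_rate_hz))
    w = pre + post
    if T < w:
        raise ValueError("stream shorter than the [-5, 10] s analysis window")
    stds = _rolling_std(x, w)  # stds[i] covers [i, i+w)
    metric = np.full(T, np.nan)
    # window centred so that sample t sees [t - pre, t + post)
    metric[pre : pre + stds.shape[0]] = np.percentile(stds, percentile, axis=1)
    below = metric < cutoff  # NaN compares False
    sustain = max(int(round(sustain_s * sample_rate_hz)), 1)
    flagged = []
    for trial_id, start_s, end_s in trial_spans:
        a = max(int(round(start_s * sample_rate_hz)), 0)
        b = min(int(round(end_s * sample_rate_hz)), T)
        run = best = 0
        for v in below[a:b]:
            run = run + 1 if v else 0
            best = max(best, run)
        if best >= sustain:
            flagged.append(trial_id)
    return ArtifactReport(metric=metric, flagged_trials=flagged, cutoff=cutoff)
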