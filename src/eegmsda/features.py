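"""Spectral feature extraction for segmented multi-channel EEG.

The pipeline mirrors standard fatigue-EEG practice: recordings are cut into
short non-overlapping windows, each window is reduced to the log power of its
one-sided periodogram read at integer frequencies, and the theta (4-7 Hz),
alpha (8-13 Hz) and beta (14-30 Hz) band points are assembled channel-major
into one feature vector per window.  With 61 channels and the default bands
this yields 61 x 27 = 1647 features per half-second segment.

A 0.5 s window at 200 Hz holds 100 samples and so natively resolves only
2 Hz bins; each window is therefore zero-padded to one second (``fs``
samples) before the transform so the periodogram lands exactly on the
1 Hz grid the band definitions use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "EEGRecording",
    "BandSpec",
    "FeatureMatrix",
    "DEFAULT_BANDS",
    "segment",
    "bandpass",
    "log_psd",
    "band_features",
    "extract_features",
]

#: Power floor applied before taking log10, so silent channels stay finite.
POWER_FLOOR = 1e-12

#: Label coding for the two mental states.
AWAKE, FATIGUE = 0, 1


@dataclass
class EEGRecording:
    """A multi-channel recording: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    channel_names: list[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class BandSpec:
    """A named integer frequency band with inclusive edges."""

    name: str
    lo: int
    hi: int

    def __post_init__(self):
        if not (1 <= self.lo <= self.hi):
            raise ValueError(f"invalid band {self.name}: need 1 <= lo <= hi")

    @property
    def n_points(self) -> int:
        return self.hi - self.lo + 1


DEFAULT_BANDS = (
    BandSpec("theta", 4, 7),
    BandSpec("alpha", 8, 13),
    BandSpec("beta", 14, 30),
)


@dataclass
class FeatureMatrix:
    """Per-subject segments x features matrix of band log-powers.

    ``labels`` is None for an unlabeled (target) subject; otherwise one class
    index per row: 0 = awake, 1 = fatigue.
    """

    features: np.ndarray
    labels: np.ndarray | None = None
    layout: str = "channel-major: per channel, bands in order, ascending frequency"
    subject_id: str = ""
    band_names: tuple = field(default_factory=tuple)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if len(self.labels) != len(self.features):
                raise ValueError("labels length must match feature rows")

    @property
    def n_segments(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def segment(recording: EEGRecording, window_s: float = 0.5, overlap: float = 0.0):
    """Cut a recording into channel x window matrices.

    Windows are contiguous when ``overlap`` is 0; a trailing partial window is
    dropped.  Returns a list of ``n_channels x window`` arrays.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    win = recording.fs * window_s
    if abs(win - round(win)) > 1e-9:
        raise ValueError("fs * window_s must be an integer number of samples")
    win = int(round(win))
    step = max(1, int(round(win * (1 - overlap))))
    n = recording.n_samples
    if n < win:
        warnings.warn("recording shorter than one window; returning no segments")
        return []
    starts = range(0, n - win + 1, step)
    return [recording.data[:, s : s + win].copy() for s in starts]


def bandpass(recording: EEGRecording, lo: float = 1.0, hi: float = 30.0) -> EEGRecording:
    """Zero-phase Butterworth band-pass, the standard 1-30 Hz EEG clean-up."""
    nyq = recording.fs / 2
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"high edge {hi} Hz must lie below Nyquist {nyq} Hz")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=recording.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.data, axis=1)
    return EEGRecording(filtered, recording.fs, recording.channel_names)


def log_psd(window: np.ndarray, fs: float, f_max: int = 100) -> np.ndarray:
    """One-sided log10 power spectral density at integer frequencies 1..f_max.

    Each window is mean-detrended and zero-padded to ``fs`` samples so the
    single-window periodogram lands on a 1 Hz grid.  Frequencies above the
    Nyquist (possible when ``f_max`` >= fs/2) are filled with the log floor.
    Accepts a single channels x samples window (2-D) or a stack of windows
    (3-D), returning channels x f_max per window.
    """
    window = np.asarray(window, dtype=np.float64)
    if not np.isfinite(window).all():
        raise ValueError("window contains non-finite values")
    if window.shape[-1] < 2:
        raise ValueError("window must hold at least 2 samples")
    nfft = max(int(round(fs)), window.shape[-1])
    freqs, pxx = signal.periodogram(
        window, fs=fs, window="boxcar", nfft=nfft, detrend="constant", axis=-1
    )
    # integer-frequency bins 1..min(f_max, available)
    out_shape = window.shape[:-1] + (f_max,)
    out = np.full(out_shape, np.log10(POWER_FLOOR))
    avail = freqs[-1]
    f_hi = int(min(f_max, avail))
    idx = np.array([np.argmin(np.abs(freqs - f)) for f in range(1, f_hi + 1)])
    out[..., :f_hi] = np.log10(np.maximum(pxx[..., idx], POWER_FLOOR))
    return out


def band_features(psd: np.ndarray, bands=DEFAULT_BANDS) -> np.ndarray:
    """Assemble band points channel-major into one feature vector.

    ``psd`` is channels x f_max with row f-1 holding frequency f (as produced
    by :func:`log_psd`); output length = channels x sum of band widths.
    A 3-D stack of PSDs yields one row per window.
    """
    psd = np.asarray(psd)
    f_max = psd.shape[-1]
    cols = []
    for b in bands:
        if b.hi > f_max:
            raise ValueError(f"band {b.name} ({b.lo}-{b.hi} Hz) exceeds available {f_max} Hz")
        cols.extend(range(b.lo - 1, b.hi))
    sel = psd[..., cols]  # ... x channels x n_points
    if psd.ndim == 2:
        return sel.reshape(-1)
    return sel.reshape(psd.shape[0], -1)


def extract_features(
    recordings: dict,
    fs: float | None = None,
    window_s: float = 0.5,
    bands=DEFAULT_BANDS,
    f_max: int = 100,
    apply_bandpass: bool = True,
    bandpass_edges: tuple = (1.0, 30.0),
    subject_id: str = "",
) -> FeatureMatrix:
    """Full per-subject pipeline: segment -> log-PSD -> band features + labels.

    ``recordings`` maps class label (0 awake, 1 fatigue) to an
    :class:`EEGRecording`; pass ``{None: recording}`` for unlabeled data.
    Band-pass is on by default, matching raw-EEG practice; it is irrelevant to
    the default bands, which stop at 30 Hz.
    """
    feats, labels, labeled = [], [], True
    n_channels = None
    for label, rec in recordings.items():
        if n_channels is None:
            n_channels = rec.n_channels
        elif rec.n_channels != n_channels:
            raise ValueError("channel count differs between recordings")
        if fs is not None and rec.fs != fs:
            raise ValueError("sampling rate differs from the stated fs")
        if apply_bandpass:
            rec = bandpass(rec, *bandpass_edges)
        windows = segment(rec, window_s)
        if not windows:
            continue
        psd = log_psd(np.stack(windows), rec.fs, f_max=f_max)
        feats.append(band_features(psd, bands))
        if label is None:
            labeled = False
        else:
            labels.extend([label] * len(windows))
    if not feats:
        dim = (n_channels or 0) * sum(b.n_points for b in bands)
        return FeatureMatrix(np.empty((0, dim)), np.empty(0, dtype=int), subject_id=subject_id)
    features = np.concatenate(feats, axis=0)
    return FeatureMatrix(
        features,
        np.asarray(labels) if labeled else None,
        subject_id=subject_id,
        band_names=tuple(b.name for b in bands),
    )
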