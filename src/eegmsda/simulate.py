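"""Synthetic multi-domain data: Gaussian blob domains and an EEG cohort.

Two generators serve two purposes.  ``make_blob_domains`` produces small
labeled point clouds with a controllable inter-domain affine shift — fast
fixtures for exercising the alignment losses and the training loop.
``simulate_cohort`` emulates the geometry of a cross-subject driving-fatigue
study: 15 subjects, 61 channels at 200 Hz, and per subject 700 awake plus
700 fatigue half-second segments.  Class separation is injected as
multiplicative band-power gain in the frequency domain (fatigue elevates
theta/alpha power); cross-subject shift is injected as per-channel log-normal
gains plus a per-subject jitter of the band gains, standing in for the
physiological differences that make cross-subject EEG transfer hard.

Hidden ground-truth labels for the designated target domain are always
returned in a separate structure, so no training code path can reach them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .features import EEGRecording

__all__ = [
    "BlobSpec",
    "CohortSpec",
    "DomainBatch",
    "make_blob_domains",
    "simulate_cohort",
]


@dataclass
class DomainBatch:
    """One domain's samples: features plus one-hot labels (None if unlabeled)."""

    features: np.ndarray
    labels: np.ndarray | None
    domain_id: str = ""

    @property
    def n(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class BlobSpec:
    """Gaussian-blob multi-domain benchmark specification."""

    n_domains: int = 3
    n_classes: int = 2
    n_per_class: int = 50
    dim: int = 2
    class_separation: float = 3.0
    domain_shift_scale: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_domains < 2:
            raise ValueError("need at least 2 domains (1 source + target)")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_per_class < 1 or self.dim < 1:
            raise ValueError("counts must be positive")
        if self.class_separation < 0 or self.domain_shift_scale < 0:
            raise ValueError("scales must be nonnegative")


def make_blob_domains(spec: BlobSpec):
    """Draw ``n_domains`` blob datasets; the last is the unlabeled target.

    Each class is an isotropic Gaussian around a shared mean; each domain
    applies its own random rotation and offset of scale ``domain_shift_scale``
    (zero scale means all domains share one distribution).  Returns
    ``(domains, target_labels)`` where ``target_labels`` holds the target's
    hidden ground truth as a plain integer array.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    means = rng.normal(size=(spec.n_classes, spec.dim))
    means *= spec.class_separation / 2
    domains: list[DomainBatch] = []
    target_labels = None
    for d in range(spec.n_domains):
        # per-domain affine shift: translation of scale shift_scale plus a
        # mild rotation (typical plane angle ~ 0.2 * shift_scale rad).  The
        # translation dominates on purpose: large random rotations can swap
        # the class geometry outright, which no unsupervised adapter could
        # recover from and which real between-subject variation does not do.
        skew = rng.normal(
            scale=0.1 * spec.domain_shift_scale / np.sqrt(spec.dim),
            size=(spec.dim, spec.dim),
        )
        rot = expm(skew - skew.T) if spec.domain_shift_scale > 0 else np.eye(spec.dim)
        offset = rng.normal(scale=spec.domain_shift_scale, size=spec.dim)
        x = np.concatenate(
            [means[c] + rng.normal(size=(spec.n_per_class, spec.dim))
             for c in range(spec.n_classes)]
        )
        y = np.repeat(np.arange(spec.n_classes), spec.n_per_class)
        perm = rng.permutation(len(x))
        x, y = x[perm] @ rot.T + offset, y[perm]
        onehot = np.eye(spec.n_classes)[y]
        is_target = d == spec.n_domains - 1
        domains.append(
            DomainBatch(x, None if is_target else onehot, domain_id=f"D{d + 1}")
        )
        if is_target:
            target_labels = y
    return domains, target_labels


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic EEG cohort specification (defaults follow the study geometry)."""

    n_subjects: int = 15
    n_channels: int = 61
    fs: float = 200.0
    segments_per_class: int = 700
    window_s: float = 0.5
    band_effects: dict = field(
        default_factory=lambda: {
            "theta": (1.0, 2.2),  # (awake gain, fatigue gain) on band power
            "alpha": (1.0, 1.6),
            "beta": (1.0, 0.9),
        }
    )
    subject_gain_sd: float = 0.25
    noise_model: str = "pink"
    seed: int = 0

    def validate(self) -> None:
        win = self.fs * self.window_s
        if abs(win - round(win)) > 1e-9 or win <= 0:
            raise ValueError("fs * window_s must be a positive integer")
        if self.segments_per_class < 1:
            raise ValueError("segments_per_class must be >= 1")
        if self.n_subjects < 1 or self.n_channels < 1:
            raise ValueError("counts must be positive")
        if not set(self.band_effects) <= {"theta", "alpha", "beta"}:
            raise ValueError("band_effects keys must be among theta/alpha/beta")
        if self.noise_model not in ("pink", "white"):
            raise ValueError("noise_model must be 'pink' or 'white'")


_BAND_EDGES = {"theta": (4, 7), "alpha": (8, 13), "beta": (14, 30)}


def _colored_recording(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    fs: float,
    pink: bool,
    band_gain: dict,
    channel_gain: np.ndarray,
) -> np.ndarray:
    """White noise shaped in the frequency domain: 1/f slope + band power gains."""
    x = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(x, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.ones_like(freqs)
    if pink:
        amp[1:] = 1.0 / np.sqrt(freqs[1:])
        amp[0] = 0.0
    for band, gain in band_gain.items():
        lo, hi = _BAND_EDGES[band]
        mask = (freqs >= lo) & (freqs <= hi)
        amp[mask] *= np.sqrt(gain)  # gain acts on power
    spec *= amp
    out = np.fft.irfft(spec, n=n_samples, axis=1)
    return out * channel_gain[:, None]


def simulate_cohort(spec: CohortSpec):
    """Simulate per-subject (awake, fatigue) recording pairs.

    Returns ``(subjects, meta)``: ``subjects`` is a list of dicts with keys
    ``subject_id``, ``awake`` and ``fatigue`` (:class:`EEGRecording` of
    ``segments_per_class * fs * window_s`` samples each); ``meta`` records the
    per-subject gains actually drawn.
    """
    spec.validate()
    root = np.random.default_rng(spec.seed)
    # one independent child seed per subject so subjects are exchangeable
    subject_seeds = root.integers(0, 2**31 - 1, size=spec.n_subjects)
    win = int(round(spec.fs * spec.window_s))
    n_samples = spec.segments_per_class * win
    pink = spec.noise_model == "pink"
    subjects, meta = [], []
    for s, seed in enumerate(subject_seeds):
        rng = np.random.default_rng(int(seed))
        channel_gain = np.exp(rng.normal(0.0, spec.subject_gain_sd, spec.n_channels))
        band_jitter = {
            b: float(np.exp(rng.normal(0.0, spec.subject_gain_sd)))
            for b in spec.band_effects
        }
        recs = {}
        for cls_idx, cls in enumerate(("awake", "fatigue")):
            gains = {
                b: spec.band_effects[b][cls_idx] * band_jitter[b]
                for b in spec.band_effects
            }
            data = _colored_recording(
                rng, spec.n_channels, n_samples, spec.fs, pink, gains, channel_gain
            )
            recs[cls] = EEGRecording(data, spec.fs)
        subjects.append(
            {"subject_id": f"N{s + 1}", "awake": recs["awake"], "fatigue": recs["fatigue"]}
        )
        meta.append(
            {
                "subject_id": f"N{s + 1}",
                "seed": int(seed),
                "channel_gain": channel_gain,
                "band_jitter": band_jitter,
            }
        )
    return subjects, meta
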