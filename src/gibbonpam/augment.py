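"""Training-data augmentation: additive noise, random cropping, duplication,
and image color jitter.

Augmentation never changes a clip's label, and it is applied to training
partitions only. The standard plans are: "noise_added" (one white-noise and
one pink-noise copy per clip), "cropped" (two random crops per clip, each
re-normalized to full scale), and "duplicated" (five copies of each training
image, usually combined with on-the-fly color jitter).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .audio import AudioSegment
from .dataset import LabeledClip
from .synth import band_rms, synth_noise

__all__ = ["AugmentPlan", "add_noise", "random_crop", "duplicate", "color_jitter", "augment_clips"]

#: ITU-R BT.601 luma coefficients for the grayscale used by saturation jitter
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class AugmentPlan:
    kind: str = "none"  # none | noise_added | cropped | duplicated
    copies_per_clip: int = 2
    color_jitter: bool = False
    jitter_strength: float = 0.2
    snr_db: float = 10.0
    min_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "noise_added", "cropped", "duplicated"):
            raise ValueError(f"unknown augmentation kind {self.kind!r}")
        if self.copies_per_clip < 1:
            raise ValueError("copies_per_clip must be >= 1")
        if not (0 <= self.jitter_strength <= 1):
            raise ValueError("jitter_strength must be in [0, 1]")


def add_noise(
    seg: AudioSegment,
    kind: str,
    snr_db: float,
    seed: int,
    band_hz: tuple | None = None,
) -> AudioSegment:
    """Mix seeded white or pink noise under a clip at a requested SNR.

    SNR is the RMS ratio of the clean clip to the added noise in dB, measured
    in ``band_hz`` when given (the species band — the measure detectability
    is graded by) and over the full band otherwise. ``snr_db = inf`` is the
    identity. Duration and rate are unchanged.
    """
    if np.isinf(snr_db):
        return dataclasses.replace(seg, samples=seg.samples.copy())
    noise = synth_noise(kind, len(seg.samples), seg.sample_rate_hz, seed).samples
    if band_hz is not None:
        sig_rms = band_rms(seg.samples, seg.sample_rate_hz, band_hz)
        noise_rms = band_rms(noise, seg.sample_rate_hz, band_hz)
    else:
        sig_rms = float(np.sqrt(np.mean(seg.samples**2)))
        noise_rms = float(np.sqrt(np.mean(noise**2)))
    gain = sig_rms / noise_rms * 10.0 ** (-snr_db / 20.0)
    return dataclasses.replace(seg, samples=seg.samples + gain * noise)


def random_crop(
    seg: AudioSegment, min_fraction: float = 0.5, seed: int = 0, peak_level: float = 1.0
) -> AudioSegment:
    """A random contiguous slice, strictly shorter than the clip, then
    peak-normalized to ``peak_level``.

    The crop start and length are drawn uniformly per seed; the output is at
    least ``min_fraction`` of the input duration.
    """
    if not (0 < min_fraction < 1):
        raise ValueError("min_fraction must be in (0, 1)")
    n = len(seg.samples)
    if n == 0:
        raise ValueError("cannot crop an empty segment")
    rng = np.random.default_rng(seed)
    m = int(rng.integers(max(1, int(np.ceil(min_fraction * n))), n))  # < n strictly
    start = int(rng.integers(0, n - m + 1))
    out = seg.samples[start : start + m].copy()
    peak = np.max(np.abs(out))
    if peak > 0:
        out *= peak_level / peak
    return AudioSegment(
        out, seg.sample_rate_hz, source_id=seg.source_id, offset_s=seg.offset_s + start / seg.sample_rate_hz
    )


def duplicate(images: list, k: int = 5) -> list:
    """k independent copies of every image, in input order (k=1 is identity)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    out = []
    for img in images:
        for _ in range(k):
            out.append(np.array(img, copy=True))
    return out


def color_jitter(img: np.ndarray, strength: float, seed: int) -> np.ndarray:
    """Randomly scale brightness, contrast, and saturation of an RGB image.

    Each factor is drawn independently and uniformly from
    [1 - strength, 1 + strength]; the result is clamped to [0, 1]. Strength 0
    is the exact identity. Hue is deliberately untouched.
    """
    if not (0 <= strength <= 1):
        raise ValueError("strength must be in [0, 1]")
    img = np.asarray(img, dtype=np.float64)
    if strength == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    b, c, s = rng.uniform(1 - strength, 1 + strength, size=3)
    out = img * b
    mean = out @ _LUMA
    out = float(mean.mean()) + (out - float(mean.mean())) * c
    gray = (out @ _LUMA)[..., None]
    out = gray + (out - gray) * s
    return np.clip(out, 0.0, 1.0)


def augment_clips(clips: list, plan: AugmentPlan) -> list:
    """Apply an audio-level plan to labeled clips; labels are inherited.

    "noise_added" emits one white and one pink copy per clip; "cropped" emits
    ``copies_per_clip`` random crops; "none" returns the input list. Image
    duplication/jitter operate on rendered images (see :func:`duplicate` and
    :func:`color_jitter`).
    """
    if plan.kind == "none":
        return list(clips)
    if plan.kind == "duplicated":
        raise ValueError("'duplicated' operates on images; use duplicate()")
    out = []
    for i, clip in enumerate(clips):
        if plan.kind == "noise_added":
            variants = [
                add_noise(clip.audio, "white", plan.snr_db, seed=plan.seed * 7919 + 2 * i),
                add_noise(clip.audio, "pink", plan.snr_db, seed=plan.seed * 7919 + 2 * i + 1),
            ]
            tags = ["noise:white", "noise:pink"]
        else:  # cropped
            variants = [
                random_crop(clip.audio, plan.min_fraction, seed=plan.seed * 104729 + i * plan.copies_per_clip + j)
                for j in range(plan.copies_per_clip)
            ]
            tags = [f"crop:{j}" for j in range(plan.copies_per_clip)]
        for seg, tag in zip(variants, tags):
            out.append(
                LabeledClip(
                    audio=seg,
                    label=clip.label,
                    origin=clip.origin,
                    source_id=clip.source_id,
                    begin_s=clip.begin_s,
                    augmentation=tag,
                )
            )
    return out
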