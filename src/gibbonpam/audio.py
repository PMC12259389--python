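"""Audio I/O, resampling, and band-limited spectrogram-image rendering.

Long passive-acoustic-monitoring recordings arrive as 16-bit PCM WAV at
16-48 kHz. Everything downstream classifies fixed-size 3-channel images of
log-magnitude spectrograms restricted to the species band (0.5-1.6 kHz for
gray gibbons, 0.5-3.0 kHz for crested gibbons), so this module owns the
waveform <-> image contract: samples are kept at full scale +-1, recordings
above the working rate are downsampled, and images are rendered at a fixed
edge length (default 224 px) with the usual per-channel mean/std
normalization applied just before they enter a model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "AudioSegment",
    "RenderSpec",
    "SpectroImage",
    "read_wav",
    "write_wav",
    "resample",
    "band_log_magnitude",
    "spectrogram_image",
    "normalize_image",
    "denormalize_image",
    "save_image",
]

#: full-scale value of a 16-bit sample; reading int16 divides by this
_INT16_FULL_SCALE = 32768.0

#: per-channel statistics of the natural-image corpora CNN backbones are
#: conventionally initialized against; stored on RenderSpec, never inlined
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass
class AudioSegment:
    """A sampled waveform at full scale +-1 with provenance."""

    samples: np.ndarray
    sample_rate_hz: int
    source_id: str = ""
    offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioSegment requires a 1-D sample array")
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioSegment samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    def slice(self, begin_s: float, end_s: float) -> "AudioSegment":
        """Contiguous sub-segment [begin_s, end_s) with adjusted offset."""
        i0 = int(round(begin_s * self.sample_rate_hz))
        i1 = int(round(end_s * self.sample_rate_hz))
        i0 = max(i0, 0)
        return AudioSegment(
            self.samples[i0:i1],
            self.sample_rate_hz,
            source_id=self.source_id,
            offset_s=self.offset_s + i0 / self.sample_rate_hz,
        )


@dataclass
class RenderSpec:
    """How a waveform becomes a fixed-size spectrogram image.

    The STFT uses a 512-sample window with no overlap (the plotting tool the
    field conventionally uses defaults to this); log magnitudes are clipped
    at ``db_floor`` dB below the segment maximum, mapped through a fixed
    perceptually-uniform colormap to 3 channels, cropped to the species band,
    and resized to ``image_edge_px`` square.
    """

    band_low_hz: float = 500.0
    band_high_hz: float = 1600.0
    stft_window_samples: int = 512
    stft_overlap_fraction: float = 0.0
    image_edge_px: int = 224
    normalization_mean: tuple = IMAGENET_MEAN
    normalization_std: tuple = IMAGENET_STD
    colormap: str = "viridis"
    db_floor: float = -80.0

    def __post_init__(self) -> None:
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValueError("require 0 < band_low_hz < band_high_hz")
        if not (0 <= self.stft_overlap_fraction < 1):
            raise ValueError("stft_overlap_fraction must be in [0, 1)")
        if self.image_edge_px <= 0:
            raise ValueError("image_edge_px must be positive")
        if self.db_floor >= 0:
            raise ValueError("db_floor must be negative (dB below max)")


@dataclass
class SpectroImage:
    """A rendered band-limited spectrogram: 3-channel pixels in [0, 1]."""

    pixels: np.ndarray  # (edge, edge, 3), row 0 = band_high_hz
    band: tuple
    time_span_s: float
    render: RenderSpec


def read_wav(path) -> AudioSegment:
    """Read a PCM WAV file, scaling samples to full scale +-1.

    Multi-channel files are mixed down to mono by averaging. Compressed or
    malformed files raise a format error naming what failed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise ValueError(f"not a readable PCM WAV file ({path.name}): {exc}") from exc
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _INT16_FULL_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format: {data.dtype}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioSegment(samples, int(rate), source_id=path.stem)


def write_wav(path, seg: AudioSegment) -> None:
    """Write a segment as 16-bit PCM, clipping to the representable range."""
    clipped = np.clip(seg.samples, -1.0, 1.0 - 1.0 / _INT16_FULL_SCALE)
    data = np.round(clipped * _INT16_FULL_SCALE).astype(np.int16)
    wavfile.write(str(path), int(seg.sample_rate_hz), data)


def resample(seg: AudioSegment, target_rate_hz: int, antialias: bool = True) -> AudioSegment:
    """Downsample a segment to ``target_rate_hz``.

    Upsampling is rejected: recordings are only ever brought down to the
    working rate. With ``antialias`` the polyphase filter is applied; without
    it samples are taken by nearest-index decimation, mirroring pipelines
    that downsample without a low-pass stage.
    """
    if target_rate_hz <= 0:
        raise ValueError("target_rate_hz must be positive")
    if target_rate_hz > seg.sample_rate_hz:
        raise ValueError(
            f"upsampling unsupported: {seg.sample_rate_hz} Hz -> {target_rate_hz} Hz"
        )
    if target_rate_hz == seg.sample_rate_hz:
        return dataclasses.replace(seg)
    if antialias:
        from math import gcd

        g = gcd(int(target_rate_hz), int(seg.sample_rate_hz))
        up, down = int(target_rate_hz) // g, int(seg.sample_rate_hz) // g
        out = signal.resample_poly(seg.samples, up, down)
    else:
        n_out = int(round(len(seg.samples) * target_rate_hz / seg.sample_rate_hz))
        idx = np.minimum(
            np.round(np.arange(n_out) * seg.sample_rate_hz / target_rate_hz).astype(int),
            len(seg.samples) - 1,
        )
        out = seg.samples[idx]
    return AudioSegment(out, int(target_rate_hz), source_id=seg.source_id, offset_s=seg.offset_s)


def _stft_magnitude(seg: AudioSegment, render: RenderSpec):
    nperseg = render.stft_window_samples
    if len(seg.samples) < nperseg:
        raise ValueError("segment shorter than one STFT window")
    noverlap = int(round(render.stft_overlap_fraction * nperseg))
    freqs, times, zxx = signal.stft(
        seg.samples,
        fs=seg.sample_rate_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        boundary=None,
        padded=False,
    )
    return freqs, times, np.abs(zxx)


def band_log_magnitude(seg: AudioSegment, render: RenderSpec):
    """Absolute log-magnitude STFT restricted to the species band.

    Returns ``(freqs, times, db)`` where rows of ``db`` are the STFT bins
    whose center frequency lies inside [band_low_hz, band_high_hz]. This is
    the monotone pre-colormap quantity: scaling the input never decreases
    any cell.
    """
    if render.band_high_hz > seg.sample_rate_hz / 2:
        raise ValueError(
            f"band_high_hz {render.band_high_hz} above Nyquist {seg.sample_rate_hz / 2}"
        )
    freqs, times, mag = _stft_magnitude(seg, render)
    keep = (freqs >= render.band_low_hz) & (freqs <= render.band_high_hz)
    if not np.any(keep):
        raise ValueError("no STFT bins inside the requested band")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(mag[keep, :])
    return freqs[keep], times, db


def spectrogram_image(seg: AudioSegment, render: RenderSpec) -> SpectroImage:
    """Render a band-limited log-magnitude spectrogram as a square RGB image.

    Magnitudes are expressed in dB relative to the segment maximum and
    clipped at ``render.db_floor``; digital silence therefore renders as a
    constant image at the color floor. Rows run high frequency (top) to low
    (bottom), matching how spectrograms are drawn.
    """
    from matplotlib import colormaps
    from skimage.transform import resize as sk_resize

    freqs, times, db = band_log_magnitude(seg, render)
    peak = db.max()
    if not np.isfinite(peak):  # all-zero input: everything at the floor
        rel = np.full_like(db, render.db_floor)
    else:
        rel = np.clip(db - peak, render.db_floor, 0.0)
    unit = (rel - render.db_floor) / (-render.db_floor)  # [0, 1]
    unit = np.flipud(unit)  # row 0 = highest frequency
    cmap = colormaps[render.colormap]
    rgb = cmap(unit)[..., :3]
    edge = render.image_edge_px
    pixels = sk_resize(rgb, (edge, edge), order=1, anti_aliasing=True, preserve_range=True)
    pixels = np.clip(pixels, 0.0, 1.0)
    return SpectroImage(
        pixels=pixels,
        band=(render.band_low_hz, render.band_high_hz),
        time_span_s=seg.duration_s,
        render=render,
    )


def normalize_image(img, render: RenderSpec) -> np.ndarray:
    """Per-channel (x - mean) / std, the form CNN backbones expect."""
    pixels = img.pixels if isinstance(img, SpectroImage) else np.asarray(img)
    mean = np.asarray(render.normalization_mean, dtype=np.float64)
    std = np.asarray(render.normalization_std, dtype=np.float64)
    if np.any(std == 0):
        raise ValueError("normalization_std must be non-zero in every channel")
    return (pixels - mean) / std


def denormalize_image(arr: np.ndarray, render: RenderSpec) -> np.ndarray:
    """Exact inverse of :func:`normalize_image`."""
    mean = np.asarray(render.normalization_mean, dtype=np.float64)
    std = np.asarray(render.normalization_std, dtype=np.float64)
    return np.asarray(arr) * std + mean


def save_image(img, path) -> None:
    """Write a rendered spectrogram as JPEG/PNG with no axes or margins."""
    from PIL import Image

    pixels = img.pixels if isinstance(img, SpectroImage) else np.asarray(img)
    data = np.round(np.clip(pixels, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(data).save(str(path))
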