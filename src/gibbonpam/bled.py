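"""Band-limited energy detector (BLED).

Isolates candidate sound events from long recordings by summing STFT power
over the species band per frame, smoothing, and thresholding relative to the
file's own noise floor: the threshold is ``threshold_factor`` times a robust
envelope quantile (the median by default, which estimates the background
level as long as calls are sparse). Runs above threshold are merged across
short gaps and filtered to plausible call durations. Anchoring the threshold
to a per-file quantile keeps the detector invariant to gain differences
across recording units, while the multiplicative factor keeps the false-event
rate on call-free recordings near zero — a plain upper-tail quantile cannot
do both, since by construction a fixed fraction of every file exceeds it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .audio import AudioSegment
from .dataset import Annotation, SelectionTable

__all__ = ["BledConfig", "CandidateEvent", "band_energy_envelope", "detect_events", "events_to_table"]


@dataclass
class BledConfig:
    band_low_hz: float = 500.0
    band_high_hz: float = 1600.0
    smooth_s: float = 0.25
    threshold_quantile: float = 0.5
    threshold_factor: float = 4.0
    min_event_s: float = 1.0
    max_event_s: float = 12.0
    merge_gap_s: float = 1.0
    stft_window_samples: int = 512

    def __post_init__(self) -> None:
        if not (0 < self.threshold_quantile < 1):
            raise ValueError("threshold_quantile must be in (0, 1)")
        if self.threshold_factor <= 1:
            raise ValueError("threshold_factor must exceed 1")
        if not self.min_event_s <= self.max_event_s:
            raise ValueError("min_event_s must be <= max_event_s")
        if not self.band_low_hz < self.band_high_hz:
            raise ValueError("band_low_hz must be below band_high_hz")


@dataclass
class CandidateEvent:
    begin_s: float
    end_s: float
    peak_energy: float
    source_id: str = ""

    @property
    def duration_s(self) -> float:
        return self.end_s - self.begin_s


def band_energy_envelope(seg: AudioSegment, cfg: BledConfig):
    """Per-frame in-band STFT power, moving-average smoothed.

    Returns ``(frame_times_s, energy)``; energy is non-negative and scales
    quadratically with amplitude. Frame times are frame centers.
    """
    if cfg.band_high_hz > seg.sample_rate_hz / 2:
        raise ValueError(
            f"band_high_hz {cfg.band_high_hz} above Nyquist {seg.sample_rate_hz / 2}"
        )
    nperseg = cfg.stft_window_samples
    if len(seg.samples) < nperseg:
        raise ValueError("segment shorter than one STFT frame")
    freqs, times, zxx = signal.stft(
        seg.samples,
        fs=seg.sample_rate_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=0,
        boundary=None,
        padded=False,
    )
    keep = (freqs >= cfg.band_low_hz) & (freqs <= cfg.band_high_hz)
    energy = np.sum(np.abs(zxx[keep, :]) ** 2, axis=0)
    frame_dt = times[1] - times[0] if len(times) > 1 else nperseg / seg.sample_rate_hz
    win = max(1, int(round(cfg.smooth_s / frame_dt)))
    if win > 1:
        energy = uniform_filter1d(energy, size=win, mode="nearest")
    return times, energy


def _merge_runs(runs: list, merge_gap_s: float) -> list:
    """Merge (begin, end) runs separated by gaps smaller than merge_gap_s.

    Idempotent: merging an already-merged list changes nothing.
    """
    if not runs:
        return []
    merged = [list(runs[0])]
    for b, e in runs[1:]:
        if b - merged[-1][1] < merge_gap_s:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([b, e])
    return [(b, e) for b, e in merged]


def detect_events(seg: AudioSegment, cfg: BledConfig = BledConfig()) -> list:
    """Candidate events: maximal runs of envelope strictly above threshold.

    The threshold is ``threshold_factor x quantile(envelope,
    threshold_quantile)`` — by default 4x the median, i.e. 6 dB above the
    noise floor. The strict inequality means a constant envelope (e.g.
    digital silence) yields no events. Runs closer than ``merge_gap_s`` are
    merged, then events outside [min_event_s, max_event_s] are dropped.
    Events are sorted, non-overlapping, and clipped to the file bounds.
    """
    times, energy = band_energy_envelope(seg, cfg)
    thr = cfg.threshold_factor * float(np.quantile(energy, cfg.threshold_quantile))
    mask = energy > thr
    frame_dt = times[1] - times[0] if len(times) > 1 else cfg.stft_window_samples / seg.sample_rate_hz

    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            runs.append((times[i] - frame_dt / 2, times[j] + frame_dt / 2))
            i = j + 1
        else:
            i += 1

    events = []
    for b, e in _merge_runs(runs, cfg.merge_gap_s):
        b = max(0.0, b)
        e = min(seg.duration_s, e)
        if cfg.min_event_s <= e - b <= cfg.max_event_s:
            sel = (times >= b) & (times <= e)
            peak = float(energy[sel].max()) if np.any(sel) else float(energy.max())
            events.append(CandidateEvent(b, e, peak, source_id=seg.source_id))
    return events


def events_to_table(events: list, cfg: BledConfig, label: str = "candidate") -> SelectionTable:
    """Candidate events as a Raven-compatible selection table."""
    anns = [
        Annotation(
            begin_s=ev.begin_s,
            end_s=ev.end_s,
            low_hz=cfg.band_low_hz,
            high_hz=cfg.band_high_hz,
            label=label,
        )
        for ev in events
    ]
    source = events[0].source_id if events else ""
    return SelectionTable(anns, source_id=source)
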