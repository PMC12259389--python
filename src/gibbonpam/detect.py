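"""Sliding-window deployment of a trained classifier over long recordings.

Every full 12-s window (6-s hop by default) of a recording is scored; windows
where a target class's confidence reaches the threshold become detection
events, optionally with a review spectrogram image each. Processing is
window-by-window, so the peak working set does not grow with file length.
Adjacent positive windows are reported as separate events (window-level
counting); bout merging is left to downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .audio import AudioSegment, save_image, spectrogram_image
from .dataset import Annotation, NOISE_LABEL, SelectionTable, WindowSpec, enumerate_windows

__all__ = ["DetectionEvent", "DeployConfig", "detect_file", "summarize_deployment", "write_detections_csv"]


@dataclass
class DetectionEvent:
    source_id: str
    begin_s: float
    end_s: float
    predicted_class: str
    confidence: float
    image_path: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.confidence <= 1):
            raise ValueError("confidence must be in [0, 1]")
        if self.begin_s < 0:
            raise ValueError("begin_s must be >= 0")


@dataclass
class DeployConfig:
    window: WindowSpec = field(default_factory=WindowSpec)
    threshold: float = 0.90
    target_classes: tuple = ("gibbon",)
    export_images: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.threshold <= 1):
            raise ValueError("threshold must be in [0, 1]")


def detect_file(model, seg: AudioSegment, cfg: DeployConfig, out_dir=None) -> list:
    """Score every full window of a recording and emit thresholded events.

    ``model`` is anything exposing ``score_window(AudioSegment, begin_s) ->
    {class: confidence}`` — normally a :class:`~gibbonpam.model.TrainedModel`,
    but a ground-truth stub serves for pipeline validation. One event is
    emitted per (window, target class) whose confidence >= threshold; the
    noise class is never a detection target. Events come back sorted by
    begin time.
    """
    expected_rate = getattr(model, "sample_rate_hz", None)
    if expected_rate is not None and expected_rate != seg.sample_rate_hz:
        raise ValueError(
            f"recording at {seg.sample_rate_hz} Hz but model expects {expected_rate} Hz; resample first"
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    events = []
    for wb, we in enumerate_windows(seg.duration_s, cfg.window):
        window_audio = seg.slice(wb, we)
        scores = model.score_window(window_audio, wb)
        for cls in cfg.target_classes:
            if cls == NOISE_LABEL:
                continue
            conf = float(scores.get(cls, 0.0))
            if conf >= cfg.threshold:
                image_path = ""
                if cfg.export_images and out_dir is not None:
                    render = getattr(model, "render", None)
                    if render is not None:
                        image_path = str(out_dir / f"{seg.source_id}_{wb:.0f}s_{cls}.jpg")
                        save_image(spectrogram_image(window_audio, render), image_path)
                events.append(
                    DetectionEvent(
                        source_id=seg.source_id,
                        begin_s=wb,
                        end_s=we,
                        predicted_class=cls,
                        confidence=conf,
                        image_path=image_path,
                    )
                )
    events.sort(key=lambda ev: (ev.begin_s, ev.predicted_class))
    return events


def summarize_deployment(events: list, verified_labels: list) -> dict:
    """Precision and counts from manually verified detections.

    ``verified_labels`` aligns with ``events``; a verification equal to the
    noise label marks a false positive, anything else a true positive.
    Returns overall precision plus per-class and per-source count tables.
    """
    if len(verified_labels) != len(events):
        raise ValueError(
            f"every event needs a verification label: {len(events)} events, "
            f"{len(verified_labels)} labels"
        )
    tp = sum(1 for lab in verified_labels if lab != NOISE_LABEL)
    fp = len(events) - tp
    per_class: dict = {}
    per_source: dict = {}
    for ev, lab in zip(events, verified_labels):
        ok = lab != NOISE_LABEL
        c = per_class.setdefault(ev.predicted_class, {"tp": 0, "fp": 0})
        c["tp" if ok else "fp"] += 1
        s = per_source.setdefault(ev.source_id, {"tp": 0, "fp": 0})
        s["tp" if ok else "fp"] += 1
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    return {
        "n_detections": len(events),
        "true_positives": tp,
        "false_positives": fp,
        "precision": precision,
        "per_class": per_class,
        "per_source": per_source,
    }


def write_detections_csv(events: list, path) -> None:
    pd.DataFrame(
        [
            {
                "source": ev.source_id,
                "begin_s": ev.begin_s,
                "end_s": ev.end_s,
                "class": ev.predicted_class,
                "confidence": ev.confidence,
                "image_path": ev.image_path,
            }
            for ev in events
        ]
    ).to_csv(path, index=False)


def events_to_selection_table(events: list, band: tuple = (500.0, 1600.0)) -> SelectionTable:
    """Detections as a Raven-compatible review table."""
    anns = [
        Annotation(ev.begin_s, ev.end_s, band[0], band[1], label=ev.predicted_class)
        for ev in events
    ]
    return SelectionTable(anns, source_id=events[0].source_id if events else "")
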