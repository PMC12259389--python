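"""Annotations, windowing, labeling rules, and dataset assembly.

Call annotations travel as Raven-style tab-separated selection tables (begin
and end time in seconds, low and high frequency in Hz, a label, an optional
quality grade). Long recordings are cut into fixed windows — 12 s every 6 s —
and each window is labeled either by call containment (the window holds at
least 80% of some annotated call) or by start proximity (the window starts
within +-6 s of some call's start). Train/validation/test splits are made by
recorder location so no site leaks across partitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .audio import AudioSegment

__all__ = [
    "NOISE_LABEL",
    "Annotation",
    "SelectionTable",
    "WindowSpec",
    "LabeledClip",
    "SplitPlan",
    "read_selection_table",
    "write_selection_table",
    "enumerate_windows",
    "label_by_containment",
    "label_by_start_proximity",
    "assemble_dataset",
]

NOISE_LABEL = "noise"

# Raven Pro selection-table column names
_COL_SELECTION = "Selection"
_COL_BEGIN = "Begin Time (s)"
_COL_END = "End Time (s)"
_COL_LOW = "Low Freq (Hz)"
_COL_HIGH = "High Freq (Hz)"
_COL_LABEL = "Label"
_COL_QUALITY = "Quality"


@dataclass
class Annotation:
    """One annotated sound event: time-frequency bounds plus label."""

    begin_s: float
    end_s: float
    low_hz: float = 0.0
    high_hz: float = 0.0
    label: str = "gibbon"
    quality: str = ""

    def __post_init__(self) -> None:
        if not self.begin_s < self.end_s:
            raise ValueError(f"annotation must have begin < end, got [{self.begin_s}, {self.end_s}]")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.begin_s


@dataclass
class SelectionTable:
    """An ordered collection of annotations for one recording."""

    annotations: list = field(default_factory=list)
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)

    def __getitem__(self, i):
        return self.annotations[i]


def read_selection_table(path) -> SelectionTable:
    """Parse a Raven-style tab-separated selection table.

    Only begin and end times are mandatory; frequency bounds, label, and
    quality are kept when present. Row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in (_COL_BEGIN, _COL_END) if c not in df.columns]
    if missing:
        raise ValueError(
            f"selection table {path.name} missing mandatory columns {missing}; "
            f"found columns {list(df.columns)}"
        )
    anns = []
    for _, row in df.iterrows():
        anns.append(
            Annotation(
                begin_s=float(row[_COL_BEGIN]),
                end_s=float(row[_COL_END]),
                low_hz=float(row.get(_COL_LOW, 0.0) or 0.0),
                high_hz=float(row.get(_COL_HIGH, 0.0) or 0.0),
                label=str(row.get(_COL_LABEL, "gibbon")),
                quality=str(row.get(_COL_QUALITY, "") or ""),
            )
        )
    return SelectionTable(anns, source_id=path.stem)


def write_selection_table(table: SelectionTable, path) -> None:
    """Write annotations as a Raven-compatible tab-separated table."""
    rows = [
        {
            _COL_SELECTION: i + 1,
            _COL_BEGIN: a.begin_s,
            _COL_END: a.end_s,
            _COL_LOW: a.low_hz,
            _COL_HIGH: a.high_hz,
            _COL_LABEL: a.label,
            _COL_QUALITY: a.quality,
        }
        for i, a in enumerate(table)
    ]
    columns = [_COL_SELECTION, _COL_BEGIN, _COL_END, _COL_LOW, _COL_HIGH, _COL_LABEL, _COL_QUALITY]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


@dataclass
class WindowSpec:
    """Fixed analysis windows: 12 s long, one every 6 s by default."""

    window_s: float = 12.0
    hop_s: float = 6.0

    def __post_init__(self) -> None:
        if not (0 < self.hop_s <= self.window_s):
            raise ValueError("require 0 < hop_s <= window_s")


def enumerate_windows(
    duration_s: float, spec: WindowSpec = WindowSpec(), pad_last: bool = False
) -> list:
    """All full-length windows starting at 0, hop, 2*hop, ...

    Trailing audio shorter than one window is dropped by default: count is
    floor((duration - window) / hop) + 1 when duration >= window, else 0.
    With ``pad_last`` one extra window is appended whenever a tail of the
    file would otherwise be uncovered; it may extend past the end of the
    recording (the caller pads the audio with silence when rendering).
    A small epsilon absorbs floating-point jitter at exact multiples.
    """
    if duration_s < 0:
        raise ValueError("duration_s must be non-negative")
    if duration_s + 1e-9 < spec.window_s:
        n = 0
    else:
        n = int(math.floor((duration_s - spec.window_s) / spec.hop_s + 1e-9)) + 1
    wins = [(i * spec.hop_s, i * spec.hop_s + spec.window_s) for i in range(n)]
    if pad_last and duration_s > 0:
        covered = wins[-1][1] if wins else 0.0
        if covered + 1e-9 < duration_s:
            wins.append((n * spec.hop_s, n * spec.hop_s + spec.window_s))
    return wins


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def label_by_containment(
    window, table: SelectionTable, min_fraction: float = 0.8
) -> str:
    """Training-side labeling: positive iff a window contains >= 80% of a call.

    The fraction is overlap duration over the annotation's own duration, and
    the boundary is inclusive. When several annotations qualify the one with
    the largest contained fraction wins; with no qualifying annotation the
    window is noise.
    """
    wb, we = window
    best_label, best_frac = NOISE_LABEL, -1.0
    for ann in table:
        if ann.duration_s <= 0:
            raise ValueError("zero-duration annotation")
        frac = _overlap(wb, we, ann.begin_s, ann.end_s) / ann.duration_s
        if frac + 1e-12 >= min_fraction and frac > best_frac:
            best_label, best_frac = ann.label, frac
    return best_label


def label_by_start_proximity(
    window, table: SelectionTable, tol_s: float = 6.0
) -> str:
    """Test-side labeling: positive iff the window starts within +-tol_s of a
    call start (inclusive); the nearest-start annotation provides the label.
    """
    wb = window[0]
    best_label, best_dist = NOISE_LABEL, math.inf
    for ann in table:
        dist = abs(wb - ann.begin_s)
        if dist <= tol_s + 1e-12 and dist < best_dist:
            best_label, best_dist = ann.label, dist
    return best_label


@dataclass
class SplitPlan:
    """Recorder-location based partition assignment (leakage guard)."""

    assignment: Mapping[str, str]  # location_id -> train | validation | test

    _PARTITIONS = ("train", "validation", "test")

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.assignment.items() if v not in self._PARTITIONS}
        if bad:
            raise ValueError(f"invalid partitions: {bad}; expected one of {self._PARTITIONS}")


@dataclass
class LabeledClip:
    """One labeled training/eval example cut from a recording."""

    audio: AudioSegment
    label: str
    origin: str  # "bled" | "window"
    source_id: str
    begin_s: float
    augmentation: str = ""


def assemble_dataset(
    recordings: Mapping[str, AudioSegment],
    tables: Mapping[str, SelectionTable],
    spec: WindowSpec,
    rule: str,
    split: SplitPlan,
    class_set: Iterable[str],
    locations: Mapping[str, str] | None = None,
    exclude_low_quality: bool = True,
) -> dict:
    """Cut every recording into windows, label them, and partition by location.

    ``rule`` is ``"containment"`` (training prep) or ``"start"`` (test prep).
    ``locations`` maps recording id to recorder location; by default each
    recording id is its own location. Class imbalance is preserved — nothing
    is rebalanced. Annotations graded low quality are dropped before labeling
    when ``exclude_low_quality`` (their windows become noise).

    Returns ``{"train": [...], "validation": [...], "test": [...]}`` of
    :class:`LabeledClip`, guaranteeing no source appears in two partitions.
    """
    class_set = list(class_set)
    if not class_set:
        raise ValueError("class_set must not be empty")
    if rule not in ("containment", "start"):
        raise ValueError(f"unknown labeling rule {rule!r}")
    locations = locations if locations is not None else {sid: sid for sid in recordings}

    partitions: dict = {p: [] for p in SplitPlan._PARTITIONS}
    for sid, seg in recordings.items():
        loc = locations.get(sid)
        if loc is None or loc not in split.assignment:
            raise ValueError(f"recording {sid!r} has no location in the split plan")
        part = split.assignment[loc]
        table = tables.get(sid, SelectionTable([], source_id=sid))
        if exclude_low_quality:
            table = SelectionTable(
                [a for a in table if a.quality.lower() not in ("low", "l")],
                source_id=table.source_id,
            )
        for wb, we in enumerate_windows(seg.duration_s, spec):
            if rule == "containment":
                label = label_by_containment((wb, we), table)
            else:
                label = label_by_start_proximity((wb, we), table)
            if label != NOISE_LABEL and label not in class_set:
                label = NOISE_LABEL
            partitions[part].append(
                LabeledClip(
                    audio=seg.slice(wb, we),
                    label=label,
                    origin="window",
                    source_id=sid,
                    begin_s=wb,
                )
            )
    # leakage guard: a source id may appear in one partition only
    seen: dict = {}
    for part, clips in partitions.items():
        for clip in clips:
            prev = seen.setdefault(clip.source_id, part)
            if prev != part:
                raise AssertionError(f"source {clip.source_id} leaked into {part} and {prev}")
    return partitions


def write_manifest(partitions: Mapping[str, Sequence[LabeledClip]], path) -> None:
    """Dataset manifest CSV: one row per clip with label, partition, and origin."""
    rows = [
        {
            "partition": part,
            "source": clip.source_id,
            "begin_s": clip.begin_s,
            "label": clip.label,
            "origin": clip.origin,
            "augmentation": clip.augmentation,
        }
        for part, clips in partitions.items()
        for clip in clips
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def subsample_clips(clips: Sequence[LabeledClip], n: int, seed: int) -> list:
    """Seeded uniform subsample without replacement (noise-class thinning)."""
    if n >= len(clips):
        return list(clips)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(clips), size=n, replace=False)
    return [clips[i] for i in sorted(idx)]
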