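"""Selection tables, windowing, labeling rules, and split discipline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gibbonpam import (
    Annotation,
    AudioSegment,
    LabeledClip,
    SelectionTable,
    SplitPlan,
    WindowSpec,
    assemble_dataset,
    enumerate_windows,
    label_by_containment,
    label_by_start_proximity,
    read_selection_table,
    write_selection_table,
)

RATE = 16000


class TestSelectionTableIO:
    def test_header_only_file_is_empty(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("Selection\tBegin Time (s)\tEnd Time (s)\n")
        assert len(read_selection_table(p)) == 0

    def test_round_trip_preserves_fields(self, tmp_path):
        table = SelectionTable(
            [
                Annotation(1.5, 4.25, 500.0, 1600.0, "gray_gibbon", "high"),
                Annotation(10.0, 13.5, 500.0, 3000.0, "crested_gibbon", "medium"),
            ]
        )
        p = tmp_path / "t.txt"
        write_selection_table(table, p)
        back = read_selection_table(p)
        assert len(back) == 2
        for a, b in zip(table, back):
            assert (a.begin_s, a.end_s, a.low_hz, a.high_hz, a.label, a.quality) == (
                b.begin_s,
                b.end_s,
                b.low_hz,
                b.high_hz,
                b.label,
                b.quality,
            )

    def test_missing_mandatory_columns_reported(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("Selection\tStart\tStop\n1\t0\t1\n")
        with pytest.raises(ValueError, match="Begin Time"):
            read_selection_table(p)


class TestEnumerateWindows:
    def test_60s_default_gives_nine_windows(self):
        wins = enumerate_windows(60.0, WindowSpec())
        assert len(wins) == 9
        assert wins[0] == (0.0, 12.0)
        assert wins[-1] == (48.0, 60.0)

    def test_boundary_cases(self):
        assert enumerate_windows(12.0, WindowSpec()) == [(0.0, 12.0)]
        assert enumerate_windows(11.9, WindowSpec()) == []
        assert enumerate_windows(0.0, WindowSpec()) == []

    @given(duration=st.floats(min_value=0.0, max_value=7200.0))
    @settings(max_examples=200, deadline=None)
    def test_count_matches_brute_force(self, duration):
        spec = WindowSpec()
        wins = enumerate_windows(duration, spec)
        # brute-force enumeration oracle
        expected = 0
        k = 0
        while k * spec.hop_s + spec.window_s <= duration + 1e-9:
            expected += 1
            k += 1
        assert len(wins) == expected
        if duration >= spec.window_s:
            assert len(wins) == int(math.floor((duration - spec.window_s) / spec.hop_s + 1e-9)) + 1

    def test_windows_reconstruct_coverage(self):
        wins = enumerate_windows(63.0, WindowSpec())
        assert wins[0][0] == 0.0
        for (b0, e0), (b1, _) in zip(wins, wins[1:]):
            assert b1 <= e0  # overlapping chain: union is [0, last_end]


class TestLabelingRules:
    def test_full_containment_positive(self):
        table = SelectionTable([Annotation(10, 14, label="gray_gibbon")])
        assert label_by_containment((6, 18), table) == "gray_gibbon"

    def test_eighty_percent_boundary_inclusive(self):
        table = SelectionTable([Annotation(0, 10, label="gray_gibbon")])
        assert label_by_containment((2, 14), table) == "gray_gibbon"  # 8/10 = 0.8
        assert label_by_containment((3, 15), table) == "noise"  # 7/10 = 0.7

    def test_most_overlapped_annotation_wins(self):
        table = SelectionTable(
            [Annotation(0, 10, label="a"), Annotation(1, 11, label="b")]
        )
        # window [2, 14]: a contains 8/10, b contains 9/10
        assert label_by_containment((2, 14), table) == "b"

    def test_start_proximity_inclusive_boundary(self):
        table = SelectionTable([Annotation(33, 40, label="g")])
        assert label_by_start_proximity((30, 42), table) == "g"  # |30-33| = 3
        table = SelectionTable([Annotation(36, 40, label="g")])
        assert label_by_start_proximity((30, 42), table) == "g"  # exactly 6
        table = SelectionTable([Annotation(36.5, 40, label="g")])
        assert label_by_start_proximity((30, 42), table) == "noise"

    def test_empty_table_is_noise(self):
        assert label_by_start_proximity((30, 42), SelectionTable([])) == "noise"
        assert label_by_containment((30, 42), SelectionTable([])) == "noise"

    def test_rules_agree_on_contained_nearby_call(self):
        # consistency: a window fully containing a call whose start is within
        # tolerance is positive under both rules
        rng = np.random.default_rng(0)
        for _ in range(50):
            wb = rng.uniform(0, 100)
            start = wb + rng.uniform(0, 6)
            table = SelectionTable([Annotation(start, min(start + rng.uniform(0.5, 4), wb + 12), label="g")])
            assert label_by_containment((wb, wb + 12), table) == "g"
            assert label_by_start_proximity((wb, wb + 12), table) == "g"


class TestAssembleDataset:
    @staticmethod
    def _toy_corpus():
        rng = np.random.default_rng(1)
        recs, tabs = {}, {}
        for sid, n_calls in [("locA", 2), ("locB", 1)]:
            recs[sid] = AudioSegment(rng.standard_normal(60 * RATE) * 0.01, RATE, source_id=sid)
            tabs[sid] = SelectionTable(
                [Annotation(6.0 + 18 * k, 9.0 + 18 * k, label="gray_gibbon") for k in range(n_calls)],
                source_id=sid,
            )
        return recs, tabs

    def test_partition_discipline(self):
        recs, tabs = self._toy_corpus()
        split = SplitPlan({"locA": "train", "locB": "test"})
        parts = assemble_dataset(recs, tabs, WindowSpec(), "containment", split, ["gray_gibbon"])
        assert {c.source_id for c in parts["train"]} == {"locA"}
        assert {c.source_id for c in parts["test"]} == {"locB"}
        assert {c.source_id for c in parts["train"]} & {c.source_id for c in parts["test"]} == set()

    def test_positive_count_matches_exhaustive_oracle(self):
        recs, tabs = self._toy_corpus()
        split = SplitPlan({"locA": "train", "locB": "train"})
        parts = assemble_dataset(recs, tabs, WindowSpec(), "containment", split, ["gray_gibbon"])
        got = sum(1 for c in parts["train"] if c.label == "gray_gibbon")
        expected = 0
        for sid in recs:
            for win in enumerate_windows(recs[sid].duration_s, WindowSpec()):
                if label_by_containment(win, tabs[sid]) != "noise":
                    expected += 1
        assert got == expected > 0

    def test_empty_class_set_rejected(self):
        recs, tabs = self._toy_corpus()
        split = SplitPlan({"locA": "train", "locB": "test"})
        with pytest.raises(ValueError):
            assemble_dataset(recs, tabs, WindowSpec(), "containment", split, [])

    def test_missing_location_rejected(self):
        recs, tabs = self._toy_corpus()
        split = SplitPlan({"locA": "train"})
        with pytest.raises(ValueError, match="locB"):
            assemble_dataset(recs, tabs, WindowSpec(), "containment", split, ["gray_gibbon"])

    def test_low_quality_annotations_excluded(self):
        recs, tabs = self._toy_corpus()
        for ann in tabs["locA"]:
            ann.quality = "low"
        split = SplitPlan({"locA": "train", "locB": "validation"})
        parts = assemble_dataset(recs, tabs, WindowSpec(), "containment", split, ["gray_gibbon"])
        assert all(c.label == "noise" for c in parts["train"])
        kept = assemble_dataset(
            recs, tabs, WindowSpec(), "containment", split, ["gray_gibbon"], exclude_low_quality=False
        )
        assert any(c.label == "gray_gibbon" for c in kept["train"])


class TestManifestAndPadding:
    def test_pad_last_covers_tail(self):
        spec = WindowSpec()
        wins = enumerate_windows(63.0, spec, pad_last=True)
        assert wins[-1] == (54.0, 66.0)  # one padded window past the end
        assert enumerate_windows(60.0, spec, pad_last=True) == enumerate_windows(60.0, spec)

    def test_manifest_round_trip(self, tmp_path):
        import pandas as pd

        from gibbonpam.dataset import write_manifest

        clip = LabeledClip(AudioSegment(np.zeros(RATE), RATE), "gray_gibbon", "window", "locA", 6.0)
        write_manifest({"train": [clip], "validation": [], "test": []}, tmp_path / "m.csv")
        df = pd.read_csv(tmp_path / "m.csv")
        assert len(df) == 1
        assert df.loc[0, "partition"] == "train"
        assert df.loc[0, "label"] == "gray_gibbon"
        assert df.loc[0, "begin_s"] == 6.0
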