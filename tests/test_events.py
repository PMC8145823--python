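"""Prediction post-processing: smoothing, events, clustering, diel, depth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from accelethogram import events
from accelethogram.errors import InvalidContextError

labels_strategy = st.lists(st.sampled_from(["swim", "feed", "courtship"]), min_size=1,
                           max_size=40)


class TestSmoothing:
    def test_isolated_window_reassigned(self):
        assert events.smooth_isolated(["swim", "swim", "feed", "swim", "swim"]) == [
            "swim"] * 5

    def test_constant_sequence_unchanged(self):
        assert events.smooth_isolated(["feed"] * 4) == ["feed"] * 4

    def test_sequential_pass_hand_trace(self):
        assert events.smooth_isolated(["a", "b", "c", "a"]) == ["a", "a", "a", "a"]

    @given(labels_strategy)
    def test_idempotent(self, labels):
        once = events.smooth_isolated(labels)
        assert events.smooth_isolated(once) == once

    @given(labels_strategy)
    def test_no_new_labels_and_endpoints_fixed(self, labels):
        out = events.smooth_isolated(labels)
        assert set(out) <= set(labels)
        assert out[0] == labels[0] and out[-1] == labels[-1]
        # only interior positions may change (the cascade can touch them all)
        changes = sum(a != b for a, b in zip(labels, out))
        assert changes <= max(len(labels) - 2, 0)

    @given(labels_strategy)
    def test_no_interior_singleton_runs(self, labels):
        out = events.smooth_isolated(labels)
        for i in range(1, len(out) - 1):
            assert out[i] == out[i - 1] or out[i] == out[i + 1]


class TestSettling:
    def _track(self, seconds):
        return pd.DataFrame({"window_start": np.arange(seconds, dtype=float),
                             "label_raw": "swim"})

    def test_first_hour_dropped(self):
        kept = events.exclude_settling(self._track(3 * 3600))
        assert len(kept) == 2 * 3600
        assert kept["window_start"].iloc[0] == 3600.0

    def test_zero_exclusion_identity(self):
        track = self._track(100)
        pd.testing.assert_frame_equal(events.exclude_settling(track, 0.0), track)

    def test_short_track_empties_with_warning(self):
        with pytest.warns(UserWarning, match="settling"):
            kept = events.exclude_settling(self._track(45 * 60))
        assert kept.empty


def _track_with_labels(labels, depth=None, diel=None):
    df = pd.DataFrame({"window_start": np.arange(len(labels), dtype=float),
                       "label_smoothed": labels})
    if depth is not None:
        df["depth_m"] = depth
    if diel is not None:
        df["diel"] = diel
    return df


class TestSpawningEvents:
    def test_run_length_extraction(self):
        labels = ["swim"] * 5 + ["courtship"] * 3 + ["swim"] * 4 + ["courtship"] * 10 + ["swim"]
        ev = events.segment_spawning_events(_track_with_labels(labels))
        assert [e.duration_s for e in ev] == [3.0, 10.0]
        assert ev[0].start_s == 5.0 and ev[0].end_s == 8.0

    def test_no_courtship_no_events(self):
        assert events.segment_spawning_events(_track_with_labels(["swim"] * 10)) == []

    def test_durations_conserve_courtship_seconds(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["swim", "courtship", "feed"], size=500).tolist()
        smoothed = events.smooth_isolated(labels)
        ev = events.segment_spawning_events(_track_with_labels(smoothed))
        assert sum(e.duration_s for e in ev) == smoothed.count("courtship")

    def test_event_depth_and_diel_attribution(self):
        labels = ["swim"] * 2 + ["courtship"] * 4 + ["swim"] * 2
        depth = [1.0] * 2 + [10.0, 10.0, 14.0, 14.0] + [1.0] * 2
        diel = ["night"] * 2 + ["dawn"] * 4 + ["day"] * 2
        (event,) = events.segment_spawning_events(_track_with_labels(labels, depth, diel))
        assert event.mean_depth_m == pytest.approx(12.0)
        assert event.diel_bin == "dawn"


def _event(start, end):
    return events.SpawningEvent(start, end, end - start, float("nan"), None)


class TestClustering:
    def test_within_gap_chain(self):
        ev = [_event(0, 10), _event(20 * 60, 20 * 60 + 10)]
        (beh,) = events.cluster_reproductive(ev, gap_s=30 * 60)
        assert beh.event_count == 2

    def test_wide_gap_splits_singletons(self):
        ev = [_event(0, 10), _event(20 * 60, 20 * 60 + 10)]
        behs = events.cluster_reproductive(ev, gap_s=10 * 60)
        assert [b.event_count for b in behs] == [1, 1]

    def test_long_chain_single_behaviour(self):
        # 18 events ~6 min apart spanning ~109 min
        ev = [_event(i * 384.0, i * 384.0 + 10.0) for i in range(18)]
        (beh,) = events.cluster_reproductive(ev, gap_s=30 * 60)
        assert beh.event_count == 18
        assert beh.span_s == pytest.approx(17 * 384.0 + 10.0)
        assert beh.span_s / 60 == pytest.approx(108.6, abs=1.0)

    def test_clustering_conserves_events_and_spans_disjoint(self):
        rng = np.random.default_rng(3)
        starts = np.cumsum(rng.uniform(60, 3600, size=30))
        ev = [_event(s, s + 5) for s in starts]
        behs = events.cluster_reproductive(ev, gap_s=1800)
        assert sum(b.event_count for b in behs) == len(ev)
        for a, b in zip(behs, behs[1:]):
            assert a.end_s < b.start_s


class TestDielBins:
    SUNRISE, SUNSET = "06:28", "19:51"

    @pytest.mark.parametrize(
        "clock, expected",
        [
            ("06:00", "dawn"),
            ("12:00", "day"),
            ("23:30", "night"),
            ("19:00", "dusk"),
            ("05:27", "night"),
            ("05:28", "dawn"),
            ("07:28", "day"),
        ],
    )
    def test_bin_examples(self, clock, expected):
        t = events.parse_clock(clock)
        assert events.assign_diel_bin(t, self.SUNRISE, self.SUNSET) == expected

    @given(st.integers(0, 86399))
    def test_every_second_gets_exactly_one_bin(self, t):
        assert events.assign_diel_bin(t, self.SUNRISE, self.SUNSET) in events.DIEL_BINS

    def test_bin_seconds_partition_the_day(self):
        t = np.arange(0, 86400, 60)
        bins = [events.assign_diel_bin(float(x), self.SUNRISE, self.SUNSET) for x in t]
        counts = pd.Series(bins).value_counts()
        assert counts["dawn"] == 120 and counts["dusk"] == 120
        assert counts.sum() == len(t)

    def test_pathological_daylight_rejected(self):
        with pytest.raises(InvalidContextError):
            events.assign_diel_bin(0.0, "11:00", "12:30")
        with pytest.raises(InvalidContextError):
            events.assign_diel_bin(0.0, "13:00", "12:00")


class TestAttachDepth:
    def test_locf_fill(self):
        track = pd.DataFrame({"window_start": np.arange(10, dtype=float)})
        depth = pd.DataFrame({"time_s": [0.0, 5.0], "depth_m": [10.0, 12.0]})
        out = events.attach_depth(track, depth)
        assert out["depth_m"].tolist() == [10.0] * 5 + [12.0] * 5

    def test_no_channel_all_missing(self):
        track = pd.DataFrame({"window_start": [0.0, 1.0]})
        assert events.attach_depth(track, None)["depth_m"].isna().all()

    def test_windows_before_first_sample_missing(self):
        track = pd.DataFrame({"window_start": np.arange(8, dtype=float)})
        depth = pd.DataFrame({"time_s": [5.0], "depth_m": [3.0]})
        out = events.attach_depth(track, depth)
        assert out["depth_m"].isna().tolist() == [True] * 5 + [False] * 3

    def test_matches_dense_resample_oracle(self):
        rng = np.random.default_rng(2)
        knots = pd.DataFrame({"time_s": np.arange(0, 100, 5.0),
                              "depth_m": rng.uniform(1, 30, 20)})
        track = pd.DataFrame({"window_start": np.arange(100, dtype=float)})
        out = events.attach_depth(track, knots)
        dense = knots.set_index("time_s")["depth_m"].reindex(
            np.arange(100.0)).ffill()
        np.testing.assert_allclose(out["depth_m"].to_numpy(), dense.to_numpy())


class TestDielSummary:
    def test_published_tally_percentages(self):
        ev = (
            [_evt("dawn")] * 17 + [_evt("day")] * 18 + [_evt("night")] * 7
            + [_evt("dusk")] * 6
        )
        table = events.summarise_diel(ev).set_index("diel")
        assert table.loc["dawn", "percent"] == 35
        assert table.loc["day", "percent"] == 38
        assert table.loc["night", "percent"] == 15
        assert table.loc["dusk", "percent"] == 13
        assert table["count"].sum() == 48

    def test_single_event_is_100_percent(self):
        table = events.summarise_diel([_evt("dusk")]).set_index("diel")
        assert table.loc["dusk", "percent"] == 100

    def test_empty_is_all_zero(self):
        table = events.summarise_diel([])
        assert (table["count"] == 0).all() and (table["percent"] == 0).all()


def _evt(diel):
    return events.SpawningEvent(0.0, 1.0, 1.0, float("nan"), diel)
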