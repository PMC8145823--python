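"""Applying the ethogram to unseen tracks and post-processing predictions.

A prediction track is one record per retained second: raw predicted label,
smoothed label, LOCF-filled depth, and diel bin.  Runs of courtship seconds
become spawning events; events chained by short gaps become reproductive
behaviours; events are tallied into dawn/day/dusk/night bins defined by ±1 h
windows around sunrise and sunset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from accelethogram.classify import ClassifierModel, round_half_up
from accelethogram.errors import InvalidArgumentError, InvalidContextError

logger = logging.getLogger(__name__)

DIEL_BINS = ("dawn", "day", "dusk", "night")


def parse_clock(value: str | float) -> float:
    """Parse "HH:MM[:SS]" (or seconds) to seconds since local midnight."""
    if isinstance(value, (int, float)):
        return float(value) % 86400.0
    parts = [float(p) for p in str(value).split(":")]
    while len(parts) < 3:
        parts.append(0.0)
    h, m, s = parts[:3]
    return (h * 3600.0 + m * 60.0 + s) % 86400.0


def exclude_settling(
    track: pd.DataFrame, exclusion_s: float = 3600.0, release_time_s: float | None = None
) -> pd.DataFrame:
    """Drop the settling period after release (default first 60 min).

    ``release_time_s`` defaults to the first window of the track.  Returns an
    empty track (with a warning) when nothing survives the exclusion.
    """
    if exclusion_s < 0:
        raise InvalidArgumentError("exclusion_s must be >= 0")
    if track.empty:
        return track
    t0 = release_time_s if release_time_s is not None else float(track["window_start"].iloc[0])
    kept = track[track["window_start"] >= t0 + exclusion_s].reset_index(drop=True)
    if kept.empty:
        warnings.warn(
            f"track shorter than the {exclusion_s / 60:.0f}-min settling exclusion; "
            "nothing retained",
            stacklevel=2,
        )
    return kept


def smooth_isolated(labels) -> list:
    """Reclassify isolated 1-s predictions to their preceding label.

    Single left-to-right pass over interior positions: a label differing from
    both its (already-updated) left neighbour and its right neighbour is
    replaced by the left neighbour.  Sub-second behaviour switches are
    implausible, so a one-window island is treated as a misallocation.  First
    and last positions are untouched; the pass is idempotent.
    """
    out = list(labels)
    for i in range(1, len(out) - 1):
        if out[i] != out[i - 1] and out[i] != out[i + 1]:
            out[i] = out[i - 1]
    return out


@dataclass(frozen=True)
class SpawningEvent:
    """Maximal contiguous run of seconds classified as courtship."""

    start_s: float
    end_s: float
    duration_s: float
    mean_depth_m: float  # NaN when no depth was attached
    diel_bin: str | None


@dataclass(frozen=True)
class ReproductiveBehaviour:
    """Gap-linked cluster of spawning events."""

    events: tuple[SpawningEvent, ...]
    start_s: float
    end_s: float
    span_s: float
    event_count: int


def segment_spawning_events(track: pd.DataFrame, window_s: float = 1.0) -> list[SpawningEvent]:
    """Extract spawning events from the smoothed label track.

    Depth is averaged over member seconds; the diel bin is the bin at event
    start.
    """
    if track.empty:
        return []
    col = "label_smoothed" if "label_smoothed" in track.columns else "label_raw"
    labels = track[col].to_numpy(dtype=object)
    times = track["window_start"].to_numpy(dtype=float)
    depth = track["depth_m"].to_numpy(dtype=float) if "depth_m" in track.columns else None
    diel = track["diel"].to_numpy(dtype=object) if "diel" in track.columns else None
    is_court = labels == "courtship"
    edges = np.flatnonzero(np.diff(np.concatenate([[0], is_court.astype(int), [0]])))
    events = []
    for i, j in zip(edges[::2], edges[1::2]):
        events.append(
            SpawningEvent(
                start_s=float(times[i]),
                end_s=float(times[j - 1]) + window_s,
                duration_s=(j - i) * window_s,
                mean_depth_m=float(np.nanmean(depth[i:j])) if depth is not None else float("nan"),
                diel_bin=str(diel[i]) if diel is not None else None,
            )
        )
    return events


def cluster_reproductive(
    events: list[SpawningEvent], gap_s: float = 1800.0
) -> list[ReproductiveBehaviour]:
    """Single-linkage chaining of spawning events into reproductive behaviours.

    Consecutive events separated by at most ``gap_s`` (default 30 min) join
    the same behaviour; singleton behaviours are allowed.
    """
    behaviours: list[ReproductiveBehaviour] = []
    cluster: list[SpawningEvent] = []
    for event in sorted(events, key=lambda e: e.start_s):
        if cluster and event.start_s - cluster[-1].end_s > gap_s:
            behaviours.append(_finalise(cluster))
            cluster = []
        cluster.append(event)
    if cluster:
        behaviours.append(_finalise(cluster))
    return behaviours


def _finalise(cluster: list[SpawningEvent]) -> ReproductiveBehaviour:
    return ReproductiveBehaviour(
        events=tuple(cluster),
        start_s=cluster[0].start_s,
        end_s=cluster[-1].end_s,
        span_s=cluster[-1].end_s - cluster[0].start_s,
        event_count=len(cluster),
    )


def assign_diel_bin(
    time_s: float,
    sunrise: str | float,
    sunset: str | float,
    half_width_s: float = 3600.0,
) -> str:
    """Diel bin of a clock time: dawn/dusk are ±1 h around sunrise/sunset.

    dawn = [sunrise−h, sunrise+h), dusk = [sunset−h, sunset+h),
    day = [sunrise+h, sunset−h), night otherwise (half-open intervals).
    """
    rise = parse_clock(sunrise)
    setr = parse_clock(sunset)
    if rise >= setr:
        raise InvalidContextError("sunrise must precede sunset within the civil day")
    if rise + half_width_s > setr - half_width_s:
        raise InvalidContextError("dawn and dusk windows overlap; day vanishes")
    t = float(time_s) % 86400.0
    if rise - half_width_s <= t < rise + half_width_s:
        return "dawn"
    if setr - half_width_s <= t < setr + half_width_s:
        return "dusk"
    if rise + half_width_s <= t < setr - half_width_s:
        return "day"
    return "night"


def attach_depth(track: pd.DataFrame, depth: pd.DataFrame | None) -> pd.DataFrame:
    """LOCF-fill the sparse depth channel onto per-second windows.

    Windows before the first depth sample carry missing depth.
    """
    track = track.copy()
    if depth is None or depth.empty:
        track["depth_m"] = np.nan
        return track
    dt = depth.sort_values("time_s")
    times = dt["time_s"].to_numpy(dtype=float)
    values = dt["depth_m"].to_numpy(dtype=float)
    ws = track["window_start"].to_numpy(dtype=float)
    idx = np.searchsorted(times, ws + 1e-9) - 1
    filled = np.where(idx >= 0, values[np.clip(idx, 0, len(values) - 1)], np.nan)
    track["depth_m"] = filled
    return track


def predict_track(
    model: ClassifierModel,
    features: pd.DataFrame,
    depth: pd.DataFrame | None = None,
    sunrise: str | float | None = None,
    sunset: str | float | None = None,
    track_start_clock: str | float = 0.0,
    release_time_s: float | None = None,
    exclusion_s: float = 3600.0,
    smoothing: bool = True,
) -> pd.DataFrame:
    """Full application chain: predict, exclude settling, smooth, depth, diel.

    ``track_start_clock`` anchors window offsets to the local clock for diel
    binning; windows are per-second records.
    """
    track = pd.DataFrame(
        {
            "window_start": features["window_start"].to_numpy(dtype=float),
            "label_raw": model.predict(features),
        }
    )
    track = exclude_settling(track, exclusion_s, release_time_s)
    if track.empty:
        for col in ("label_smoothed", "depth_m", "diel"):
            track[col] = pd.Series(dtype=object)
        return track
    track["label_smoothed"] = (
        smooth_isolated(track["label_raw"].tolist()) if smoothing else track["label_raw"]
    )
    track = attach_depth(track, depth)
    if sunrise is not None and sunset is not None:
        anchor = parse_clock(track_start_clock)
        track["diel"] = [
            assign_diel_bin(anchor + t, sunrise, sunset)
            for t in track["window_start"]
        ]
    else:
        track["diel"] = None
    return track


def summarise_diel(events: list[SpawningEvent]) -> pd.DataFrame:
    """Counts and rounded integer percentages of events per diel bin.

    Percentages use half-up rounding; an empty event list yields all zeros.
    """
    counts = {b: 0 for b in DIEL_BINS}
    for event in events:
        if event.diel_bin in counts:
            counts[event.diel_bin] += 1
    total = sum(counts.values())
    rows = [
        {
            "diel": b,
            "count": counts[b],
            "percent": int(round_half_up(100.0 * counts[b] / total, 0)) if total else 0,
        }
        for b in DIEL_BINS
    ]
    return pd.DataFrame(rows)
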