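"""1-s statistical feature windows over the derived signals.

Every non-overlapping window (left-aligned to the first timestamp) yields six
statistics — mean, standard deviation, skewness, kurtosis, minimum, maximum —
for each of the 11 derived signals, giving the full 66-column predictor set.
Skewness is the (population) moment skewness and kurtosis is excess kurtosis;
both are defined as 0 for constant windows so training never sees undefined
values.  Orientation-undefined samples (NaN pitch/roll) are excluded from the
window statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from accelethogram.behaviours import parse_behaviour
from accelethogram.errors import InvalidMaskError, InvalidWindowError
from accelethogram.signals import AccelSeries, ProcessedSeries, split_static_dynamic

STATISTICS = ("mean", "sd", "skew", "kurt", "min", "max")

PREDICTOR_SETS = ("full66", "published58", "published64")


def predictor_columns(predictor_set: str = "full66") -> list[str]:
    """Predictor column names for a named subset.

    ``full66`` is the complete 11-signal × 6-statistic grid.  The published
    analysis quotes both 58 and 64 predictors without listing the dropped
    columns; these subsets are this package's documented reconstructions:
    ``published64`` drops the shape statistics of absolute roll (whose
    sign-folding distorts skewness/kurtosis), and ``published58`` additionally
    drops the shape statistics of pitch, cycle and amplitude.
    """
    full = [f"{sig}_{stat}" for sig in ProcessedSeries.SIGNALS for stat in STATISTICS]
    if predictor_set == "full66":
        return full
    if predictor_set == "published64":
        dropped = {"roll_abs_skew", "roll_abs_kurt"}
    elif predictor_set == "published58":
        dropped = {
            f"{sig}_{stat}"
            for sig in ("roll_abs", "pitch", "cycle", "amplitude")
            for stat in ("skew", "kurt")
        }
    else:
        raise ValueError(f"unknown predictor set {predictor_set!r}; use one of {PREDICTOR_SETS}")
    return [c for c in full if c not in dropped]


def _window_stats(values: np.ndarray) -> dict[str, np.ndarray]:
    """NaN-aware moment statistics over axis 1 of an (n_windows, n_samples) array."""
    finite = np.isfinite(values)
    cnt = finite.sum(axis=1).astype(float)
    safe = np.where(finite, values, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, safe.sum(axis=1) / cnt, np.nan)
        dev = np.where(finite, values - mean[:, None], 0.0)
        m2 = (dev**2).sum(axis=1) / cnt
        m3 = (dev**3).sum(axis=1) / cnt
        m4 = (dev**4).sum(axis=1) / cnt
        vmin = np.where(cnt > 0, np.where(finite, values, np.inf).min(axis=1), np.nan)
        vmax = np.where(cnt > 0, np.where(finite, values, -np.inf).max(axis=1), np.nan)
        # constant windows are exactly dispersion-free (min == max beats
        # accumulated round-off in the moment sums)
        nonconst = (m2 > 0) & (vmax > vmin)
        sd = np.where((cnt > 1) & nonconst, np.sqrt(m2 * cnt / np.maximum(cnt - 1, 1)), 0.0)
        skew = np.where(nonconst, m3 / np.where(nonconst, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(nonconst, m4 / np.where(nonconst, m2, 1.0) ** 2 - 3.0, 0.0)
    return {"mean": mean, "sd": sd, "skew": skew, "kurt": kurt, "min": vmin, "max": vmax}


def summarise_windows(processed: ProcessedSeries, window_s: float = 1.0) -> pd.DataFrame:
    """Summarise a processed series into non-overlapping feature windows.

    Windows are left-aligned to the first timestamp; a trailing partial window
    is dropped.  Returns one row per window with ``window_start``, ``fish_id``
    and the 66 ``<signal>_<stat>`` predictor columns.
    """
    fs = processed.sample_rate
    spw = int(round(window_s * fs))
    if spw < 1:
        raise InvalidWindowError(f"window {window_s} s is below the sample interval")
    n = len(processed)
    n_win = n // spw
    t0 = float(processed.data["time_s"].iloc[0]) if n else 0.0
    if n_win == 0:
        cols = ["window_start", "fish_id"] + predictor_columns("full66")
        return pd.DataFrame(columns=cols)
    out: dict[str, np.ndarray] = {
        "window_start": t0 + np.arange(n_win) * window_s,
    }
    for sig in ProcessedSeries.SIGNALS:
        values = processed.data[sig].to_numpy()[: n_win * spw].reshape(n_win, spw)
        for stat, arr in _window_stats(values).items():
            out[f"{sig}_{stat}"] = arr
    df = pd.DataFrame(out)
    df.insert(1, "fish_id", processed.fish_id)
    return df


def join_labels(
    features: pd.DataFrame, mask: pd.DataFrame, window_s: float = 1.0
) -> pd.DataFrame:
    """Attach ground-truth behaviour labels to feature windows.

    A window ``[s, s + window_s)`` takes a label iff it lies entirely inside
    one mask interval ``[start_s, end_s)``; all other windows get a missing
    label (``behaviour`` NaN) and are excluded from training downstream.

    Raises :class:`InvalidMaskError` when mask intervals overlap.
    """
    features = features.copy()
    if mask is None or mask.empty:
        features["behaviour"] = pd.Series([pd.NA] * len(features), dtype="object")
        return features
    mask = mask.sort_values("start_s").reset_index(drop=True)
    starts = mask["start_s"].to_numpy(dtype=float)
    ends = mask["end_s"].to_numpy(dtype=float)
    overlap = np.nonzero(starts[1:] < ends[:-1] - 1e-12)[0]
    if overlap.size:
        pairs = ", ".join(
            f"[{starts[i]}, {ends[i]}) and [{starts[i + 1]}, {ends[i + 1]})"
            for i in overlap[:5]
        )
        raise InvalidMaskError(f"overlapping mask intervals: {pairs}")
    labels = mask["behaviour"].map(parse_behaviour).to_numpy()

    ws = features["window_start"].to_numpy(dtype=float)
    idx = np.searchsorted(starts, ws + 1e-9, side="right") - 1
    valid = idx >= 0
    idx_c = np.clip(idx, 0, len(starts) - 1)
    inside = valid & (ws >= starts[idx_c] - 1e-9) & (ws + window_s <= ends[idx_c] + 1e-9)
    out = np.where(inside, labels[idx_c], None)
    features["behaviour"] = pd.Series(out, index=features.index, dtype="object")
    return features


def _intervals_from_bool(flag: np.ndarray, time_s: np.ndarray) -> list[tuple[float, float]]:
    """Maximal [start, end] time intervals where a boolean mask is True."""
    if not flag.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[False], flag, [False]]).astype(int)))
    return [(float(time_s[i]), float(time_s[j - 1])) for i, j in zip(edges[::2], edges[1::2])]


def flag_burst_candidates(
    series: AccelSeries,
    sway_threshold_g: float = 1.0,
    roll_rate_threshold_deg_s: float = 45.0,
    merge_gap_s: float = 1.0,
) -> list[tuple[float, float]]:
    """Flag candidate burst intervals for manual ground-truthing.

    Marks maximal intervals where |sway| exceeds ``sway_threshold_g`` or the
    absolute-roll rate exceeds ``roll_rate_threshold_deg_s``, merging intervals
    separated by less than ``merge_gap_s``.  This is a screening aid only —
    the classifier does not consume it.
    """
    from accelethogram.signals import compute_roll_abs  # local: avoid cycle at import

    flag = np.abs(series.az_g) > sway_threshold_g
    if len(series) >= 2:
        raw = np.column_stack([series.ax_g, series.ay_g, series.az_g])
        static, _ = split_static_dynamic(raw, series.sample_rate)
        roll = compute_roll_abs(static)
        rate = np.abs(np.gradient(roll, series.time_s))
        flag = flag | (np.nan_to_num(rate) > roll_rate_threshold_deg_s)
    intervals = _intervals_from_bool(flag, series.time_s)
    merged: list[tuple[float, float]] = []
    for start, end in intervals:
        if merged and start - merged[-1][1] < merge_gap_s:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def labelled_rows(features: pd.DataFrame) -> pd.DataFrame:
    """Rows carrying a ground-truth behaviour label (the training pool)."""
    return features[features["behaviour"].notna()].reset_index(drop=True)
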