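"""Derived movement signals from raw tri-axial acceleration.

Axis semantics follow the standard body frame of a logger-borne fish:
X = surge (anterior–posterior), Y = heave (dorso-ventral, gravity-aligned
when the fish is upright and level), Z = sway (lateral).  All accelerations
are in g, angles in degrees, times in seconds.

The per-sample derivations are:

* static acceleration   — centred moving average of each raw axis (posture);
* dynamic acceleration  — raw − static (body movement);
* VeDBA                 — ``sqrt(dx**2 + dy**2 + dz**2)`` over the dynamic triplet;
* pitch                 — ``atan(Xs / sqrt(Ys**2 + Zs**2))`` on the static triplet,
                          positive when ascending;
* absolute roll         — ``|atan2(Zs, Ys)|`` in [0, 180], direction removed;
* cycle / amplitude     — period and amplitude of the dominant sway
                          oscillation (tail beat) from a continuous Morlet
                          wavelet transform of the dynamic sway axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import pywt

from accelethogram.errors import (
    InsufficientDataError,
    InvalidArgumentError,
    InvalidWindowError,
)

#: Morlet mother wavelet with angular centre frequency omega0 = 6:
#: pywt's cmorB-C is (pi*B)^-1/2 exp(2i*pi*C*t) exp(-t^2/B), so B = 2 gives the
#: classic exp(-t^2/2) envelope and C = 6 / (2*pi).
MORLET = "cmor2.0-0.954929658551372"

DEFAULT_SAMPLE_RATE = 50.0
DEFAULT_STATIC_WINDOW_S = 3.0
DEFAULT_PERIOD_RANGE_S = (0.2, 2.0)
DEFAULT_N_PERIODS = 50
LOGGER_RANGE_G = 2.0


@dataclass
class AccelSeries:
    """Raw tri-axial acceleration stream at a fixed sample rate.

    ``depth`` is a sparse table (columns ``time_s``, ``depth_m``), typically on
    a 5-s cadence; it is attached to prediction windows later, never resampled
    here.
    """

    time_s: np.ndarray
    ax_g: np.ndarray  # surge
    ay_g: np.ndarray  # heave
    az_g: np.ndarray  # sway
    sample_rate: float = DEFAULT_SAMPLE_RATE
    depth: pd.DataFrame | None = None
    fish_id: str = "unknown"
    sunrise: str | None = None  # "HH:MM" local clock
    sunset: str | None = None
    release_time_s: float = 0.0
    logger_range_g: float = LOGGER_RANGE_G

    def __post_init__(self) -> None:
        for name in ("time_s", "ax_g", "ay_g", "az_g"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.time_s)
        if not (len(self.ax_g) == len(self.ay_g) == len(self.az_g) == n):
            raise InvalidArgumentError("axis arrays must share the time length")
        if n >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise InvalidArgumentError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate

    def clipped_mask(self) -> np.ndarray:
        """Boolean mask of samples at the logger range bound on any axis."""
        r = self.logger_range_g
        return (
            (np.abs(self.ax_g) >= r)
            | (np.abs(self.ay_g) >= r)
            | (np.abs(self.az_g) >= r)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "ax_g": self.ax_g,
                "ay_g": self.ay_g,
                "az_g": self.az_g,
            }
        )


@dataclass
class ProcessedSeries:
    """Per-sample derived signals aligned to the source timestamps."""

    data: pd.DataFrame
    sample_rate: float
    fish_id: str = "unknown"
    depth: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    #: the 11 derived signals summarised into feature windows
    SIGNALS = (
        "static_x",
        "static_y",
        "static_z",
        "dynamic_x",
        "dynamic_y",
        "dynamic_z",
        "vedba",
        "pitch",
        "roll_abs",
        "cycle",
        "amplitude",
    )

    def __len__(self) -> int:
        return len(self.data)


def split_static_dynamic(
    raw: np.ndarray | pd.DataFrame,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    window_s: float = DEFAULT_STATIC_WINDOW_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Split raw axes into static (posture) and dynamic (movement) components.

    Static is a centred box moving average over ``window_s`` (default 3 s,
    long enough to keep the slowest ~0.9 s tail-beat stroke out of the posture
    estimate); edges use shrinking windows.  Dynamic = raw − static exactly,
    so the two components always reconstruct the input.

    Parameters
    ----------
    raw
        Array of shape (n, k) — one column per axis — or a DataFrame.
    """
    arr = np.asarray(raw, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    n_win = int(round(window_s * sample_rate))
    if n_win < 2:
        raise InvalidWindowError(
            f"static window {window_s} s spans {n_win} sample(s); need >= 2"
        )
    if n_win % 2 == 0:  # odd width keeps the average centred
        n_win += 1
    df = pd.DataFrame(arr)
    static = df.rolling(n_win, center=True, min_periods=1).mean().to_numpy()
    dynamic = arr - static
    if squeeze:
        return static[:, 0], dynamic[:, 0]
    return static, dynamic


def compute_vedba(dynamic: np.ndarray) -> np.ndarray:
    """Vectorial dynamic body acceleration: Euclidean norm of the dynamic triplet."""
    d = np.asarray(dynamic, dtype=float)
    return np.sqrt(np.sum(d * d, axis=-1))


def compute_pitch(static: np.ndarray) -> np.ndarray:
    """Body inclination (degrees) from the static triplet.

    ``pitch = atan(Xs / sqrt(Ys**2 + Zs**2)) * 180/pi``; positive when the
    anterior axis points up (ascending).  An all-zero static vector has no
    defined orientation and yields NaN.
    """
    s = np.atleast_2d(np.asarray(static, dtype=float))
    horiz = np.hypot(s[..., 1], s[..., 2])
    with np.errstate(invalid="ignore", divide="ignore"):
        pitch = np.degrees(np.arctan2(s[..., 0], horiz))
    undefined = (horiz == 0) & (s[..., 0] == 0)
    pitch = np.where(undefined, np.nan, pitch)
    return pitch[0] if np.asarray(static).ndim == 1 else pitch


def compute_roll_abs(static: np.ndarray) -> np.ndarray:
    """Absolute roll angle (degrees, [0, 180]) from the static triplet.

    ``|atan2(Zs, Ys)| * 180/pi`` — the sign (roll direction) is removed so
    opposite-handed rolls do not cancel in window means.  Ys = Zs = 0 has no
    defined roll and yields NaN.
    """
    s = np.atleast_2d(np.asarray(static, dtype=float))
    with np.errstate(invalid="ignore"):
        roll = np.abs(np.degrees(np.arctan2(s[..., 2], s[..., 1])))
    undefined = (s[..., 1] == 0) & (s[..., 2] == 0)
    roll = np.where(undefined, np.nan, roll)
    return roll[0] if np.asarray(static).ndim == 1 else roll


def default_period_grid(
    period_range_s: tuple[float, float] = DEFAULT_PERIOD_RANGE_S,
    n_periods: int = DEFAULT_N_PERIODS,
) -> np.ndarray:
    """Log-spaced tail-beat period grid (s); brackets all reported cycles."""
    lo, hi = period_range_s
    if not (0 < lo < hi):
        raise InvalidArgumentError("period range must satisfy 0 < lo < hi")
    return np.logspace(np.log10(lo), np.log10(hi), n_periods)


@lru_cache(maxsize=8)
def _scale_gains(periods_key: tuple, sample_rate: float) -> np.ndarray:
    """Per-scale gain of |CWT| for a unit-amplitude sinusoid at each period.

    Computed numerically once per (grid, rate): dividing moduli by these gains
    makes the reported amplitude read directly in g.
    """
    periods = np.asarray(periods_key)
    scales = _periods_to_scales(periods, sample_rate)
    gains = np.empty(len(periods))
    for i, (p, s) in enumerate(zip(periods, scales)):
        n = int(np.ceil(max(12 * p, 6.0) * sample_rate))
        t = np.arange(n) / sample_rate
        probe = np.sin(2 * np.pi * t / p)
        coef, _ = pywt.cwt(probe, [s], MORLET, sampling_period=1.0 / sample_rate)
        centre = slice(n // 3, 2 * n // 3)
        gains[i] = np.abs(coef[0, centre]).max()
    return gains


def _periods_to_scales(periods: np.ndarray, sample_rate: float) -> np.ndarray:
    fc = pywt.central_frequency(MORLET)
    return fc * sample_rate * periods


def tailbeat_cwt(
    sway_dynamic: np.ndarray,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    periods: np.ndarray | None = None,
    chunk_s: float = 120.0,
    pad_s: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Dominant tail-beat cycle and amplitude per sample via a Morlet CWT.

    For every sample the cycle is the grid period whose (gain-normalised)
    wavelet modulus is largest, and the amplitude is that modulus — scaled so
    a pure sinusoid of amplitude A returns amplitude ≈ A.

    Long series are transformed in overlapping chunks (``chunk_s`` interior,
    ``pad_s`` discarded margins) to bound memory; results are identical to the
    monolithic transform away from the extreme ends.

    Returns
    -------
    (cycle_s, amplitude_g) arrays aligned to the input samples.
    """
    x = np.asarray(sway_dynamic, dtype=float)
    if periods is None:
        periods = default_period_grid()
    periods = np.asarray(periods, dtype=float)
    min_len = int(np.ceil(periods.max() * sample_rate))
    if len(x) < max(min_len, 2):
        raise InsufficientDataError(
            f"series of {len(x)} samples is shorter than the longest analysed "
            f"period ({periods.max()} s at {sample_rate} Hz)"
        )
    scales = _periods_to_scales(periods, sample_rate)
    gains = _scale_gains(tuple(periods), sample_rate)

    n = len(x)
    cycle = np.empty(n)
    amplitude = np.empty(n)
    step = max(int(chunk_s * sample_rate), min_len)
    pad = int(pad_s * sample_rate)
    start = 0
    while start < n:
        stop = min(start + step, n)
        lo = max(start - pad, 0)
        hi = min(stop + pad, n)
        coef, _ = pywt.cwt(
            x[lo:hi], scales, MORLET, sampling_period=1.0 / sample_rate
        )
        norm = np.abs(coef) / gains[:, None]
        seg = slice(start - lo, stop - lo)
        idx = np.argmax(norm[:, seg], axis=0)
        cycle[start:stop] = periods[idx]
        amplitude[start:stop] = np.take_along_axis(
            norm[:, seg], idx[None, :], axis=0
        )[0]
        start = stop
    return cycle, amplitude


def process(
    series: AccelSeries,
    static_window_s: float = DEFAULT_STATIC_WINDOW_S,
    periods: np.ndarray | None = None,
    chunk_s: float = 120.0,
) -> ProcessedSeries:
    """Run the full per-sample derivation chain on a raw series."""
    raw = np.column_stack([series.ax_g, series.ay_g, series.az_g])
    static, dynamic = split_static_dynamic(raw, series.sample_rate, static_window_s)
    vedba = compute_vedba(dynamic)
    pitch = compute_pitch(static)
    roll_abs = compute_roll_abs(static)
    cycle, amplitude = tailbeat_cwt(
        dynamic[:, 2], series.sample_rate, periods=periods, chunk_s=chunk_s
    )
    data = pd.DataFrame(
        {
            "time_s": series.time_s,
            "ax_g": series.ax_g,
            "ay_g": series.ay_g,
            "az_g": series.az_g,
            "static_x": static[:, 0],
            "static_y": static[:, 1],
            "static_z": static[:, 2],
            "dynamic_x": dynamic[:, 0],
            "dynamic_y": dynamic[:, 1],
            "dynamic_z": dynamic[:, 2],
            "vedba": vedba,
            "pitch": pitch,
            "roll_abs": roll_abs,
            "cycle": cycle,
            "amplitude": amplitude,
        }
    )
    return ProcessedSeries(
        data=data,
        sample_rate=series.sample_rate,
        fish_id=series.fish_id,
        depth=series.depth,
        meta={
            "sunrise": series.sunrise,
            "sunset": series.sunset,
            "release_time_s": series.release_time_s,
        },
    )
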