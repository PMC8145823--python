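"""CSV/JSON dialects and model persistence.

All times in file artefacts are seconds since track start (floats); local
clock times (sunrise/sunset, track start) live only in the metadata sidecar.
Floats are written with 9 significant digits so write→read→write round-trips
are byte-stable.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from accelethogram.classify import ClassifierModel, EvaluationReport, confusion_metrics
from accelethogram.errors import InvalidArgumentError, MalformedInputError
from accelethogram.signals import AccelSeries

FLOAT_FMT = "%.9g"
MODEL_FORMAT_VERSION = 1

ACCEL_COLUMNS = ("time_s", "ax_g", "ay_g", "az_g")
MASK_COLUMNS = ("fish_id", "start_s", "end_s", "behaviour")


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _depth_path(path: Path) -> Path:
    return path.with_name(path.stem + ".depth.csv")


def write_accel_csv(series: AccelSeries, path) -> None:
    """Write a raw series; depth goes to a sparse sidecar, metadata to JSON."""
    path = Path(path)
    series.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)
    if series.depth is not None and not series.depth.empty:
        series.depth.to_csv(_depth_path(path), index=False, float_format=FLOAT_FMT)
    meta = {
        "fish_id": series.fish_id,
        "sample_rate": series.sample_rate,
        "sunrise": series.sunrise,
        "sunset": series.sunset,
        "release_time_s": series.release_time_s,
        "logger_range_g": series.logger_range_g,
    }
    _meta_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_accel_csv(path, sample_rate: float | None = None) -> AccelSeries:
    """Read a raw series, validating schema, cadence and logger range.

    Depth is loaded sparse, either from an inline ``depth_m`` column (blank
    off-knot rows) or from the ``<stem>.depth.csv`` sidecar.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ACCEL_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{path.name}: missing columns {missing}")
    meta: dict = {}
    if _meta_path(path).exists():
        meta = json.loads(_meta_path(path).read_text())
    fs = sample_rate or meta.get("sample_rate")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) >= 2:
        dt = np.diff(t)
        if fs is None:
            fs = 1.0 / np.median(dt)
        bad = np.flatnonzero(np.abs(dt - 1.0 / fs) > 1e-6)
        if bad.size:
            i = int(bad[0]) + 1
            raise MalformedInputError(
                f"{path.name}: non-uniform cadence at row {i + 1} "
                f"(time_s={t[i]!r}, expected step {1.0 / fs:.6g} s)"
            )
    elif fs is None:
        raise InvalidArgumentError("sample_rate required for a <2-row series")

    depth = None
    if "depth_m" in df.columns:
        knots = df.loc[df["depth_m"].notna(), ["time_s", "depth_m"]]
        if not knots.empty:
            depth = knots.reset_index(drop=True)
    elif _depth_path(path).exists():
        depth = pd.read_csv(_depth_path(path))
    if depth is not None:
        depth = depth.astype(float)

    series = AccelSeries(
        time_s=t,
        ax_g=df["ax_g"].to_numpy(dtype=float),
        ay_g=df["ay_g"].to_numpy(dtype=float),
        az_g=df["az_g"].to_numpy(dtype=float),
        sample_rate=float(fs),
        depth=depth,
        fish_id=str(meta.get("fish_id", path.stem)),
        sunrise=meta.get("sunrise"),
        sunset=meta.get("sunset"),
        release_time_s=float(meta.get("release_time_s", 0.0)),
        logger_range_g=float(meta.get("logger_range_g", 2.0)),
    )
    n_clipped = int(series.clipped_mask().sum())
    if n_clipped:
        import logging

        logging.getLogger(__name__).warning(
            "%s: %d sample(s) at the ±%g g logger bound flagged as clipped",
            path.name,
            n_clipped,
            series.logger_range_g,
        )
    return series


def write_mask_csv(mask: pd.DataFrame, path) -> None:
    mask[list(MASK_COLUMNS)].to_csv(path, index=False, float_format=FLOAT_FMT)


def read_mask_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MASK_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{Path(path).name}: missing columns {missing}")
    return df


def write_features_csv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "behaviour" in df.columns:
        df["behaviour"] = df["behaviour"].astype(object).where(df["behaviour"].notna(), None)
    return df


def save_model(model: ClassifierModel, path) -> None:
    """Persist a trained model as a versioned joblib archive."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "ntree": model.ntree,
        "mtry": model.mtry,
        "seed": model.seed,
        "predictors": model.predictors,
        "classes": model.classes,
        "oob_error": model.oob_error,
        "importance": model.importance,
        "forest": model.forest,
    }
    joblib.dump(payload, path)


def load_model(path) -> ClassifierModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise MalformedInputError(
            f"model archive version {version!r} unsupported (expected {MODEL_FORMAT_VERSION})"
        )
    return ClassifierModel(
        forest=payload["forest"],
        ntree=payload["ntree"],
        mtry=payload["mtry"],
        seed=payload["seed"],
        predictors=payload["predictors"],
        classes=payload["classes"],
        oob_error=payload["oob_error"],
        importance=payload.get("importance"),
    )


def write_report_json(report: EvaluationReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))


def read_report_json(path) -> EvaluationReport:
    data = json.loads(Path(path).read_text())
    confusion = pd.DataFrame(data["confusion"]).T
    confusion = confusion.loc[list(data["confusion"]), list(data["confusion"])]
    per_class, accuracy = confusion_metrics(confusion)
    return EvaluationReport(
        confusion=confusion,
        per_class=per_class,
        overall_accuracy=data["overall_accuracy"],
        n_test=data.get("n_test", 0),
    )


def write_track_csv(track: pd.DataFrame, path) -> None:
    track.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_track_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
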