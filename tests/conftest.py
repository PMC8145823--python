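"""Shared fixtures: a full 2-h synthetic experiment and small per-class traces."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from accelethogram import classify, features, signals, synth

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@dataclass
class Experiment:
    """Everything the default synthetic study produces, end to end."""

    series: signals.AccelSeries
    mask: pd.DataFrame
    schedule: synth.Schedule
    processed: signals.ProcessedSeries
    windows: pd.DataFrame  # all windows, labelled where ground truth covers them
    labelled: pd.DataFrame
    train: pd.DataFrame
    test: pd.DataFrame
    model: classify.ClassifierModel
    report: classify.EvaluationReport


@pytest.fixture(scope="session")
def experiment() -> Experiment:
    """Default study conditions: 2 h, published class mix, fixed seeds."""
    series, mask, schedule = synth.generate_dataset(seed=11)
    processed = signals.process(series)
    windows = features.join_labels(features.summarise_windows(processed), mask)
    labelled = features.labelled_rows(windows)
    train, test = classify.split_train_test(labelled, 0.7, seed=5)
    model = classify.train_forest(train, ntree=1000, seed=7)
    report = classify.evaluate(model, test)
    return Experiment(
        series=series,
        mask=mask,
        schedule=schedule,
        processed=processed,
        windows=windows,
        labelled=labelled,
        train=train,
        test=test,
        model=model,
        report=report,
    )


@pytest.fixture(scope="session")
def class_traces() -> dict[str, signals.ProcessedSeries]:
    """>=500 s of each behaviour class, processed through the signal chain."""
    from accelethogram.behaviours import BEHAVIOUR_CLASSES

    out = {}
    for i, label in enumerate(BEHAVIOUR_CLASSES):
        trace = synth.synthesize_class_trace(label, 520.0, seed=100 + i)
        out[label] = signals.process(trace)
    return out
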