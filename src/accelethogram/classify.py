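"""Random-forest ethogram classifier: training, hyperparameter sweep, evaluation.

The forest follows the published protocol: pooled 70/30 train/test split,
``ntree`` = 1000 trees, ``mtry`` = ⌊√p⌋ features per split, majority vote.
Ties in the vote are broken by the canonical class order (swim, feed, escape,
courtship, chafe).  Evaluation derives per-class precision, recall and F1
directly from the confusion-matrix counts:

    P = TP / (TP + FP),   R = TP / (TP + FN),   F1 = 2PR / (P + R),

with F1 = 0 when P + R = 0, and overall accuracy = trace / total.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from accelethogram.behaviours import BEHAVIOUR_CLASSES
from accelethogram.errors import DegenerateTrainingError, InvalidArgumentError

logger = logging.getLogger(__name__)

LABEL_COLUMN = "behaviour"
_NON_PREDICTOR = {"window_start", "fish_id", LABEL_COLUMN, "depth_m", "diel"}


def _predictor_names(features: pd.DataFrame) -> list[str]:
    return [c for c in features.columns if c not in _NON_PREDICTOR]


def split_train_test(
    features: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform random row split pooled across individuals.

    Deterministic per seed; warns (does not fail) when a class present in the
    pool is absent from the training partition.
    """
    if not (0 < train_fraction < 1):
        raise InvalidArgumentError("train_fraction must be in (0, 1)")
    n = len(features)
    if n < 2:
        raise InvalidArgumentError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)  # both partitions non-empty
    train = features.iloc[order[:n_train]].reset_index(drop=True)
    test = features.iloc[order[n_train:]].reset_index(drop=True)
    if LABEL_COLUMN in features.columns:
        pooled = set(features[LABEL_COLUMN].dropna())
        missing = pooled - set(train[LABEL_COLUMN].dropna())
        if missing:
            warnings.warn(
                f"classes absent from training partition: {sorted(missing)}",
                stacklevel=2,
            )
            logger.warning("classes absent from training partition: %s", sorted(missing))
    return train, test


@dataclass
class ClassifierModel:
    """Trained forest plus the metadata needed to reapply it safely."""

    forest: RandomForestClassifier
    ntree: int
    mtry: int
    seed: int
    predictors: list[str]
    classes: list[str]
    oob_error: float
    importance: pd.Series | None = None

    def _matrix(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.predictors if c not in features.columns]
        if missing:
            raise InvalidArgumentError(f"prediction input lacks predictors: {missing[:5]}")
        return features[self.predictors].to_numpy(dtype=float)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Majority-vote class labels; ties break by canonical class order."""
        proba = self.forest.predict_proba(self._matrix(features))
        # forest classes_ are canonical-order integer codes; argmax returns the
        # first (highest-priority) class on exact vote ties
        codes = self.forest.classes_[np.argmax(proba, axis=1)]
        lookup = np.array(BEHAVIOUR_CLASSES, dtype=object)
        return lookup[codes]


def _permutation_importance(
    forest: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    predictors: list[str],
    rng: np.random.Generator,
    max_rows: int = 1000,
    n_repeats: int = 2,
) -> pd.Series:
    """Mean decrease in accuracy when each predictor is permuted (seeded)."""
    if len(X) > max_rows:
        idx = rng.choice(len(X), size=max_rows, replace=False)
        X, y = X[idx], y[idx]
    baseline = float(np.mean(forest.predict(X) == y))
    drops = np.zeros(len(predictors))
    for j in range(X.shape[1]):
        accs = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            accs.append(float(np.mean(forest.predict(Xp) == y)))
        drops[j] = baseline - float(np.mean(accs))
    return pd.Series(drops, index=predictors, name="mean_decrease_accuracy").sort_values(
        ascending=False
    )


def train_forest(
    train: pd.DataFrame,
    ntree: int = 1000,
    mtry: int | None = None,
    seed: int = 0,
    stratify: bool = False,
    compute_importance: bool = False,
) -> ClassifierModel:
    """Fit the random forest on labelled feature windows.

    ``mtry`` defaults to ⌊√p⌋ over the p predictor columns.  ``stratify``
    switches on sklearn's balanced-subsample class weighting, the analogue of
    the stratified-bootstrap variant that was tested and rejected in the
    source protocol; it is off by default.  OOB error is always recorded;
    mean-decrease-in-accuracy importance (seeded permutation importance on a
    capped training subsample) is computed on request.
    """
    labelled = train[train[LABEL_COLUMN].notna()]
    predictors = _predictor_names(train)
    classes = sorted(set(labelled[LABEL_COLUMN]), key=BEHAVIOUR_CLASSES.index)
    if len(classes) < 2:
        raise DegenerateTrainingError(
            f"training data holds {len(classes)} class(es); need >= 2"
        )
    X = labelled[predictors].to_numpy(dtype=float)
    y = np.array([BEHAVIOUR_CLASSES.index(label) for label in labelled[LABEL_COLUMN]])
    p = len(predictors)
    if mtry is None:
        mtry = max(int(np.floor(np.sqrt(p))), 1)
    forest = RandomForestClassifier(
        n_estimators=ntree,
        max_features=min(mtry, p),
        oob_score=True,
        random_state=seed,
        class_weight="balanced_subsample" if stratify else None,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # small fixtures can leave some rows never out-of-bag
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        forest.fit(X, y)
    oob_error = float(1.0 - forest.oob_score_)
    importance = None
    if compute_importance:
        rng = np.random.default_rng(seed + 1)
        importance = _permutation_importance(forest, X, y, predictors, rng)
    logger.info("trained forest: ntree=%d mtry=%d oob_error=%.4f", ntree, mtry, oob_error)
    return ClassifierModel(
        forest=forest,
        ntree=ntree,
        mtry=mtry,
        seed=seed,
        predictors=predictors,
        classes=classes,
        oob_error=oob_error,
        importance=importance,
    )


def sweep_hyperparameters(
    train: pd.DataFrame,
    ntree_grid: tuple[int, ...] = (500, 1000, 1500, 2000),
    mtry_grid: tuple[int, ...] = (5, 10, 15, 20),
    seed: int = 0,
    plateau_after: int = 1000,
    plateau_tol: float = 0.005,
) -> pd.DataFrame:
    """OOB error over an ntree × mtry grid.

    The ``plateau`` column flags grid points beyond ``plateau_after`` trees
    whose OOB error differs by less than ``plateau_tol`` (0.5 points) from the
    same-``mtry`` fit at ``plateau_after`` — forests are expected to have
    stabilised there.
    """
    rows = []
    for mtry in mtry_grid:
        ref_error = None
        for ntree in sorted(ntree_grid):
            model = train_forest(train, ntree=ntree, mtry=mtry, seed=seed)
            if ntree == plateau_after:
                ref_error = model.oob_error
            rows.append({"ntree": ntree, "mtry": mtry, "oob_error": model.oob_error})
        for row in rows:
            if row["mtry"] == mtry:
                row["plateau"] = bool(
                    ref_error is not None
                    and row["ntree"] > plateau_after
                    and abs(row["oob_error"] - ref_error) < plateau_tol
                )
    return pd.DataFrame(rows)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (report-table convention; 0.125 → 0.13)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass
class EvaluationReport:
    """Confusion matrix (rows = actual, columns = predicted) plus metrics."""

    confusion: pd.DataFrame
    per_class: pd.DataFrame  # columns: precision, recall, f1 (full precision)
    overall_accuracy: float
    n_test: int = 0

    def per_class_rounded(self, ndigits: int = 2) -> pd.DataFrame:
        return self.per_class.map(lambda v: round_half_up(v, ndigits))

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "n_test": self.n_test,
            "confusion": {
                actual: {pred: int(v) for pred, v in row.items()}
                for actual, row in self.confusion.iterrows()
            },
            "per_class": {
                cls: {k: float(v) for k, v in row.items()}
                for cls, row in self.per_class.iterrows()
            },
        }


def confusion_metrics(confusion: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-class P/R/F1 and overall accuracy from a confusion-count table."""
    counts = confusion.to_numpy(dtype=float)
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
    f1 = np.array([f1_score(p, r) for p, r in zip(precision, recall)])
    total = counts.sum()
    accuracy = float(tp.sum() / total) if total else 0.0
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1}, index=confusion.index
    )
    return per_class, accuracy


def evaluate(model: ClassifierModel, test: pd.DataFrame) -> EvaluationReport:
    """Score the model on labelled test windows."""
    if LABEL_COLUMN not in test.columns or test[LABEL_COLUMN].isna().any():
        raise InvalidArgumentError("test rows must all carry a behaviour label")
    actual = test[LABEL_COLUMN].to_numpy(dtype=object)
    predicted = model.predict(test)
    classes = [c for c in BEHAVIOUR_CLASSES if c in set(actual) | set(predicted)]
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for a, p in zip(actual, predicted):
        counts.loc[a, p] += 1
    per_class, accuracy = confusion_metrics(counts)
    return EvaluationReport(
        confusion=counts,
        per_class=per_class,
        overall_accuracy=accuracy,
        n_test=len(test),
    )
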