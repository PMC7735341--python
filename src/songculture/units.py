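"""Quantitative validation of qualitative unit-type labels.

Each song unit carries 11 numeric acoustic parameters (durations,
frequencies, derived ratios, inflection and pulse counts) and a qualitative
type name assigned by eye during transcription.  A random forest trained to
predict the qualitative name from the numeric parameters measures how well
the subjective labels are supported by the measurements: a low out-of-bag
(OOB) error means the qualitative classification is robust and repeatable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .corpus import CorpusError, UnitObservation

__all__ = ["derive_features", "RFReport", "rf_agreement", "UnitAgreementForest"]

FEATURES = list(UnitObservation.NUMERIC_FIELDS)


def derive_features(raw: Mapping) -> UnitObservation:
    """Build a validated :class:`UnitObservation` from raw measurements.

    ``raw`` supplies the measured fields (duration, peak/high/low/start/end
    frequency, inflections, pulse_rate, qualitative_name); the derived ones
    are computed here: frequency_trend = start/end, frequency_range =
    high/low, bandwidth = high − low (unless supplied, in which case it is
    checked for consistency).
    """
    raw = dict(raw)
    for f in ("end_frequency", "low_frequency"):
        if float(raw.get(f, 0.0)) == 0.0:
            raise ZeroDivisionError(f"{f} is zero; derived ratios are undefined")
    high, low = float(raw["high_frequency"]), float(raw["low_frequency"])
    if high < low:
        raise CorpusError(f"high_frequency {high} < low_frequency {low}")
    return UnitObservation(
        duration=float(raw["duration"]),
        bandwidth=float(raw.get("bandwidth", high - low)),
        peak_frequency=float(raw["peak_frequency"]),
        high_frequency=high,
        low_frequency=low,
        start_frequency=float(raw["start_frequency"]),
        end_frequency=float(raw["end_frequency"]),
        frequency_trend=float(raw["start_frequency"]) / float(raw["end_frequency"]),
        frequency_range=high / low,
        inflections=int(raw.get("inflections", 0)),
        pulse_rate=float(raw.get("pulse_rate", 0.0)),
        qualitative_name=str(raw["qualitative_name"]),
    )


@dataclass
class RFReport:
    """Random-forest agreement summary between labels and measurements."""

    oob_error: float
    confusion: pd.DataFrame          # rows = true class, cols = OOB-predicted
    importance: pd.Series            # mean decrease in accuracy per feature
    n_trees: int
    vars_per_split: int
    seed: int | None

    def __post_init__(self):
        trace = float(np.trace(self.confusion.to_numpy()))
        total = float(self.confusion.to_numpy().sum())
        # definitional identity: OOB accuracy is the confusion-matrix trace
        assert np.isclose(trace / total, 1.0 - self.oob_error, atol=1e-12)


class UnitAgreementForest(BaseEstimator):
    """Random-forest check of unit-label/measurement agreement.

    Wraps a :class:`~sklearn.ensemble.RandomForestClassifier` grown with
    bootstrap sampling so every unit has an out-of-bag prediction.  Defaults
    follow standard practice for this task: 1000 trees, 3 candidate
    variables per split.

    Attributes (after ``fit``)
    --------------------------
    oob_error_ : float
        Fraction of units whose OOB-predicted class differs from the label.
    confusion_ : DataFrame
        OOB confusion matrix (rows true, columns predicted); row sums equal
        per-class observation counts.
    importance_ : Series
        Permutation importance (mean decrease in accuracy) per parameter.
    report_ : RFReport
    """

    def __init__(self, n_trees: int = 1000, vars_per_split: int = 3,
                 n_permutations: int = 5, random_state: int | None = None):
        self.n_trees = n_trees
        self.vars_per_split = vars_per_split
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X, y=None):
        X, y, classes = _as_feature_frame(X, y)
        if len(classes) < 2:
            raise ValueError("need at least 2 unit classes")
        counts = y.value_counts()
        if counts.min() < 2:
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"every class needs >= 2 observations; too few in {small}")
        if not np.isfinite(X.to_numpy()).all():
            bad = int(np.where(~np.isfinite(X.to_numpy()).all(axis=1))[0][0])
            raise ValueError(f"non-finite feature value in record {bad}")

        rf = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=min(self.vars_per_split, X.shape[1]),
            oob_score=True,
            bootstrap=True,
            random_state=self.random_state,
        )
        rf.fit(X, y)
        proba = rf.oob_decision_function_
        pred = pd.Categorical.from_codes(
            proba.argmax(axis=1), categories=list(rf.classes_)
        )
        oob_error = float(np.mean(np.asarray(pred) != y.to_numpy()))
        confusion = pd.crosstab(
            pd.Categorical(y, categories=list(rf.classes_)),
            pred,
            rownames=["true"],
            colnames=["predicted"],
            dropna=False,
        )
        imp = permutation_importance(
            rf, X, y, n_repeats=self.n_permutations,
            random_state=self.random_state, scoring="accuracy",
        )
        importance = pd.Series(imp.importances_mean, index=X.columns,
                               name="mean_decrease_accuracy").sort_values(ascending=False)
        self.estimator_ = rf
        self.classes_ = rf.classes_
        self.oob_error_ = oob_error
        self.confusion_ = confusion
        self.importance_ = importance
        self.report_ = RFReport(
            oob_error=oob_error,
            confusion=confusion,
            importance=importance,
            n_trees=self.n_trees,
            vars_per_split=self.vars_per_split,
            seed=self.random_state,
        )
        return self

    def predict(self, X):
        X, _, _ = _as_feature_frame(X, None, require_labels=False)
        return self.estimator_.predict(X)


def _as_feature_frame(X, y, require_labels: bool = True):
    """Normalize input to (feature frame, label series, classes)."""
    if isinstance(X, (list, tuple)) and X and isinstance(X[0], UnitObservation):
        rows = [{f: getattr(u, f) for f in FEATURES} for u in X]
        labels = [u.qualitative_name for u in X]
        X = pd.DataFrame(rows)
        y = pd.Series(labels) if y is None else pd.Series(y)
    elif isinstance(X, pd.DataFrame):
        X = X.copy()
        if y is None and "qualitative_name" in X.columns:
            y = X.pop("qualitative_name")
        X = X[FEATURES]
        y = pd.Series(y).reset_index(drop=True) if y is not None else None
        X = X.reset_index(drop=True)
    else:
        raise ValueError("X must be UnitObservations or a units DataFrame")
    if require_labels and y is None:
        raise ValueError("labels are required")
    classes = sorted(set(y)) if y is not None else []
    return X, y, classes


def rf_agreement(
    observations: Iterable[UnitObservation] | pd.DataFrame,
    trees: int = 1000,
    vars_per_split: int = 3,
    seed: int | None = None,
) -> RFReport:
    """Out-of-bag agreement between qualitative labels and measurements."""
    obs = observations if isinstance(observations, pd.DataFrame) else list(observations)
    forest = UnitAgreementForest(
        n_trees=trees, vars_per_split=vars_per_split, random_state=seed
    ).fit(obs)
    return forest.report_
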