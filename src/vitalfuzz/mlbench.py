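"""Multi-classifier evaluation harness for condition prediction.

Five classifiers (support vector, Gaussian naive Bayes, decision tree,
random forest, Bernoulli naive Bayes) are fitted on labeled vital-sign
records under a stratified train/test split and scored with accuracy and
macro-averaged precision, recall and F1.  Features are either the raw vital
values or their ordinal crisp-label encodings.  On synthetic cohorts whose
labels come from the inference pipeline this is a closed-loop consistency
check: tree ensembles should essentially recover the finite rule table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core import VITAL_ORDER, VOCABULARY, RangeTable, VitalKind, classify_vital, default_range_table

ALGORITHMS = ("support_vector", "gaussian_nb", "decision_tree", "random_forest", "bernoulli_nb")


@dataclass(frozen=True)
class BenchConfig:
    """Benchmark settings: algorithms, split, seed and feature encoding."""

    algorithms: tuple[str, ...] = ALGORITHMS
    test_fraction: float = 0.2
    seed: int = 0
    feature_mode: str = "crisp_labels"  # "raw_values" | "crisp_labels"

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if not self.algorithms:
            raise ValueError("at least one algorithm required")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")
        if self.feature_mode not in ("raw_values", "crisp_labels"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")


@dataclass(frozen=True)
class MetricsRow:
    """Held-out metrics for one classifier (macro-averaged)."""

    algorithm: str
    accuracy: float
    f1: float
    precision: float
    recall: float


def _make_classifier(name: str, seed: int):
    # Fixed, documented hyperparameters: library defaults with pinned seeds.
    if name == "support_vector":
        return SVC(random_state=seed)
    if name == "gaussian_nb":
        return GaussianNB()
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if name == "bernoulli_nb":
        return BernoulliNB()
    raise ValueError(f"unknown algorithm {name!r}")


def make_features(
    frame: pd.DataFrame,
    feature_mode: str = "crisp_labels",
    table: RangeTable | None = None,
) -> np.ndarray:
    """Feature matrix from a records table (one column per vital).

    ``raw_values`` uses the numeric readings; ``crisp_labels`` replaces each
    reading with the ordinal index of its crisp label in the vital's
    vocabulary (0 = lowest label).
    """
    if table is None:
        table = default_range_table()
    cols = [k.value for k in VITAL_ORDER]
    raw = frame[cols].to_numpy(dtype=float)
    if feature_mode == "raw_values":
        return raw
    encoded = np.empty_like(raw)
    for j, kind in enumerate(VITAL_ORDER):
        vocab = VOCABULARY[kind]
        encoded[:, j] = [vocab.index(classify_vital(v, kind, table)) for v in raw[:, j]]
    return encoded


def run_benchmark(frame: pd.DataFrame, labels: pd.Series | np.ndarray, cfg: BenchConfig) -> list[MetricsRow]:
    """Fit and score each configured classifier; deterministic under cfg.seed."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("benchmark needs at least two classes")
    X = make_features(frame, cfg.feature_mode)
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=cfg.test_fraction, random_state=cfg.seed, stratify=y
    )
    rows = []
    for name in cfg.algorithms:
        clf = _make_classifier(name, cfg.seed)
        clf.fit(X_train, y_train)
        pred = clf.predict(X_test)
        rows.append(
            MetricsRow(
                algorithm=name,
                accuracy=float(accuracy_score(y_test, pred)),
                f1=float(f1_score(y_test, pred, average="macro", zero_division=0)),
                precision=float(precision_score(y_test, pred, average="macro", zero_division=0)),
                recall=float(recall_score(y_test, pred, average="macro", zero_division=0)),
            )
        )
    return rows


def metrics_frame(rows: list[MetricsRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "algorithm": r.algorithm,
                "accuracy": r.accuracy,
                "f1": r.f1,
                "precision": r.precision,
                "recall": r.recall,
            }
            for r in rows
        ]
    )


def compare_report(rows_a: list[MetricsRow], rows_b: list[MetricsRow]) -> pd.DataFrame:
    """Side-by-side accuracy comparison of two benchmark runs.

    Both runs must cover the same algorithm set; the result has one row per
    algorithm with both accuracies and the delta (a - b).
    """
    a = {r.algorithm: r for r in rows_a}
    b = {r.algorithm: r for r in rows_b}
    if set(a) != set(b) or not a:
        raise ValueError(f"algorithm sets differ or are empty: {sorted(a)} vs {sorted(b)}")
    return pd.DataFrame(
        [
            {
                "algorithm": name,
                "accuracy_a": a[name].accuracy,
                "accuracy_b": b[name].accuracy,
                "delta": a[name].accuracy - b[name].accuracy,
            }
            for name in sorted(a)
        ]
    )
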