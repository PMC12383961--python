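"""Classifiers, the 31-subgroup majority-vote ensemble, and evaluation.

Six classifier families are trained on the 11-dimensional PCA inputs:
linear logistic regression, linear soft-margin SVM, LDA, 3-nearest
neighbours, a 100-tree random forest and a small fully connected network
(one ReLU hidden layer).  The ensemble partitions the trials of every
condition into 31 non-overlapping subgroups, averages each subgroup into
its own band-series grid, runs the full feature/selection/PCA/classifier
pipeline independently per subgroup, and aggregates test predictions by
majority vote.  Selection and PCA are re-fitted inside every member on
training subjects only, preserving the leakage guarantee member-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, precision_score, recall_score,
                             roc_auc_score)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

from .config import PipelineConfig
from .selection import (POSITIVE_CLASS, SelectionResult, SplitPlan,
                        apply_projection, fit_project, make_splits,
                        ttest_select)

CLASSIFIER_KINDS = ("logistic_regression", "linear_svm", "lda", "knn",
                    "random_forest", "ann")


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family with pinned hyperparameters."""

    kind: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")


def make_classifier(spec: ClassifierSpec):
    """Instantiate the sklearn estimator for a spec.

    Hyperparameters are pinned: LR (L2, C=1), linear SVM (hinge, C=1),
    LDA (SVD solver), KNN (k=3, Euclidean), RF (100 trees), ANN (one
    32-unit ReLU hidden layer, full-batch L-BFGS training).
    """
    if spec.kind == "logistic_regression":
        return LogisticRegression(C=1.0, max_iter=2000)  # L2 by default
    if spec.kind == "linear_svm":
        return LinearSVC(C=1.0, loss="hinge", max_iter=20000)
    if spec.kind == "lda":
        return LinearDiscriminantAnalysis()
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=3, metric="euclidean")
    if spec.kind == "random_forest":
        return RandomForestClassifier(n_estimators=100,
                                      random_state=spec.seed)
    if spec.kind == "ann":
        return MLPClassifier(hidden_layer_sizes=(32,), activation="relu",
                             solver="lbfgs", max_iter=200,
                             random_state=spec.seed)
    raise AssertionError


def score_samples(model, x: np.ndarray) -> np.ndarray:
    """Continuous class-1 propensity for AUROC (probability or margin)."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x)[:, 1]
    return model.decision_function(x)


def partition_trials(n_trials: int, n_subgroups: int = 31, seed: int = 0,
                     scheme: str = "contiguous") -> list[np.ndarray]:
    """Deterministic partition of trial indices into subgroups.

    Sizes differ by at most one (72 into 31 gives ten groups of 3 and
    twenty-one of 2).  ``contiguous`` slices trials in recording order;
    ``interleaved`` deals them round-robin after a seeded shuffle.
    """
    if n_trials < n_subgroups:
        raise ValueError(f"cannot partition {n_trials} trials into "
                         f"{n_subgroups} non-empty subgroups")
    order = np.arange(n_trials)
    if scheme == "interleaved":
        np.random.default_rng(seed).shuffle(order)
        return [np.sort(order[g::n_subgroups]) for g in range(n_subgroups)]
    if scheme != "contiguous":
        raise ValueError(f"unknown scheme {scheme!r}")
    base, extra = divmod(n_trials, n_subgroups)
    sizes = [base + 1] * extra + [base] * (n_subgroups - extra)
    bounds = np.cumsum([0] + sizes)
    return [order[bounds[g]:bounds[g + 1]] for g in range(n_subgroups)]


def majority_vote(member_labels: np.ndarray, tie_break: int = 1) -> np.ndarray:
    """Most frequent label per column of a (members, samples) array.

    With an odd member count ties cannot occur; for even counts the tie
    goes to ``tie_break`` (the positive class by default).
    """
    member_labels = np.atleast_2d(np.asarray(member_labels))
    ones = (member_labels == 1).sum(axis=0)
    zeros = member_labels.shape[0] - ones
    out = (ones > zeros).astype(int)
    if member_labels.shape[0] % 2 == 0:
        out[ones == zeros] = tie_break
    return out


@dataclass
class FittedMember:
    """One pipeline member: selection mask + projection + classifier."""

    selection: SelectionResult
    projection: object
    model: object

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        return apply_projection(self.projection, features)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.model.predict(self.transform(features))

    def score(self, features: pd.DataFrame) -> np.ndarray:
        return score_samples(self.model, self.transform(features))


def fit_member(features: pd.DataFrame, y: np.ndarray, train_idx: np.ndarray,
               spec: ClassifierSpec, config: PipelineConfig) -> FittedMember:
    """Fit selection, PCA and a classifier using training rows only."""
    train_features = features.iloc[train_idx]
    y_train = y[train_idx]
    selection = ttest_select(train_features, y_train, alpha=config.alpha)
    projection = fit_project(train_features, selection,
                             n_components=config.n_components,
                             scale=config.scale_features)
    model = make_classifier(spec)
    model.fit(apply_projection(projection, train_features), y_train)
    return FittedMember(selection=selection, projection=projection,
                        model=model)


@dataclass
class EnsembleModel:
    """Independently fitted members aggregated by majority vote."""

    members: list[FittedMember]

    def predict(self, features_per_member: list[pd.DataFrame]) -> np.ndarray:
        votes = np.stack([m.predict(f) for m, f in
                          zip(self.members, features_per_member)])
        return majority_vote(votes)

    def score(self, features_per_member: list[pd.DataFrame]) -> np.ndarray:
        """Mean member score: finer-grained than the vote fraction."""
        return np.mean([m.score(f) for m, f in
                        zip(self.members, features_per_member)], axis=0)


def encode_labels(labels) -> np.ndarray:
    """preAD -> 1 (positive class), NO -> 0."""
    return np.asarray([1 if lab == POSITIVE_CLASS else 0 for lab in labels])


METRICS = ("accuracy", "precision", "recall", "auroc")


@dataclass
class SplitReport:
    """Per-round test metrics per classifier kind, plus aggregates.

    ``details`` holds one row per (round, test subject) with the true and
    predicted labels — the basis for subject-level (cluster-robust)
    uncertainty, since rounds share subjects and are not independent.
    """

    rounds: dict[str, pd.DataFrame]   # kind -> (n_rounds x metrics)
    details: dict[str, pd.DataFrame] = field(default_factory=dict)

    def subject_accuracy(self, kind: str) -> pd.Series:
        """Per-subject fraction of correct test predictions across rounds."""
        d = self.details[kind]
        return (d["y_true"] == d["y_pred"]).groupby(d["subject"]).mean()

    def summary(self) -> pd.DataFrame:
        rows = {}
        for kind, frame in self.rounds.items():
            row = {}
            for m in METRICS:
                row[f"{m}_mean"] = frame[m].mean()
                row[f"{m}_std"] = frame[m].std(ddof=1) if len(frame) > 1 else 0.0
            rows[kind] = row
        return pd.DataFrame(rows).T

    def formatted(self) -> pd.DataFrame:
        """Percent-scale mean~std table (rows = classifiers)."""
        s = self.summary()
        out = {}
        for m in METRICS:
            out[m] = [f"{100 * mu:.2f}~{100 * sd:.2f}"
                      for mu, sd in zip(s[f"{m}_mean"], s[f"{m}_std"])]
        return pd.DataFrame(out, index=s.index)


def _metric_row(y_true: np.ndarray, y_pred: np.ndarray,
                scores: np.ndarray) -> dict[str, float]:
    row = {
        "accuracy": accuracy_score(y_true, y_pred),
        "precision": precision_score(y_true, y_pred, zero_division=0),
        "recall": recall_score(y_true, y_pred, zero_division=0),
    }
    if np.unique(y_true).size == 2 and np.unique(scores).size > 1:
        row["auroc"] = roc_auc_score(y_true, scores)
    else:  # degenerate score vector: no ranking information
        row["auroc"] = 0.5
    return row


def evaluate_tables(single_table: pd.DataFrame | None,
                    member_tables: list[pd.DataFrame] | None,
                    labels, specs: list[ClassifierSpec],
                    plans: list[SplitPlan],
                    config: PipelineConfig) -> SplitReport:
    """Train and test every classifier over precomputed feature tables.

    ``single_table`` drives the no-ensemble mode; ``member_tables`` (one
    feature table per trial subgroup) drives the majority-vote ensemble.
    Exactly one of them must be given.
    """
    if (single_table is None) == (member_tables is None):
        raise ValueError("provide exactly one of single_table/member_tables")
    y = encode_labels(labels)
    tables = [single_table] if single_table is not None else member_tables
    rows: dict[str, list[dict[str, float]]] = {s.kind: [] for s in specs}
    detail_rows: dict[str, list] = {s.kind: [] for s in specs}
    for plan in plans:
        y_train, y_test = y[plan.train], y[plan.test]
        # selection + projection are classifier-independent: fit once per
        # member on the training rows and reuse the coordinates
        coords = []
        for table in tables:
            train_features = table.iloc[plan.train]
            sel = ttest_select(train_features, y_train, alpha=config.alpha)
            proj = fit_project(train_features, sel,
                               n_components=config.n_components,
                               scale=config.scale_features)
            coords.append((apply_projection(proj, train_features),
                           apply_projection(proj, table.iloc[plan.test])))
        for spec in specs:
            votes, scores = [], []
            for x_train, x_test in coords:
                model = make_classifier(spec)
                model.fit(x_train, y_train)
                votes.append(model.predict(x_test))
                scores.append(score_samples(model, x_test))
            y_pred = majority_vote(np.stack(votes))
            mean_scores = np.mean(scores, axis=0)
            rows[spec.kind].append(_metric_row(y_test, y_pred, mean_scores))
            for pos, subject in enumerate(plan.test):
                detail_rows[spec.kind].append(
                    (plan.round_index, int(subject), int(y_test[pos]),
                     int(y_pred[pos]), float(mean_scores[pos])))
    details = {
        k: pd.DataFrame(v, columns=["round", "subject", "y_true", "y_pred",
                                    "score"])
        for k, v in detail_rows.items()
    }
    return SplitReport(rounds={k: pd.DataFrame(v) for k, v in rows.items()},
                       details=details)
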