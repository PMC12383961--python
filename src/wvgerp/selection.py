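"""Leakage-safe feature selection and dimensionality reduction.

Selection and projection are fitted on training subjects only: a
two-sample two-tailed t-test per feature with a p < 0.01 mask, followed
by PCA of the selected columns down to 11 components.  Test rows never
enter the fits, which keeps the reported test metrics honest with far
more features (8676) than subjects (40).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .config import CCSS_KEY

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "preAD"


@dataclass(frozen=True)
class SplitPlan:
    """One train/test division of the cohort by subject index."""

    train: np.ndarray
    test: np.ndarray
    round_index: int

    def __post_init__(self) -> None:
        if np.intersect1d(self.train, self.test).size:
            raise ValueError("train and test overlap")


def make_splits(labels: list[str] | np.ndarray, n_rounds: int = 100,
                test_frac: float = 0.15, seed: int = 0) -> list[SplitPlan]:
    """Random 85/15 splits with group-matched test sets.

    The test set holds ``round(test_frac * n_subjects) / 2`` subjects per
    group (at least one each), so both groups are equally represented at
    evaluation; everything else trains.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("need exactly two groups")
    per_group = [np.flatnonzero(labels == g) for g in groups]
    if min(len(ix) for ix in per_group) < 2:
        raise ValueError("both groups need at least two subjects")
    n_test_per_group = int(round(test_frac * labels.size)) // 2
    if n_test_per_group < 1:
        raise ValueError("test_frac yields fewer than one subject per group")
    rng = np.random.default_rng(seed)
    plans = []
    for r in range(n_rounds):
        test = np.sort(np.concatenate([
            rng.choice(ix, size=n_test_per_group, replace=False)
            for ix in per_group
        ]))
        train = np.setdiff1d(np.arange(labels.size), test)
        plans.append(SplitPlan(train=train, test=test, round_index=r))
    return plans


@dataclass
class SelectionResult:
    """Per-feature p-values and the p < alpha mask (training data only)."""

    pvalues: pd.Series
    mask: pd.Series
    alpha: float

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def selected_names(self) -> list[str]:
        return list(self.mask.index[self.mask])


def ttest_select(features: pd.DataFrame, labels: np.ndarray,
                 alpha: float = 0.01, equal_var: bool = True) -> SelectionResult:
    """Two-sample two-tailed t-test per feature column.

    Student (pooled-variance) by default; ``equal_var=False`` gives the
    Welch variant.  Features constant in both groups get p = 1.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("need exactly two groups")
    a = features.values[labels == groups[0]]
    b = features.values[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two training subjects")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), \
            warnings.catch_warnings():
        # near-constant columns (discrete graph features) trigger scipy's
        # precision-loss warning; their p-values are forced to 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    p = np.where(np.isnan(p), 1.0, p)
    pvalues = pd.Series(p, index=features.columns)
    mask = pvalues < alpha
    return SelectionResult(pvalues=pvalues, mask=mask, alpha=alpha)


def marginal_counts(result: SelectionResult, rows: str,
                    conditions: tuple[str, ...]) -> pd.DataFrame:
    """Selected-feature counts broken down as condition columns.

    ``rows`` is ``"band"``, ``"channel"`` or ``"feature"``; the CCSS
    feature is keyed under the channel sentinel ``ALL``.  Row and column
    sums cross-foot to the same total.
    """
    part = {"channel": 0, "band": 1, "condition": 2, "feature": 3}
    if rows not in ("band", "channel", "feature"):
        raise ValueError("rows must be 'band', 'channel' or 'feature'")
    selected = result.selected_names()
    table: dict[str, dict[str, int]] = {}
    for name in selected:
        bits = name.split("|")
        r = bits[part[rows]]
        c = bits[part["condition"]]
        table.setdefault(r, {}).setdefault(c, 0)
        table[r][c] += 1
    frame = pd.DataFrame(table).T.reindex(columns=list(conditions)).fillna(0)
    frame = frame.astype(int)
    frame["Total"] = frame.sum(axis=1)
    return frame


@dataclass
class ProjectionModel:
    """Centred linear projection fitted on selected training columns."""

    columns: list[str]
    mean: np.ndarray
    scale: np.ndarray | None
    components: np.ndarray            # (n_components, n_features)
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_project(features: pd.DataFrame, selection: SelectionResult,
                n_components: int = 11,
                scale: bool = False) -> ProjectionModel:
    """PCA of the selected columns of the training rows.

    If fewer than ``n_components`` features survive selection, all
    surviving directions are used; if none survive, the ``n_components``
    smallest-p features are taken instead.  Both fallbacks are logged.
    """
    cols = selection.selected_names()
    if not cols:
        cols = list(selection.pvalues.nsmallest(n_components).index)
        logger.warning("no features selected at alpha=%g; falling back to "
                       "the %d smallest-p features", selection.alpha,
                       len(cols))
    # fresh contiguous copy: keeps the fit bit-reproducible regardless of
    # the parent table's memory layout
    x = np.array(features[cols].values, dtype=float, order="C")
    n_comp = min(n_components, x.shape[1], x.shape[0])
    if n_comp < n_components:
        # routine under unlucky splits / small member tables
        logger.debug("projecting onto %d < %d available directions",
                     n_comp, n_components)
    mean = x.mean(axis=0)
    sd = None
    if scale:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - mean) / sd
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(x if scale else x - mean)
    return ProjectionModel(columns=cols, mean=mean, scale=sd,
                           components=pca.components_,
                           explained_variance_ratio=pca.explained_variance_ratio_)


def apply_projection(model: ProjectionModel, features: pd.DataFrame) -> np.ndarray:
    """Project rows using training statistics only."""
    x = np.array(features[model.columns].values, dtype=float,
                 order="C") - model.mean
    if model.scale is not None:
        x = x / model.scale
    return x @ model.components.T
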