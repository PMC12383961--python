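"""End-to-end orchestration: cohort -> feature tables -> evaluation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .graph_features import extract_features
from .modeling import (ClassifierSpec, SplitReport, evaluate_tables,
                       partition_trials)
from .preprocessing import preprocess_subject
from .selection import SplitPlan, make_splits
from .synthetic import EpochSet


def subject_features(epochs: EpochSet, config: PipelineConfig,
                     trial_indices: np.ndarray | None = None,
                     seed: int = 0) -> pd.Series:
    """Feature vector of one subject (optionally from a trial subset)."""
    grid = preprocess_subject(epochs, config, trial_indices)
    return extract_features(grid, seed=seed)


def feature_table(cohort: list[EpochSet], config: PipelineConfig,
                  trial_indices: np.ndarray | None = None,
                  seed: int = 0) -> pd.DataFrame:
    """Subjects-by-features table with a shared, ordered key set."""
    rows = [subject_features(ep, config, trial_indices, seed=seed)
            for ep in cohort]
    frame = pd.DataFrame(rows)
    frame.index = [ep.subject_id for ep in cohort]
    return frame


def ensemble_subgroup_count(n_trials: int, requested: int = 31) -> int:
    """Largest odd subgroup count <= min(requested, n_trials).

    Odd counts keep the majority vote tie-free; sessions shorter than the
    requested 31 subgroups fall back to the largest odd count their trial
    budget supports.
    """
    n = min(requested, n_trials)
    if n < 1:
        raise ValueError("need at least one trial")
    return n if n % 2 == 1 else n - 1


def ensemble_feature_tables(cohort: list[EpochSet], config: PipelineConfig,
                            seed: int = 0) -> list[pd.DataFrame]:
    """One feature table per trial subgroup (31 for 72-trial sessions).

    The subgroup partition is fixed by ``seed`` and shared across
    subjects, so member g always aggregates the same trial indices.
    """
    n_trials = cohort[0].n_trials
    if config.n_trials is not None:
        n_trials = min(n_trials, config.n_trials)
    n_subgroups = ensemble_subgroup_count(n_trials, config.n_subgroups)
    subgroups = partition_trials(n_trials, n_subgroups, seed=seed,
                                 scheme=config.subgroup_scheme)
    return [feature_table(cohort, config, trial_indices=g, seed=seed)
            for g in subgroups]


def evaluate_cohort(cohort: list[EpochSet], labels: list[str],
                    specs: list[ClassifierSpec], plans: list[SplitPlan],
                    mode: str = "single",
                    config: PipelineConfig | None = None,
                    seed: int = 0) -> SplitReport:
    """Run the full pipeline for every split plan and classifier.

    ``mode`` is ``single`` (all trials averaged into one feature table)
    or ``ensemble`` (31 trial subgroups with majority vote).  Feature
    tables are computed once and shared across splits; selection, PCA and
    the classifiers are re-fitted inside every split on its training
    subjects only.
    """
    config = config or PipelineConfig()
    if mode == "single":
        table = feature_table(cohort, config, seed=seed)
        return evaluate_tables(table, None, labels, specs, plans, config)
    if mode == "ensemble":
        tables = ensemble_feature_tables(cohort, config, seed=seed)
        return evaluate_tables(None, tables, labels, specs, plans, config)
    raise ValueError(f"unknown mode {mode!r}")
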