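"""Majority-vote ensembles of independently trained classifiers.

Odd numbers of members (1, 3, ..., 101 by default) avoid ties; when even sizes
are evaluated, an exact tie resolves to a configurable default class
(allergic). Each member is a feature set whose model is re-fitted per fold with
per-fold family selection; the ensemble's hidden accuracy at size m averages,
over folds, the accuracy of the vote among the m best-scoring members. The
steady-state value summarizes the plateau reached once enough members vote.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .folds import FoldPlan
from .io import ALLERGIC, BetaMatrix, LabeledCohort
from .models import DEFAULT_CONFIG, ModelConfig, accuracy, select_and_evaluate
from .search import ScoredFeatureSet


def default_odd_sizes(max_size: int = 101) -> tuple:
    return tuple(range(1, max_size + 1, 2))


@dataclass(frozen=True)
class EnsembleSpec:
    """Ordered member pool (best accuracy score first) and sizes to evaluate."""

    members: tuple            # ScoredFeatureSets, ordered best-first
    sizes: tuple = default_odd_sizes()
    tie_rule: str = ALLERGIC

    def __post_init__(self):
        if any(s < 1 for s in self.sizes):
            raise ValueError("ensemble sizes must be positive")
        keys = [frozenset(m.features) for m in self.members]
        if len(set(keys)) != len(keys):
            raise ValueError("ensemble members must be distinct feature sets")


@dataclass(frozen=True)
class EnsembleCurve:
    sizes: tuple
    accuracies: tuple          # mean hidden accuracy per size
    steady_state: float        # mean accuracy over sizes >= convergence_size
    convergence_size: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"size": self.sizes, "mean_accuracy": self.accuracies})


def majority_vote(votes: Sequence[str], tie_rule: str = ALLERGIC) -> str:
    """Strict-majority class of the votes; exact ties go to ``tie_rule``."""
    if not votes:
        raise ValueError("votes must be nonempty")
    counts = Counter(votes)
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return tie_rule
    return top[0][0]


def order_members(sets: Sequence[ScoredFeatureSet]) -> tuple:
    """Canonical member order: accuracy score descending, then feature IDs."""
    return tuple(sorted(sets, key=lambda s: (-s.accuracy_score, s.features)))


def ensemble_curve(
    spec: EnsembleSpec,
    fold_plan: FoldPlan,
    matrix: BetaMatrix,
    cohort: LabeledCohort,
    seed: int = 0,
    config: ModelConfig = DEFAULT_CONFIG,
    convergence_size: int = 29,
) -> EnsembleCurve:
    """Hidden accuracy of the top-m member vote for each requested size m."""
    sizes = tuple(s for s in spec.sizes if s <= len(spec.members))
    if len(sizes) < len(spec.sizes):
        warnings.warn(
            f"only {len(spec.members)} members available; "
            f"sizes truncated to <= {len(spec.members)}",
            stacklevel=2,
        )
    if not sizes:
        raise ValueError("no evaluable ensemble size")
    max_m = max(sizes)

    # per member x fold: hidden predictions from the per-fold selected family
    predictions = []  # predictions[m][f] -> tuple of labels
    for member in spec.members[:max_m]:
        per_fold = []
        for fold in fold_plan.folds:
            ev = select_and_evaluate(
                member.features,
                fold,
                matrix,
                cohort,
                child_seed(seed, "set", member.features, "fold", fold.index),
                config,
            )
            per_fold.append(ev)
        predictions.append(per_fold)

    truth = [
        [cohort.label_of[s] for s in fold.hidden] for fold in fold_plan.folds
    ]
    accuracies = []
    for m in sizes:
        fold_accs = []
        for f, fold in enumerate(fold_plan.folds):
            n_hidden = len(fold.hidden)
            voted = [
                majority_vote(
                    [predictions[j][f].hidden_predictions[i] for j in range(m)],
                    spec.tie_rule,
                )
                for i in range(n_hidden)
            ]
            fold_accs.append(accuracy(voted, truth[f]))
        accuracies.append(float(np.mean(fold_accs)))

    plateau = [a for s, a in zip(sizes, accuracies) if s >= convergence_size]
    steady = float(np.mean(plateau)) if plateau else float(accuracies[-1])
    return EnsembleCurve(sizes, tuple(accuracies), steady, convergence_size)
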