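"""Accuracy-score computation, singleton screening, sequential forward selection.

The "accuracy score" of a feature set is its mean hidden-cohort accuracy across
the folds of a plan, after per-fold classifier-family selection on the
cross-validation cohort. Singleton CpGs from the aggregate ranking are screened
against a score threshold; the survivors seed a restricted sequential forward
selection: each of the top-``beam`` sets of size s-1 is extended by every
shortlist feature not already present, candidates are deduplicated as unordered
sets, truncated to ``cap_per_size`` by parent score, and scored. All sizes up
to ``max_size`` are evaluated; a perfect score never short-circuits the search.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .folds import FoldPlan
from .io import BetaMatrix, LabeledCohort
from .models import DEFAULT_CONFIG, FAMILIES, FoldEvaluation, ModelConfig, select_and_evaluate
from .ranking import AggregateRanking


@dataclass(frozen=True)
class ScoredFeatureSet:
    """A CpG subset with per-fold evaluations and cross-fold mean metrics."""

    features: tuple                 # sorted, unique
    evaluations: tuple = field(compare=False, default=())
    accuracy_score: float = 0.0     # mean hidden accuracy over folds
    mean_auroc: float = 0.0

    @property
    def selected_families(self) -> tuple:
        return tuple(e.selected_family for e in self.evaluations)

    def __len__(self) -> int:
        return len(self.features)


def _score_one(
    features: Iterable[str],
    fold_plan: FoldPlan,
    matrix: BetaMatrix,
    cohort: LabeledCohort,
    seed: int,
    config: ModelConfig,
) -> ScoredFeatureSet:
    feats = tuple(sorted(set(features)))
    evals = tuple(
        select_and_evaluate(
            feats, fold, matrix, cohort, child_seed(seed, "set", feats, "fold", fold.index), config
        )
        for fold in fold_plan.folds
    )
    return ScoredFeatureSet(
        feats,
        evals,
        float(np.mean([e.hidden_accuracy for e in evals])),
        float(np.mean([e.hidden_auroc for e in evals])),
    )


def score_feature_sets(
    sets: Sequence[Iterable[str]],
    fold_plan: FoldPlan,
    matrix: BetaMatrix,
    cohort: LabeledCohort,
    seed: int = 0,
    config: ModelConfig = DEFAULT_CONFIG,
    dry_run: bool = False,
):
    """Score feature sets across all folds; returns (scored_sets, n_fits).

    ``n_fits`` counts every (family, fold, set) model fit the evaluation
    entails. With ``dry_run=True`` only the counter is computed and no model is
    trained (useful for workload accounting).
    """
    sets = list(sets)
    n_fits = len(FAMILIES) * len(fold_plan.folds) * len(sets)
    if dry_run:
        return [], n_fits
    scored = [_score_one(fs, fold_plan, matrix, cohort, seed, config) for fs in sets]
    return scored, n_fits


def screen_singletons(
    candidates,
    fold_plan: FoldPlan,
    matrix: BetaMatrix,
    cohort: LabeledCohort,
    threshold: float = 0.75,
    seed: int = 0,
    config: ModelConfig = DEFAULT_CONFIG,
):
    """Score every candidate CpG as a singleton; keep those at/above threshold.

    ``candidates`` may be an AggregateRanking or any iterable of feature IDs.
    Returns (shortlist, all_scored), shortlist ordered by score descending then
    feature ID. An empty shortlist degrades gracefully with a warning.
    """
    if not 0 < threshold <= 1 and threshold != 0:
        raise ValueError("threshold must lie in [0, 1]")
    if isinstance(candidates, AggregateRanking):
        ids = list(candidates.feature_ids)
    else:
        ids = list(candidates)
    scored, _ = score_feature_sets([(f,) for f in ids], fold_plan, matrix, cohort, seed, config)
    scored.sort(key=lambda s: (-s.accuracy_score, s.features))
    shortlist = [s for s in scored if s.accuracy_score >= threshold]
    if not shortlist:
        warnings.warn(
            f"no singleton reached accuracy score {threshold}; shortlist is empty",
            stacklevel=2,
        )
    return shortlist, scored


@dataclass(frozen=True)
class SearchFrontier:
    """Per-size retained candidate sets (score-ordered) from the forward search."""

    by_size: dict            # size -> list[ScoredFeatureSet], best first
    beam: float
    cap_per_size: int
    shortlist_ids: tuple

    def best(self, size: int) -> ScoredFeatureSet:
        return self.by_size[size][0]

    def summary(self) -> pd.DataFrame:
        """Per size: best score, mean score and AUROC of the top five sets."""
        rows = []
        for size in sorted(self.by_size):
            sets = self.by_size[size]
            top5 = sets[:5]
            rows.append(
                {
                    "n_features": size,
                    "best_accuracy_score": sets[0].accuracy_score,
                    "top5_mean_score": float(np.mean([s.accuracy_score for s in top5])),
                    "top5_mean_auroc": float(np.mean([s.mean_auroc for s in top5])),
                    "n_sets_evaluated": len(sets),
                }
            )
        return pd.DataFrame(rows)


def sfs_expand(
    shortlist: Sequence[ScoredFeatureSet],
    fold_plan: FoldPlan,
    matrix: BetaMatrix,
    cohort: LabeledCohort,
    max_size: int = 12,
    beam: float = 25,
    cap_per_size: int = 200,
    seed: int = 0,
    config: ModelConfig = DEFAULT_CONFIG,
) -> SearchFrontier:
    """Grow feature sets from the shortlist one feature at a time up to max_size.

    {a, b} and {b, a} are the same candidate and are scored once. Every size up
    to ``max_size`` is evaluated even if a perfect score appears earlier.
    """
    if not shortlist:
        raise ValueError("shortlist must be nonempty")
    if max_size < 2:
        raise ValueError("max_size must be >= 2")
    pool = [s.features[0] for s in shortlist]
    ordered1 = sorted(shortlist, key=lambda s: (-s.accuracy_score, s.features))
    by_size = {1: list(ordered1)}
    n_parents = len(ordered1) if math.isinf(beam) else int(beam)
    parents = ordered1[:n_parents]

    for size in range(2, max_size + 1):
        children: dict = {}
        for parent in parents:
            for f in pool:
                if f in parent.features:
                    continue
                key = frozenset(parent.features) | {f}
                prev = children.get(key, -1.0)
                children[key] = max(prev, parent.accuracy_score)
        ordered_keys = sorted(
            children, key=lambda k: (-children[k], tuple(sorted(k)))
        )[:cap_per_size]
        if not ordered_keys:
            break
        scored, _ = score_feature_sets(
            [tuple(sorted(k)) for k in ordered_keys], fold_plan, matrix, cohort, seed, config
        )
        scored.sort(key=lambda s: (-s.accuracy_score, -s.mean_auroc, s.features))
        by_size[size] = scored
        parents = scored[:n_parents]

    return SearchFrontier(by_size, beam, cap_per_size, tuple(pool))


def write_scored_sets(sets: Sequence[ScoredFeatureSet], path) -> None:
    pd.DataFrame(
        {
            "features": [";".join(s.features) for s in sets],
            "accuracy_score": [s.accuracy_score for s in sets],
            "mean_auroc": [s.mean_auroc for s in sets],
            "selected_families": [",".join(s.selected_families) for s in sets],
        }
    ).to_csv(path, sep="\t", index=False)


def read_scored_sets(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        ScoredFeatureSet(
            tuple(str(row["features"]).split(";")),
            (),
            float(row["accuracy_score"]),
            float(row["mean_auroc"]),
        )
        for _, row in df.iterrows()
    ]


def write_frontier(frontier: SearchFrontier, path) -> None:
    rows = []
    for size in sorted(frontier.by_size):
        for s in frontier.by_size[size]:
            rows.append(
                {
                    "n_features": size,
                    "features": ";".join(s.features),
                    "accuracy_score": s.accuracy_score,
                    "mean_auroc": s.mean_auroc,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_frontier(path, beam: float = float("nan"), cap_per_size: int = -1) -> SearchFrontier:
    df = pd.read_csv(path, sep="\t")
    by_size: dict = {}
    for _, row in df.iterrows():
        s = ScoredFeatureSet(
            tuple(str(row["features"]).split(";")),
            (),
            float(row["accuracy_score"]),
            float(row["mean_auroc"]),
        )
        by_size.setdefault(int(row["n_features"]), []).append(s)
    shortlist = tuple(s.features[0] for s in by_size.get(1, []))
    return SearchFrontier(by_size, beam, cap_per_size, shortlist)
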