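"""Balanced train / cross-validation / hidden fold construction.

Every fold assigns each sample to exactly one of three cohorts with fixed sizes
(default 40/10/8 on 58 samples) and an equal number of samples from each class
in every cohort. In coverage mode the hidden sets are drawn per class from a
shuffled queue consumed without replacement across folds (reshuffled once a
class's pool is exhausted), which constructively guarantees that every sample
is hidden at least once provided n_folds x hidden_size >= n_samples.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .io import ALLERGIC, SENSITIZED, LabeledCohort

COHORTS = ("train", "cv", "hidden")


class FoldValidationError(ValueError):
    """Sizes or class counts violate the balanced-split preconditions."""


class FoldFeasibilityError(ValueError):
    """Hidden coverage cannot be achieved with the requested fold count."""


@dataclass(frozen=True)
class Fold:
    index: int
    train: tuple
    cv: tuple
    hidden: tuple

    def assignment(self) -> dict:
        out = {s: "train" for s in self.train}
        out.update({s: "cv" for s in self.cv})
        out.update({s: "hidden" for s in self.hidden})
        return out

    def cohort(self, name: str) -> tuple:
        return getattr(self, name)


@dataclass(frozen=True)
class FoldPlan:
    folds: tuple
    sizes: tuple  # (train, cv, hidden)
    seed: int

    def __len__(self) -> int:
        return len(self.folds)

    def hidden_counts(self) -> Counter:
        c: Counter = Counter()
        for fold in self.folds:
            c.update(fold.hidden)
        return c

    def hidden_coverage(self) -> int:
        """Number of distinct samples appearing in the hidden cohort >= once."""
        return len(self.hidden_counts())


def _validate(cohort: LabeledCohort, sizes, n_folds: int, require_coverage: bool) -> tuple:
    train, cv, hidden = sizes
    counts = cohort.counts()
    n_all = counts.get(ALLERGIC, 0)
    n_sen = counts.get(SENSITIZED, 0)
    if counts.get("neither", 0):
        raise FoldValidationError("cohort must be filtered to two classes before splitting")
    if n_all != n_sen:
        raise FoldValidationError(f"class counts must be equal, got {n_all} vs {n_sen}")
    n = len(cohort)
    if train + cv + hidden != n:
        raise FoldValidationError(f"sizes {sizes} do not sum to cohort size {n}")
    if any(s % 2 != 0 for s in sizes) or any(s <= 0 for s in sizes):
        raise FoldValidationError(f"cohort sizes must be positive and even, got {sizes}")
    if require_coverage and n_folds * hidden < n:
        raise FoldFeasibilityError(
            f"{n_folds} folds x {hidden} hidden < {n} samples; "
            f"need at least {math.ceil(n / hidden)} folds for full hidden coverage"
        )
    return n_all, n_sen


def _balanced_fold(index, per_class_hidden, rest_by_class, sizes, rng) -> Fold:
    train_n, cv_n, _ = sizes
    train, cv, hidden = [], [], []
    for cls in (ALLERGIC, SENSITIZED):
        hidden.extend(per_class_hidden[cls])
        rest = list(rest_by_class[cls])
        rng.shuffle(rest)
        train.extend(rest[: train_n // 2])
        cv.extend(rest[train_n // 2 : train_n // 2 + cv_n // 2])
    return Fold(index, tuple(train), tuple(cv), tuple(hidden))


def make_fold_plan(
    cohort: LabeledCohort,
    n_folds: int = 8,
    sizes: Sequence[int] = (40, 10, 8),
    seed: int = 0,
) -> FoldPlan:
    """Build a coverage-mode fold plan: balanced cohorts, every sample hidden once.

    Deterministic given ``seed``; per-fold randomness comes from child seeds so
    increasing ``n_folds`` never perturbs earlier folds.
    """
    sizes = tuple(int(s) for s in sizes)
    _validate(cohort, sizes, n_folds, require_coverage=True)
    hidden_per_class = sizes[2] // 2

    members = {cls: list(cohort.ids_with(cls)) for cls in (ALLERGIC, SENSITIZED)}
    queues = {}
    for cls in (ALLERGIC, SENSITIZED):
        q_rng = np.random.default_rng(child_seed(seed, "queue", cls))
        queues[cls] = list(q_rng.permutation(members[cls]))

    folds = []
    for i in range(n_folds):
        per_class_hidden = {}
        for cls in (ALLERGIC, SENSITIZED):
            take: list = []
            while len(take) < hidden_per_class:
                if not queues[cls]:
                    pool = [s for s in members[cls] if s not in take]
                    r_rng = np.random.default_rng(child_seed(seed, "reshuffle", cls, i))
                    queues[cls] = list(r_rng.permutation(pool))
                take.append(queues[cls].pop(0))
            per_class_hidden[cls] = take
        rest = {
            cls: [s for s in members[cls] if s not in per_class_hidden[cls]]
            for cls in (ALLERGIC, SENSITIZED)
        }
        fold_rng = np.random.default_rng(child_seed(seed, "fold", i, "split"))
        folds.append(_balanced_fold(i, per_class_hidden, rest, sizes, fold_rng))
    return FoldPlan(tuple(folds), sizes, seed)


def make_reallocations(
    cohort: LabeledCohort,
    n_repeats: int = 200,
    sizes: Sequence[int] = (40, 10, 8),
    seed: int = 0,
) -> list:
    """Independent balanced single-fold reallocations for final validation.

    Each repeat shuffles the samples into fresh train/cv/hidden cohorts of the
    configured sizes with equal class counts; no coverage constraint applies.
    """
    sizes = tuple(int(s) for s in sizes)
    _validate(cohort, sizes, n_repeats, require_coverage=False)
    hidden_per_class = sizes[2] // 2
    members = {cls: list(cohort.ids_with(cls)) for cls in (ALLERGIC, SENSITIZED)}

    plans = []
    for r in range(n_repeats):
        rng = np.random.default_rng(child_seed(seed, "realloc", r))
        per_class_hidden, rest = {}, {}
        for cls in (ALLERGIC, SENSITIZED):
            order = list(rng.permutation(members[cls]))
            per_class_hidden[cls] = order[:hidden_per_class]
            rest[cls] = order[hidden_per_class:]
        fold = _balanced_fold(0, per_class_hidden, rest, sizes, rng)
        plans.append(FoldPlan((fold,), sizes, child_seed(seed, "realloc", r)))
    return plans


def write_fold_plan(plan: FoldPlan, path) -> None:
    rows = []
    for fold in plan.folds:
        for cohort_name in COHORTS:
            for s in fold.cohort(cohort_name):
                rows.append((fold.index, s, cohort_name))
    with open(path, "w") as fh:
        fh.write(f"# sizes={','.join(map(str, plan.sizes))} seed={plan.seed}\n")
        pd.DataFrame(rows, columns=["fold_index", "sample_id", "cohort"]).to_csv(
            fh, sep="\t", index=False
        )


def read_fold_plan(path) -> FoldPlan:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
    sizes = tuple(int(x) for x in meta["sizes"].split(","))
    seed = int(meta["seed"])
    df = pd.read_csv(path, sep="\t", comment=None, skiprows=1)
    folds = []
    for idx, grp in df.groupby("fold_index", sort=True):
        by = {name: tuple(grp.loc[grp["cohort"] == name, "sample_id"].astype(str)) for name in COHORTS}
        folds.append(Fold(int(idx), by["train"], by["cv"], by["hidden"]))
    return FoldPlan(tuple(folds), sizes, seed)
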