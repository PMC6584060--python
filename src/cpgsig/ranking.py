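"""Differential-methylation ranking by empirical-Bayes moderated t.

With only ~20 training samples per class, per-feature variance estimates are
noisy; the moderated two-sample t shrinks each feature's pooled variance s_g^2
toward a prior s0^2 estimated from all features:

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t~_g   = (mean_A - mean_B) / (s~_g * sqrt(1/n_A + 1/n_B))

The prior degrees of freedom d0 and prior variance s0^2 are fitted by a
method-of-moments on log s_g^2 (trigamma inversion solved by bisection),
falling back to d0 = +inf (all variances equal to s0^2) when the moment
equation has no root. Features are ranked by |t~| descending; rankings from
several folds are merged by a frequency/position heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from .io import ALLERGIC, SENSITIZED, BetaMatrix, LabeledCohort


class InsufficientReplicationError(ValueError):
    """A class has fewer than two samples; no residual variance exists."""


@dataclass(frozen=True)
class ModeratedTResult:
    feature_ids: tuple
    mean_diff: np.ndarray      # allergic minus sensitized, beta units
    s2: np.ndarray             # pooled residual variance per feature
    df_residual: float         # d_g, constant across features
    prior_df: float            # d0 (may be +inf)
    prior_var: float           # s0^2
    s2_post: np.ndarray        # shrunken variance
    t: np.ndarray              # moderated statistic

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_diff": self.mean_diff,
                "s2": self.s2,
                "s2_post": self.s2_post,
                "t": self.t,
            },
            index=list(self.feature_ids),
        )


@dataclass(frozen=True)
class RankedList:
    fold_index: int
    feature_ids: tuple   # best first
    statistic: tuple     # |t~| per feature, parallel

    def __len__(self) -> int:
        return len(self.feature_ids)


@dataclass(frozen=True)
class AggregateRanking:
    """Merged per-fold rankings ordered by a frequency/position heuristic.

    Features are ordered by occurrence count across lists (descending), then by
    mean 1-based list position (ascending), then by feature ID. The heuristic
    only orders the merged pool; every member is evaluated individually
    downstream, so the exact tie-breaking carries no analytical weight.
    """

    feature_ids: tuple
    occurrence: tuple     # count of lists containing the feature
    positions: tuple      # tuple of 1-based positions per feature
    n_lists: int

    def __len__(self) -> int:
        return len(self.feature_ids)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": list(self.feature_ids),
                "occurrence": list(self.occurrence),
                "mean_position": [float(np.mean(p)) for p in self.positions],
                "positions": [",".join(map(str, p)) for p in self.positions],
            }
        )


def _fit_prior(s2: np.ndarray, df: float, lo: float = 1e-2, hi: float = 1e6) -> tuple:
    """Method-of-moments fit of (d0, s0^2) on log s^2; bisection on trigamma."""
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.exp(np.mean(np.log(s2[ok])))) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    rhs = e_var - float(polygamma(1, df / 2.0))
    tri = lambda d0: float(polygamma(1, d0 / 2.0))
    if rhs <= tri(hi):  # variance of log s^2 fully explained by sampling noise
        return np.inf, float(np.exp(e_mean))
    if rhs >= tri(lo):
        d0 = lo
    else:
        a, b = lo, hi  # trigamma is decreasing: tri(a) > rhs > tri(b)
        for _ in range(200):
            mid = np.sqrt(a * b)
            if tri(mid) > rhs:
                a = mid
            else:
                b = mid
        d0 = np.sqrt(a * b)
    s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def moderated_t(
    matrix: BetaMatrix,
    cohort: LabeledCohort,
    prior_df: float | None = None,
) -> ModeratedTResult:
    """Moderated two-sample t per feature (allergic vs sensitized).

    ``matrix`` must be restricted to the training cohort; statistics are never
    computed on cross-validation or hidden samples. ``prior_df`` overrides the
    fitted d0 (0 recovers the ordinary pooled t; +inf pools all variances).
    """
    ids_a = [s for s in matrix.sample_ids if cohort.label_of[s] == ALLERGIC]
    ids_b = [s for s in matrix.sample_ids if cohort.label_of[s] == SENSITIZED]
    n_a, n_b = len(ids_a), len(ids_b)
    if n_a < 2 or n_b < 2:
        raise InsufficientReplicationError(
            f"need >=2 samples per class, got {n_a} allergic / {n_b} sensitized"
        )
    if len(matrix.feature_ids) < 2:
        raise ValueError("need >=2 features for the empirical-Bayes fit")

    xa = matrix.data[ids_a].to_numpy(dtype=float)
    xb = matrix.data[ids_b].to_numpy(dtype=float)
    mean_diff = xa.mean(axis=1) - xb.mean(axis=1)
    ss = xa.var(axis=1, ddof=1) * (n_a - 1) + xb.var(axis=1, ddof=1) * (n_b - 1)
    df = float(n_a + n_b - 2)
    s2 = ss / df

    if prior_df is None:
        d0, s0_sq = _fit_prior(s2, df)
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_prior(s2, df)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    elif d0 == 0:
        s2_post = s2.copy()
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)

    scale = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(mean_diff == 0.0, 0.0, mean_diff / scale)
    return ModeratedTResult(
        matrix.feature_ids, mean_diff, s2, df, d0, s0_sq, s2_post, t
    )


def rank_top_k(result: ModeratedTResult, k: int, fold_index: int = 0) -> RankedList:
    """Top-k features by |t~| descending; ties broken by feature ID."""
    if k < 1:
        raise ValueError("k must be >= 1")
    abs_t = np.abs(result.t)
    order = sorted(range(len(abs_t)), key=lambda i: (-abs_t[i], result.feature_ids[i]))
    top = order[: min(k, len(order))]
    return RankedList(
        fold_index,
        tuple(result.feature_ids[i] for i in top),
        tuple(float(abs_t[i]) for i in top),
    )


def merge_rankings(lists: Sequence[RankedList]) -> AggregateRanking:
    """Merge per-fold ranked lists into a unique pool with a heuristic order."""
    if not lists:
        raise ValueError("need at least one ranked list")
    occurrence: dict = {}
    positions: dict = {}
    for rl in lists:
        for pos, fid in enumerate(rl.feature_ids, start=1):
            occurrence[fid] = occurrence.get(fid, 0) + 1
            positions.setdefault(fid, []).append(pos)
    ordered = sorted(
        occurrence,
        key=lambda f: (-occurrence[f], float(np.mean(positions[f])), f),
    )
    return AggregateRanking(
        tuple(ordered),
        tuple(occurrence[f] for f in ordered),
        tuple(tuple(positions[f]) for f in ordered),
        len(lists),
    )


def write_aggregate(agg: AggregateRanking, path) -> None:
    agg.as_frame().to_csv(path, sep="\t", index=False)


def read_aggregate(path) -> AggregateRanking:
    df = pd.read_csv(path, sep="\t")
    positions = tuple(
        tuple(int(x) for x in str(p).split(",")) for p in df["positions"]
    )
    n_lists = max((max(len(p) for p in positions), int(df["occurrence"].max()))) if len(df) else 0
    return AggregateRanking(
        tuple(df["feature_id"].astype(str)),
        tuple(int(x) for x in df["occurrence"]),
        positions,
        n_lists,
    )
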