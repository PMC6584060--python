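"""Final-signature validation and signature extraction.

A candidate signature (feature set) is validated by evaluating it on many
independent random reallocations of the samples into balanced train/cv/hidden
cohorts; the per-repeat hidden accuracies yield a mean and a Student-t 95%
confidence interval on the percent scale. The signature report tallies how
often each CpG appears across the top classifiers and maps the union to genes,
collapsing configured pseudogene groups to a single gene.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import child_seed
from .folds import FoldPlan
from .io import BetaMatrix, GeneAnnotation, LabeledCohort
from .models import DEFAULT_CONFIG, ModelConfig, select_and_evaluate
from .search import ScoredFeatureSet


@dataclass(frozen=True)
class ValidationSummary:
    signature_id: str
    n_repeats: int
    accuracies: tuple          # per repeat, fraction scale
    aurocs: tuple
    mean_accuracy: float       # percent
    mean_auroc: float
    ci_low: float              # percent
    ci_high: float             # percent

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "signature": [self.signature_id],
                "n": [self.n_repeats],
                "mean_accuracy_pct": [self.mean_accuracy],
                "mean_auroc": [self.mean_auroc],
                "ci95_low_pct": [self.ci_low],
                "ci95_high_pct": [self.ci_high],
            }
        )


@dataclass(frozen=True)
class SignatureReport:
    cpg_ids: tuple             # ordered by frequency desc, ID asc
    frequencies: tuple         # occurrences across the top classifiers
    genes: tuple               # tuple of gene tuples per CpG
    n_classifiers: int
    unique_gene_count: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cpg_id": list(self.cpg_ids),
                "frequency": list(self.frequencies),
                "gene_symbols": [";".join(g) if g else "-" for g in self.genes],
            }
        )


def t_interval(values: Sequence[float], confidence: float = 0.95) -> tuple:
    """Student-t CI for the mean of repeated evaluations; degenerate at zero sd."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    m = float(np.mean(x))
    if n < 2 or np.allclose(x, x[0]):
        return m, m
    half = float(stats.t.ppf((1 + confidence) / 2.0, n - 1) * np.std(x, ddof=1) / np.sqrt(n))
    return m - half, m + half


def validate_signature(
    features: Sequence[str],
    reallocations: Sequence[FoldPlan],
    matrix: BetaMatrix,
    cohort: LabeledCohort,
    seed: int = 0,
    config: ModelConfig = DEFAULT_CONFIG,
    signature_id: str = "signature",
) -> ValidationSummary:
    """Evaluate a feature set on every reallocation's hidden cohort."""
    if not reallocations:
        raise ValueError("reallocations must be nonempty")
    feats = tuple(sorted(set(features)))
    accs, aucs = [], []
    for r, plan in enumerate(reallocations):
        fold = plan.folds[0]
        assert not set(fold.train) & set(fold.hidden), "hidden cohort must be unseen"
        ev = select_and_evaluate(
            feats, fold, matrix, cohort, child_seed(seed, "repeat", r), config
        )
        accs.append(ev.hidden_accuracy)
        aucs.append(ev.hidden_auroc)
    lo, hi = t_interval(accs)
    return ValidationSummary(
        signature_id,
        len(reallocations),
        tuple(accs),
        tuple(aucs),
        float(np.mean(accs)) * 100.0,
        float(np.mean(aucs)),
        lo * 100.0,
        hi * 100.0,
    )


def extract_signature(
    top_classifiers: Sequence[ScoredFeatureSet],
    annotation: GeneAnnotation = GeneAnnotation(),
) -> SignatureReport:
    """Tally CpG occurrences across the top classifiers and map to genes."""
    if not top_classifiers:
        raise ValueError("top_classifiers must be nonempty")
    counts: Counter = Counter()
    for clf in top_classifiers:
        counts.update(set(clf.features))
    ordered = sorted(counts, key=lambda c: (-counts[c], c))
    genes = tuple(annotation.genes_for(c) for c in ordered)
    all_symbols = {s for g in genes for s in g}
    return SignatureReport(
        tuple(ordered),
        tuple(counts[c] for c in ordered),
        genes,
        len(top_classifiers),
        annotation.count_unique_genes(all_symbols),
    )


def render_markdown(
    summary: "ValidationSummary | None" = None,
    signature: "SignatureReport | None" = None,
) -> str:
    """Human-readable run report: validation summary and CpG frequency table."""
    parts = ["# Signature run report\n"]
    if summary is not None:
        parts.append("## Reallocation validation\n")
        parts.append(
            f"Signature `{summary.signature_id}` over n={summary.n_repeats} "
            f"random reallocations: mean hidden accuracy "
            f"{summary.mean_accuracy:.2f}% "
            f"(95% CI {summary.ci_low:.2f}-{summary.ci_high:.2f}), "
            f"mean AUROC {summary.mean_auroc:.4f}.\n"
        )
    if signature is not None:
        parts.append("## CpG frequencies across top classifiers\n")
        parts.append("| CpG | Frequency | Genes |")
        parts.append("| --- | --- | --- |")
        for cpg, freq, genes in zip(
            signature.cpg_ids, signature.frequencies, signature.genes
        ):
            parts.append(f"| {cpg} | {freq} | {';'.join(genes) if genes else '-'} |")
        parts.append(
            f"\n{len(signature.cpg_ids)} unique CpGs across "
            f"{signature.n_classifiers} classifiers map to "
            f"{signature.unique_gene_count} unique genes.\n"
        )
    return "\n".join(parts)


def select_top_classifiers(
    sets: Sequence[ScoredFeatureSet], n_score_levels: int = 2
) -> list:
    """All sets whose accuracy score reaches one of the best ``n_score_levels``
    distinct scores observed (default two, capturing a perfect tier plus the
    near-perfect tier beneath it)."""
    if not sets:
        return []
    scores = sorted({s.accuracy_score for s in sets}, reverse=True)
    cutoff = scores[: n_score_levels][-1]
    chosen = [s for s in sets if s.accuracy_score >= cutoff]
    return sorted(chosen, key=lambda s: (-s.accuracy_score, s.features))
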