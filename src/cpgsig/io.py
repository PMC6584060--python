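"""Data model and delimited-text I/O for methylation matrices, labels, annotations.

The canonical in-memory form of a methylation matrix is features (CpG probes) in
rows and samples in columns, matching how GEO series matrices are laid out;
classifier code transposes to the sample-major orientation that scikit-learn
expects. Beta values are methylation proportions and must lie in [0, 1].
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ALLERGIC = "allergic"
SENSITIZED = "sensitized"
NEITHER = "neither"
VALID_LABELS = (ALLERGIC, SENSITIZED, NEITHER)


class BetaBoundsError(ValueError):
    """A beta value fell outside [0, 1]."""


class DuplicateIDError(ValueError):
    """Duplicate feature or sample identifiers."""


class MissingValueError(ValueError):
    """A matrix cell is missing and imputation was not enabled."""


class LabelError(ValueError):
    """Malformed sample-label table."""


@dataclass(frozen=True)
class BetaMatrix:
    """Bounded methylation values, features x samples, with stable string IDs."""

    data: pd.DataFrame  # index: feature IDs, columns: sample IDs

    def __post_init__(self):
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise DuplicateIDError(f"duplicate feature ID {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise DuplicateIDError(f"duplicate sample ID {dup!r}")
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise MissingValueError(
                f"missing value at feature {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        if (values < 0).any() or (values > 1).any():
            i, j = np.argwhere((values < 0) | (values > 1))[0]
            raise BetaBoundsError(
                f"beta value {values[i, j]!r} outside [0, 1] at "
                f"feature {df.index[i]!r}, sample {df.columns[j]!r}"
            )

    @property
    def feature_ids(self) -> tuple:
        return tuple(self.data.index)

    @property
    def sample_ids(self) -> tuple:
        return tuple(self.data.columns)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def select_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.data.loc[:, list(sample_ids)])

    def sample_array(self, feature_ids: Sequence[str], sample_ids: Sequence[str]) -> np.ndarray:
        """Return a samples x features float array for the given IDs."""
        return self.data.loc[list(feature_ids), list(sample_ids)].to_numpy(dtype=float).T


@dataclass(frozen=True)
class LabeledCohort:
    """Ordered sample IDs, each carrying exactly one class label."""

    sample_ids: tuple
    labels: tuple  # parallel to sample_ids

    def __post_init__(self):
        if len(self.sample_ids) != len(self.labels):
            raise LabelError("sample_ids and labels differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DuplicateIDError("duplicate sample ID in cohort")
        bad = [l for l in self.labels if l not in VALID_LABELS]
        if bad:
            raise LabelError(f"unknown label {bad[0]!r}; expected one of {VALID_LABELS}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def label_of(self) -> Mapping[str, str]:
        return dict(zip(self.sample_ids, self.labels))

    def counts(self) -> dict:
        out: dict = {}
        for l in self.labels:
            out[l] = out.get(l, 0) + 1
        return out

    def ids_with(self, label: str) -> tuple:
        return tuple(s for s, l in zip(self.sample_ids, self.labels) if l == label)

    def subset(self, sample_ids: Sequence[str]) -> "LabeledCohort":
        mapping = self.label_of
        return LabeledCohort(tuple(sample_ids), tuple(mapping[s] for s in sample_ids))


@dataclass(frozen=True)
class GeneAnnotation:
    """CpG -> gene-symbol mapping plus pseudogene groups counted as one gene.

    Lookups of unannotated CpGs return the empty tuple, never raise.
    """

    mapping: Mapping[str, tuple] = field(default_factory=dict)
    merge_groups: tuple = ()  # tuple of frozensets of symbols counted once

    def genes_for(self, cpg_id: str) -> tuple:
        return tuple(self.mapping.get(cpg_id, ()))

    def count_unique_genes(self, symbols: Iterable[str]) -> int:
        """Count distinct genes, collapsing each merge group to a single gene."""
        canon = {}
        for group in self.merge_groups:
            rep = min(group)
            for sym in group:
                canon[sym] = rep
        return len({canon.get(s, s) for s in symbols})


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def load_beta_matrix(
    path,
    orientation: str = "features_in_rows",
    impute_missing: bool = False,
) -> BetaMatrix:
    """Load a delimited beta-value matrix (TSV default, CSV accepted).

    The file has one header line of IDs and one leading ID column. With
    ``orientation="samples_in_rows"`` the table is transposed into the canonical
    features x samples form. Missing cells raise unless ``impute_missing`` is
    set, in which case each is replaced by its feature's mean.
    """
    path = Path(path)
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sniff_sep(path)
    with open(path) as fh:
        header_ids = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header_ids)) != len(header_ids):
        dup = next(h for h in header_ids if header_ids.count(h) > 1)
        raise DuplicateIDError(f"duplicate column ID {dup!r}")
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "samples_in_rows":
        df = df.T
    if impute_missing:
        means = df.mean(axis=1)
        df = df.apply(lambda row: row.fillna(means[row.name]), axis=1)
    return BetaMatrix(df)


def write_beta_matrix(matrix: BetaMatrix, path, orientation: str = "features_in_rows") -> None:
    df = matrix.data if orientation == "features_in_rows" else matrix.data.T
    df.to_csv(path, sep="\t", float_format="%.17g")


def load_labels(path) -> LabeledCohort:
    """Load a sample-label table with columns sample_id, label."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if not {"sample_id", "label"} <= set(df.columns):
        raise LabelError("label table requires columns sample_id, label")
    return LabeledCohort(tuple(df["sample_id"].astype(str)), tuple(df["label"].astype(str)))


def write_labels(cohort: LabeledCohort, path) -> None:
    pd.DataFrame({"sample_id": cohort.sample_ids, "label": cohort.labels}).to_csv(
        path, sep="\t", index=False
    )


def load_annotation(path, merge_groups: Sequence[Iterable[str]] = ()) -> GeneAnnotation:
    """Load a CpG->gene table with columns cpg_id, gene_symbols (';'-separated)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path)).fillna("")
    if not {"cpg_id", "gene_symbols"} <= set(df.columns):
        raise ValueError("annotation table requires columns cpg_id, gene_symbols")
    mapping = {}
    for cpg, genes in zip(df["cpg_id"].astype(str), df["gene_symbols"].astype(str)):
        symbols = tuple(g for g in (s.strip() for s in genes.split(";")) if g and g != "-")
        mapping[cpg] = symbols
    return GeneAnnotation(mapping, tuple(frozenset(g) for g in merge_groups))


def filter_cohort(cohort: LabeledCohort) -> LabeledCohort:
    """Drop samples labeled neither allergic nor sensitized, preserving order.

    Samples outside the two discrimination classes (skin-prick negative, not
    challenged) carry no class information for the allergic-vs-sensitized task.
    Idempotent.
    """
    keep = [
        (s, l) for s, l in zip(cohort.sample_ids, cohort.labels) if l in (ALLERGIC, SENSITIZED)
    ]
    return LabeledCohort(tuple(s for s, _ in keep), tuple(l for _, l in keep))


def read_geo_series_matrix(path) -> BetaMatrix:
    """Minimal plain-text GEO series-matrix adapter.

    Skips '!'-prefixed metadata lines and parses the table between the
    series_matrix_table_begin/end markers. Provided for convenience with real
    array downloads; the rest of the package never depends on it.
    """
    lines = []
    inside = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if inside and line.strip():
                lines.append(line)
    if not lines:
        raise ValueError("no series_matrix_table found")
    df = pd.read_csv(_io.StringIO("".join(lines)), sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = df.columns.astype(str).str.strip('"')
    return BetaMatrix(df)
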