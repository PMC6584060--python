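"""End-to-end orchestration with per-stage caching and JSON-lines logging.

Stages run in order: cohort filter -> fold plan -> per-fold ranking -> merge ->
singleton screen -> forward selection -> ensemble curve -> reallocation
validation -> signature extraction. Each stage writes a TSV artifact plus a
sidecar meta file recording the config hash and the checksums of its upstream
artifacts; a stage is recomputed only if its artifact is missing or the meta no
longer matches, so deleting a downstream artifact re-runs only downstream
work. Identical config and seed reproduce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from ._seeds import child_seed
from .config import RunConfig
from .ensemble import EnsembleSpec, default_odd_sizes, ensemble_curve, order_members
from .folds import make_fold_plan, make_reallocations, read_fold_plan, write_fold_plan
from .io import (
    GeneAnnotation,
    filter_cohort,
    load_annotation,
    load_beta_matrix,
    load_labels,
    write_labels,
)
from .ranking import merge_rankings, moderated_t, rank_top_k, read_aggregate, write_aggregate
from .report import extract_signature, select_top_classifiers, validate_signature
from .search import (
    read_frontier,
    read_scored_sets,
    screen_singletons,
    sfs_expand,
    write_frontier,
    write_scored_sets,
)

STAGES = (
    "filter",
    "folds",
    "rankings",
    "aggregate",
    "screen",
    "sfs",
    "ensemble",
    "validation",
    "signature",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Cache:
    def __init__(self, out_dir: Path, config_hash: str, log):
        self.out_dir = out_dir
        self.config_hash = config_hash
        self.log = log

    def artifact(self, stage: str) -> Path:
        return self.out_dir / f"{stage}.tsv"

    def _meta(self, stage: str) -> Path:
        return self.out_dir / f"{stage}.meta.json"

    def fresh(self, stage: str, upstream: list) -> bool:
        art, meta = self.artifact(stage), self._meta(stage)
        if not art.exists() or not meta.exists():
            return False
        try:
            recorded = json.loads(meta.read_text())
        except json.JSONDecodeError:
            return False
        expected = {
            "config_hash": self.config_hash,
            "upstream": {s: _checksum(self.artifact(s)) for s in upstream},
        }
        return recorded == expected

    def mark(self, stage: str, upstream: list) -> None:
        meta = {
            "config_hash": self.config_hash,
            "upstream": {s: _checksum(self.artifact(s)) for s in upstream},
        }
        self._meta(stage).write_text(json.dumps(meta, sort_keys=True))

    def run(self, stage: str, upstream: list, compute, load):
        """Return the stage product, computing it only when stale."""
        if self.fresh(stage, upstream):
            self.log(stage=stage, cached=True)
            return load(self.artifact(stage))
        try:
            t0 = time.monotonic()
            product = compute(self.artifact(stage))
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise StageError(stage, exc) from exc
        self.mark(stage, upstream)
        self.log(stage=stage, cached=False, seconds=round(time.monotonic() - t0, 3))
        return product


def _write_markdown_report(out_dir: Path, signature_report) -> None:
    from .report import ValidationSummary, render_markdown

    summary = None
    validation_tsv = out_dir / "validation.tsv"
    if validation_tsv.exists():
        row = pd.read_csv(validation_tsv, sep="\t").iloc[0]
        summary = ValidationSummary(
            str(row["signature"]), int(row["n"]), (), (),
            float(row["mean_accuracy_pct"]), float(row["mean_auroc"]),
            float(row["ci95_low_pct"]), float(row["ci95_high_pct"]),
        )
    (out_dir / "run_report.md").write_text(render_markdown(summary, signature_report))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns {stage: artifact_path}.

    Re-running with the same config and seed reproduces byte-identical TSVs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    log_path = out_dir / "run_log.jsonl"

    def log(**fields):
        with open(log_path, "a") as fh:
            fh.write(json.dumps({"time": time.time(), **fields}, sort_keys=True) + "\n")

    cache = _Cache(out_dir, config.hash(), log)
    seed = config.seed
    mcfg = config.model

    matrix = load_beta_matrix(config.matrix_path, config.orientation)
    cohort_raw = load_labels(config.labels_path)

    # 1. cohort filter
    def compute_filter(path):
        cohort = filter_cohort(cohort_raw)
        write_labels(cohort, path)
        return cohort

    def load_filter(path):
        from .io import load_labels as _ll

        return _ll(path)

    cohort = cache.run("filter", [], compute_filter, load_filter)
    matrix = matrix.select_samples(cohort.sample_ids)

    # 2. fold plan
    def compute_folds(path):
        plan = make_fold_plan(
            cohort, config.n_folds, config.cohort_sizes, child_seed(seed, "folds")
        )
        write_fold_plan(plan, path)
        return plan

    plan = cache.run("folds", ["filter"], compute_folds, read_fold_plan)

    # 3. per-fold moderated-t rankings
    def compute_rankings(path):
        lists = []
        rows = []
        for fold in plan.folds:
            res = moderated_t(matrix.select_samples(fold.train), cohort)
            rl = rank_top_k(res, config.rank_k, fold.index)
            lists.append(rl)
            for pos, (fid, stat) in enumerate(zip(rl.feature_ids, rl.statistic), start=1):
                rows.append((fold.index, pos, fid, stat))
        pd.DataFrame(rows, columns=["fold_index", "position", "feature_id", "abs_t"]).to_csv(
            path, sep="\t", index=False
        )
        return lists

    def load_rankings(path):
        from .ranking import RankedList

        df = pd.read_csv(path, sep="\t")
        lists = []
        for idx, grp in df.groupby("fold_index", sort=True):
            grp = grp.sort_values("position")
            lists.append(
                RankedList(int(idx), tuple(grp["feature_id"].astype(str)), tuple(grp["abs_t"]))
            )
        return lists

    ranked_lists = cache.run("rankings", ["folds"], compute_rankings, load_rankings)

    # 4. merge
    def compute_aggregate(path):
        agg = merge_rankings(ranked_lists)
        write_aggregate(agg, path)
        return agg

    aggregate = cache.run("aggregate", ["rankings"], compute_aggregate, read_aggregate)

    # 5. singleton screen
    def compute_screen(path):
        ids = list(aggregate.feature_ids)
        if config.screen_max_candidates is not None:
            ids = ids[: config.screen_max_candidates]
        shortlist, _scored = screen_singletons(
            ids, plan, matrix, cohort, config.screen_threshold, child_seed(seed, "screen"), mcfg
        )
        log(stage="screen", n_fits=4 * len(plan.folds) * len(ids),
            seed=child_seed(seed, "screen"))
        write_scored_sets(shortlist, path)
        return shortlist

    shortlist = cache.run("screen", ["aggregate"], compute_screen, read_scored_sets)

    # 6. forward selection
    def compute_sfs(path):
        frontier = sfs_expand(
            shortlist,
            plan,
            matrix,
            cohort,
            config.sfs_max_size,
            config.sfs_beam,
            config.sfs_cap_per_size,
            child_seed(seed, "sfs"),
            mcfg,
        )
        n_sets = sum(len(v) for s, v in frontier.by_size.items() if s >= 2)
        log(stage="sfs", n_fits=4 * len(plan.folds) * n_sets, seed=child_seed(seed, "sfs"))
        write_frontier(frontier, path)
        frontier.summary().to_csv(out_dir / "sfs_summary.tsv", sep="\t", index=False)
        return frontier

    frontier = cache.run(
        "sfs",
        ["screen"],
        compute_sfs,
        lambda p: read_frontier(p, config.sfs_beam, config.sfs_cap_per_size),
    )

    # 7. ensemble curve over single-feature members
    def compute_ensemble(path):
        members = order_members(shortlist)
        sizes = default_odd_sizes(config.ensemble_max_size)
        spec = EnsembleSpec(members, sizes)
        curve = ensemble_curve(
            spec, plan, matrix, cohort, child_seed(seed, "ensemble"), mcfg,
            config.ensemble_convergence_size,
        )
        df = curve.as_frame()
        df["steady_state"] = curve.steady_state
        df.to_csv(path, sep="\t", index=False)
        return curve

    cache.run("ensemble", ["screen"], compute_ensemble, lambda p: pd.read_csv(p, sep="\t"))

    # 8. reallocation validation of the best final-size set
    max_size = max(frontier.by_size)
    best_final = frontier.by_size[max_size][0]

    def compute_validation(path):
        reallocs = make_reallocations(
            cohort, config.n_repeats, config.cohort_sizes, child_seed(seed, "realloc")
        )
        summary = validate_signature(
            best_final.features, reallocs, matrix, cohort,
            child_seed(seed, "validate"), mcfg, f"best_{max_size}cpg",
        )
        summary.as_frame().to_csv(path, sep="\t", index=False)
        return summary

    cache.run("validation", ["sfs"], compute_validation, lambda p: pd.read_csv(p, sep="\t"))

    # 9. signature extraction from the top final-size classifiers
    def compute_signature(path):
        annotation = (
            load_annotation(config.annotation_path)
            if config.annotation_path
            else GeneAnnotation()
        )
        top = select_top_classifiers(frontier.by_size[max_size], config.signature_score_levels)
        report = extract_signature(top, annotation)
        df = report.as_frame()
        df["n_classifiers"] = report.n_classifiers
        df["unique_gene_count"] = report.unique_gene_count
        df.to_csv(path, sep="\t", index=False)
        _write_markdown_report(out_dir, report)
        return report

    cache.run("signature", ["sfs"], compute_signature, lambda p: pd.read_csv(p, sep="\t"))

    return {stage: str(cache.artifact(stage)) for stage in STAGES}
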