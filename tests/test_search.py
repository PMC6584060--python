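import math
from itertools import combinations

import numpy as np
import pytest

import cpgsig as c


@pytest.fixture(scope="module")
def small_search_instance():
    """20 samples, 8 features all moderately informative, short fold plan."""
    matrix, cohort, planted = c.generate(
        c.SyntheticSpec(10, 8, 8, 1.2, 0.5, seed=21)
    )
    plan = c.make_fold_plan(cohort, 5, (12, 4, 4), seed=22)
    return matrix, cohort, plan


class TestScoreFeatureSets:
    def test_fit_counter_counts_real_fits(self, small_search_instance, cheap_config):
        matrix, cohort, plan = small_search_instance
        sets = [(matrix.feature_ids[0],), (matrix.feature_ids[1],)]
        scored, n_fits = c.score_feature_sets(sets, plan, matrix, cohort, 1, cheap_config)
        assert n_fits == 4 * len(plan.folds) * 2
        assert len(scored) == 2
        for s in scored:
            assert len(s.evaluations) == len(plan.folds)
            assert 0 <= s.accuracy_score <= 1

    def test_duplicate_features_collapse_to_set(self, small_search_instance, cheap_config):
        matrix, cohort, plan = small_search_instance
        f1, f2 = matrix.feature_ids[:2]
        scored, _ = c.score_feature_sets(
            [(f1, f2, f1), (f2, f1)], plan, matrix, cohort, 1, cheap_config
        )
        assert scored[0].features == scored[1].features == tuple(sorted((f1, f2)))
        assert scored[0].accuracy_score == scored[1].accuracy_score

    def test_planted_feature_attains_max_score(self, strong_instance, cheap_config):
        """A hugely separated planted CpG outscores ten null CpGs under direct
        evaluation."""
        matrix, cohort, planted, plan = strong_instance
        nulls = sorted(set(matrix.feature_ids) - planted)[:10]
        target = sorted(planted)[0]
        scored, _ = c.score_feature_sets(
            [(f,) for f in [target] + nulls], plan, matrix, cohort, 2, cheap_config
        )
        best = max(scored, key=lambda s: s.accuracy_score)
        assert best.features == (target,)


class TestScreenSingletons:
    def test_threshold_zero_keeps_all(self, small_search_instance, cheap_config):
        matrix, cohort, plan = small_search_instance
        shortlist, scored = c.screen_singletons(
            matrix.feature_ids, plan, matrix, cohort, 0.0, 1, cheap_config
        )
        assert len(shortlist) == len(scored) == len(matrix.feature_ids)
        scores = [s.accuracy_score for s in shortlist]
        assert scores == sorted(scores, reverse=True)

    def test_unattainable_threshold_warns_and_degrades(self, small_search_instance, cheap_config):
        matrix, cohort, plan = small_search_instance
        with pytest.warns(UserWarning, match="shortlist is empty"):
            shortlist, _ = c.screen_singletons(
                matrix.feature_ids[:3], plan, matrix, cohort, 1.0, 99, cheap_config
            )
        assert shortlist == []


class TestSFS:
    def test_shortlist_of_two_yields_single_pair(self, small_search_instance, cheap_config):
        matrix, cohort, plan = small_search_instance
        shortlist, _ = c.screen_singletons(
            matrix.feature_ids[:2], plan, matrix, cohort, 0.0, 3, cheap_config
        )
        frontier = c.sfs_expand(
            shortlist, plan, matrix, cohort, max_size=2, beam=25, cap_per_size=200,
            seed=3, config=cheap_config,
        )
        assert len(frontier.by_size[2]) == 1
        assert frontier.by_size[2][0].features == tuple(sorted(matrix.feature_ids[:2]))

    def test_cap_limits_candidates_per_size(self, small_search_instance, cheap_config):
        matrix, cohort, plan = small_search_instance
        shortlist, _ = c.screen_singletons(
            matrix.feature_ids, plan, matrix, cohort, 0.0, 4, cheap_config
        )
        frontier = c.sfs_expand(
            shortlist, plan, matrix, cohort, max_size=3, beam=3, cap_per_size=5,
            seed=4, config=cheap_config,
        )
        for size in (2, 3):
            assert len(frontier.by_size[size]) <= 5

    def test_reproducible_given_seed(self, small_search_instance, cheap_config):
        matrix, cohort, plan = small_search_instance
        shortlist, _ = c.screen_singletons(
            matrix.feature_ids[:4], plan, matrix, cohort, 0.0, 5, cheap_config
        )
        run = lambda: c.sfs_expand(
            shortlist, plan, matrix, cohort, 3, 2, 10, seed=6, config=cheap_config
        )
        a, b = run(), run()
        for size in a.by_size:
            assert [(s.features, s.accuracy_score) for s in a.by_size[size]] == [
                (s.features, s.accuracy_score) for s in b.by_size[size]
            ]

    def test_beam_widening_never_hurts_best_score(self, small_search_instance, cheap_config):
        matrix, cohort, plan = small_search_instance
        shortlist, _ = c.screen_singletons(
            matrix.feature_ids[:5], plan, matrix, cohort, 0.0, 7, cheap_config
        )
        narrow = c.sfs_expand(
            shortlist, plan, matrix, cohort, 3, 1, 200, seed=8, config=cheap_config
        )
        wide = c.sfs_expand(
            shortlist, plan, matrix, cohort, 3, 5, 200, seed=8, config=cheap_config
        )
        for size in (2, 3):
            assert (
                wide.best(size).accuracy_score >= narrow.best(size).accuracy_score - 1e-12
            )

    def test_summary_table_shape(self, small_search_instance, cheap_config):
        matrix, cohort, plan = small_search_instance
        shortlist, _ = c.screen_singletons(
            matrix.feature_ids[:3], plan, matrix, cohort, 0.0, 9, cheap_config
        )
        frontier = c.sfs_expand(
            shortlist, plan, matrix, cohort, 3, math.inf, 200, seed=10, config=cheap_config
        )
        summary = frontier.summary()
        assert list(summary["n_features"]) == [1, 2, 3]
        assert (summary["best_accuracy_score"] >= summary["top5_mean_score"] - 1e-12).all()
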