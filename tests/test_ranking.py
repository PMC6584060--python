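import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cpgsig as c
from cpgsig.ranking import InsufficientReplicationError


def _matrix_from(values, n_allergic):
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    sample_ids = [f"a{i}" for i in range(n_allergic)] + [
        f"s{i}" for i in range(n - n_allergic)
    ]
    labels = (c.ALLERGIC,) * n_allergic + (c.SENSITIZED,) * (n - n_allergic)
    bm = c.BetaMatrix(
        pd.DataFrame(values, index=[f"cg{i}" for i in range(len(values))], columns=sample_ids)
    )
    return bm, c.LabeledCohort(tuple(sample_ids), labels)


class TestModeratedT:
    def test_zero_mean_difference_gives_zero_t(self):
        bm, cohort = _matrix_from(
            [[0.25, 0.75, 0.5, 0.5], [0.1, 0.2, 0.5, 0.6]], n_allergic=2
        )
        res = c.moderated_t(bm, cohort)
        assert res.t[0] == 0.0

    def test_prior_df_zero_recovers_pooled_t(self, rng):
        """With d0 forced to 0 the statistic equals the textbook pooled
        two-sample t, checked on a 3-vs-3 toy."""
        values = rng.uniform(0.1, 0.9, size=(20, 6))
        bm, cohort = _matrix_from(values, n_allergic=3)
        res = c.moderated_t(bm, cohort, prior_df=0)
        for g in range(20):
            expected = stats.ttest_ind(values[g, :3], values[g, 3:], equal_var=True).statistic
            assert res.t[g] == pytest.approx(expected, rel=1e-12)

    def test_shrinkage_bounds_and_monotonicity(self, rng):
        values = rng.uniform(0.1, 0.9, size=(50, 10))
        bm, cohort = _matrix_from(values, n_allergic=5)
        res = c.moderated_t(bm, cohort, prior_df=4.0)
        lo = np.minimum(res.s2, res.prior_var)
        hi = np.maximum(res.s2, res.prior_var)
        differ = ~np.isclose(res.s2, res.prior_var)
        assert ((res.s2_post[differ] > lo[differ]) & (res.s2_post[differ] < hi[differ])).all()
        # larger d0 pulls every variance closer to the prior
        near = c.moderated_t(bm, cohort, prior_df=100.0)
        far = c.moderated_t(bm, cohort, prior_df=1.0)
        assert (
            np.abs(near.s2_post - near.prior_var) <= np.abs(far.s2_post - far.prior_var) + 1e-15
        ).all()

    def test_scale_invariance_of_ordinary_t(self, rng):
        values = rng.uniform(0.2, 0.9, size=(30, 8))
        bm, cohort = _matrix_from(values, n_allergic=4)
        bm_half, _ = _matrix_from(values * 0.5, n_allergic=4)
        t1 = c.moderated_t(bm, cohort, prior_df=0).t
        t2 = c.moderated_t(bm_half, cohort, prior_df=0).t
        assert np.allclose(t1, t2)

    def test_insufficient_replication(self):
        bm, cohort = _matrix_from([[0.1, 0.2, 0.3], [0.2, 0.1, 0.4]], n_allergic=1)
        with pytest.raises(InsufficientReplicationError):
            c.moderated_t(bm, cohort)

    def test_matches_limma_ebayes(self, tmp_path):
        """Independent oracle: Bioconductor limma's lmFit+eBayes on the same
        matrix reproduces d0, s0^2 and every moderated t."""
        matrix, cohort, _ = c.generate(c.SyntheticSpec(10, 60, 5, 1.0, 0.5, seed=11))
        c.write_beta_matrix(matrix, tmp_path / "mat.tsv")
        c.write_labels(cohort, tmp_path / "lab.tsv")
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("mat.tsv", row.names=1))
            lab <- read.delim("lab.tsv")
            grp <- factor(lab$label, levels=c("sensitized","allergic"))
            fit <- eBayes(lmFit(x, model.matrix(~grp)))
            out <- data.frame(id=rownames(x), t=fit$t[,2])
            out$d0 <- fit$df.prior; out$s0sq <- fit$s2.prior
            write.table(out, "limma.tsv", sep="\\t", row.names=FALSE, quote=FALSE)
            """
        )
        (tmp_path / "check.R").write_text(script)
        subprocess.run(["Rscript", "check.R"], cwd=tmp_path, check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t", index_col=0)
        res = c.moderated_t(matrix, cohort)
        assert res.prior_df == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-5)
        assert res.prior_var == pytest.approx(float(ref["s0sq"].iloc[0]), rel=1e-5)
        ours = pd.Series(res.t, index=list(res.feature_ids))
        assert np.allclose(ours, ref["t"].reindex(ours.index), rtol=1e-6, atol=1e-8)


class TestRankTopK:
    def test_top_99_of_636(self, rng):
        values = rng.uniform(0.1, 0.9, size=(636, 10))
        bm, cohort = _matrix_from(values, n_allergic=5)
        rl = c.rank_top_k(c.moderated_t(bm, cohort), 99)
        assert len(rl) == 99

    def test_k_saturates_at_feature_count(self, rng):
        values = rng.uniform(0.1, 0.9, size=(7, 8))
        bm, cohort = _matrix_from(values, n_allergic=4)
        rl = c.rank_top_k(c.moderated_t(bm, cohort), 1000)
        assert len(rl) == 7

    def test_order_matches_brute_force_sort(self, rng):
        values = rng.uniform(0.1, 0.9, size=(50, 12))
        bm, cohort = _matrix_from(values, n_allergic=6)
        res = c.moderated_t(bm, cohort)
        rl = c.rank_top_k(res, 50)
        expected = [
            fid
            for _, fid in sorted(
                zip(-np.abs(res.t), res.feature_ids), key=lambda p: (p[0], p[1])
            )
        ]
        assert list(rl.feature_ids) == expected
        assert all(a >= b for a, b in zip(rl.statistic, rl.statistic[1:]))


class TestMergeRankings:
    @staticmethod
    def _list(fold, ids):
        return c.RankedList(fold, tuple(ids), tuple(float(len(ids) - i) for i in range(len(ids))))

    def test_identical_lists_preserve_order(self):
        ids = [f"cg{i}" for i in range(99)]
        agg = c.merge_rankings([self._list(f, ids) for f in range(8)])
        assert len(agg) == 99
        assert list(agg.feature_ids) == ids
        assert set(agg.occurrence) == {8}

    def test_disjoint_lists_hit_upper_bound(self):
        lists = [
            self._list(f, [f"cg{f}_{i}" for i in range(99)]) for f in range(8)
        ]
        agg = c.merge_rankings(lists)
        assert len(agg) == 8 * 99

    def test_frequency_dominates_position(self):
        """A CpG present in 7 of 8 lists outranks one present in 6, whatever
        the positions (the Table-1-style frequency/position heuristic)."""
        base = [f"f{i}" for i in range(10)]
        lists = []
        for fold in range(8):
            ids = list(base)
            if fold < 7:
                ids.insert(min(fold * 13, len(ids)), "seven")
            if fold < 6:
                ids.insert(0, "six")  # always first where present
            lists.append(self._list(fold, ids))
        agg = c.merge_rankings(lists)
        order = list(agg.feature_ids)
        assert order.index("seven") < order.index("six")
        occ = dict(zip(agg.feature_ids, agg.occurrence))
        assert occ["seven"] == 7 and occ["six"] == 6

    def test_positions_recorded_one_based(self):
        agg = c.merge_rankings([self._list(0, ["a", "b"]), self._list(1, ["b", "a"])])
        pos = dict(zip(agg.feature_ids, agg.positions))
        assert sorted(pos["a"]) == [1, 2] and sorted(pos["b"]) == [1, 2]
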