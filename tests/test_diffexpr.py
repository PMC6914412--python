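import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernanet import diffexpr as de
from cernanet.diffexpr import RVMPrior
from conftest import toy_matrix


class TestRVMPrior:
    def test_parameter_recovery(self):
        """Variances simulated from the scaled-F model give back (a, b) within 15%."""
        rng = np.random.default_rng(5)
        a_true, b_true, d = 2.5, 0.6, 18
        inv_sigma2 = rng.gamma(shape=a_true, scale=b_true, size=5000)
        sigma = 1.0 / np.sqrt(inv_sigma2)
        n1 = n2 = (d + 2) // 2
        x = rng.normal(0, sigma[:, None], size=(5000, n1 + n2))
        prior = de.fit_rvm_prior(toy_matrix(x, n_tumor=n1))
        assert prior.a == pytest.approx(a_true, rel=0.15)
        assert prior.b == pytest.approx(b_true, rel=0.15)

    def test_identical_variances_give_degenerate_prior(self):
        """With every feature at the same variance the moderated variance
        collapses onto that shared value."""
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2.0, size=(800, 20))
        mat = toy_matrix(x, n_tumor=10)
        prior = de.fit_rvm_prior(mat)
        tumor, normal = de._group_arrays(mat)
        s2, d = de._pooled_variances(tumor, normal)
        s2_mod = (d * s2 + 2.0 / prior.b) / (d + 2.0 * prior.a)
        assert np.all(np.abs(s2_mod - 4.0) / 4.0 < 0.35)
        # shrinkage pulls every feature closer to the common variance
        assert s2_mod.std() < s2.std()

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            RVMPrior(a=-1.0, b=1.0)


class TestModeratedT:
    def test_no_prior_equals_classical_t(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, size=(100, 16))
        mat = toy_matrix(x, n_tumor=8)
        res = de.moderated_t(mat, prior=None)
        t_ref, p_ref = stats.ttest_ind(x[:, :8], x[:, 8:], axis=1, equal_var=True)
        np.testing.assert_allclose(res["t"].to_numpy(), t_ref, atol=1e-12)
        np.testing.assert_allclose(res["p"].to_numpy(), p_ref, atol=1e-12)

    def test_vanishing_prior_influence_recovers_classical(self):
        """As the prior's pseudo-observations a -> 0 (with matching scale),
        the moderated statistic converges to the classical t."""
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, size=(50, 12))
        mat = toy_matrix(x, n_tumor=6)
        classical = de.moderated_t(mat, prior=None)["t"].to_numpy()
        weak = de.moderated_t(mat, prior=RVMPrior(a=1e-13, b=1e13))["t"].to_numpy()
        assert np.max(np.abs(weak - classical)) < 1e-9

    def test_equal_means_give_t0_p1(self):
        x = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        res = de.moderated_t(toy_matrix(x, n_tumor=3), prior=None)
        assert res["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_null_type_i_calibration(self):
        """No planted effect: rejection rate at alpha=.05 within binomial 99% CI."""
        rng = np.random.default_rng(3)
        n_feat = 10_000
        x = rng.normal(0, 1, size=(n_feat, 40))
        mat = toy_matrix(x, n_tumor=20)
        prior = de.fit_rvm_prior(mat)
        res = de.moderated_t(mat, prior)
        rate = float((res["p"] < 0.05).mean())
        half = 2.576 * np.sqrt(0.05 * 0.95 / n_feat)
        assert abs(rate - 0.05) < half + 0.005  # small slack for moderation at finite n

    def test_shifted_feature_has_smallest_p(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, size=(200, 20))
            x[7, :10] += 3.0
            res = de.moderated_t(toy_matrix(x, n_tumor=10), prior=None)
            hits += int(res["p"].idxmin() == "F007")
        assert hits >= 19

    def test_too_few_samples_rejected(self):
        x = np.ones((3, 3))
        with pytest.raises(ValueError, match=">=2 samples"):
            de.moderated_t(toy_matrix(x, n_tumor=1), prior=None)


class TestFoldChange:
    @pytest.mark.parametrize(
        "tumor_shift,expected",
        [(0.0, 1.0), (-2.0, -4.0), (1.0, 2.0)],
    )
    def test_signed_convention(self, tumor_shift, expected):
        base = np.full((1, 8), 5.0)
        base[0, :4] += tumor_shift
        fc = de.fold_change(toy_matrix(base, n_tumor=4))
        assert fc["fc_signed"].iloc[0] == pytest.approx(expected)
        assert fc["log2fc"].iloc[0] == pytest.approx(tumor_shift)


class TestFDR:
    def test_single_p(self):
        assert de.bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        np.testing.assert_allclose(de.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_bh_bounded_and_monotone(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        q = de.bh_fdr(p)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_legacy_fdr_boundaries(self):
        # the smallest p has Nk=0 -> 1; a p above all others has Nk=T-1
        vals = de.legacy_fdr([0.5, 0.01, 0.2, 0.9])
        assert vals[1] == pytest.approx(1.0)
        assert vals[3] == pytest.approx(1.0 - 3 / 4)

    def test_legacy_fdr_out_of_range(self):
        with pytest.raises(ValueError):
            de.legacy_fdr([1.2])


class TestSelectDE:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["feature_id", "feature_class", "fc_signed", "p", "fdr"])

    def test_mrna_threshold(self):
        rec = self._records([("g", "mRNA", 2.5, 0.01, 0.5)])
        assert len(de.select_de(rec)) == 1

    def test_mirna_needs_fdr(self):
        rec = self._records([("m", "miRNA", 1.6, 0.01, 0.2)])
        assert len(de.select_de(rec)) == 0

    def test_empty_input(self):
        assert de.select_de(self._records([])).empty

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="no selection rule"):
            de.select_de(self._records([("x", "piRNA", 3.0, 0.01, 0.01)]))

    def test_matches_exhaustive_predicate(self):
        rng = np.random.default_rng(6)
        classes = rng.choice(["mRNA", "lncRNA", "miRNA"], size=200)
        rec = pd.DataFrame(
            {
                "feature_id": [f"f{i}" for i in range(200)],
                "feature_class": classes,
                "fc_signed": rng.normal(0, 3, 200),
                "p": rng.uniform(size=200),
                "fdr": rng.uniform(size=200),
            }
        )
        got = set(de.select_de(rec)["feature_id"])
        want = set()
        for _, r in rec.iterrows():
            if r.feature_class in ("mRNA", "lncRNA"):
                ok = abs(r.fc_signed) > 2 and r.p < 0.05
            else:
                ok = abs(r.fc_signed) > 1.5 and r.p < 0.05 and r.fdr < 0.05
            if ok:
                want.add(r.feature_id)
        assert got == want


class TestIntersect:
    def _df(self, pairs):
        return pd.DataFrame(
            [(f, "mRNA", d) for f, d in pairs], columns=["feature_id", "feature_class", "direction"]
        )

    def test_single_cohort_identity(self):
        out, _ = de.intersect_de({"A": self._df([("g1", "up"), ("g2", "down")])})
        assert set(out["feature_id"]) == {"g1", "g2"}

    def test_disjoint_lists_empty(self):
        out, _ = de.intersect_de({"A": self._df([("g1", "up")]), "B": self._df([("g2", "up")])})
        assert out.empty

    def test_direction_conflict_dropped(self):
        lists = {
            "A": self._df([("g1", "up"), ("g2", "up")]),
            "B": self._df([("g1", "up"), ("g2", "up")]),
            "C": self._df([("g1", "up"), ("g2", "down")]),
        }
        out, venn = de.intersect_de(lists)
        assert set(out["feature_id"]) == {"g1"}
        assert venn["A&B&C"] == 2

    def test_min_cohorts(self):
        lists = {
            "A": self._df([("g1", "up")]),
            "B": self._df([("g1", "up"), ("g2", "down")]),
            "C": self._df([("g2", "down")]),
        }
        out, _ = de.intersect_de(lists, min_cohorts=2)
        assert set(out["feature_id"]) == {"g1", "g2"}


class TestHierarchicalCluster:
    def test_identical_rows_merge_first(self):
        x = np.array([[1, 2, 3, 4.0], [2, 4, 6, 8.0], [4, 3, 2, 1.0], [9, 1, 8, 2.0]])
        z, order = de.hierarchical_cluster(toy_matrix(x))
        # rows 0 and 1 are perfectly correlated -> distance 0, merged first
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}

    def test_planted_blocks_separate(self):
        rng = np.random.default_rng(7)
        sig = rng.normal(size=12)
        block_a = sig + rng.normal(0, 0.05, size=(3, 12))
        block_b = -sig + rng.normal(0, 0.05, size=(3, 12))
        mat = toy_matrix(np.vstack([block_a, block_b]))
        _, order = de.hierarchical_cluster(mat)
        idx = {f: i for i, f in enumerate(order)}
        a_pos = sorted(idx[f"F00{i}"] for i in range(3))
        b_pos = sorted(idx[f"F00{i}"] for i in range(3, 6))
        assert a_pos[-1] < b_pos[0] or b_pos[-1] < a_pos[0]

    def test_linkage_heights_nondecreasing(self):
        rng = np.random.default_rng(8)
        z, _ = de.hierarchical_cluster(toy_matrix(rng.normal(size=(10, 8))))
        assert np.all(np.diff(z[:, 2]) >= -1e-12)

    def test_constant_feature_handled(self):
        x = np.vstack([np.ones(6), np.arange(6.0), -np.arange(6.0)])
        z, order = de.hierarchical_cluster(toy_matrix(x))
        assert len(order) == 3
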