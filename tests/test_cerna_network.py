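import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernanet import cerna_network as cn
from cernanet.synthetic_data import SimulationConfig, generate, truth_report
from cernanet.target_prediction import TargetPair, TargetSite


def _pair(m, t):
    return TargetPair(m, t, [TargetSite(m, t, 0, 8, "8mer")])


def _de_from_truth(truth):
    rows = [
        {
            "feature_id": f,
            "feature_class": "miRNA" if f.startswith("mir") else "lncRNA" if f.startswith("L") else "mRNA",
            "direction": d,
        }
        for f, d in truth.de_features.items()
    ]
    return pd.DataFrame(rows)


def _planted_pairs(bundle):
    lnc = [_pair(m, t) for (m, t) in bundle.truth.target_pairs if t.startswith("L")]
    mrna = [_pair(m, t) for (m, t) in bundle.truth.target_pairs if t.startswith("G")]
    return mrna, lnc


class TestPearson:
    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        r, p = cn.pearson_with_p(x, -x)
        assert r == pytest.approx(-1.0)
        assert p == pytest.approx(0.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(size=(2, 15))
            r, p = cn.pearson_with_p(x, y)
            r_ref, p_ref = stats.pearsonr(x, y)
            assert r == pytest.approx(r_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, rel=1e-9)

    def test_zero_variance_reported_missing(self):
        r, p = cn.pearson_with_p(np.ones(5), np.arange(5.0))
        assert np.isnan(r) and np.isnan(p)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            cn.pearson_with_p([1.0, 2.0], [3.0, 4.0])

    def test_null_p_uniform(self):
        """Independent vectors: p-values are uniform (KS test)."""
        rng = np.random.default_rng(1)
        n_rep, n = 2000, 50
        x = rng.normal(size=(n_rep, n))
        y = rng.normal(size=(n_rep, n))
        ps = np.array([cn.pearson_with_p(x[i], y[i])[1] for i in range(n_rep)])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_p_within_permutation_mc_interval(self):
        """Small-n analytic p agrees with a permutation null within MC error."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=8)
        y = 0.7 * x + rng.normal(size=8)
        r_obs, p_analytic = cn.pearson_with_p(x, y)
        n_perm = 100_000
        perm_r = np.empty(n_perm)
        for i in range(n_perm):
            perm_r[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p_mc = float((np.abs(perm_r) >= abs(r_obs) - 1e-12).mean())
        se = np.sqrt(p_mc * (1 - p_mc) / n_perm)
        # analytic p assumes normality; allow ~4 MC standard errors plus slack
        assert abs(p_analytic - p_mc) < 4 * se + 0.01


class TestBuildCerna:
    def test_no_pairs_gives_empty_network(self, small_bundle):
        de = _de_from_truth(small_bundle.truth)
        expr = {"mRNA": small_bundle.mrna, "lncRNA": small_bundle.lncrna, "miRNA": small_bundle.mirna}
        net = cn.build_cerna(de, [], [], expr)
        assert net.edges.empty and net.triplets.empty

    def test_planted_triplet_recovery(self):
        cfg = SimulationConfig(
            n_cohorts=1,
            samples_per_cohort=(100, 25),
            n_mRNA=200,
            n_lncRNA=60,
            n_miRNA=40,
            n_triplets=10,
            sponge_strength=2.0,
            noise_sd=1.0,
            transcript_length=200,
            seed=11,
        )
        bundle = generate(cfg)
        pairs_m, pairs_lnc = _planted_pairs(bundle)
        de = _de_from_truth(bundle.truth)
        expr = {"mRNA": bundle.mrna, "lncRNA": bundle.lncrna, "miRNA": bundle.mirna}
        net = cn.build_cerna(de, pairs_m, pairs_lnc, expr)
        metrics = truth_report(bundle.truth, net)
        assert metrics.recall >= 0.9
        assert metrics.precision >= 0.9

    def test_every_edge_satisfies_all_gates(self, small_bundle):
        """Independent predicate pass over retained edges."""
        pairs_m, pairs_lnc = _planted_pairs(small_bundle)
        de = _de_from_truth(small_bundle.truth)
        expr = {"mRNA": small_bundle.mrna, "lncRNA": small_bundle.lncrna, "miRNA": small_bundle.mirna}
        net = cn.build_cerna(de, pairs_m, pairs_lnc, expr)
        predicted = {(p.miRNA_id, p.target_id) for p in pairs_m + pairs_lnc}
        direction = dict(zip(de["feature_id"], de["direction"]))
        tumor = {
            fid: mat.subset_condition("tumor").values.loc[fid].to_numpy()
            for mat in expr.values()
            for fid in mat.feature_ids
        }
        assert not net.edges.empty
        for _, e in net.edges.iterrows():
            assert (e["miRNA_id"], e["partner_id"]) in predicted
            assert direction[e["miRNA_id"]] != direction[e["partner_id"]]
            r, p = stats.pearsonr(tumor[e["miRNA_id"]], tumor[e["partner_id"]])
            assert r < 0 and p < 0.05
            assert e["r"] == pytest.approx(r, abs=1e-10)

    def test_same_direction_pair_excluded(self):
        """r < 0 alone is not enough: DE directions must oppose."""
        rng = np.random.default_rng(3)
        from conftest import toy_matrix

        m = rng.normal(size=30)
        mir_x = np.concatenate([5 + m + 0.1 * rng.normal(size=30), 5 + rng.normal(size=10)])
        tgt_x = np.concatenate([5 - m + 0.1 * rng.normal(size=30), 5 + rng.normal(size=10)])
        mirna = toy_matrix(mir_x[None, :], "miRNA", n_tumor=30, feature_ids=["mir1"])
        mrna = toy_matrix(tgt_x[None, :], "mRNA", n_tumor=30, feature_ids=["g1"])
        de = pd.DataFrame(
            [("mir1", "miRNA", "up"), ("g1", "mRNA", "up")],
            columns=["feature_id", "feature_class", "direction"],
        )
        net = cn.build_cerna(de, [_pair("mir1", "g1")], [], {"mRNA": mrna, "miRNA": mirna})
        assert net.edges.empty
        de_opp = de.assign(direction=["up", "down"])
        net2 = cn.build_cerna(de_opp, [_pair("mir1", "g1")], [], {"mRNA": mrna, "miRNA": mirna})
        assert len(net2.edges) == 1

    def test_recall_monotone_in_sponge_strength(self):
        """Stronger sponging never reduces planted-triplet recall."""
        mean_recall = []
        for strength in (0.5, 1.0, 2.0):
            recalls = []
            for rep in range(6):
                cfg = SimulationConfig(
                    n_cohorts=1,
                    samples_per_cohort=(60, 15),
                    n_mRNA=120,
                    n_lncRNA=40,
                    n_miRNA=30,
                    n_triplets=6,
                    sponge_strength=strength,
                    transcript_length=150,
                    seed=100 + rep,
                )
                bundle = generate(cfg)
                pairs_m, pairs_lnc = _planted_pairs(bundle)
                net = cn.build_cerna(
                    _de_from_truth(bundle.truth),
                    pairs_m,
                    pairs_lnc,
                    {"mRNA": bundle.mrna, "lncRNA": bundle.lncrna, "miRNA": bundle.mirna},
                )
                recalls.append(truth_report(bundle.truth, net).recall)
            mean_recall.append(np.mean(recalls))
        assert mean_recall[0] <= mean_recall[1] + 1e-9 <= mean_recall[2] + 2e-9

    def test_subnetwork_partition_is_exact(self, small_bundle):
        pairs_m, pairs_lnc = _planted_pairs(small_bundle)
        net = cn.build_cerna(
            _de_from_truth(small_bundle.truth),
            pairs_m,
            pairs_lnc,
            {"mRNA": small_bundle.mrna, "lncRNA": small_bundle.lncrna, "miRNA": small_bundle.mirna},
        )
        up = net.subnetwork("up")
        down = net.subnetwork("down")
        assert set(up.nodes["feature_id"]).isdisjoint(set(down.nodes["feature_id"]))
        assert len(up.edges) + len(down.edges) == len(net.edges)
        # sign structure: up-miRNA subnetwork has down partners only
        if not up.nodes.empty:
            partners = up.nodes[up.nodes["feature_class"] != "miRNA"]
            assert (partners["direction"] == "down").all()


class TestSummarize:
    def test_empty(self):
        s = cn.summarize_network(cn._empty_network())
        assert (s["n_lncRNA"], s["n_miRNA"], s["n_mRNA"], s["n_edges"], s["n_triplets"]) == (0, 0, 0, 0, 0)

    def test_two_triplets_sharing_one_mirna(self):
        rng = np.random.default_rng(4)
        from conftest import toy_matrix

        m = rng.normal(size=40)
        rows, ids = [], []
        for fid, sign in (("mir1", 1.0), ("L1", -1.0), ("L2", -1.0), ("g1", -1.0), ("g2", -1.0)):
            rows.append(5 + sign * 2 * m + 0.3 * rng.normal(size=40))
            ids.append(fid)
        x = np.array(rows)
        mats = {
            "miRNA": toy_matrix(x[:1], "miRNA", n_tumor=40, feature_ids=ids[:1]),
            "lncRNA": toy_matrix(x[1:3], "lncRNA", n_tumor=40, feature_ids=ids[1:3]),
            "mRNA": toy_matrix(x[3:], "mRNA", n_tumor=40, feature_ids=ids[3:]),
        }
        de = pd.DataFrame(
            [("mir1", "miRNA", "up"), ("L1", "lncRNA", "down"), ("L2", "lncRNA", "down"),
             ("g1", "mRNA", "down"), ("g2", "mRNA", "down")],
            columns=["feature_id", "feature_class", "direction"],
        )
        pairs_m = [_pair("mir1", "g1"), _pair("mir1", "g2")]
        pairs_lnc = [_pair("mir1", "L1"), _pair("mir1", "L2")]
        net = cn.build_cerna(de, pairs_m, pairs_lnc, mats)
        s = cn.summarize_network(net)
        assert (s["n_lncRNA"], s["n_miRNA"], s["n_mRNA"]) == (2, 1, 2)
        assert s["n_edges"] == 4
        assert s["n_triplets"] == 4  # 2 lncRNAs x 2 mRNAs through the shared miRNA
        assert s["degree"].set_index("feature_id").loc["mir1", "degree"] == 4
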