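"""Differential expression, FDR control, ranking and consensus clustering."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm
from sklearn.metrics import adjusted_rand_score

import visig
from visig.countcore import CountMatrix
from visig.signature import DEResult


def _toy_cm(counts):
    counts = np.asarray(counts)
    return CountMatrix(np.array([f"g{i}" for i in range(counts.shape[0])], object),
                       np.array([f"s{j}" for j in range(counts.shape[1])], object),
                       counts)


class TestNbGlmLrt:
    def test_null_cohort_pvalues_calibrated(self, null_de):
        p = null_de.table["pvalue"].dropna().to_numpy()
        frac = (p < 0.05).mean()
        assert 0.03 <= frac <= 0.07
        assert scipy.stats.kstest(p, "uniform").statistic < 0.05

    def test_planted_high_effect_genes_recovered(self):
        cfg = visig.CohortConfig(cluster_log2fc=(2.0, 2.0, 2.0, -2.0), seed=3)
        cm, meta, truth = visig.generate_bulk_cohort(cfg)
        cmf = visig.with_tmm(visig.filter_genes(cm))
        de = visig.nb_glm_lrt(cmf, visig.grade_design(meta), "VI")
        sig = set(de.significant(0.01)["gene_id"])
        recovered = np.mean([g in sig for g in truth.planted_genes])
        assert recovered >= 0.90

    def test_identical_group_means_give_null_lrt(self):
        counts = np.tile([[100, 100, 100, 100, 100, 100]], (3, 1))
        cm = _toy_cm(counts)
        meta = pd.DataFrame({"sample_id": cm.sample_ids,
                             "grade": ["LMP", "LMP", "NST", "NST", "VI", "VI"]})
        de = visig.nb_glm_lrt(cm, visig.grade_design(meta), "VI",
                              dispersions=np.full(3, 0.1))
        assert (de.table["lrt"] < 1e-6).all()
        assert (de.table["pvalue"] > 0.99).all()

    def test_poisson_limit_matches_poisson_glm(self, rng):
        # at dispersion -> 0 the NB LRT deviance approaches the Poisson one
        n = 40
        grades = np.repeat(["LMP", "NST", "VI"], [14, 13, 13])
        meta = pd.DataFrame({"sample_id": [f"s{j}" for j in range(n)],
                             "grade": grades})
        counts = rng.poisson(50 * np.exp(0.4 * (grades == "VI")), size=(25, n))
        cm = CountMatrix(np.array([f"g{i}" for i in range(25)], object),
                         np.array(meta["sample_id"], object), counts,
                         lib_sizes=np.full(n, 1e4))
        design = visig.grade_design(meta)
        de = visig.nb_glm_lrt(cm, design, "VI", dispersions=np.full(25, 1e-6))
        X_full = design.to_numpy(float)
        X_red = design.drop(columns="VI").to_numpy(float)
        off = np.log(cm.lib_sizes)
        for i in range(25):
            full = sm.GLM(counts[i], X_full, family=sm.families.Poisson(),
                          offset=off).fit()
            red = sm.GLM(counts[i], X_red, family=sm.families.Poisson(),
                         offset=off).fit()
            lrt_pois = red.deviance - full.deviance
            if lrt_pois > 0.1:
                assert abs(de.table["lrt"][i] - lrt_pois) / lrt_pois < 0.01

    def test_nonconverged_genes_excluded_from_fdr(self, de_result):
        t = de_result.table
        assert t.loc[t["pvalue"].isna(), "qvalue"].isna().all()


class TestBhAdjust:
    def test_hand_stepped_example(self):
        np.testing.assert_allclose(visig.bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_degenerate_inputs(self):
        np.testing.assert_allclose(visig.bh_adjust([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_allclose(visig.bh_adjust([0.2]), [0.2])

    def test_nan_passthrough_and_range_check(self):
        out = visig.bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1])
        with pytest.raises(ValueError):
            visig.bh_adjust([-0.1])

    def test_q_at_least_p_and_monotone(self, de_result):
        t = de_result.table.dropna(subset=["pvalue"]).sort_values("pvalue")
        assert (t["qvalue"] + 1e-12 >= t["pvalue"]).all()
        assert (np.diff(t["qvalue"]) >= -1e-12).all()


class TestSignedRank:
    def _de(self, rows):
        tab = pd.DataFrame(rows, columns=["gene_id", "log2fc", "pvalue"])
        tab["lrt"] = 1.0
        tab["df"] = 1
        tab["qvalue"] = tab["pvalue"]
        tab["mean_logcpm"] = 1.0
        return DEResult(tab)

    def test_plugin_values(self):
        de = self._de([("a", -1.0, 0.01), ("b", 2.0, 1.0)])
        vals = visig.signed_rank_statistic(de)
        assert vals["a"] == pytest.approx(-2.0)
        assert vals["b"] == pytest.approx(0.0)

    def test_tie_breaks_by_abs_fold_change(self):
        de = self._de([("low", 0.5, 0.01), ("high", 1.5, 0.01)])
        vals = visig.signed_rank_statistic(de)
        assert list(vals.index) == ["high", "low"]


class TestWard2:
    def test_separated_blobs_recovered_exactly(self, rng):
        z = np.vstack([rng.normal(5, 0.2, (10, 6)), rng.normal(-5, 0.2, (12, 6))])
        labels = visig.ward2_cluster(z, 2)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equals_n_gives_singletons(self, rng):
        z = rng.normal(size=(5, 4))
        assert sorted(visig.ward2_cluster(z, 5)) == [1, 2, 3, 4, 5]

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            visig.ward2_cluster(rng.normal(size=(4, 3)), 5)

    def test_planted_clusters_recovered(self, signature_z, truth_cluster_of):
        genes, z = signature_z
        labels = visig.ward2_cluster(z, 4)
        truth_labels = [truth_cluster_of.get(g, 0) for g in genes]
        assert adjusted_rand_score(truth_labels, labels) >= 0.9


class TestConsensus:
    def test_two_perfectly_separated_clusters_choose_k2(self):
        z = np.vstack([np.tile(np.full(10, 5.0), (30, 1)),
                       np.tile(np.full(10, -5.0), (30, 1))])
        k, diag = visig.consensus_select_k(z, k_range=range(2, 7),
                                           n_subsamples=50, seed=0)
        assert k == 2
        cons = diag["consensus"][2]
        assert set(np.round(np.unique(cons), 12)) <= {0.0, 1.0}

    def test_consensus_matrix_well_formed(self, rng):
        z = rng.normal(size=(25, 8))
        _, diag = visig.consensus_select_k(z, k_range=[3], n_subsamples=30, seed=1)
        cons = diag["consensus"][3]
        np.testing.assert_allclose(cons, cons.T)
        np.testing.assert_allclose(np.diag(cons), 1.0)
        assert cons.min() >= 0.0 and cons.max() <= 1.0

    def test_permutation_equivariance_on_separable_data(self, rng):
        z = np.vstack([np.tile(np.full(6, 4.0), (15, 1)),
                       np.tile(np.full(6, -4.0), (15, 1))])
        perm = rng.permutation(30)
        _, d1 = visig.consensus_select_k(z, k_range=[2], n_subsamples=40, seed=2)
        _, d2 = visig.consensus_select_k(z[perm], k_range=[2], n_subsamples=40, seed=2)
        np.testing.assert_allclose(d2["consensus"][2],
                                   d1["consensus"][2][np.ix_(perm, perm)])


class TestRecoveryMonotonicity:
    def test_doubling_effects_never_reduces_recovery(self):
        # planted-gene recovery at fixed FDR is monotone in effect size
        for seed in range(5):
            recovered = []
            for scale in (0.6, 1.2):
                cfg = visig.CohortConfig(
                    n_samples=60, n_genes=800,
                    cluster_sizes=(40, 15, 60, 45),
                    cluster_log2fc=(scale, scale, scale, -scale), seed=seed)
                cm, meta, truth = visig.generate_bulk_cohort(cfg)
                cmf = visig.with_tmm(visig.filter_genes(cm))
                de = visig.nb_glm_lrt(cmf, visig.grade_design(meta), "VI")
                sig = set(de.significant(0.01)["gene_id"])
                recovered.append(sum(g in sig for g in truth.planted_genes))
            assert recovered[1] >= recovered[0]
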