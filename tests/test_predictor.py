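"""Feature selection, ridge logit, nested CV, AUROC/Youden, harmonization."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.special
import scipy.stats

import visig
from visig.predictor import (
    PredictorConfig,
    _auroc_stat,
    _predict_proba,
    _ridge_logit_objective,
    fit_outer_split,
)


class TestProportionalSelect:
    def test_largest_remainder_quotas_12_4_18_14(self, make_de_clusters):
        de, clusters = make_de_clusters()
        chosen = visig.proportional_select(de, clusters, n_total=48)
        assert len(chosen) == 48
        per = pd.Series([g.split("_")[0] for g in chosen]).value_counts()
        assert per.to_dict() == {"c3": 18, "c4": 14, "c1": 12, "c2": 4}

    def test_within_cluster_choice_by_ascending_p(self, make_de_clusters):
        de, clusters = make_de_clusters()
        chosen = set(visig.proportional_select(de, clusters, n_total=48))
        sig = de.table.set_index("gene_id")
        for c, quota in (("c1", 12), ("c2", 4)):
            members = sig[sig.index.str.startswith(c)]["pvalue"].sort_values()
            assert set(members.index[:quota]) <= chosen

    def test_single_cluster_supplies_all(self, make_de_clusters):
        de, clusters = make_de_clusters(sizes=(60, 1, 1, 1))
        chosen = visig.proportional_select(de, clusters, n_total=48)
        assert sum(g.startswith("c1") for g in chosen) >= 45

    def test_selecting_everything_is_identity(self, make_de_clusters):
        de, clusters = make_de_clusters(sizes=(10, 5, 8, 7))
        chosen = visig.proportional_select(de, clusters, n_total=30)
        assert sorted(chosen) == sorted(de.table["gene_id"])


class TestRidgeLogit:
    def test_matches_independent_numerical_optimizer(self, rng):
        X = rng.normal(size=(6, 2))
        y = np.array([0, 0, 0, 1, 1, 1.0])
        beta, b0 = visig.fit_ridge_logit(X, y, 1.0)
        res = scipy.optimize.minimize(
            lambda t: _ridge_logit_objective(t[1:], t[0], X, y, 1.0),
            np.zeros(3), method="BFGS", options={"gtol": 1e-12})
        np.testing.assert_allclose(np.r_[b0, beta], res.x, atol=1e-6)

    def test_full_shrinkage_limit(self, rng):
        X = rng.normal(size=(50, 4))
        y = (rng.uniform(size=50) < 0.4).astype(float)
        beta, b0 = visig.fit_ridge_logit(X, y, 1e6)
        assert np.linalg.norm(beta) < 1e-3
        assert abs(b0 - scipy.special.logit(y.mean())) < 1e-3

    def test_row_duplication_invariance(self, rng):
        X = rng.normal(size=(20, 3))
        y = (rng.uniform(size=20) < 0.5).astype(float)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        b1 = visig.fit_ridge_logit(X, y, 0.5)
        b2 = visig.fit_ridge_logit(np.vstack([X, X]), np.concatenate([y, y]), 0.5)
        np.testing.assert_allclose(np.r_[b1[1], b1[0]], np.r_[b2[1], b2[0]],
                                   atol=1e-7)

    def test_shrinkage_monotone_in_lambda(self, rng):
        X = rng.normal(size=(40, 5))
        y = (rng.uniform(size=40) < scipy.special.expit(X[:, 0])).astype(float)
        norms = [np.linalg.norm(visig.fit_ridge_logit(X, y, lam)[0])
                 for lam in (0.01, 0.1, 1.0, 10.0, 100.0)]
        assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))

    def test_separation_at_lambda_zero_raises(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1.0])
        with pytest.raises(RuntimeError):
            visig.fit_ridge_logit(X, y, 0.0)


class TestInnerCv:
    def test_singleton_grid_returned(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.r_[np.zeros(15), np.ones(15)]
        assert visig.inner_cv_lambda(X, y, [0.7], seed=0) == 0.7

    def test_strong_correlated_signal_prefers_moderate_penalty(self):
        # whitening matters when features are correlated, so the inner CV
        # must not run to the top of the grid
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 120
            x1 = r.normal(size=n)
            x2 = 0.9 * x1 + np.sqrt(1 - 0.81) * r.normal(size=n)
            y = (r.uniform(size=n) < scipy.special.expit(4 * (x1 - x2))).astype(float)
            lam = visig.inner_cv_lambda(np.c_[x1, x2], y, seed=seed)
            assert lam < visig.predictor.DEFAULT_LAMBDA_GRID.max()

    def test_identical_folds_make_choice_seed_independent(self):
        a = np.full((30, 2), 1.0)
        b = np.full((30, 2), -1.0)
        X = np.vstack([a, b])
        y = np.r_[np.ones(30), np.zeros(30)]
        lams = {visig.inner_cv_lambda(X, y, seed=s) for s in range(3)}
        assert len(lams) == 1


class TestAuroc:
    def test_exhaustive_pair_counting_examples(self):
        assert _auroc_stat([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert _auroc_stat([1, 3, 2, 4], [0, 0, 1, 1]) == 0.75

    def test_label_flip_antisymmetry(self, rng):
        s = rng.normal(size=8)
        y = np.array([0, 1, 0, 1, 1, 0, 0, 1])
        assert _auroc_stat(s, y) == pytest.approx(1 - _auroc_stat(s, 1 - y))

    def test_bootstrap_ci_contains_estimate(self, rng):
        s = np.r_[rng.normal(0, 1, 40), rng.normal(1.5, 1, 40)]
        y = np.r_[np.zeros(40), np.ones(40)]
        res = visig.auroc(s, y, n_boot=500, seed=0)
        assert res["ci"][0] <= res["auroc"] <= res["ci"][1]
        assert res["pvalue"] < 0.001

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            _auroc_stat([1.0, 2.0], [1, 1])


class TestYouden:
    def test_enumerated_example(self):
        cutoff = visig.youden_cutoff([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert 0.1 < cutoff < 0.35

    def test_perfect_separation_midpoint(self):
        cutoff = visig.youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert 0.2 < cutoff < 0.8

    def test_constant_scores_give_chance_threshold(self):
        cutoff = visig.youden_cutoff([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
        pred = np.array([0.5] * 4) > cutoff
        sens = pred[[1, 3]].mean()
        spec = 1 - pred[[0, 2]].mean()
        assert sens + spec - 1 == pytest.approx(0.0)


class TestKsRankEnrichment:
    def test_top_block_is_extreme(self):
        ranked = [f"g{i}" for i in range(100)]
        d, p = visig.ks_rank_enrichment(ranked, ranked[:5])
        assert d >= 1 - 5 / 100
        assert p < 0.01

    def test_random_subsets_are_calibrated(self, rng):
        ranked = [f"g{i}" for i in range(200)]
        ps = []
        for _ in range(100):
            sub = rng.choice(ranked, size=10, replace=False)
            ps.append(visig.ks_rank_enrichment(ranked, sub)[1])
        assert scipy.stats.kstest(ps, "uniform").statistic < 0.2
        assert np.mean(np.array(ps) < 0.05) < 0.15

    def test_full_subset_rejected(self):
        with pytest.raises(ValueError):
            visig.ks_rank_enrichment(["a", "b"], ["a", "b"])


class TestNestedCv:
    def test_report_is_seed_deterministic(self, bulk_cohort):
        cm, meta, _ = bulk_cohort
        cfg = PredictorConfig(n_outer=2)
        r1 = visig.nested_cv_evaluate(cm, meta, cfg, seed=5)
        r2 = visig.nested_cv_evaluate(cm, meta, cfg, seed=5)
        pd.testing.assert_frame_equal(r1.splits, r2.splits)
        assert r1.selected_genes == r2.selected_genes

    def test_outer_test_labels_cannot_leak(self, bulk_cohort):
        cm, meta, _ = bulk_cohort
        cfg = PredictorConfig(n_outer=1)
        train_idx = np.arange(0, 70)
        corrupted = meta.copy()
        flip = corrupted.index >= 70
        corrupted.loc[flip, "vi"] = 1 - corrupted.loc[flip, "vi"]
        corrupted.loc[flip, "grade"] = "LMP"
        g1, b1, i1, m1, s1, l1 = fit_outer_split(cm, meta, train_idx, cfg, seed=0)
        g2, b2, i2, m2, s2, l2 = fit_outer_split(cm, corrupted, train_idx, cfg, seed=0)
        assert g1 == g2
        np.testing.assert_array_equal(b1, b2)
        assert i1 == i2 and l1 == l2


class TestFinalModel:
    def test_has_48_genes_and_valid_standardization(self, final_model):
        assert len(final_model.gene_ids) == 48
        assert (final_model.sds > 0).all()

    def test_retraining_reproduces_coefficients(self, bulk_cohort, final_model):
        cm, meta, _ = bulk_cohort
        again = visig.train_final(cm, meta, seed=0)
        np.testing.assert_array_equal(again.coefficients, final_model.coefficients)
        assert again.youden_cutoff == final_model.youden_cutoff

    def test_training_scores_reproduce_youden_cutoff(self, bulk_cohort, final_model):
        cm, meta, _ = bulk_cohort
        lcm = visig.log_cpm(visig.with_tmm(cm))
        scores = visig.predict_score(final_model, lcm)
        cutoff = visig.youden_cutoff(scores["value"], meta["vi"])
        assert cutoff == pytest.approx(final_model.youden_cutoff, abs=1e-12)

    def test_coefficient_signs_recover_planted_directions(
            self, bulk_cohort, final_model):
        _, _, truth = bulk_cohort
        down = set(truth.cluster_genes[4])
        coef = dict(zip(final_model.gene_ids, final_model.coefficients))
        pos = [g for g, c in coef.items() if c > 0]
        assert np.mean([g not in down for g in pos]) >= 0.8
        down_selected = [g for g in final_model.gene_ids if g in down]
        assert len(down_selected) > 0
        assert np.mean([coef[g] < 0 for g in down_selected]) >= 0.8

    def test_json_roundtrip(self, final_model):
        back = visig.PredictorModel.from_json(final_model.to_json())
        np.testing.assert_array_equal(back.coefficients, final_model.coefficients)
        assert back.gene_ids == final_model.gene_ids


class TestPredictScore:
    def test_all_features_at_training_means(self, final_model):
        lcm = visig.LogCpmMatrix(
            np.array(final_model.gene_ids, object), np.array(["u0"], object),
            np.array(final_model.means)[:, None])
        out = visig.predict_score(final_model, lcm)
        assert out["value"][0] == pytest.approx(
            scipy.special.expit(final_model.intercept))

    def test_positive_coefficient_gene_is_monotone(self, final_model):
        j = int(np.argmax(final_model.coefficients))
        base = np.array(final_model.means)[:, None]
        bumped = base.copy()
        bumped[j] += 1.0
        genes = np.array(final_model.gene_ids, object)
        s0 = visig.predict_score(
            final_model, visig.LogCpmMatrix(genes, np.array(["u"], object), base))
        s1 = visig.predict_score(
            final_model, visig.LogCpmMatrix(genes, np.array(["u"], object), bumped))
        assert s1["value"][0] > s0["value"][0]

    def test_missing_gene_policy(self, final_model, rng):
        genes = np.array(final_model.gene_ids[:-1], object)
        lcm = visig.LogCpmMatrix(genes, np.array(["u"], object),
                                 rng.normal(size=(len(genes), 1)))
        with pytest.raises(ValueError):
            visig.predict_score(final_model, lcm)
        with pytest.warns(UserWarning):
            visig.predict_score(final_model, lcm, impute_missing=True)


class TestReferenceAdjust:
    def _lcm(self, rng, n_genes=30, n_samples=12, shift=0.0):
        vals = rng.normal(5, 1, size=(n_genes, n_samples)) + shift
        return visig.LogCpmMatrix(
            np.array([f"g{i}" for i in range(n_genes)], object),
            np.array([f"s{j}" for j in range(n_samples)], object), vals)

    def test_moments_match_reference_exactly(self, rng):
        ref = self._lcm(rng)
        tgt = self._lcm(rng, shift=3.0)
        adj = visig.reference_adjust(tgt, ref)
        np.testing.assert_allclose(adj.values.mean(axis=1),
                                   ref.values.mean(axis=1), atol=1e-10)
        np.testing.assert_allclose(adj.values.std(axis=1, ddof=1),
                                   ref.values.std(axis=1, ddof=1), atol=1e-10)

    def test_self_map_is_identity_on_moments(self, rng):
        ref = self._lcm(rng)
        adj = visig.reference_adjust(ref, ref)
        np.testing.assert_allclose(adj.values, ref.values, atol=1e-10)

    def test_adjustment_improves_shifted_validation_auroc(
            self, bulk_cohort, final_model):
        cm, _, _ = bulk_cohort
        ref_lcm = visig.log_cpm(visig.with_tmm(cm))
        gains = []
        for vseed in (7, 8, 9):
            cfgv = visig.CohortConfig(seed=vseed, batch_shift_sd=1.0, n_batches=4)
            cmv, metav, _ = visig.generate_bulk_cohort(cfgv)
            val_lcm = visig.log_cpm(visig.with_tmm(cmv))
            raw = _auroc_stat(
                visig.predict_score(final_model, val_lcm)["value"], metav["vi"])
            adj = _auroc_stat(
                visig.predict_score(
                    final_model,
                    visig.reference_adjust(val_lcm, ref_lcm))["value"],
                metav["vi"])
            gains.append(adj - raw)
        assert np.mean(gains) > 0


class TestPredictAffineInvariance:
    def test_rescaling_a_gene_is_absorbed_by_refit_standardization(self, rng):
        X = rng.normal(size=(40, 5))
        y = (rng.uniform(size=40) < scipy.special.expit(X[:, 0])).astype(float)
        def fit_scores(Xin):
            mu, sd = Xin.mean(axis=0), Xin.std(axis=0, ddof=1)
            beta, b0 = visig.fit_ridge_logit((Xin - mu) / sd, y, 0.5)
            return _predict_proba((Xin - mu) / sd, beta, b0)
        X2 = X.copy()
        X2[:, 2] = 3.5 * X2[:, 2] - 7.0
        np.testing.assert_allclose(fit_scores(X), fit_scores(X2), atol=1e-7)
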