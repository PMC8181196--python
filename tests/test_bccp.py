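"""Compound covariate scores, Gaussian posteriors, prediction, LOOCV AUC."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from lnc6 import bccp, io
from lnc6.bccp import BinaryCcpModel, SubtypeAssignment
from lnc6.matrix import ExpressionMatrix
from lnc6.signature import build_all_signatures, build_signature, ovr_t_test
from lnc6.synthetic import CohortConfig, apply_batch_shift, generate_training_cohort


def _model(weights, genes=None, mu_in=1.0, mu_out=-1.0, sd=1.0, prior=0.5):
    genes = genes or [f"G{i}" for i in range(len(weights))]
    return BinaryCcpModel(subtype=1, gene_ids=genes, weights=np.asarray(weights, float),
                          score_mean_in=mu_in, score_mean_out=mu_out,
                          score_sd=sd, prior_in=prior)


class TestCompoundScore:
    def test_linear_combination(self):
        m = _model([1.0, -1.0])
        assert bccp.compound_score(m, {"G0": 2.0, "G1": 3.0}) == -1.0

    def test_zero_profile_scores_zero(self):
        m = _model([2.0, 3.0, -4.0])
        assert bccp.compound_score(m, {"G0": 0, "G1": 0, "G2": 0}) == 0.0

    def test_doubling_weights_doubles_score(self, rng):
        w = rng.normal(size=8)
        profile = {f"G{i}": v for i, v in enumerate(rng.normal(size=8))}
        s1 = bccp.compound_score(_model(w), profile)
        s2 = bccp.compound_score(_model(2 * w), profile)
        assert s2 == pytest.approx(2 * s1)

    def test_missing_genes_contribute_zero_above_coverage(self):
        m = _model([1.0, 1.0, 1.0, 1.0])
        assert bccp.compound_score(m, {"G0": 5.0, "G1": 2.0}) == 7.0

    def test_low_coverage_rejected(self):
        m = _model([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="cover"):
            bccp.compound_score(m, {"G0": 5.0})


class TestPosterior:
    def test_closed_form_logistic_value(self):
        # mu = +-1, sigma = 1, prior 0.5, score 1 -> 1 / (1 + e^-2)
        m = _model([1.0])
        assert bccp.posterior(m, 1.0) == pytest.approx(1 / (1 + np.exp(-2)), abs=1e-12)

    def test_midpoint_score_gives_half(self):
        m = _model([1.0], mu_in=3.0, mu_out=-7.0)
        assert bccp.posterior(m, -2.0) == pytest.approx(0.5)

    def test_equal_means_return_prior(self):
        m = _model([1.0], mu_in=2.0, mu_out=2.0, prior=0.3)
        for score in (-5.0, 0.0, 7.0):
            assert bccp.posterior(m, score) == pytest.approx(0.3)

    def test_monotone_in_score_direction(self):
        up = _model([1.0], mu_in=1.0, mu_out=-1.0)
        down = _model([1.0], mu_in=-1.0, mu_out=1.0)
        scores = np.linspace(-5, 5, 30)
        p_up = [bccp.posterior(up, s) for s in scores]
        p_dn = [bccp.posterior(down, s) for s in scores]
        assert (np.diff(p_up) > 0).all() and (np.diff(p_dn) < 0).all()

    def test_extreme_scores_stay_finite(self):
        m = _model([1.0])
        assert bccp.posterior(m, 1e8) == 1.0
        assert bccp.posterior(m, -1e8) == 0.0


class TestTrainBinary:
    def _cohort_k2(self, seed=13):
        cfg = CohortConfig(n_samples=60, n_lnc_genes=80, n_mrna_genes=200,
                           k_subtypes=2, n_marker_genes_per_subtype=30, seed=seed)
        _, mrna, labels = generate_training_cohort(cfg)
        return io.zscore_genes(mrna), labels

    def test_class_means_match_brute_force(self):
        z, labels = self._cohort_k2()
        sig = build_signature(ovr_t_test(z, labels, 1), subtype=1, max_genes=30)
        model = bccp.train_binary(z, labels, 1, sig)
        # independent brute force: per-sample python-loop scores
        scores = np.array([
            sum(w * z.values[z.gene_ids.index(g), j]
                for g, w in zip(model.gene_ids, model.weights))
            for j in range(z.n_samples)
        ])
        assert model.score_mean_in == pytest.approx(scores[labels == 1].mean(), abs=1e-10)
        assert model.score_mean_out == pytest.approx(scores[labels == 2].mean(), abs=1e-10)
        ss = ((scores[labels == 1] - scores[labels == 1].mean()) ** 2).sum() + \
             ((scores[labels == 2] - scores[labels == 2].mean()) ** 2).sum()
        assert model.score_sd == pytest.approx(np.sqrt(ss / (len(labels) - 2)), abs=1e-10)

    def test_separable_classes_give_confident_training_posteriors(self):
        z, labels = self._cohort_k2()
        sig = build_signature(ovr_t_test(z, labels, 1), subtype=1, max_genes=30)
        model = bccp.train_binary(z, labels, 1, sig)
        assignments = bccp.predict([model], z)
        probs = np.array([a.probabilities[0] for a in assignments])
        assert probs[labels == 1].min() > 0.95
        assert probs[labels == 2].max() < 0.05

    def test_permuted_labels_give_small_class_separation(self):
        z, labels = self._cohort_k2()
        rng = np.random.default_rng(0)
        sep = []
        for _ in range(5):
            perm = rng.permutation(labels)
            stats = ovr_t_test(z, perm, 1)
            with np.errstate(all="ignore"):
                s = build_signature(stats, subtype=1, p_threshold=0.5, max_genes=30)
            model = bccp.train_binary(z, perm, 1, s)
            sep.append(abs(model.score_mean_in - model.score_mean_out) / model.score_sd)
        true_sig = build_signature(ovr_t_test(z, labels, 1), subtype=1, max_genes=30)
        true_model = bccp.train_binary(z, labels, 1, true_sig)
        true_sep = abs(true_model.score_mean_in - true_model.score_mean_out) / true_model.score_sd
        assert max(sep) < true_sep / 3


class TestPredict:
    def test_training_cohort_prediction_is_consistent(self, small_cohort):
        _, _, mrna, labels = small_cohort
        z = io.zscore_genes(mrna)
        sigs = build_all_signatures(z, labels, max_genes=50)
        models = bccp.train_multiclass(z, labels, sigs)
        a1 = bccp.predict(models, z)
        a2 = bccp.predict(models, z)
        assert all(x.hard_label == y.hard_label for x, y in zip(a1, a2))
        acc = np.mean([a.hard_label == l for a, l in zip(a1, labels)])
        assert acc >= 0.95

    def test_one_vs_rest_posteriors_need_not_sum_to_one(self):
        # weak signal keeps the posteriors soft, exposing the absence of
        # cross-subtype renormalization
        cfg = CohortConfig(n_samples=90, n_lnc_genes=100, n_mrna_genes=300,
                           k_subtypes=3, n_marker_genes_per_subtype=30,
                           effect_size=1.0, seed=31)
        _, mrna, labels = generate_training_cohort(cfg)
        z = io.zscore_genes(mrna)
        sigs = build_all_signatures(z, labels, p_threshold=0.05, max_genes=50)
        models = bccp.train_multiclass(z, labels, sigs)
        sums = np.array([a.probabilities.sum() for a in bccp.predict(models, z)])
        assert (np.abs(sums - 1.0) > 0.05).any()

    def test_batch_shifted_cohort_recovered_after_zscoring(self, small_cohort):
        _, _, mrna, labels = small_cohort
        z = io.zscore_genes(mrna)
        sigs = build_all_signatures(mrna, labels, max_genes=50)
        models = bccp.train_multiclass(z, labels, sigs)
        shifted = apply_batch_shift(mrna, 2.0, seed=99)
        assignments = bccp.predict(models, io.zscore_genes(shifted))
        acc = np.mean([a.hard_label == l for a, l in zip(assignments, labels)])
        assert acc >= 0.9

    def test_hard_label_is_argmax_with_smallest_index_tie(self):
        a = SubtypeAssignment("s", np.array([0.2, 0.8, 0.8]))
        assert a.hard_label == 2

    def test_prediction_invariant_to_sample_order(self, small_cohort):
        _, _, mrna, labels = small_cohort
        z = io.zscore_genes(mrna)
        sigs = build_all_signatures(z, labels, max_genes=50)
        models = bccp.train_multiclass(z, labels, sigs)
        ref = {a.sample_id: a.hard_label for a in bccp.predict(models, z)}
        perm = np.random.default_rng(3).permutation(z.n_samples)
        shuffled = z.subset_samples([z.sample_ids[j] for j in perm])
        out = {a.sample_id: a.hard_label for a in bccp.predict(models, shuffled)}
        assert ref == out

    def test_coverage_error_names_model_and_fraction(self, small_cohort):
        _, _, mrna, labels = small_cohort
        z = io.zscore_genes(mrna)
        sigs = build_all_signatures(z, labels, max_genes=50)
        models = bccp.train_multiclass(z, labels, sigs)
        tiny = z.subset_genes(models[0].gene_ids[:10])  # 20% coverage
        with pytest.raises(ValueError, match=rf"subtype {models[0].subtype}.*%"):
            bccp.predict(models, tiny)


class TestAucRank:
    def test_matches_pair_counting_on_toys_with_ties(self, rng):
        for _ in range(20):
            scores = rng.integers(0, 5, size=10).astype(float)  # ties guaranteed
            truth = rng.random(10) < 0.4
            if truth.all() or not truth.any():
                continue
            pos, neg = scores[truth], scores[~truth]
            pairs = [(1.0 if p > q else 0.5 if p == q else 0.0)
                     for p in pos for q in neg]
            assert bccp.auc_rank(scores, truth) == pytest.approx(np.mean(pairs))

    def test_matches_sklearn(self, rng):
        scores = rng.normal(size=50)
        truth = rng.random(50) < 0.3
        assert bccp.auc_rank(scores, truth) == pytest.approx(
            roc_auc_score(truth, scores))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        truth = rng.random(40) < 0.5
        a = bccp.auc_rank(scores, truth)
        b = bccp.auc_rank(1 / (1 + np.exp(-3 * scores)), truth)
        assert a == pytest.approx(b)


class TestLoocv:
    def test_fast_loocv_equals_naive_rederivation(self):
        cfg = CohortConfig(n_samples=30, n_lnc_genes=40, n_mrna_genes=80,
                           k_subtypes=2, n_marker_genes_per_subtype=20, seed=17)
        _, mrna, labels = generate_training_cohort(cfg)
        _, fast_post = bccp.loocv_auc(mrna, labels, max_genes=15,
                                      return_posteriors=True)
        for i, sid in enumerate(mrna.sample_ids):
            keep = [s for s in mrna.sample_ids if s != sid]
            fold = mrna.subset_samples(keep)
            fold_labels = np.delete(labels, i)
            fold_z = io.zscore_genes(fold)
            mu = fold.values.mean(axis=1)
            sd = fold.values.std(axis=1, ddof=1)
            for c, s in enumerate((1, 2)):
                sig = build_signature(ovr_t_test(fold, fold_labels, s),
                                      subtype=s, max_genes=15)
                model = bccp.train_binary(fold_z, fold_labels, s, sig)
                idx = [fold.gene_ids.index(g) for g in model.gene_ids]
                profile = {g: (mrna.values[mrna.gene_ids.index(g), i] - mu[j]) / sd[j]
                           for g, j in zip(model.gene_ids, idx)}
                expected = bccp.posterior(model, bccp.compound_score(model, profile))
                assert fast_post.iloc[i, c] == pytest.approx(expected, abs=1e-9)

    def test_perfect_and_null_rankings(self):
        truth = np.array([True] * 5 + [False] * 5)
        assert bccp.auc_rank(np.where(truth, 1.0, 0.0), truth) == 1.0
        assert bccp.auc_rank(np.full(10, 0.5), truth) == 0.5

    def test_loocv_auc_high_on_separated_cohort(self, small_cohort):
        _, _, mrna, labels = small_cohort
        table = bccp.loocv_auc(mrna, labels, max_genes=50)
        assert table["auc"].min() >= 0.95

    def test_small_subtype_rejected(self):
        cfg = CohortConfig(n_samples=10, n_lnc_genes=30, n_mrna_genes=30,
                           k_subtypes=2, subtype_proportions=[0.9, 0.1],
                           n_marker_genes_per_subtype=10, seed=1)
        _, mrna, _ = generate_training_cohort(cfg)
        labels = np.array([1] * 8 + [2] * 2)
        with pytest.raises(ValueError, match=">=3"):
            bccp.loocv_auc(mrna, labels)


class TestSerialization:
    def test_model_json_round_trip(self, tmp_path, small_cohort):
        _, _, mrna, labels = small_cohort
        z = io.zscore_genes(mrna)
        sigs = build_all_signatures(z, labels, max_genes=20)
        models = bccp.train_multiclass(z, labels, sigs)
        bccp.models_to_json(models, tmp_path / "m.json")
        back = bccp.models_from_json(tmp_path / "m.json")
        for a, b in zip(models, back):
            assert a.subtype == b.subtype and a.gene_ids == b.gene_ids
            np.testing.assert_allclose(a.weights, b.weights)
            assert a.score_sd == b.score_sd
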