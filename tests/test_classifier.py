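import numpy as np
import pytest

from irhisto.classifier import (ClassModel, ClassifierConfig, MetricScore,
                                classify, fit, posterior, score_metrics,
                                select_metrics)
from irhisto.metrics import FeatureImage, compute_features, default_metric_library
from irhisto.preprocess import PixelMask, preprocess_cube
from irhisto.synthetic_data import PhantomSpec, synth_phantom

from oracles import o_rank_auc


def feature_image(values, names=None):
    """1 x n feature raster from an (n, m) matrix, all pixels kept."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim == 1:
        values = values[:, None]
    names = names or [f"m{j}" for j in range(values.shape[1])]
    return FeatureImage(values[None, :, :], names, PixelMask(np.ones((1, values.shape[0]), bool)))


def truth_row(labels):
    return np.asarray(labels)[None, :]


def hand_model(params, weights=None, threshold=0.5, likelihood="gaussian"):
    names = sorted(next(iter(params.values())).keys())
    weights = weights or {n: 1.0 for n in names}
    return ClassModel(
        classes=(1, 2, 3, 4, 5),
        priors={c: 0.2 for c in range(1, 6)},
        metric_names=names,
        weights=weights,
        likelihood=likelihood,
        params=params,
        posterior_threshold=threshold,
    )


class TestScoreMetrics:
    def make_features(self, rng, shift):
        """Two informative classes (codes 1, 2) + filler classes 3..5."""
        n = 60
        vals, labels = [], []
        for c in range(1, 6):
            loc = shift if c == 2 else 0.0
            vals.append(rng.normal(loc, 1.0, n))
            labels += [c] * n
        return feature_image(np.concatenate(vals)), truth_row(labels)

    def test_perfect_separation(self):
        vals = np.concatenate([np.zeros(30), np.ones(30) * 10])
        feats = feature_image(vals)
        truth = truth_row([1] * 30 + [2] * 30)
        with pytest.warns(UserWarning):  # classes 3..5 absent is fine here
            scores = score_metrics(feats, truth)
        s = {x.class_code: x for x in scores}
        assert s[2].auc == 1.0 and s[2].min_error == 0.0

    def test_null_distributions_auc_half(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, 1000)
        feats = feature_image(vals)
        truth = truth_row([1] * 500 + [2] * 500)
        with pytest.warns(UserWarning):
            scores = score_metrics(feats, truth)
        for s in scores:
            assert s.auc == pytest.approx(0.5, abs=0.05)
            assert s.auc >= 0.5  # orientation applied

    def test_auc_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(9)
        pos = rng.normal(1.0, 1.0, 8)
        neg = rng.normal(0.0, 1.0, 12)
        feats = feature_image(np.concatenate([pos, neg]))
        truth = truth_row([1] * 8 + [2] * 12)
        with pytest.warns(UserWarning):
            scores = score_metrics(feats, truth, min_class_pixels=5)
        got = {s.class_code: s.auc for s in scores}
        want = o_rank_auc(list(pos), list(neg))
        want = max(want, 1 - want)
        assert got[1] == pytest.approx(want, abs=1e-12)
        assert got[2] == pytest.approx(want, abs=1e-12)

    def test_needs_two_classes(self):
        feats = feature_image(np.arange(40.0))
        with pytest.raises(ValueError):
            score_metrics(feats, truth_row([1] * 40))


class TestSelectMetrics:
    def scores_for(self, entries):
        return [MetricScore(n, c, a, e) for n, c, a, e in entries]

    def test_topk_union(self):
        scores = self.scores_for(
            [(f"m{c}", c, 0.9, 0.1) for c in range(1, 6)]
            + [(f"x{c}", c, 0.6, 0.3) for c in range(1, 6)])
        assert select_metrics(scores, 1) == [f"m{c}" for c in range(1, 6)]

    def test_ties_break_deterministically(self):
        scores = self.scores_for(
            [("b", 1, 0.8, 0.2), ("a", 1, 0.8, 0.2), ("c", 1, 0.8, 0.1)]
            + [("a", 2, 0.7, 0.2)])
        # lower min_error first, then name order; stable across runs
        assert select_metrics(scores, 2) == ["c", "a"]
        assert select_metrics(scores, 2) == select_metrics(scores, 2)

    def test_k_capped_with_warning(self):
        scores = self.scores_for([("a", 1, 0.8, 0.1), ("a", 2, 0.6, 0.3)])
        with pytest.warns(UserWarning):
            assert select_metrics(scores, 5) == ["a"]


class TestFit:
    def make_training(self, rng, n=500):
        means = {1: 0.0, 2: 4.0, 3: 8.0, 4: 12.0, 5: 16.0}
        sds = {c: 1.0 for c in means}
        vals = np.concatenate([rng.normal(means[c], sds[c], n) for c in means])
        labels = sum(([c] * n for c in means), [])
        return feature_image(vals), truth_row(labels), means, sds

    def test_gaussian_parameter_recovery(self):
        rng = np.random.default_rng(12)
        feats, truth, means, sds = self.make_training(rng, n=500)
        model = fit(feats, truth)
        for c in range(1, 6):
            p = model.params[c]["m0"]
            n = 500
            assert p["mean"] == pytest.approx(means[c], abs=3 * sds[c] / np.sqrt(n))
            assert p["sd"] == pytest.approx(sds[c], abs=3 * sds[c] / np.sqrt(2 * n))

    def test_duplicated_training_set_identical_model(self):
        rng = np.random.default_rng(13)
        feats, truth, *_ = self.make_training(rng, n=50)
        doubled = feature_image(np.concatenate([feats.values[0, :, 0]] * 2))
        truth2 = np.concatenate([truth, truth], axis=1)
        m1 = fit(doubled, truth2)
        m2 = fit(doubled, truth2)
        assert m1.to_json() == m2.to_json()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(14)
        feats, truth, *_ = self.make_training(rng, n=60)
        perm = rng.permutation(truth.shape[1])
        m1 = fit(feats, truth)
        m2 = fit(feature_image(feats.values[0, perm, 0]), truth[:, perm])
        assert m1.to_json() == m2.to_json()

    def test_serialization_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(15)
        feats, truth, *_ = self.make_training(rng, n=40)
        model = fit(feats, truth)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ClassModel.from_json(path)
        assert back.to_json() == model.to_json()
        assert back.params == model.params

    def test_missing_class_named_in_error(self):
        feats = feature_image(np.arange(80.0))
        truth = truth_row([1] * 20 + [2] * 20 + [3] * 20 + [4] * 20)
        with pytest.raises(ValueError, match="Lymphocytes"):
            fit(feats, truth)

    def test_histogram_likelihood_trains_and_applies(self):
        rng = np.random.default_rng(16)
        feats, truth, *_ = self.make_training(rng, n=200)
        model = fit(feats, truth, ClassifierConfig(likelihood="histogram"))
        post, defined = posterior(feats, model)
        pred = classify(post, feats.mask, model, defined)
        acc = (pred[0] == truth[0]).mean()
        assert acc > 0.9


class TestPosterior:
    def test_symmetric_likelihoods_give_uniform_posterior(self):
        params = {c: {"m0": {"mean": 0.0, "sd": 1.0}} for c in range(1, 6)}
        model = hand_model(params)
        feats = feature_image(np.array([0.3]))
        post, defined = posterior(feats, model)
        np.testing.assert_allclose(post[0, 0], 0.2, rtol=1e-12)
        assert defined.all()

    def test_posteriors_sum_to_one(self, small_features):
        feats, truth = small_features
        model = fit(feats, truth.labels)
        post, defined = posterior(feats, model)
        sums = post[defined].sum(axis=-1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_hand_computed_bayes_fusion(self):
        """Two metrics, hand-specified Gaussians: fusion must match the
        longhand product of densities (three informative classes)."""
        params = {
            1: {"a": {"mean": 0.0, "sd": 1.0}, "b": {"mean": 0.0, "sd": 2.0}},
            2: {"a": {"mean": 2.0, "sd": 1.0}, "b": {"mean": 1.0, "sd": 2.0}},
            3: {"a": {"mean": 4.0, "sd": 1.0}, "b": {"mean": 2.0, "sd": 2.0}},
            4: {"a": {"mean": 40.0, "sd": 1.0}, "b": {"mean": 40.0, "sd": 2.0}},
            5: {"a": {"mean": -40.0, "sd": 1.0}, "b": {"mean": -40.0, "sd": 2.0}},
        }
        w = {"a": 1.0, "b": 0.5}
        model = hand_model(params, weights=w)
        x_a, x_b = 1.1, 0.4
        feats = feature_image(np.array([[x_a, x_b]]), names=["a", "b"])
        post, _ = posterior(feats, model)

        def dens(x, mu, sd):
            return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))

        raw = {c: 0.2 * dens(x_a, params[c]["a"]["mean"], 1.0) ** w["a"]
                  * dens(x_b, params[c]["b"]["mean"], 2.0) ** w["b"]
               for c in range(1, 6)}
        total = sum(raw.values())
        for k, c in enumerate(range(1, 6)):
            assert post[0, 0, k] == pytest.approx(raw[c] / total, rel=1e-9)

    def test_nan_metric_dropped_from_product(self):
        params = {
            c: {"a": {"mean": float(c), "sd": 0.5}, "b": {"mean": 0.0, "sd": 1.0}}
            for c in range(1, 6)
        }
        model = hand_model(params)
        feats = feature_image(np.array([[2.0, np.nan]]), names=["a", "b"])
        post, defined = posterior(feats, model)
        assert defined[0, 0]
        assert np.argmax(post[0, 0]) == 1  # class 2 by metric "a" alone

    def test_all_nan_pixel_undefined(self):
        params = {c: {"a": {"mean": 0.0, "sd": 1.0}} for c in range(1, 6)}
        model = hand_model(params)
        feats = feature_image(np.array([[np.nan]]), names=["a"])
        post, defined = posterior(feats, model)
        assert not defined[0, 0]
        pred = classify(post, feats.mask, model, defined)
        assert pred[0, 0] == 0


class TestClassify:
    def setup_method(self):
        params = {c: {"a": {"mean": float(c), "sd": 0.5}} for c in range(1, 6)}
        self.model = hand_model(params)

    def test_confident_pixel_assigned(self):
        post = np.zeros((1, 1, 5))
        post[0, 0] = [0.9, 0.025, 0.025, 0.025, 0.025]
        pred = classify(post, PixelMask(np.ones((1, 1), bool)), self.model)
        assert pred[0, 0] == 1

    def test_low_confidence_unclassified(self):
        post = np.full((1, 1, 5), 0.2)
        post[0, 0] = [0.3, 0.25, 0.25, 0.1, 0.1]
        pred = classify(post, PixelMask(np.ones((1, 1), bool)), self.model)
        assert pred[0, 0] == 0

    def test_zero_threshold_classifies_everything(self, small_features):
        feats, truth = small_features
        model = fit(feats, truth.labels, ClassifierConfig(posterior_threshold=0.0))
        post, defined = posterior(feats, model)
        pred = classify(post, feats.mask, model, defined)
        assert ((pred == 0) & feats.mask.keep & defined).sum() == 0

    def test_lowering_threshold_monotone_in_classified_count(self, small_features):
        feats, truth = small_features
        counts = []
        for thr in (0.9, 0.5, 0.1, 0.0):
            model = fit(feats, truth.labels, ClassifierConfig(posterior_threshold=thr))
            post, defined = posterior(feats, model)
            pred = classify(post, feats.mask, model, defined)
            counts.append(int((pred > 0).sum()))
        assert counts == sorted(counts)

    def test_argmax_tie_resolves_to_lowest_code(self):
        post = np.zeros((1, 1, 5))
        post[0, 0] = [0.4, 0.4, 0.1, 0.05, 0.05]
        model = self.model
        pred = classify(post, PixelMask(np.ones((1, 1), bool)),
                        hand_model({c: {"a": {"mean": 0.0, "sd": 1.0}} for c in range(1, 6)},
                                   threshold=0.3))
        assert pred[0, 0] == 1


class TestEndToEnd:
    def test_noiseless_unmixed_phantom_is_perfect(self, metric_defs):
        spec = PhantomSpec(rows=48, cols=48, seed=4, snr=np.inf,
                           boundary_mixing=False, lymph_focus_radius=3)
        cube, truth = synth_phantom(spec)
        processed, mask, _ = preprocess_cube(cube)
        feats = compute_features(processed, mask, metric_defs)
        model = fit(feats, truth.labels)
        post, defined = posterior(feats, model)
        pred = classify(post, mask, model, defined)
        labeled = mask.keep & (truth.labels > 0)
        assert (pred[labeled] == truth.labels[labeled]).all()

    def test_snr500_pure_pixel_accuracy(self, metric_defs):
        """At the acquisition SNR of 500:1, held-out pure (unmixed) pixels
        classify at >= 99% accuracy."""
        def make(seed):
            cube, truth = synth_phantom(PhantomSpec(rows=100, cols=100, seed=seed))
            processed, mask, _ = preprocess_cube(cube)
            return compute_features(processed, mask, metric_defs), truth
        f_tr, t_tr = make(31)
        f_va, t_va = make(32)
        model = fit(f_tr, t_tr.labels)
        post, defined = posterior(f_va, model)
        pred = classify(post, f_va.mask, model, defined)
        pure = f_va.mask.keep & (t_va.labels > 0) & (t_va.mixing_fraction == 1.0)
        acc = (pred[pure] == t_va.labels[pure]).mean()
        assert acc >= 0.99
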