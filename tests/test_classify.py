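import numpy as np
import pytest

from hbcikit.classify import (
    EstimationError,
    MetaModel,
    PredictionError,
    SLDAModel,
    decision_values,
    fit_meta,
    fit_slda,
    ledoit_wolf_lambda,
    predict_meta,
    predict_slda,
)
from hbcikit.features import FeatureMatrix


def _fm(values, labels):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(values, np.asarray(labels),
                         np.zeros(len(labels), dtype=int),
                         tuple(f"f{i}" for i in range(values.shape[1])))


def _gaussian_pair(rng, n_per, D, delta, scale=1.0):
    a = rng.standard_normal((n_per, D)) * scale + delta
    b = rng.standard_normal((n_per, D)) * scale - delta
    values = np.vstack([a, b])
    labels = np.array(["A"] * n_per + ["B"] * n_per)
    return _fm(values, labels)


class TestLedoitWolf:
    def test_consistency_small_lambda_at_large_n(self):
        """n >> D with a non-spherical truth: almost no shrinkage.

        Consistency of the sample covariance shows only when the truth
        differs from the scaled-identity target; for a spherical truth the
        target coincides with the truth and the optimal intensity is large
        no matter how big n is.
        """
        rng = np.random.default_rng(0)
        X = rng.standard_normal((2000, 5)) @ np.diag([3.0, 2.0, 1.0, 0.5, 0.2])
        lam, _ = ledoit_wolf_lambda(X - X.mean(axis=0))
        assert 0.0 <= lam < 0.1
        # spherical truth: the target is correct, so intensity stays high
        lam_sph, nu = ledoit_wolf_lambda(
            rng.standard_normal((2000, 5)))
        assert lam_sph > 0.5
        assert nu == pytest.approx(1.0, rel=0.1)

    def test_high_dimension_lambda_near_one(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((4, 500))  # zero-mean by construction
        lam, nu = ledoit_wolf_lambda(X)
        assert lam > 0.9
        S = X.T @ X / X.shape[0]
        shrunk = (1 - lam) * S + lam * nu * np.eye(500)
        assert np.linalg.cond(shrunk) < 1e4

    def test_identical_samples_degenerate(self):
        X = np.zeros((5, 3))
        lam, nu = ledoit_wolf_lambda(X)
        assert lam == 1.0 and nu == 0.0

    def test_too_few_samples(self):
        with pytest.raises(EstimationError):
            ledoit_wolf_lambda(np.zeros((1, 3)))

    def test_matches_sklearn_oracle_up_to_convention(self):
        """Independent oracle: sklearn's Ledoit-Wolf on centered data.

        Our intensity uses the unbiased finite-sample variance scaling, which
        exceeds the original estimator by exactly n/(n-1) before clipping.
        """
        from sklearn.covariance import ledoit_wolf_shrinkage

        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 8)) @ np.diag([3, 2, 1, 1, 1, 1, 0.5, 0.2])
        Xc = X - X.mean(axis=0)
        n = Xc.shape[0]
        lam, _ = ledoit_wolf_lambda(Xc)
        lam_sk = float(ledoit_wolf_shrinkage(Xc, assume_centered=True))
        assert lam == pytest.approx(n / (n - 1) * lam_sk, abs=1e-10)

    def test_shrinkage_reduces_frobenius_risk(self):
        """Average Frobenius error of the shrunk estimate <= sample cov."""
        rng = np.random.default_rng(3)
        D, n = 20, 15
        err_shrunk, err_sample = [], []
        for _ in range(100):
            X = rng.standard_normal((n, D))
            Xc = X - X.mean(axis=0)
            S = Xc.T @ Xc / n
            lam, nu = ledoit_wolf_lambda(Xc)
            shrunk = (1 - lam) * S + lam * nu * np.eye(D)
            err_shrunk.append(np.sum((shrunk - np.eye(D)) ** 2))
            err_sample.append(np.sum((S - np.eye(D)) ** 2))
        assert np.mean(err_shrunk) <= np.mean(err_sample)


class TestSLDA:
    def test_spherical_classes_weight_parallel_to_mean_difference(self):
        """Spherical classes: the shrunk metric is ~ I, so w || mu1 - mu2."""
        rng = np.random.default_rng(4)
        fm = _gaussian_pair(rng, 1000, 6, delta=np.array([2, 0, 0, 0, 0, 0]))
        model = fit_slda(fm, ("A", "B"))
        mu_diff = fm.values[fm.labels == "A"].mean(0) - \
            fm.values[fm.labels == "B"].mean(0)
        cos = model.w @ mu_diff / (np.linalg.norm(model.w) * np.linalg.norm(mu_diff))
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 1.0

    def test_lambda_one_is_nearest_mean_rule(self):
        rng = np.random.default_rng(5)
        fm = _gaussian_pair(rng, 20, 4, delta=1.0)
        model = fit_slda(fm, ("A", "B"), shrinkage=1.0)
        mu_a = fm.values[fm.labels == "A"].mean(0)
        mu_b = fm.values[fm.labels == "B"].mean(0)
        x = rng.standard_normal((10, 4))
        _, labels = predict_slda(model, x)
        d_a = np.linalg.norm(x - mu_a, axis=1)
        d_b = np.linalg.norm(x - mu_b, axis=1)
        np.testing.assert_array_equal(labels, np.where(d_a < d_b, "A", "B"))

    def test_midpoint_on_boundary(self):
        rng = np.random.default_rng(6)
        fm = _gaussian_pair(rng, 30, 5, delta=1.0)
        model = fit_slda(fm, ("A", "B"))
        mu_a = fm.values[fm.labels == "A"].mean(0)
        mu_b = fm.values[fm.labels == "B"].mean(0)
        f = decision_values(model, (mu_a + mu_b) / 2)
        assert f[0] == pytest.approx(0.0, abs=1e-10)

    def test_zero_shrinkage_matches_classic_lda(self):
        """lambda=0 reproduces the plain pooled-covariance LDA weights."""
        rng = np.random.default_rng(7)
        fm = _gaussian_pair(rng, 200, 4, delta=np.array([1, 0.5, 0, 0]))
        model = fit_slda(fm, ("A", "B"), shrinkage=0.0)
        masks = [fm.labels == c for c in ("A", "B")]
        mus = [fm.values[m].mean(0) for m in masks]
        centered = np.vstack([fm.values[m] - mu for m, mu in zip(masks, mus)])
        S = centered.T @ centered / (centered.shape[0] - 2)  # pooled, 2 classes
        w_ref = np.linalg.solve(S, mus[0] - mus[1])
        np.testing.assert_allclose(model.w, w_ref, atol=1e-8)

    def test_missing_class_rejected(self):
        fm = _fm(np.zeros((4, 2)), ["A", "A", "A", "A"])
        with pytest.raises(EstimationError):
            fit_slda(fm, ("A", "B"))

    def test_tie_resolved_to_second_class(self):
        model = SLDAModel(w=np.array([1.0]), b=0.0, lam=0.0, nu=1.0,
                          class_pair=("A", "B"), feature_names=("f0",))
        _, labels = predict_slda(model, np.array([[0.0]]))
        assert labels[0] == "B"

    def test_negation_flips_all_labels(self):
        rng = np.random.default_rng(8)
        fm = _gaussian_pair(rng, 25, 3, delta=0.5)
        model = fit_slda(fm, ("A", "B"))
        flipped = SLDAModel(w=-model.w, b=-model.b, lam=model.lam, nu=model.nu,
                            class_pair=model.class_pair,
                            feature_names=model.feature_names)
        x = rng.standard_normal((50, 3))
        _, l1 = predict_slda(model, x)
        _, l2 = predict_slda(flipped, x)
        assert np.all((l1 == "A") == (l2 == "B"))

    def test_decision_affine_in_input(self):
        rng = np.random.default_rng(9)
        fm = _gaussian_pair(rng, 25, 3, delta=0.5)
        model = fit_slda(fm, ("A", "B"))
        x = rng.standard_normal((5, 3))
        f2 = decision_values(model, 2.0 * x)
        f1 = decision_values(model, x)
        np.testing.assert_allclose(f2, 2 * (f1 + model.b) - model.b, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(10)
        model = fit_slda(_gaussian_pair(rng, 10, 3, 1.0), ("A", "B"))
        with pytest.raises(PredictionError):
            decision_values(model, np.zeros((2, 5)))


def _modal_features(rng, n_per, informative, noise_dims=6, sep=2.0):
    """Three 'modalities'; only those in `informative` carry the labels."""
    labels = np.array(["A"] * n_per + ["B"] * n_per)
    sign = np.where(labels == "A", 1.0, -1.0)
    out = {}
    for mod in ("EEG", "HbR", "HbO"):
        base = rng.standard_normal((2 * n_per, noise_dims))
        if mod in informative:
            base[:, 0] += sign * sep
        out[mod] = _fm(base, labels)
    return out, labels


class TestMeta:
    def test_input_dimension_matches_combination(self):
        rng = np.random.default_rng(11)
        feats, _ = _modal_features(rng, 20, informative=("EEG",))
        m2 = fit_meta(feats, ("A", "B"), combination=("HbR", "HbO"))
        m3 = fit_meta(feats, ("A", "B"), combination=("EEG", "HbR", "HbO"))
        assert m2.meta.w.size == 2
        assert m3.meta.w.size == 3

    def test_single_informative_modality_not_drowned(self):
        """Hybrid accuracy within 3 points of the informative modality."""
        rng = np.random.default_rng(12)
        acc_uni, acc_hybrid = [], []
        for _ in range(10):
            train, _ = _modal_features(rng, 30, informative=("EEG",))
            test, labels = _modal_features(rng, 30, informative=("EEG",))
            base = fit_slda(train["EEG"], ("A", "B"))
            acc_uni.append(np.mean(predict_slda(base, test["EEG"])[1] == labels))
            meta = fit_meta(train, ("A", "B"))
            acc_hybrid.append(np.mean(predict_meta(meta, test)[1] == labels))
        assert np.mean(acc_hybrid) >= np.mean(acc_uni) - 0.03

    def test_fusion_of_independent_information(self):
        """Hybrid >= max(unimodal) - 2 points when info is complementary."""
        rng = np.random.default_rng(13)
        acc = {"EEG": [], "NIRS": [], "hybrid": []}
        for _ in range(10):
            train, _ = _modal_features(rng, 30, informative=("EEG", "HbR", "HbO"),
                                       sep=1.0)
            test, labels = _modal_features(rng, 30,
                                           informative=("EEG", "HbR", "HbO"),
                                           sep=1.0)
            eeg = fit_slda(train["EEG"], ("A", "B"))
            acc["EEG"].append(np.mean(predict_slda(eeg, test["EEG"])[1] == labels))
            nirs = fit_meta(train, ("A", "B"), combination=("HbR", "HbO"))
            acc["NIRS"].append(np.mean(predict_meta(nirs, test)[1] == labels))
            hyb = fit_meta(train, ("A", "B"))
            acc["hybrid"].append(np.mean(predict_meta(hyb, test)[1] == labels))
        best_uni = max(np.mean(acc["EEG"]), np.mean(acc["NIRS"]))
        assert np.mean(acc["hybrid"]) >= best_uni - 0.02

    def test_duplicated_modality_handled_by_shrinkage(self):
        rng = np.random.default_rng(14)
        feats, _ = _modal_features(rng, 15, informative=("EEG",))
        feats["HbR"] = feats["EEG"]
        feats["HbO"] = feats["EEG"]
        meta = fit_meta(feats, ("A", "B"))
        assert np.all(np.isfinite(meta.meta.w))

    def test_label_flip_flips_predictions(self):
        rng = np.random.default_rng(15)
        train, _ = _modal_features(rng, 20, informative=("EEG", "HbR", "HbO"))
        test, _ = _modal_features(rng, 20, informative=("EEG", "HbR", "HbO"))
        meta = fit_meta(train, ("A", "B"), seed=0)
        flipped_train = {
            mod: _fm(fm.values, np.where(fm.labels == "A", "B", "A"))
            for mod, fm in train.items()}
        meta_f = fit_meta(flipped_train, ("A", "B"), seed=0)
        _, l1 = predict_meta(meta, test)
        _, l2 = predict_meta(meta_f, test)
        assert np.mean(l1 != l2) > 0.9

    def test_identical_bases_monotone_meta(self):
        rng = np.random.default_rng(16)
        feats, _ = _modal_features(rng, 25, informative=("EEG", "HbR", "HbO"))
        feats["HbR"] = feats["EEG"]
        feats["HbO"] = feats["EEG"]
        meta = fit_meta(feats, ("A", "B"))
        test, _ = _modal_features(rng, 25, informative=("EEG",))
        test["HbR"] = test["EEG"]
        test["HbO"] = test["EEG"]
        f_meta, _ = predict_meta(meta, test)
        f_base = decision_values(meta.base["EEG"], test["EEG"].values)
        r = np.corrcoef(np.argsort(np.argsort(f_meta)),
                        np.argsort(np.argsort(f_base)))[0, 1]
        assert abs(r) > 0.99

    def test_too_few_trials_reduces_folds_with_warning(self):
        rng = np.random.default_rng(17)
        feats, _ = _modal_features(rng, 3, informative=("EEG",))
        with pytest.warns(RuntimeWarning, match="reducing inner folds"):
            meta = fit_meta(feats, ("A", "B"), inner_folds=5)
        assert meta.inner_folds == 3

    def test_missing_modality_rejected(self):
        rng = np.random.default_rng(18)
        feats, _ = _modal_features(rng, 10, informative=("EEG",))
        meta = fit_meta(feats, ("A", "B"))
        del feats["HbO"]
        with pytest.raises(PredictionError):
            predict_meta(meta, feats)
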