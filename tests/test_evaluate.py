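import numpy as np
import pandas as pd
import pytest

from hbcikit import evaluate as ev
from hbcikit.preprocess import ParameterError

from conftest import make_epochset


class TestITR:
    def test_perfect_accuracy(self):
        res = ev.itr(1.0, 2, 5.0)
        assert res.m == 12.0
        assert res.bits_per_min == pytest.approx(12.0, abs=1e-12)

    def test_chance_is_zero(self):
        for trial_len in (1.0, 5.0, 10.0):
            assert ev.itr(0.5, 2, trial_len).bits_per_min == pytest.approx(
                0.0, abs=1e-12)

    def test_printed_value_at_ninety_percent(self):
        # 12 * (1 + 0.9 log2 0.9 + 0.1 log2 0.1) = 6.3716...
        assert ev.itr(0.900, 2, 5.0).bits_per_min == pytest.approx(6.372, abs=5e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ev.itr(0.0, 2, 5.0)
        with pytest.raises(ValueError):
            ev.itr(1.2, 2, 5.0)
        with pytest.raises(ValueError):
            ev.itr(0.8, 1, 5.0)

    def test_convex_in_accuracy(self):
        """ITR is convex on (0.5, 1]; Jensen: ITR(mean P) <= mean ITR."""
        ps = np.linspace(0.55, 0.999, 100)
        vals = np.array([ev.itr(p, 2, 5.0).bits_per_min for p in ps])
        second_diff = np.diff(vals, 2)
        assert np.all(second_diff > -1e-9)
        subj = np.array([0.7, 0.8, 0.95])
        mean_itr = np.mean([ev.itr(p).bits_per_min for p in subj])
        assert ev.itr(subj.mean()).bits_per_min <= mean_itr + 1e-12


class TestChanceLevel:
    def test_sixty_trials(self):
        # smallest k with P(X >= k | n=60, p=.5) < .05 is 37
        assert ev.chance_level(60, 0.05) == pytest.approx(37 / 60)

    def test_exact_binomial_oracle(self):
        from scipy.stats import binom

        for n in (10, 30, 60, 200):
            thr = ev.chance_level(n, 0.05)
            k = int(round(thr * n))
            assert binom.sf(k - 1, n, 0.5) < 0.05
            assert binom.sf(k - 2, n, 0.5) >= 0.05

    def test_single_trial_saturates(self):
        assert ev.chance_level(1, 0.05) == 1.0

    def test_alpha_one_passes_everything(self):
        assert ev.chance_level(60, 1.0) == 0.0

    def test_non_increasing_in_n(self):
        thresholds = [ev.chance_level(n, 0.05) for n in (20, 40, 60, 120, 240)]
        assert all(a >= b for a, b in zip(thresholds, thresholds[1:]))


class TestStats:
    def test_bh_step_up_hand_example(self):
        adj = ev.benjamini_hochberg(np.array([0.01, 0.02, 0.04]))
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.04], atol=1e-12)

    def test_bh_monotone_and_dominating(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        adj = ev.benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_identical_columns_degenerate(self):
        col = np.array([0.7, 0.8, 0.75, 0.9, 0.65])
        table = pd.DataFrame({"EEG": col, "NIRS": col, "hBCI": col})
        with pytest.warns(RuntimeWarning):
            rep = ev.compare_modalities(table)
        assert rep.friedman_statistic == 0.0
        assert rep.friedman_p == 1.0

    def test_strict_ordering_significant(self):
        """10 subjects, strictly ordered conditions: Friedman stat = 20."""
        rng = np.random.default_rng(1)
        base = rng.uniform(0.5, 0.6, 10)
        table = pd.DataFrame({
            "EEG": base, "NIRS": base + 0.15, "hBCI": base + 0.3})
        rep = ev.compare_modalities(table)
        # every row ranks (1,2,3): chi2_F = 12n/(k(k+1)) * sum (Rbar - 2)^2
        assert rep.friedman_statistic == pytest.approx(20.0, abs=1e-9)
        assert rep.friedman_p < 0.05
        assert np.all(rep.pairwise["p_adjusted"] < 0.05)
        assert np.all(rep.pairwise["p_adjusted"] >= rep.pairwise["p_raw"] - 1e-15)

    def test_needs_three_conditions(self):
        with pytest.raises(ParameterError):
            ev.compare_modalities(pd.DataFrame({"a": [1, 2, 3], "b": [1, 2, 3]}))


class TestBinomialInterval:
    def test_contains_half(self):
        lo, hi = ev.binomial_null_interval(600)
        assert lo < 0.5 < hi
        assert lo == pytest.approx(0.46, abs=0.005)

    def test_tightens_with_n(self):
        lo1, hi1 = ev.binomial_null_interval(60)
        lo2, hi2 = ev.binomial_null_interval(600)
        assert hi2 - lo2 < hi1 - lo1


def _tf_epochs(task_gain=0.5, freq=10.0, n_trials=12, fs=100.0, seed=0,
               labels=None):
    """Oscillation whose amplitude changes by `task_gain` after t=0."""
    rng = np.random.default_rng(seed)
    t = -5.0 + np.arange(1001) / fs
    data = np.zeros((n_trials, 2, t.size))
    for i in range(n_trials):
        phase = rng.uniform(0, 2 * np.pi)
        osc = np.sin(2 * np.pi * freq * t + phase)
        amp = np.where(t >= 0, task_gain, 1.0)
        data[i] = amp * osc + 0.01 * rng.standard_normal((2, t.size))
    return make_epochset(data, fs=fs, labels=labels or ["MA"] * n_trials)


class TestERSP:
    def test_amplitude_halving_gives_minus_six_db(self):
        ep = _tf_epochs(task_gain=0.5)
        maps, _ = ev.ersp(ep, window_ms=1000, step_ms=80, pad_ratio=2,
                          baseline=(-4.5, -1.5))
        tf = maps["MA"]
        fi = np.argmin(np.abs(tf.frequencies - 10.0))
        task_cols = (tf.times >= 1.0) & (tf.times <= 4.0)
        val = tf.values[fi, task_cols].mean()
        assert val == pytest.approx(10 * np.log10(0.25), abs=0.5)

    def test_stationary_noise_is_flat(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((20, 3, 1001))
        ep = make_epochset(data, fs=100.0, labels=["BL"] * 20)
        maps, _ = ev.ersp(ep, window_ms=1000, step_ms=160, pad_ratio=2,
                          baseline=(-4.5, -1.5))
        inner = maps["BL"].values[5:-5]  # skip edge bins
        assert np.abs(inner.mean(axis=1)).max() < 1.0

    def test_pad_ratio_halves_frequency_spacing(self):
        ep = _tf_epochs()
        maps1, _ = ev.ersp(ep, 1000, 160, pad_ratio=1, baseline=(-4.5, -1.5))
        maps2, _ = ev.ersp(ep, 1000, 160, pad_ratio=2, baseline=(-4.5, -1.5))
        df1 = np.diff(maps1["MA"].frequencies[:2])[0]
        df2 = np.diff(maps2["MA"].frequencies[:2])[0]
        assert df2 == pytest.approx(df1 / 2)

    def test_difference_maps_emitted(self):
        ep = _tf_epochs(labels=["MA"] * 6 + ["BL"] * 6)
        maps, diffs = ev.ersp(ep, 1000, 160, 2, baseline=(-4.5, -1.5))
        assert set(diffs) == {"MA-BL"}
        np.testing.assert_allclose(
            diffs["MA-BL"].values, maps["MA"].values - maps["BL"].values,
            atol=1e-12)

    def test_bad_baseline_rejected(self):
        ep = _tf_epochs()
        with pytest.raises(ParameterError):
            ev.ersp(ep, 5120, 80, 2, baseline=(-5.0, -4.0))


class TestCrossValidation:
    def test_fold_arithmetic(self, small_epochs):
        res = ev.crossvalidate_offline(small_epochs, ("MA", "BL"),
                                       repetitions=1, folds=5, seed=0)
        r = res["hBCI"]
        assert r.fold_accuracies.shape == (1, 5)
        assert r.fold_sizes.sum() == 30  # 15 MA + 15 BL across 3 sessions
        assert r.y_true.size == 30
        assert np.all((r.fold_accuracies >= 0) & (r.fold_accuracies <= 1))

    def test_trial_order_permutation_invariant(self, default_epochs):
        """Same seed, permuted trials: fold membership is content-keyed, so
        the accuracies are exactly identical."""
        res1 = ev.crossvalidate_offline(default_epochs, ("MA", "BL"),
                                        repetitions=2, folds=5, seed=1)
        perm = np.random.default_rng(3).permutation(
            default_epochs["EEG"].n_trials)
        permuted = {k: e.subset(perm) for k, e in default_epochs.items()}
        res2 = ev.crossvalidate_offline(permuted, ("MA", "BL"),
                                        repetitions=2, folds=5, seed=1)
        for m in ("EEG", "NIRS", "hBCI"):
            assert res1[m].mean_accuracy == pytest.approx(
                res2[m].mean_accuracy, abs=1e-12)

    def test_too_few_trials_per_class(self, small_epochs):
        eeg = small_epochs["EEG"]
        keep = np.flatnonzero(eeg.class_mask(("MA",)))[:4].tolist() + \
            np.flatnonzero(eeg.class_mask(("BL",)))[:6].tolist()
        subset = {k: e.subset(np.array(keep)) for k, e in small_epochs.items()}
        with pytest.raises(ParameterError, match="stratify"):
            ev.crossvalidate_offline(subset, ("MA", "BL"), folds=5)

    def test_no_test_label_leakage(self, small_epochs):
        """Corrupting test labels never changes the trained predictions."""
        prep = ev.prepare_pair(small_epochs, ("MA", "BL"))
        n = prep.labels.size
        train = np.arange(0, n - 8)
        test = np.arange(n - 8, n)
        preds1 = ev.fit_predict_split(prep, train, test, seed=0)
        corrupted = ev.PreparedPair(
            class_pair=prep.class_pair,
            labels=prep.labels.copy(), session_ids=prep.session_ids,
            band_epochs=prep.band_epochs, nirs_fms=prep.nirs_fms,
            spec=prep.spec)
        corrupted.labels[test] = np.where(
            corrupted.labels[test] == "MA", "BL", "MA")
        preds2 = ev.fit_predict_split(corrupted, train, test, seed=0)
        for m in preds1:
            np.testing.assert_array_equal(preds1[m], preds2[m])


class TestPseudoOnline:
    def test_causal_split_counts(self, default_epochs):
        res = ev.pseudo_online(default_epochs, ("MA", "BL"), mode="causal")
        r = res["hBCI"]
        # 10 trials/class/session: train 2 sessions = 40, test 20
        assert r.fold_sizes.tolist() == [20]
        assert r.y_true.size == 20

    def test_session_cv_three_folds(self, default_epochs):
        res = ev.pseudo_online(default_epochs, ("MA", "BL"), mode="session_cv")
        assert res["EEG"].fold_accuracies.shape == (3,)

    def test_single_session_rejected(self, default_epochs):
        single = {k: e.subset(np.flatnonzero(e.session_ids == 0))
                  for k, e in default_epochs.items()}
        with pytest.raises(ParameterError, match="2 sessions"):
            ev.pseudo_online(single, ("MA", "BL"))


class TestLearningCurve:
    def test_full_training_set_matches_causal(self, small_epochs):
        causal = ev.pseudo_online(small_epochs, ("MA", "BL"), seed=5)
        lc = ev.learning_curve(small_epochs, ("MA", "BL"), n_train_grid=[20],
                               resamples=1, seed=5)
        assert lc[20]["mean"] == pytest.approx(
            causal["hBCI"].mean_accuracy, abs=1e-12)

    def test_more_training_data_helps(self, default_epochs):
        lc = ev.learning_curve(default_epochs, ("MA", "BL"),
                               n_train_grid=[6, 30], resamples=20, seed=0)
        assert lc[30]["mean"] >= lc[6]["mean"]

    def test_too_small_n_rejected(self, small_epochs):
        with pytest.raises(ParameterError):
            ev.learning_curve(small_epochs, ("MA", "BL"), n_train_grid=[1],
                              resamples=1)
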