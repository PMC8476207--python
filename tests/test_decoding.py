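"""Tests of rate features, leave-one-out LDA, and accuracy-change tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairedstim.decoding import (
    accuracy_change_mc_test,
    kernel_sweep,
    loo_lda,
    population_accuracy_tests,
    rate_features,
)
from pairedstim.histograms import PSTH_BIN_WIDTH, PSTH_WINDOW


def naive_loo_predictions(X, y01, lam=0.1, ridge=1e-8):
    """Independent oracle: refit the shrunk pooled-covariance discriminant
    from scratch for every leave-one-out fold."""
    n, d = X.shape
    preds = []
    for i in range(n):
        tr = np.ones(n, bool)
        tr[i] = False
        Xt, yt = X[tr], y01[tr]
        mu0, mu1 = Xt[yt == 0].mean(0), Xt[yt == 1].mean(0)
        Xc = Xt - np.where(yt[:, None] == 0, mu0, mu1)
        G = Xc.T @ Xc
        S = ((1 - lam) * G + lam * np.diag(np.diag(G))) / (len(Xt) - 2)
        S = S + ridge * (np.trace(S) / d + 1.0) * np.eye(d)
        w = np.linalg.solve(S, mu1 - mu0)
        score = w @ (X[i] - (mu0 + mu1) / 2)
        preds.append(1 if score > 0 else 0)
    return np.array(preds)


class TestRateFeatures:
    def test_single_spike_at_bin_center_peak_value(self):
        sigma = 0.003
        center = PSTH_WINDOW[0] + PSTH_BIN_WIDTH * 10.5
        f = rate_features([np.array([center])], ["a"], window=PSTH_WINDOW,
                          bin_width=PSTH_BIN_WIDTH, kernel_width=sigma)
        peak = 1.0 / (sigma * math.sqrt(2 * math.pi))
        assert f.values[0, 10] == pytest.approx(peak, rel=1e-9)
        assert f.values[0, 10] == pytest.approx(132.98, abs=0.01)

    def test_row_integral_matches_spike_count(self, rng):
        spikes = rng.uniform(0.0, 0.08, size=9)  # well inside the window
        f = rate_features([spikes], ["a"], window=PSTH_WINDOW,
                          bin_width=PSTH_BIN_WIDTH, kernel_width=0.003)
        assert f.values[0].sum() * PSTH_BIN_WIDTH == pytest.approx(9.0, rel=0.01)

    def test_linearity_of_separated_spikes(self):
        kw = dict(window=PSTH_WINDOW, bin_width=PSTH_BIN_WIDTH, kernel_width=0.002)
        both = rate_features([np.array([0.01, 0.07])], ["a"], **kw)
        s1 = rate_features([np.array([0.01])], ["a"], **kw)
        s2 = rate_features([np.array([0.07])], ["a"], **kw)
        np.testing.assert_allclose(both.values, s1.values + s2.values, atol=1e-9)

    def test_empty_trial_gives_zero_row(self):
        f = rate_features([np.array([])], ["a"], window=PSTH_WINDOW,
                          bin_width=PSTH_BIN_WIDTH, kernel_width=0.003)
        assert np.all(f.values == 0.0)


class TestLooLda:
    def test_matches_naive_per_fold_refit(self, rng):
        X = np.concatenate([rng.normal(0, 1, (13, 7)), rng.normal(0.7, 1, (18, 7))])
        y = np.array(["a"] * 13 + ["b"] * 18)
        res = loo_lda(values=X, labels=y)
        naive = naive_loo_predictions(X, (y == "b").astype(int))
        assert np.array_equal((res.predicted == "b").astype(int), naive)
        assert res.accuracy == np.mean(res.per_trial_correct)

    def test_matches_sklearn_without_shrinkage(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = np.concatenate([rng.normal(0, 1, (20, 5)), rng.normal(0.5, 1, (20, 5))])
        y = np.repeat([0, 1], 20)
        res = loo_lda(values=X, labels=y, shrinkage=0.0, ridge=1e-12)
        sk = []
        for i in range(len(X)):
            tr = np.ones(len(X), bool)
            tr[i] = False
            clf = LinearDiscriminantAnalysis(solver="lsqr", priors=[0.5, 0.5])
            sk.append(clf.fit(X[tr], y[tr]).predict(X[i : i + 1])[0])
        assert np.array_equal(res.predicted.astype(int), sk)

    def test_duplicated_rows_forced_tie_break(self):
        row = np.array([1.0, 2.0, 3.0])
        X = np.tile(row, (4, 1))
        res = loo_lda(values=X, labels=np.array(["a", "a", "b", "b"]))
        # zero discriminant everywhere: ties go to the lexicographically
        # first class, so exactly the "a" trials are predicted correctly
        assert np.all(res.predicted == "a")
        assert res.accuracy == 0.5

    def test_separable_classes_decoded_accurately(self, rng):
        n = 20
        trials, labels = [], []
        for _ in range(n):  # class A: strong early response
            trials.append(np.sort(np.concatenate([
                rng.uniform(*PSTH_WINDOW, rng.poisson(1.0)),
                rng.normal(0.010, 0.0015, 6),
            ])))
            labels.append("A")
        for _ in range(n):  # class B: no response
            trials.append(np.sort(rng.uniform(*PSTH_WINDOW, rng.poisson(1.0))))
            labels.append("B")
        f = rate_features(trials, labels, window=PSTH_WINDOW,
                          bin_width=PSTH_BIN_WIDTH, kernel_width=0.003)
        assert loo_lda(f).accuracy >= 0.9

    def test_chance_level_on_exchangeable_classes(self, rng):
        accs = []
        for _ in range(30):
            X = rng.normal(0, 1, (60, 12))
            y = np.repeat([0, 1], 30)
            accs.append(loo_lda(values=X, labels=y).accuracy)
        assert 0.42 < np.mean(accs) < 0.58

    def test_accuracy_monotone_in_class_separation(self, rng):
        means = []
        for delta in (0.0, 0.5, 1.0, 2.0):
            accs = [
                loo_lda(values=np.concatenate([
                    rng.normal(0, 1, (25, 6)), rng.normal(delta, 1, (25, 6))
                ]), labels=np.repeat([0, 1], 25)).accuracy
                for _ in range(8)
            ]
            means.append(np.mean(accs))
        assert means[3] > means[2] > means[1]
        assert means[1] > means[0] - 0.05  # MC tolerance near chance

    def test_requires_two_classes_with_two_trials(self):
        with pytest.raises(ValueError, match="two classes"):
            loo_lda(values=np.zeros((4, 2)), labels=np.array([0, 0, 0, 0]))
        with pytest.raises(ValueError, match="two trials"):
            loo_lda(values=np.zeros((3, 2)), labels=np.array([0, 0, 1]))

    def test_deterministic(self, rng):
        X = rng.normal(size=(30, 10))
        y = np.repeat([0, 1], 15)
        a = loo_lda(values=X, labels=y)
        b = loo_lda(values=X, labels=y)
        assert np.array_equal(a.predicted, b.predicted)


class TestKernelSweep:
    def test_sharp_latency_difference_favors_narrow_kernels(self, rng):
        trials, labels = [], []
        for _ in range(40):
            trials.append(np.sort(np.concatenate([
                rng.normal(0.010, 0.0008, 5),
                rng.uniform(*PSTH_WINDOW, rng.poisson(1.0)),
            ])))
            labels.append("A")
            trials.append(np.sort(np.concatenate([
                rng.normal(0.013, 0.0008, 5),
                rng.uniform(*PSTH_WINDOW, rng.poisson(1.0)),
            ])))
            labels.append("B")
        sweep = kernel_sweep(trials, labels, [0.002, 0.050],
                             window=PSTH_WINDOW, bin_width=PSTH_BIN_WIDTH)
        acc = dict(zip(sweep["kernel_width"], sweep["accuracy"]))
        assert acc[0.002] > 0.8
        assert acc[0.002] > acc[0.050]

    def test_slow_modulation_favors_wide_kernels(self, rng):
        window, bw = (-0.5, 0.2), 0.01
        trials, labels = [], []
        for _ in range(30):
            # class A modulated early, class B late; same total rate
            a = np.sort(rng.uniform(-0.5, -0.15, rng.poisson(8)))
            b = np.sort(rng.uniform(-0.15, 0.2, rng.poisson(8)))
            trials += [a, b]
            labels += ["A", "B"]
        sweep = kernel_sweep(trials, labels, [0.003, 0.150],
                             window=window, bin_width=bw)
        acc = dict(zip(sweep["kernel_width"], sweep["accuracy"]))
        assert acc[0.150] >= acc[0.003]
        assert acc[0.150] > 0.8

    def test_uninformative_classes_stay_near_chance(self, rng):
        trials = [np.sort(rng.uniform(*PSTH_WINDOW, 5)) for _ in range(40)]
        labels = ["A", "B"] * 20
        sweep = kernel_sweep(trials, labels, [0.003, 0.020],
                             window=PSTH_WINDOW, bin_width=PSTH_BIN_WIDTH)
        assert np.all(sweep["accuracy"].between(0.25, 0.75))


class TestAccuracyChange:
    def _features(self, rng, n=20, d=8, shift=0.0):
        X = np.concatenate([rng.normal(0, 1, (n, d)), rng.normal(shift, 1, (n, d))])
        labels = np.array(["a"] * n + ["b"] * n)
        from pairedstim.decoding import RateFeatureMatrix

        return RateFeatureMatrix(values=X, labels=labels,
                                 bin_centers=np.arange(d, dtype=float),
                                 kernel_width=0.003, window=(0.0, float(d)),
                                 bin_width=1.0)

    def test_identical_epochs_give_no_change(self, rng):
        f = self._features(rng)
        res = accuracy_change_mc_test(f, f, n_mc=100, seed=0)
        assert res.direction == "no change"
        assert res.p_value > 0.9

    def test_null_p_values_uniform(self):
        pvals = []
        for seed in range(80):
            r = np.random.default_rng(seed)
            fb = self._features(r, n=12, d=5)
            fa = self._features(r, n=12, d=5)
            pvals.append(accuracy_change_mc_test(fb, fa, n_mc=99, seed=seed).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_coding_degradation_detected(self):
        hits = 0
        for seed in range(8):
            r = np.random.default_rng(100 + seed)
            fb = self._features(r, n=40, d=6, shift=2.0)   # strongly coded
            fa = self._features(r, n=40, d=6, shift=0.0)   # coding removed
            res = accuracy_change_mc_test(fb, fa, n_mc=99, seed=seed)
            hits += res.p_value < 0.05 and res.direction == "decrease"
        assert hits >= 7

    def test_mismatched_class_pairs_rejected(self, rng):
        fa = self._features(rng)
        fb = self._features(rng)
        fb.labels = np.array(["a"] * 20 + ["c"] * 20)
        with pytest.raises(ValueError, match="same class pair"):
            accuracy_change_mc_test(fa, fb, n_mc=100)


class TestPopulationTests:
    def test_all_tied_pairs_give_p_one(self):
        df = pd.DataFrame({
            "comparison": ["median-ulnar"] * 6,
            "accuracy_before": [0.6] * 6,
            "accuracy_after": [0.6] * 6,
        })
        with pytest.warns(UserWarning, match="tied"):
            table = population_accuracy_tests(df)
        assert table["p_raw"].iloc[0] == 1.0
        assert table["prop_no_change"].iloc[0] == 1.0

    def test_consistent_shift_detected(self, rng):
        before = rng.normal(0.7, 0.05, 100)
        df = pd.DataFrame({
            "comparison": ["thumb-index"] * 100,
            "accuracy_before": before,
            "accuracy_after": before + 0.05,
        })
        table = population_accuracy_tests(df)
        assert table["significant"].iloc[0]
        assert table["prop_increase"].iloc[0] == 1.0

    def test_null_rejection_rate_near_alpha(self):
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            before = r.normal(0.7, 0.05, 30)
            after = before + r.normal(0, 0.05, 30)
            df = pd.DataFrame({"comparison": ["c"] * 30,
                               "accuracy_before": before,
                               "accuracy_after": after})
            rejections += bool(population_accuracy_tests(df)["significant"].iloc[0])
        assert 0.01 <= rejections / n_rep <= 0.10

    def test_minimum_pairs_enforced(self):
        df = pd.DataFrame({"comparison": ["c"] * 3,
                           "accuracy_before": [0.5, 0.6, 0.7],
                           "accuracy_after": [0.5, 0.6, 0.8]})
        with pytest.raises(ValueError, match="five"):
            population_accuracy_tests(df)
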