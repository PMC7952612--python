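"""Scoring, statistics and the cross-session protocol."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rsvperp.evaluate import (anova_three_factor, band_average_waveforms,
                              binary_scores, confusion_ternary,
                              make_session_folds, paired_ttest,
                              project_features_2d, roc_curve_and_auc)
from rsvperp.preprocess import EpochSet


class TestFolds:
    @pytest.mark.parametrize("n", [2, 5, 11])
    def test_leave_one_session_out(self, n):
        plan = make_session_folds(list(range(1, n + 1)))
        assert len(plan.folds) == n
        tests = [t for _, t in plan.folds]
        assert sorted(tests) == list(range(1, n + 1))
        for train, test in plan.folds:
            assert test not in train
            assert set(train) | {test} == set(range(1, n + 1))

    def test_single_session_rejected(self):
        with pytest.raises(ValueError):
            make_session_folds([1])


class TestBinaryScores:
    def test_perfect(self):
        y = np.array(["target", "nontarget", "nontarget"])
        s = binary_scores(y, y)
        assert s == {"recall": 1.0, "precision": 1.0, "f1": 1.0, "accuracy": 1.0}

    def test_hand_counted_example(self):
        truth = ["target", "target"] + ["nontarget"] * 8
        pred = ["target", "nontarget", "target"] + ["nontarget"] * 7
        s = binary_scores(truth, pred)  # TP=1 FN=1 FP=1 TN=7
        assert s["recall"] == 0.5
        assert s["precision"] == 0.5
        assert s["f1"] == 0.5
        assert s["accuracy"] == pytest.approx(0.8)

    def test_no_predicted_positives_zero_convention(self):
        truth = ["target"] + ["nontarget"] * 4
        pred = ["nontarget"] * 5
        s = binary_scores(truth, pred)
        assert s["precision"] == 0.0 and s["recall"] == 0.0 and s["f1"] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            binary_scores(["target"], ["target", "nontarget"])


class TestConfusion:
    def test_diagonal_when_perfect(self):
        y = [1, 1, 2, 2, 3, 3]
        cm = confusion_ternary(y, y)
        np.testing.assert_array_equal(np.diag(cm.percentages), [100, 100, 100])
        assert cm.counts.sum() == 6

    def test_all_predicted_target(self):
        cm = confusion_ternary([1, 2, 3, 2], [1, 1, 1, 1])
        np.testing.assert_array_equal(cm.percentages[:, 0], [100, 100, 100])

    def test_hand_tally(self):
        truth = [1, 1, 2, 2, 3, 3]
        pred = [1, 3, 2, 1, 3, 3]
        cm = confusion_ternary(truth, pred)
        # row order (target=1, near=3, far=2); columns likewise
        np.testing.assert_array_equal(cm.counts, [[1, 1, 0],   # true target
                                                  [0, 2, 0],   # true near
                                                  [1, 0, 1]])  # true far
        assert np.allclose(cm.percentages.sum(axis=1), 100.0, atol=0.01)

    def test_empty_true_class_flagged_nan(self):
        cm = confusion_ternary([1, 1, 2], [1, 1, 2])
        assert 3 in cm.undefined_rows
        assert np.isnan(cm.percentages[1]).all()


def _auc_pair_counting(scores, truth):
    """P(score_target > score_nontarget) + 0.5 P(tie) over all pairs."""
    pos = [s for s, t in zip(scores, truth) if t == "target"]
    neg = [s for s, t in zip(scores, truth) if t == "nontarget"]
    wins = sum((p > n) + 0.5 * (p == n) for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        out = roc_curve_and_auc([0.9, 0.8, 0.2, 0.1], ["target", "target",
                                                       "nontarget", "nontarget"])
        assert out["auc"] == 1.0

    def test_worked_example(self):
        out = roc_curve_and_auc([0.9, 0.8, 0.4, 0.2],
                                ["target", "nontarget", "target", "nontarget"])
        assert out["auc"] == pytest.approx(0.75)  # 3 of 4 pairs correctly ordered

    def test_equals_pair_counting_oracle_on_all_small_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(200):
            n = rng.integers(2, 9)
            truth = rng.choice(["target", "nontarget"], size=n)
            if len(set(truth)) < 2:
                continue
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            out = roc_curve_and_auc(scores, truth)
            assert out["auc"] == pytest.approx(_auc_pair_counting(scores, truth))

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(1)
        n = 2000
        truth = rng.choice(["target", "nontarget"], size=n)
        scores = rng.uniform(size=n)
        out = roc_curve_and_auc(scores, truth)
        assert out["auc"] == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve_and_auc([0.5, 0.6], ["target", "target"])


def _anova_projection_oracle(records, response):
    """Brute-force main-effects ANOVA via explicit design-matrix projections."""
    y = records[response].to_numpy(dtype=float)
    n = len(y)
    out = {}
    resid_df = n - 1
    ss_factors = 0.0
    for factor in ("subject", "method", "fold"):
        levels = sorted(records[factor].unique())
        X = np.zeros((n, len(levels)))
        for j, lv in enumerate(levels):
            X[:, j] = (records[factor] == lv).to_numpy()
        P = X @ np.linalg.pinv(X)
        one = np.full((n, n), 1.0 / n)
        ss = float(y @ (P - one) @ y)
        out[factor] = (len(levels) - 1, ss)
        resid_df -= len(levels) - 1
        ss_factors += ss
    ss_total = float(np.sum((y - y.mean()) ** 2))
    out["residual"] = (resid_df, ss_total - ss_factors)
    return out


def _balanced_records(rng, n_s=3, n_m=2, n_f=4):
    rows = []
    for s in range(n_s):
        for m in range(n_m):
            for f in range(n_f):
                rows.append({"subject": s, "method": f"m{m}", "fold": f,
                             "f1": rng.uniform()})
    return pd.DataFrame(rows)


class TestAnova:
    def test_dfs_on_experiment_shape(self):
        rng = np.random.default_rng(0)
        rec = _balanced_records(rng, n_s=10, n_m=2, n_f=11)
        tab = anova_three_factor(rec, "f1")
        assert tab.loc["subject", "df"] == 9
        assert tab.loc["method", "df"] == 1
        assert tab.loc["fold", "df"] == 10
        assert tab.loc["residual", "df"] == 220 - 1 - 9 - 1 - 10  # = 199

    def test_matches_projection_oracle(self):
        rng = np.random.default_rng(1)
        rec = _balanced_records(rng, n_s=3, n_m=2, n_f=4)
        # plant additive effects so every factor matters
        rec["f1"] += rec["subject"] * 0.3 + rec["fold"] * 0.05 \
            + (rec["method"] == "m1") * 0.2
        tab = anova_three_factor(rec, "f1")
        oracle = _anova_projection_oracle(rec, "f1")
        for factor in ("subject", "method", "fold", "residual"):
            df, ss = oracle[factor]
            assert tab.loc[factor, "df"] == df
            assert tab.loc[factor, "sum_sq"] == pytest.approx(ss, abs=1e-8)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(2)
        rec = _balanced_records(rng)
        tab = anova_three_factor(rec, "f1")
        fit = smf.ols("f1 ~ C(subject) + C(method) + C(fold)", data=rec).fit()
        sm_tab = sm.stats.anova_lm(fit, typ=1)
        assert tab.loc["subject", "sum_sq"] == pytest.approx(
            sm_tab.loc["C(subject)", "sum_sq"])
        assert tab.loc["method", "F"] == pytest.approx(sm_tab.loc["C(method)", "F"])
        assert tab.loc["fold", "p"] == pytest.approx(sm_tab.loc["C(fold)", "PR(>F)"])
        assert tab.loc["residual", "sum_sq"] == pytest.approx(
            sm_tab.loc["Residual", "sum_sq"])

    def test_ss_additivity(self):
        rng = np.random.default_rng(3)
        rec = _balanced_records(rng, n_s=4, n_m=3, n_f=5)
        tab = anova_three_factor(rec, "f1")
        y = rec["f1"].to_numpy()
        assert tab["sum_sq"].sum() == pytest.approx(np.sum((y - y.mean()) ** 2))

    def test_constant_response_all_nan_f(self):
        rng = np.random.default_rng(4)
        rec = _balanced_records(rng)
        rec["f1"] = 0.5
        tab = anova_three_factor(rec, "f1")
        assert np.isnan(tab.loc["method", "F"])

    def test_unbalanced_rejected(self):
        rng = np.random.default_rng(5)
        rec = _balanced_records(rng).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            anova_three_factor(rec, "f1")


class TestPairedTtest:
    def test_antisymmetry(self):
        a = np.array([0.8, 0.7, 0.9, 0.6])
        b = np.array([0.5, 0.6, 0.85, 0.4])
        t_ab, p_ab = paired_ttest(a, b)
        t_ba, p_ba = paired_ttest(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_closed_form_value(self):
        b = np.zeros(4)
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, _ = paired_ttest(a, b)
        d = a - b
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(expected)
        assert t == pytest.approx(3.873, abs=1e-3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            paired_ttest([1.0, 2.0], [0.5, 1.5])


class TestBandAverages:
    @staticmethod
    def _simulated_epochs():
        from rsvperp.evaluate import ExperimentConfig, simulate_subject_epochs
        cfg = ExperimentConfig(n_subjects=1, n_sessions=2, n_blocks=2, seed=3)
        return simulate_subject_epochs(cfg, 1)

    def test_target_delta_dominates_far_delta(self):
        epochs, labels = self._simulated_epochs()
        out = band_average_waveforms(epochs, labels)
        target_peak = np.abs(out["delta"][1]).max()
        far_peak = np.abs(out["delta"][2]).max()
        assert target_peak > 5 * far_peak

    def test_ssvep_present_in_all_classes_alpha(self):
        from scipy.signal import periodogram
        epochs, labels = self._simulated_epochs()
        out = band_average_waveforms(epochs, labels)
        for code in (1, 2, 3):
            avg = out["alpha"][code]
            ch = np.argmax(avg.var(axis=1))
            freqs, pxx = periodogram(avg[ch], fs=epochs.sampling_rate)
            assert abs(freqs[np.argmax(pxx)] - 10.0) < 1.0

    def test_band_above_nyquist_rejected(self):
        epochs, labels = self._simulated_epochs()
        with pytest.raises(ValueError):
            band_average_waveforms(epochs, labels, bands=[("bad", 10.0, 60.0)])


class TestProjection:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 10))
        a = project_features_2d(X, seed=1)
        b = project_features_2d(X, seed=1)
        assert a.shape == (40, 2)
        np.testing.assert_array_equal(a, b)

    def test_separated_clusters_stay_separated(self):
        from sklearn.metrics import silhouette_score
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, size=(30, 8)),
                       rng.normal(12, 1, size=(30, 8))])
        labels = np.array([0] * 30 + [1] * 30)
        emb = project_features_2d(X, seed=0)
        assert silhouette_score(emb, labels) > 0.5


class TestAccuracyRecallRelation:
    def test_accuracy_dominates_recall_when_nontargets_dominate(self):
        """With heavily imbalanced truth and a high true-negative rate, the
        merged-binary accuracy must sit above target recall — the reason
        overall accuracies near 0.99 coexist with recalls near 0.85."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = 500
            truth = np.where(rng.uniform(size=n) < 0.04, "target", "nontarget")
            if (truth == "target").sum() == 0:
                continue
            pred = truth.copy()
            # miss some targets; false-alarm on very few non-targets
            t_idx = np.flatnonzero(truth == "target")
            n_idx = np.flatnonzero(truth == "nontarget")
            pred[rng.choice(t_idx, size=max(1, len(t_idx) // 3), replace=False)] = "nontarget"
            pred[rng.choice(n_idx, size=2, replace=False)] = "target"
            s = binary_scores(truth, pred)
            tnr = np.mean(pred[truth == "nontarget"] == "nontarget")
            if tnr > s["recall"]:
                assert s["accuracy"] >= s["recall"]
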