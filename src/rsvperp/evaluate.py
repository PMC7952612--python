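"""Cross-session validation, merged-binary scoring and statistics.

Implements the leave-one-session-out protocol: each session serves once as
the held-out test set while all remaining sessions train the spatial
filters and classifiers, emulating an online deployment where a model fit
on past sessions must generalise to a new one.  Scores (recall, precision,
F1, accuracy) are always computed on *merged binary* labels — near- and
far-non-target collapse back to "nontarget" — so the ternary trick changes
training only, never the task.

Also provides the statistical comparison machinery: 3x3 confusion matrices
with row percentages, ROC/AUC from the softmax target probability, a
balanced three-factor (subject, method, fold) main-effects ANOVA, paired
t-tests, band-averaged class waveforms and a 2-D feature embedding.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats
from sklearn.manifold import TSNE
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve as sk_roc_curve

from ._seeding import derive_seed
from .classifiers import (CnnSpec, SvmSpec, build_cnn, predict_target_probability,
                          train_cnn, train_svm)
from .labeling import (FAR_NONTARGET, NEAR_NONTARGET, TARGET,
                       assign_ternary_labels, merge_to_binary)
from .preprocess import EpochSet, bandpass, baseline_and_detrend, extract_epochs
from .simulate import ContinuousRecording, SimConfig, make_session, make_stimulus_pool, synthesize_recording
from .xdawn import fit_xdawn, transform

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "ConfusionMatrix3",
    "ScoreRecord",
    "EvaluationReport",
    "make_session_folds",
    "binary_scores",
    "confusion_ternary",
    "roc_curve_and_auc",
    "anova_three_factor",
    "paired_ttest",
    "band_average_waveforms",
    "project_features_2d",
    "run_experiment",
    "ExperimentConfig",
]

#: row/column order of the ternary confusion matrix
_TERNARY_ORDER = (TARGET, NEAR_NONTARGET, FAR_NONTARGET)


@dataclass(frozen=True)
class FoldPlan:
    """Leave-one-session-out split: each session is the test set exactly once."""

    folds: tuple  # of (train_ids tuple, test_id)


def make_session_folds(session_ids) -> FoldPlan:
    ids = list(dict.fromkeys(session_ids))  # unique, order-preserving
    if len(ids) < 2:
        raise ValueError("need at least 2 sessions for cross-session validation")
    folds = tuple((tuple(s for s in ids if s != test), test) for test in ids)
    return FoldPlan(folds=folds)


@dataclass
class ScoreRecord:
    subject: object
    method: str
    fold: object
    recall: float
    precision: float
    f1: float
    accuracy: float


def binary_scores(true_binary, predicted_binary) -> dict:
    """Recall/precision/F1/accuracy with "target" as the positive class.

    Zero denominators (no true or no predicted positives) yield 0 with a
    warning rather than an error.
    """
    t = np.asarray(true_binary)
    p = np.asarray(predicted_binary)
    if t.shape != p.shape:
        raise ValueError("true and predicted labels differ in length")
    for arr, name in ((t, "true"), (p, "predicted")):
        bad = set(np.unique(arr)) - {"target", "nontarget"}
        if bad:
            raise ValueError(f"{name} labels outside {{target, nontarget}}: {bad}")
    tp = int(np.sum((t == "target") & (p == "target")))
    fn = int(np.sum((t == "target") & (p == "nontarget")))
    fp = int(np.sum((t == "nontarget") & (p == "target")))
    if tp + fn == 0 or tp + fp == 0:
        logger.warning("degenerate confusion (no positives on one side); scoring 0")
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = float(np.mean(t == p))
    return {"recall": recall, "precision": precision, "f1": f1, "accuracy": accuracy}


@dataclass
class ConfusionMatrix3:
    """3x3 confusion matrix in (target, near, far) order.

    ``percentages`` rows are normalised to 100; a row with no true members
    is NaN and listed in ``undefined_rows``.
    """

    counts: np.ndarray
    percentages: np.ndarray
    order: tuple = _TERNARY_ORDER
    undefined_rows: tuple = ()


def confusion_ternary(true_ternary, predicted_ternary) -> ConfusionMatrix3:
    t = np.asarray(true_ternary, dtype=int)
    p = np.asarray(predicted_ternary, dtype=int)
    if t.shape != p.shape:
        raise ValueError("length mismatch")
    bad = set(np.unique(np.concatenate([t, p]))) - set(_TERNARY_ORDER)
    if bad:
        raise ValueError(f"labels outside {{1,2,3}}: {bad}")
    counts = np.zeros((3, 3), dtype=int)
    for i, ci in enumerate(_TERNARY_ORDER):
        for j, cj in enumerate(_TERNARY_ORDER):
            counts[i, j] = np.sum((t == ci) & (p == cj))
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * counts / row_tot
    undefined = tuple(_TERNARY_ORDER[i] for i in range(3) if row_tot[i, 0] == 0)
    if undefined:
        logger.warning("confusion rows with no true members: %s", undefined)
    return ConfusionMatrix3(counts=counts, percentages=pct, undefined_rows=undefined)


def roc_curve_and_auc(target_probability, true_binary):
    """TPR/FPR over all thresholds plus trapezoidal AUC (target positive)."""
    scores = np.asarray(target_probability, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    y = (np.asarray(true_binary) == "target").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: only one class present")
    fpr, tpr, thresholds = sk_roc_curve(y, scores)
    return {"fpr": fpr, "tpr": tpr, "thresholds": thresholds,
            "auc": float(sk_auc(fpr, tpr))}


def anova_three_factor(records: pd.DataFrame, response: str = "f1") -> pd.DataFrame:
    """Main-effects ANOVA over a balanced subject x method x fold design.

    Sums of squares come from marginal-mean contrasts (the classical
    balanced-design decomposition); F compares each factor's mean square to
    the residual, with p from the F distribution.  The design must be fully
    crossed with one observation per cell.
    """
    needed = {"subject", "method", "fold", response}
    if not needed <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(needed)}")
    cell_counts = records.groupby(["subject", "method", "fold"]).size()
    n_s = records["subject"].nunique()
    n_m = records["method"].nunique()
    n_f = records["fold"].nunique()
    if len(cell_counts) != n_s * n_m * n_f or not (cell_counts == cell_counts.iloc[0]).all():
        raise ValueError("unbalanced design: every subject x method x fold cell "
                         "must appear the same number of times")
    y = records[response].to_numpy(dtype=float)
    n = len(y)
    grand = y.mean()
    ss_total = np.sum((y - grand) ** 2)
    rows = []
    ss_factors = 0.0
    for factor, levels in (("subject", n_s), ("method", n_m), ("fold", n_f)):
        means = records.groupby(factor)[response].mean()
        per_level = n / levels
        ss = float(per_level * np.sum((means.to_numpy() - grand) ** 2))
        rows.append([factor, levels - 1, ss])
        ss_factors += ss
    df_res = (n - 1) - sum(r[1] for r in rows)
    ss_res = ss_total - ss_factors
    ms_res = ss_res / df_res if df_res > 0 else np.nan
    out = []
    for factor, df, ss in rows:
        ms = ss / df if df > 0 else np.nan
        if df > 0 and ms_res > 0:
            F = ms / ms_res
            p = float(sp_stats.f.sf(F, df, df_res))
        else:
            F, p = np.nan, np.nan
        out.append({"factor": factor, "df": float(df), "sum_sq": ss,
                    "mean_sq": ms, "F": F, "p": p})
    out.append({"factor": "residual", "df": float(df_res), "sum_sq": ss_res,
                "mean_sq": ms_res, "F": np.nan, "p": np.nan})
    return pd.DataFrame(out).set_index("factor")


def paired_ttest(scores_a, scores_b) -> tuple[float, float]:
    """Classical paired t-test on per-fold-per-subject score differences."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0):
        raise ValueError("zero variance of differences: t statistic undefined")
    res = sp_stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


DEFAULT_BANDS = (("delta", 0.5, 4.0), ("theta", 4.0, 8.0), ("alpha", 8.0, 13.0))


def band_average_waveforms(epochs: EpochSet, labels, bands=DEFAULT_BANDS) -> dict:
    """Per-band, per-class average waveforms (channels x timepoints).

    Band-filters every epoch (zero-phase Butterworth) then averages within
    each ternary class.  Empty classes are omitted with a warning.  In the
    simulated data the target-class Delta average carries the evoked
    response while the Alpha averages of all classes carry the SSVEP.
    """
    labels = np.asarray(labels, dtype=int)
    nyq = epochs.sampling_rate / 2
    out: dict[str, dict[int, np.ndarray]] = {}
    for name, lo, hi in bands:
        if not (0 < lo < hi < nyq):
            raise ValueError(f"band {name} ({lo}-{hi} Hz) not inside (0, {nyq}) Hz")
        sos = sp_signal.butter(4, [lo, hi], btype="bandpass",
                               fs=epochs.sampling_rate, output="sos")
        filt = sp_signal.sosfiltfilt(sos, epochs.data, axis=2)
        per_class = {}
        for code in _TERNARY_ORDER:
            mask = labels == code
            if not mask.any():
                warnings.warn(f"class {code} empty; omitted from band averages")
                continue
            per_class[code] = filt[mask].mean(axis=0)
        out[name] = per_class
    return out


def project_features_2d(feature_vectors: np.ndarray, labels=None, seed: int = 0) -> np.ndarray:
    """t-SNE embedding of per-trial features into 2-D, for reports only."""
    X = np.asarray(feature_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D array with at least 3 samples")
    if np.allclose(X, X[0]):
        warnings.warn("degenerate (all-identical) features; jittering before embedding")
        X = X + np.random.default_rng(seed).normal(scale=1e-6, size=X.shape)
    perplexity = min(30.0, (X.shape[0] - 1) / 3.0)
    ts = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    return ts.fit_transform(X)


# --------------------------------------------------------------------------
# End-to-end experiment
# --------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Scaled-down cross-session benchmark on simulated subjects.

    The defaults define the desk-scale recovery study: 2 subjects x 3
    sessions x 4 blocks of 100 stimuli at 10 Hz (4% targets), 16 channels,
    and reduced CNN training.  The signal regime is deliberately easy — an
    evoked response clearly visible in single trials (amplitude 10 against
    unit-total noise) with latency jitter small relative to the 100 ms
    stimulus spacing — so that recovery failures indicate implementation
    defects rather than irreducible class overlap.
    """

    n_subjects: int = 2
    n_sessions: int = 3
    n_blocks: int = 4
    block_size: int = 100
    target_fraction: float = 0.04
    presentation_rate: float = 10.0
    sampling_rate: float = 100.0
    n_channels: int = 16
    erp_amplitude: float = 10.0
    erp_latency_jitter_sd: float = 0.01
    ssvep_amplitude: float = 0.5
    pink_noise_sd: float = 0.5
    white_noise_sd: float = 0.5
    near_window: float = 0.5
    labeling_mode: str = "symmetric"
    xdawn_components: int = 6
    svm: SvmSpec = field(default_factory=SvmSpec)
    cnn_epochs: int = 100
    cnn_batch: int = 90
    methods: tuple = ("svm_binary", "svm_ternary", "cnn_binary", "cnn_ternary")
    seed: int = 0


@dataclass
class EvaluationReport:
    scores: pd.DataFrame                  # subject, method, fold, 4 scores
    summary: pd.DataFrame                 # mean +- sd per method
    confusions: dict                      # method -> averaged ConfusionMatrix3 pct
    aucs: dict                            # method -> list of per-fold AUCs
    anova: dict                           # response -> AnovaTable DataFrame
    ttests: dict                          # (method_a, method_b, response) -> (t, p)
    failures: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "scores": self.scores.to_dict(orient="records"),
            "summary": [
                {"method": m, **{f"{score}_{stat}": float(self.summary.loc[m, (score, stat)])
                                 for score, stat in self.summary.columns}}
                for m in self.summary.index],
            "confusions": {m: np.asarray(c).tolist() for m, c in self.confusions.items()},
            "aucs": self.aucs,
            "anova": {r: t.reset_index().to_dict(orient="records")
                      for r, t in self.anova.items()},
            "ttests": {"|".join(map(str, k)): list(v) for k, v in self.ttests.items()},
            "failures": self.failures,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def simulate_subject_epochs(cfg: ExperimentConfig, subject: int) -> tuple[EpochSet, np.ndarray]:
    """Simulate, preprocess and label one subject's sessions.

    Ternary labels are assigned on the *full* stimulus stream before epoch
    extraction, so an epoch dropped at a recording edge can never change a
    neighbour's near/far status.  Returns the cleaned epoch set (with
    per-epoch metadata) and the ternary label per epoch.
    """
    frames, slabs = [], []
    lead_in = int(0.5 * cfg.sampling_rate)  # room for the -200 ms epoch edge
    # spatial topographies are a property of the subject's anatomy: fixed
    # across sessions, while noise and jitter are redrawn per session
    pat_rng = np.random.default_rng(derive_seed(cfg.seed, "subject", subject, "patterns"))
    erp_pattern = pat_rng.standard_normal(cfg.n_channels)
    ssvep_pattern = pat_rng.standard_normal(cfg.n_channels)
    for sess in range(1, cfg.n_sessions + 1):
        seed = derive_seed(cfg.seed, "subject", subject, "session", sess)
        pool = make_stimulus_pool(
            n_pictures=cfg.n_blocks * cfg.block_size,
            target_fraction=cfg.target_fraction, seed=seed)
        events = make_session(pool, n_blocks=cfg.n_blocks, block_size=cfg.block_size,
                              target_fraction=cfg.target_fraction,
                              presentation_rate=cfg.presentation_rate,
                              sampling_rate=cfg.sampling_rate, seed=seed,
                              session_id=sess, start_sample=lead_in)
        labels = assign_ternary_labels(events, near_window=cfg.near_window,
                                       mode=cfg.labeling_mode)
        events.frame["ternary_label"] = labels
        sim = SimConfig(n_channels=cfg.n_channels, erp_amplitude=cfg.erp_amplitude,
                        erp_latency_jitter_sd=cfg.erp_latency_jitter_sd,
                        erp_spatial_pattern=erp_pattern,
                        ssvep_amplitude=cfg.ssvep_amplitude,
                        ssvep_spatial_pattern=ssvep_pattern,
                        pink_noise_sd=cfg.pink_noise_sd,
                        white_noise_sd=cfg.white_noise_sd,
                        seed=derive_seed(cfg.seed, "subject", subject, "noise", sess))
        rec = synthesize_recording(events, sim)
        rec = bandpass(rec)
        ep = extract_epochs(rec, events)
        ep = baseline_and_detrend(ep)
        frames.append(ep.events)
        slabs.append(ep.data)
    data = np.concatenate(slabs, axis=0)
    events = pd.concat(frames, ignore_index=True)
    merged = EpochSet(data, -0.2, 1.2, cfg.sampling_rate, events)
    labels = merged.events["ternary_label"].to_numpy(dtype=int)
    merged.events["binary_label"] = merge_to_binary(labels)
    return merged, labels


def _fit_predict_method(method: str, cfg: ExperimentConfig, epochs: EpochSet,
                        labels: np.ndarray, train_mask: np.ndarray,
                        test_mask: np.ndarray, seed: int):
    """Train one method on the training mask; return (pred_binary, target_prob, pred_ternary|None)."""
    binary = merge_to_binary(labels)
    if method.startswith("svm"):
        xd = fit_xdawn(_subset(epochs, train_mask), n_components=cfg.xdawn_components)
        feats_train = transform(xd, _subset(epochs, train_mask), flatten=True)
        feats_test = transform(xd, _subset(epochs, test_mask), flatten=True)
        y = labels[train_mask] if method.endswith("ternary") else binary[train_mask]
        clf = train_svm(feats_train, y, cfg.svm, seed=seed)
        pred = clf.predict(feats_test)
        prob = predict_target_probability(clf, feats_test)
        tern = pred if method.endswith("ternary") else None
    else:
        k = 3 if method.endswith("ternary") else 2
        spec = CnnSpec(n_channels=cfg.n_channels, n_times=epochs.n_times,
                       n_classes=k, n_epochs=cfg.cnn_epochs, batch_size=cfg.cnn_batch)
        y = labels[train_mask] if k == 3 else binary[train_mask]
        model = build_cnn(spec, seed=derive_seed(seed, "init"))
        train_cnn(model, epochs.data[train_mask], y, spec, seed=derive_seed(seed, "train"))
        pred = model.predict(epochs.data[test_mask])
        prob = predict_target_probability(model, epochs.data[test_mask])
        tern = pred if k == 3 else None
    pred_binary = merge_to_binary(pred) if tern is not None else pred
    return pred_binary, prob, tern


def _subset(epochs: EpochSet, mask: np.ndarray) -> EpochSet:
    return EpochSet(epochs.data[mask], epochs.tmin, epochs.tmax,
                    epochs.sampling_rate, epochs.events[mask].reset_index(drop=True))


def run_experiment(cfg: ExperimentConfig | None = None) -> EvaluationReport:
    """Full cross-session benchmark over simulated subjects.

    For every subject and every leave-one-session-out fold, fits the
    spatial filters and all requested classifiers on the training sessions
    only, predicts the held-out session, merges ternary predictions to
    binary, and scores.  Aggregates Table-style summaries (mean +- SD per
    method), averaged ternary confusion matrices, per-fold CNN AUCs, a
    three-factor ANOVA per response and paired t-tests between methods.
    """
    cfg = cfg or ExperimentConfig()
    records: list[dict] = []
    confusions: dict[str, list[np.ndarray]] = {}
    aucs: dict[str, list[float]] = {}
    failures: list[str] = []
    for subject in range(1, cfg.n_subjects + 1):
        epochs, labels = simulate_subject_epochs(cfg, subject)
        sessions = epochs.events["session_id"].to_numpy()
        plan = make_session_folds(sessions.tolist())
        binary = merge_to_binary(labels)
        for train_ids, test_id in plan.folds:
            train_mask = np.isin(sessions, train_ids)
            test_mask = sessions == test_id
            for method in cfg.methods:
                seed = derive_seed(cfg.seed, "fit", subject, test_id, method)
                try:
                    pred_bin, prob, tern = _fit_predict_method(
                        method, cfg, epochs, labels, train_mask, test_mask, seed)
                except Exception as exc:  # recorded, not silently dropped
                    failures.append(f"subject {subject} fold {test_id} {method}: {exc}")
                    continue
                sc = binary_scores(binary[test_mask], pred_bin)
                records.append({"subject": subject, "method": method,
                                "fold": test_id, **sc})
                if tern is not None:
                    cm = confusion_ternary(labels[test_mask], tern)
                    confusions.setdefault(method, []).append(cm.percentages)
                if method.startswith("cnn"):
                    try:
                        roc = roc_curve_and_auc(prob, binary[test_mask])
                        aucs.setdefault(method, []).append(roc["auc"])
                    except ValueError:
                        pass
    scores = pd.DataFrame(records)
    summary = scores.groupby("method")[["recall", "precision", "f1", "accuracy"]].agg(
        ["mean", "std"])
    mean_conf = {m: np.nanmean(np.stack(v), axis=0) for m, v in confusions.items()}
    anova = {}
    ttests = {}
    if not scores.empty and scores["method"].nunique() >= 2 and not failures:
        for response in ("recall", "precision", "f1", "accuracy"):
            try:
                anova[response] = anova_three_factor(scores, response)
            except ValueError as exc:
                logger.warning("ANOVA skipped for %s: %s", response, exc)
        methods = list(cfg.methods)
        for i, ma in enumerate(methods):
            for mb in methods[i + 1:]:
                a = scores[scores.method == ma].sort_values(["subject", "fold"])
                b = scores[scores.method == mb].sort_values(["subject", "fold"])
                for response in ("recall", "precision", "f1", "accuracy"):
                    try:
                        ttests[(ma, mb, response)] = paired_ttest(
                            a[response].to_numpy(), b[response].to_numpy())
                    except ValueError:
                        ttests[(ma, mb, response)] = (np.nan, np.nan)
    return EvaluationReport(scores=scores, summary=summary, confusions=mean_conf,
                            aucs=aucs, anova=anova, ttests=ttests, failures=failures)
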