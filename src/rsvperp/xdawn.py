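"""Overlap-aware evoked estimation and SSNR-maximising spatial filtering.

The front end for the SVM classifier.  Two stages:

1. **Evoked estimation.**  With stimuli only 100 ms apart and responses
   lasting ~1 s, neighbouring evoked responses overlap; the plain
   onset-locked average is biased.  The evoked template ``A`` (channels x
   template_length) is instead the least-squares solution of
   ``X^T ~ D A^T`` where ``D`` is a 0/1 Toeplitz design with a shifted
   identity block per target onset.  On non-overlapping designs this reduces
   exactly to the onset-locked average.

2. **Spatial filtering.**  Filters ``w`` maximise the signal-to-signal-
   plus-noise ratio (SSNR) ``(w' Σ_s w) / (w' Σ_x w)`` where ``Σ_s`` is the
   covariance of the reconstructed evoked time course ``D A^T`` and ``Σ_x``
   the covariance of the full recording.  The maximisers are generalized
   eigenvectors of the pencil ``(Σ_s, Σ_x)``; the Rayleigh quotient — the
   SSNR — lies in [0, 1].  The top ``n_components`` (default 6) filters
   compress the sensor array to a handful of ERP-tuned virtual channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, sparse

from .preprocess import EpochSet
from .simulate import ContinuousRecording

logger = logging.getLogger(__name__)

__all__ = ["XdawnModel", "estimate_evoked_overlap", "fit_xdawn", "transform"]


@dataclass
class XdawnModel:
    """SSNR-maximising spatial filters and the evoked estimate behind them."""

    filters: np.ndarray        # (n_components, channels)
    patterns: np.ndarray       # (channels, n_components)
    ssnr_values: np.ndarray    # descending, in [0, 1]
    evoked_estimate: np.ndarray  # (channels, template_length)
    n_components: int

    def save(self, path) -> None:
        np.savez(path, filters=self.filters, patterns=self.patterns,
                 ssnr_values=self.ssnr_values, evoked_estimate=self.evoked_estimate)

    @classmethod
    def load(cls, path) -> "XdawnModel":
        with np.load(path) as z:
            return cls(z["filters"], z["patterns"], z["ssnr_values"],
                       z["evoked_estimate"], z["filters"].shape[0])


def _toeplitz_design(onsets: np.ndarray, template_length: int, n_samples: int) -> sparse.csr_matrix:
    """Sparse (n_samples x template_length) design: row o+k has a 1 in column k."""
    rows, cols = [], []
    for o in onsets:
        ks = np.arange(template_length)
        keep = (o + ks) < n_samples
        rows.append(o + ks[keep])
        cols.append(ks[keep])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    return sparse.csr_matrix((np.ones(len(rows)), (rows, cols)),
                             shape=(n_samples, template_length))


def estimate_evoked_overlap(recording: ContinuousRecording, target_onsets,
                            template_length: int) -> np.ndarray:
    """Least-squares evoked estimate that accounts for overlapping responses.

    Solves ``min_A || X^T - D A^T ||_F`` channel-wise via the normal
    equations; falls back to a small ridge when the design is singular
    (e.g. fewer informative rows than template samples).
    Returns channels x template_length.
    """
    onsets = np.asarray(target_onsets, dtype=int)
    if template_length < 1:
        raise ValueError("template_length must be >= 1")
    if onsets.size == 0:
        raise ValueError("need at least one target onset")
    X = recording.data
    D = _toeplitz_design(onsets, template_length, X.shape[1])
    gram = (D.T @ D).toarray()
    rhs = D.T @ X.T  # (L, channels)
    try:
        evoked_t = linalg.solve(gram, rhs, assume_a="pos")
    except linalg.LinAlgError:
        ridge = 1e-8 * np.trace(gram) / template_length
        logger.warning("singular evoked design; applying ridge %.3g", ridge)
        evoked_t = linalg.solve(gram + ridge * np.eye(template_length), rhs, assume_a="pos")
    return evoked_t.T


def _shrink(cov: np.ndarray, cond_limit: float = 1e8) -> np.ndarray:
    """Scalar (trace-scaled) shrinkage when the covariance is ill-conditioned."""
    cond = np.linalg.cond(cov)
    if cond <= cond_limit:
        return cov
    gamma = 1e-6
    target = np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
    while np.linalg.cond((1 - gamma) * cov + gamma * target) > cond_limit and gamma < 0.5:
        gamma *= 10
    logger.info("covariance condition %.2g; shrinking with gamma=%.1g", cond, gamma)
    return (1 - gamma) * cov + gamma * target


def _fit_from_signal_total(sig_cov: np.ndarray, tot_cov: np.ndarray,
                           evoked: np.ndarray, n_components: int) -> XdawnModel:
    n_ch = tot_cov.shape[0]
    if n_components > n_ch:
        raise ValueError("n_components cannot exceed channel count")
    tot_cov = _shrink(tot_cov)
    vals, vecs = linalg.eigh(sig_cov, tot_cov)
    order = np.argsort(vals)[::-1][:n_components]
    ssnr = np.clip(vals[order], 0.0, 1.0)
    filters = vecs[:, order].T
    # patterns: project total covariance back through the filters
    inner = filters @ tot_cov @ filters.T
    patterns = tot_cov @ filters.T @ linalg.pinv(inner)
    return XdawnModel(filters=filters, patterns=patterns, ssnr_values=ssnr,
                      evoked_estimate=evoked, n_components=n_components)


def fit_xdawn(data, target_onsets=None, template_length: int | None = None,
              n_components: int = 6) -> XdawnModel:
    """Fit SSNR-maximising filters from continuous or epoched data.

    Continuous entry point: ``data`` is a :class:`ContinuousRecording`,
    ``target_onsets`` sample indices of target stimuli, ``template_length``
    the evoked window in samples (defaults to the epoch length, 140 at the
    standard 100 Hz window).  Epoched entry point: ``data`` is an
    :class:`EpochSet` whose events carry a "class" column; the evoked
    estimate is the target-epoch average.
    """
    if isinstance(data, ContinuousRecording):
        if target_onsets is None:
            raise ValueError("continuous fitting requires target_onsets")
        if template_length is None:
            template_length = int(round(1.4 * data.sampling_rate))
        evoked = estimate_evoked_overlap(data, target_onsets, template_length)
        D = _toeplitz_design(np.asarray(target_onsets, dtype=int), template_length,
                             data.n_samples)
        sig = (D @ evoked.T).T             # reconstructed evoked time course
        sig_cov = sig @ sig.T / sig.shape[1]
        tot_cov = data.data @ data.data.T / data.n_samples
        return _fit_from_signal_total(sig_cov, tot_cov, evoked, n_components)
    if isinstance(data, EpochSet):
        is_target = (data.events["class"] == "target").to_numpy()
        if not is_target.any():
            raise ValueError("no target epochs to fit on")
        evoked = data.data[is_target].mean(axis=0)
        sig_cov = evoked @ evoked.T / evoked.shape[1]
        flat = np.concatenate(list(data.data), axis=1)
        tot_cov = flat @ flat.T / flat.shape[1]
        return _fit_from_signal_total(sig_cov, tot_cov, evoked, n_components)
    raise TypeError("data must be a ContinuousRecording or an EpochSet")


def transform(model: XdawnModel, epochs: EpochSet, flatten: bool = False) -> np.ndarray:
    """Apply the spatial filters to every epoch.

    Returns epochs x components x timepoints, or epochs x
    (components*timepoints) when ``flatten`` — 6 x 140 -> 840-vectors with
    the standard configuration, the SVM's input.
    """
    if epochs.n_channels != model.filters.shape[1]:
        raise ValueError(
            f"epoch channel count {epochs.n_channels} != model channels {model.filters.shape[1]}")
    out = np.einsum("kc,ect->ekt", model.filters, epochs.data)
    if flatten:
        return out.reshape(out.shape[0], -1)
    return out
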