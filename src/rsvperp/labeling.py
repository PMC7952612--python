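"""Ternary labels for overlapping RSVP epochs.

At a 10 Hz presentation rate with 1.4 s epochs, neighbouring epochs overlap
heavily: a non-target flashed shortly before or after a target still has the
target's evoked response inside its window, only at the "wrong" latency.
Labelling those neighbours as a third class — *near-non-target* — lets a
classifier learn that distinction explicitly instead of treating it as
noise:

* 1 = target,
* 2 = far-non-target (no target onset within the proximity window),
* 3 = near-non-target (a target onset within ``near_window`` seconds).

At evaluation time the two non-target codes are merged back to a single
binary "nontarget", so the ternary trick is invisible to the downstream
task.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .simulate import EventTable

logger = logging.getLogger(__name__)

__all__ = [
    "TARGET",
    "FAR_NONTARGET",
    "NEAR_NONTARGET",
    "assign_ternary_labels",
    "nearest_target_distance",
    "merge_to_binary",
    "balanced_sample",
]

TARGET = 1
FAR_NONTARGET = 2
NEAR_NONTARGET = 3

_VALID_CODES = frozenset({TARGET, FAR_NONTARGET, NEAR_NONTARGET})


def _check_sorted(frame: pd.DataFrame) -> None:
    for sid, grp in frame.groupby("session_id", sort=False):
        if not np.all(np.diff(grp["onset_time"].to_numpy()) >= 0):
            raise ValueError(f"events not sorted by onset within session {sid}")


def nearest_target_distance(events: EventTable, mode: str = "symmetric") -> np.ndarray:
    """Per-event distance (s) to the nearest target onset in the same session.

    ``mode`` restricts which side counts: "symmetric" (either direction,
    default), "before_only" (only targets preceding the event) or
    "after_only" (only targets following it).  Events in sessions with no
    (eligible) target get ``inf``; distances never cross session boundaries.
    """
    if mode not in ("symmetric", "before_only", "after_only"):
        raise ValueError(f"unknown mode {mode!r}")
    frame = events.frame
    _check_sorted(frame)
    dist = np.full(len(frame), np.inf)
    for _, grp in frame.groupby("session_id", sort=False):
        onsets = grp["onset_time"].to_numpy()
        targ = onsets[(grp["class"] == "target").to_numpy()]
        if len(targ) == 0:
            continue
        delta = onsets[:, None] - targ[None, :]  # >0: target earlier
        if mode == "before_only":
            delta = np.where(delta >= 0, delta, np.inf)
        elif mode == "after_only":
            delta = np.where(delta <= 0, -delta, np.inf)
        else:
            delta = np.abs(delta)
        dist[grp.index.to_numpy()] = delta.min(axis=1)
    return dist


def assign_ternary_labels(events: EventTable, near_window: float = 0.5,
                          mode: str = "symmetric") -> np.ndarray:
    """Assign codes 1/2/3 to every event.

    Targets are always 1 (a target near another target stays a target).
    Non-targets within ``near_window`` seconds — inclusive — of a target
    onset in the same session become 3, all others 2.  On the 10 Hz grid a
    symmetric inclusive 0.5 s window converts exactly the five stimuli on
    each side of an isolated target.
    """
    if near_window <= 0:
        raise ValueError("near_window must be > 0")
    dist = nearest_target_distance(events, mode=mode)
    is_target = (events.frame["class"] == "target").to_numpy()
    labels = np.where(dist <= near_window, NEAR_NONTARGET, FAR_NONTARGET)
    labels[is_target] = TARGET
    return labels.astype(int)


def merge_to_binary(labels) -> np.ndarray:
    """Collapse ternary codes to binary strings: 1 -> "target", {2,3} -> "nontarget"."""
    labels = np.asarray(labels, dtype=int)
    unknown = set(np.unique(labels)) - _VALID_CODES
    if unknown:
        raise ValueError(f"unknown label codes: {sorted(unknown)}")
    return np.where(labels == TARGET, "target", "nontarget")


def balanced_sample(labels, n_total: int = 300, seed: int = 0,
                    with_replacement: str = "auto", classes=None) -> np.ndarray:
    """Class-balanced epoch indices: ``n_total // n_classes`` per class.

    Sampling is without replacement whenever the class is large enough,
    with replacement otherwise (logged).  ``classes`` fixes the expected
    class set (an expected class absent from ``labels`` is an error).  Used
    to build the CNN's balanced training batches (300 per epoch at full
    scale).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels) if classes is None else np.asarray(classes)
    per_class = n_total // len(classes)
    if per_class < 1:
        raise ValueError("n_total too small for the number of classes")
    rng = np.random.default_rng(seed)
    picks = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) == 0:
            raise ValueError(f"cannot balance: class {c} is empty")
        replace = len(idx) < per_class
        if replace and with_replacement == "never":
            raise ValueError(f"class {c} has {len(idx)} < {per_class} members")
        if replace:
            logger.info("class %s has %d < %d members; sampling with replacement",
                        c, len(idx), per_class)
        picks.append(rng.choice(idx, size=per_class, replace=replace))
    out = np.concatenate(picks)
    rng.shuffle(out)
    return out
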