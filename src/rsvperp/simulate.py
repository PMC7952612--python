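"""Synthetic RSVP sessions with known ground truth.

Emulates a rapid-serial-visual-presentation oddball experiment: pictures
flashed at a fixed rate (default 10 Hz, no gaps), a small fraction of them
targets, organised into blocks and sessions.  The synthesized multichannel
recording contains

* a low-frequency (Delta-band) evoked response following *target* onsets
  only, peaking near 300 ms with trial-to-trial latency jitter — the
  P300-like oddball response;
* a steady-state visual evoked response (SSVEP) at the presentation rate,
  present throughout each block regardless of stimulus class;
* 1/f^alpha ("pink") sensor noise plus white noise;
* optionally, rank-1 high-amplitude blink-like transients.

All generation is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StimulusPool",
    "EventTable",
    "ContinuousRecording",
    "SimConfig",
    "make_stimulus_pool",
    "make_block",
    "make_session",
    "synthesize_recording",
    "inject_blink_artifacts",
    "erp_template",
    "visual_angle_deg",
]

EVENT_COLUMNS = ["onset_sample", "onset_time", "class", "picture_id", "block_id", "session_id"]


def visual_angle_deg(extent_mm: float, distance_mm: float) -> float:
    """Visual angle (degrees) subtended by ``extent_mm`` viewed at ``distance_mm``.

    Standard full-angle formula ``2*atan(extent / (2*distance))``; a 150 mm
    stimulus at 680 mm subtends 12.6 degrees.
    """
    if extent_mm <= 0 or distance_mm <= 0:
        raise ValueError("extent and distance must be positive")
    return math.degrees(2.0 * math.atan2(extent_mm / 2.0, distance_mm))


@dataclass(frozen=True)
class StimulusPool:
    """A picture pool partitioned into disjoint target / non-target id sets."""

    n_pictures: int
    target_fraction: float
    target_ids: np.ndarray
    nontarget_ids: np.ndarray

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_nontargets(self) -> int:
        return len(self.nontarget_ids)


@dataclass
class EventTable:
    """Stimulus onsets with class, picture, block and session identifiers.

    ``frame`` columns: onset_sample, onset_time, class ("target"/"nontarget"),
    picture_id, block_id, session_id.  Onsets are strictly increasing within
    a block and ``onset_time == onset_sample / sampling_rate`` everywhere.
    """

    frame: pd.DataFrame
    sampling_rate: float
    presentation_rate: float

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.attrs = {}
        header = f"# sampling_rate={self.sampling_rate} presentation_rate={self.presentation_rate}\n"
        with open(path, "w") as fh:
            fh.write(header)
            out.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventTable":
        with open(path) as fh:
            first = fh.readline()
            meta = dict(tok.split("=") for tok in first.lstrip("# ").split())
            frame = pd.read_csv(fh)
        return cls(frame, float(meta["sampling_rate"]), float(meta["presentation_rate"]))


@dataclass
class ContinuousRecording:
    """channels x samples signal with sampling-rate metadata."""

    data: np.ndarray  # (n_channels, n_samples)
    sampling_rate: float
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise ValueError("data must be a channels x samples matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channel_ids:
            self.channel_ids = [f"CH{i:03d}" for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(self.data.copy(), self.sampling_rate, list(self.channel_ids))

    def to_npz(self, path) -> None:
        np.savez(path, data=self.data, sfreq=self.sampling_rate,
                 channel_ids=np.asarray(self.channel_ids))

    @classmethod
    def from_npz(cls, path) -> "ContinuousRecording":
        with np.load(path, allow_pickle=False) as z:
            return cls(z["data"], float(z["sfreq"]), [str(c) for c in z["channel_ids"]])


@dataclass
class SimConfig:
    """Signal-model parameters for :func:`synthesize_recording`.

    Amplitudes are in arbitrary field-strength units; spatial patterns are
    unit-norm vectors over channels (generated from the seed when omitted).
    """

    n_channels: int = 16
    erp_peak_latency: float = 0.30      # s after onset; classic P300 latency
    erp_latency_jitter_sd: float = 0.03  # s, Gaussian truncated at +-2 SD
    erp_width_sd: float = 0.08          # s, Gaussian pulse width
    erp_amplitude: float = 1.0
    erp_spatial_pattern: np.ndarray | None = None
    ssvep_amplitude: float = 0.5
    ssvep_spatial_pattern: np.ndarray | None = None
    noise_spectrum_exponent: float = 1.0  # alpha in 1/f^alpha
    pink_noise_sd: float = 0.5
    white_noise_sd: float = 0.5
    blink_rate: float = 0.0             # events/s
    blink_amplitude: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("erp_amplitude", "ssvep_amplitude", "pink_noise_sd",
                     "white_noise_sd", "blink_rate", "blink_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")

    def resolved_patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """ERP and SSVEP spatial patterns as unit vectors (seeded defaults)."""
        rng = np.random.default_rng(self.seed)
        erp = self.erp_spatial_pattern
        if erp is None:
            erp = rng.standard_normal(self.n_channels)
        erp = np.asarray(erp, dtype=float)
        erp = erp / np.linalg.norm(erp)
        ssvep = self.ssvep_spatial_pattern
        if ssvep is None:
            ssvep = rng.standard_normal(self.n_channels)
        ssvep = np.asarray(ssvep, dtype=float)
        ssvep = ssvep / np.linalg.norm(ssvep)
        return erp, ssvep


def make_stimulus_pool(n_pictures: int, target_fraction: float, seed: int = 0) -> StimulusPool:
    """Partition ``n_pictures`` ids into target / non-target sets.

    The target set size is ``round(n_pictures * target_fraction)`` using
    banker's rounding; with the experiment's 1400 pictures at 4% this gives
    56 targets and 1344 non-targets.
    """
    if not isinstance(n_pictures, (int, np.integer)) or n_pictures < 1:
        raise ValueError("n_pictures must be a positive integer")
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must be in [0, 1]")
    n_targets = int(round(n_pictures * target_fraction))
    rng = np.random.default_rng(seed)
    ids = rng.permutation(n_pictures)
    return StimulusPool(
        n_pictures=int(n_pictures),
        target_fraction=float(target_fraction),
        target_ids=np.sort(ids[:n_targets]),
        nontarget_ids=np.sort(ids[n_targets:]),
    )


def _onset_step(sampling_rate: float, presentation_rate: float) -> int:
    step = sampling_rate / presentation_rate
    if abs(step - round(step)) > 1e-9:
        raise ValueError(
            f"sampling_rate {sampling_rate} not divisible by presentation_rate "
            f"{presentation_rate}: onsets would fall between samples")
    return int(round(step))


def _order_with_gap(n_total: int, n_targets: int, min_target_gap: int,
                    rng: np.random.Generator, max_tries: int = 10_000) -> np.ndarray:
    """Boolean mask of target positions, consecutive targets >= gap apart."""
    for _ in range(max_tries):
        pos = np.sort(rng.choice(n_total, size=n_targets, replace=False))
        if n_targets < 2 or np.all(np.diff(pos) >= max(min_target_gap, 1)):
            mask = np.zeros(n_total, dtype=bool)
            mask[pos] = True
            return mask
    raise RuntimeError("could not satisfy min_target_gap; gap too large for block")


def make_block(pool: StimulusPool, block_size: int = 100, target_fraction: float = 0.04,
               presentation_rate: float = 10.0, sampling_rate: float = 100.0,
               start_sample: int = 0, min_target_gap: int = 0, seed: int = 0,
               block_id: int = 1, session_id: int = 1) -> EventTable:
    """One RSVP block: ``block_size`` gap-free onsets in random order.

    Exactly ``round(block_size * target_fraction)`` targets, pictures sampled
    from the pool without replacement.
    """
    n_targets = int(round(block_size * target_fraction))
    n_non = block_size - n_targets
    if n_targets > pool.n_targets or n_non > pool.n_nontargets:
        raise ValueError("stimulus pool exhausted: not enough pictures for block")
    step = _onset_step(sampling_rate, presentation_rate)
    rng = np.random.default_rng(seed)
    targ_pics = rng.choice(pool.target_ids, size=n_targets, replace=False)
    non_pics = rng.choice(pool.nontarget_ids, size=n_non, replace=False)
    if min_target_gap > 0:
        mask = _order_with_gap(block_size, n_targets, min_target_gap, rng)
    else:
        mask = np.zeros(block_size, dtype=bool)
        mask[rng.choice(block_size, size=n_targets, replace=False)] = True
    pics = np.empty(block_size, dtype=int)
    pics[mask] = targ_pics
    pics[~mask] = non_pics
    onsets = start_sample + step * np.arange(block_size)
    frame = pd.DataFrame({
        "onset_sample": onsets.astype(int),
        "onset_time": onsets / sampling_rate,
        "class": np.where(mask, "target", "nontarget"),
        "picture_id": pics,
        "block_id": block_id,
        "session_id": session_id,
    })
    return EventTable(frame, sampling_rate, presentation_rate)


def make_session(pool: StimulusPool, n_blocks: int = 14, block_size: int = 100,
                 target_fraction: float = 0.04, presentation_rate: float = 10.0,
                 sampling_rate: float = 100.0, inter_block_gap: float = 2.0,
                 seed: int = 0, session_id: int = 1, start_sample: int = 0) -> EventTable:
    """Concatenate ``n_blocks`` blocks with an inter-block gap (default 2 s).

    Pictures are consumed from the pool without replacement across the whole
    session, so 14 blocks of 100 at 4% exhaust the 1400-picture pool exactly.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    n_targets_pb = int(round(block_size * target_fraction))
    n_non_pb = block_size - n_targets_pb
    if n_blocks * n_targets_pb > pool.n_targets or n_blocks * n_non_pb > pool.n_nontargets:
        raise ValueError("stimulus pool exhausted: session needs more pictures than pool holds")
    rng = np.random.default_rng(seed)
    targ_order = rng.permutation(pool.target_ids)
    non_order = rng.permutation(pool.nontarget_ids)
    step = _onset_step(sampling_rate, presentation_rate)
    gap_samples = int(round(inter_block_gap * sampling_rate))
    frames = []
    offset = start_sample
    for b in range(n_blocks):
        sub = StimulusPool(
            n_pictures=block_size, target_fraction=target_fraction,
            target_ids=targ_order[b * n_targets_pb:(b + 1) * n_targets_pb],
            nontarget_ids=non_order[b * n_non_pb:(b + 1) * n_non_pb])
        blk = make_block(sub, block_size, target_fraction, presentation_rate,
                         sampling_rate, start_sample=offset,
                         seed=int(rng.integers(2**31)), block_id=b + 1,
                         session_id=session_id)
        frames.append(blk.frame)
        offset += step * block_size + gap_samples
    frame = pd.concat(frames, ignore_index=True)
    return EventTable(frame, sampling_rate, presentation_rate)


def erp_template(sampling_rate: float, peak_latency: float = 0.30,
                 width_sd: float = 0.08, duration: float = 0.8) -> np.ndarray:
    """Positive unimodal Gaussian pulse; energy concentrated below 4 Hz.

    Sampled on [0, duration) at ``sampling_rate``; peak value 1 at
    ``peak_latency``.
    """
    t = np.arange(int(round(duration * sampling_rate))) / sampling_rate
    return np.exp(-0.5 * ((t - peak_latency) / width_sd) ** 2)


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                exponent: float, sd: float, sampling_rate: float) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha amplitude spectrum, unit-SD rescaled."""
    if sd == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    spec = np.fft.rfft(white, axis=1) * shaping
    pink = np.fft.irfft(spec, n=n_samples, axis=1)
    scale = pink.std(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return sd * pink / scale


def _block_intervals(events: EventTable) -> list[tuple[int, int]]:
    """(start_sample, end_sample) per (session, block), end one frame past last onset."""
    step = _onset_step(events.sampling_rate, events.presentation_rate)
    out = []
    for _, grp in events.frame.groupby(["session_id", "block_id"], sort=True):
        out.append((int(grp.onset_sample.min()), int(grp.onset_sample.max()) + step))
    return out


def synthesize_recording(events: EventTable, cfg: SimConfig,
                         duration: float | None = None,
                         tail: float = 2.0) -> ContinuousRecording:
    """Render an event table into a continuous multichannel recording.

    Linear superposition of target-locked ERP pulses (rank-1 in space,
    jittered latency), a block-gated SSVEP at the presentation rate, pink
    noise and white noise.  ``duration`` defaults to the last onset plus
    ``tail`` seconds.
    """
    fs = events.sampling_rate
    last_onset = int(events.frame.onset_sample.max()) if len(events) else 0
    if duration is None:
        n_samples = last_onset + int(round(tail * fs))
    else:
        n_samples = int(round(duration * fs))
        if last_onset >= n_samples:
            raise ValueError("event onset beyond requested recording duration")
    erp_pat, ssvep_pat = cfg.resolved_patterns()
    data = np.zeros((cfg.n_channels, n_samples))

    rng = np.random.default_rng(cfg.seed)
    template = erp_template(fs, cfg.erp_peak_latency, cfg.erp_width_sd)
    targets = events.frame[events.frame["class"] == "target"]
    jitters = rng.standard_normal(len(targets)) * cfg.erp_latency_jitter_sd
    np.clip(jitters, -2 * cfg.erp_latency_jitter_sd, 2 * cfg.erp_latency_jitter_sd, out=jitters)
    if cfg.erp_amplitude > 0:
        for (onset, jit) in zip(targets.onset_sample.to_numpy(), jitters):
            start = int(onset) + int(round(jit * fs))
            stop = min(start + len(template), n_samples)
            if stop <= start:
                continue
            seg = template[: stop - start]
            data[:, start:stop] += cfg.erp_amplitude * np.outer(erp_pat, seg)

    if cfg.ssvep_amplitude > 0 and len(events):
        t = np.arange(n_samples) / fs
        carrier = np.sin(2 * np.pi * events.presentation_rate * t)
        gate = np.zeros(n_samples)
        for (a, b) in _block_intervals(events):
            gate[a:min(b, n_samples)] = 1.0
        data += cfg.ssvep_amplitude * np.outer(ssvep_pat, carrier * gate)

    data += _pink_noise(rng, cfg.n_channels, n_samples,
                        cfg.noise_spectrum_exponent, cfg.pink_noise_sd, fs)
    if cfg.white_noise_sd > 0:
        data += cfg.white_noise_sd * rng.standard_normal((cfg.n_channels, n_samples))

    rec = ContinuousRecording(data, fs)
    if cfg.blink_rate > 0:
        rec = inject_blink_artifacts(rec, cfg.blink_rate, cfg.blink_amplitude,
                                     seed=cfg.seed + 1)
    return rec


def inject_blink_artifacts(recording: ContinuousRecording, rate: float,
                           amplitude: float, spatial_pattern: np.ndarray | None = None,
                           seed: int = 0, width: float = 0.15) -> ContinuousRecording:
    """Add rank-1 low-frequency blink-like transients at Poisson times.

    ``rate`` is events per second; rate 0 returns the input unchanged.
    Blinks are smooth positive bumps (Gaussian, ``width`` s SD) projected on a
    single high-amplitude spatial pattern, mimicking ocular artifacts.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if rate == 0:
        return recording
    rng = np.random.default_rng(seed)
    fs = recording.sampling_rate
    n = recording.n_samples
    if spatial_pattern is None:
        spatial_pattern = np.zeros(recording.n_channels)
        front = max(1, recording.n_channels // 4)
        spatial_pattern[:front] = 1.0
    spatial_pattern = np.asarray(spatial_pattern, dtype=float)
    spatial_pattern = spatial_pattern / np.linalg.norm(spatial_pattern)
    n_blinks = rng.poisson(rate * n / fs)
    times = np.sort(rng.uniform(0, n / fs, size=n_blinks))
    bump = np.exp(-0.5 * ((np.arange(int(6 * width * fs)) / fs - 3 * width) / width) ** 2)
    out = recording.data.copy()
    for t0 in times:
        start = int(round(t0 * fs))
        stop = min(start + len(bump), n)
        if stop <= start:
            continue
        out[:, start:stop] += amplitude * np.outer(spatial_pattern, bump[: stop - start])
    return ContinuousRecording(out, fs, list(recording.channel_ids))
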