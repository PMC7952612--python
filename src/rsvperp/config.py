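"""Run configuration: a validated, serialisable view of every knob.

A single YAML file (or an empty one, meaning all defaults) configures the
whole pipeline.  Unknown keys are rejected and validation errors name the
offending key, so typos fail loudly.  The ``scale`` preset switches between
the fast desk-scale study and the full-scale deployment geometry
(272 channels, 14 blocks, 11 sessions, 500 CNN epochs).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .classifiers import CnnSpec, SvmSpec
from .evaluate import ExperimentConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised with a message naming every invalid or unknown key."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SimulateSection(_Section):
    n_subjects: int = Field(2, ge=1)
    n_sessions: int = Field(3, ge=2)
    n_blocks: int = Field(4, ge=1)
    block_size: int = Field(100, ge=1)
    target_fraction: float = Field(0.04, ge=0.0, le=1.0)
    presentation_rate: float = Field(10.0, gt=0)
    sampling_rate: float = Field(100.0, gt=0)
    n_channels: int = Field(16, ge=1)
    erp_amplitude: float = Field(5.0, ge=0)
    erp_peak_latency: float = Field(0.30, gt=0)
    erp_latency_jitter_sd: float = Field(0.02, ge=0)
    ssvep_amplitude: float = Field(0.5, ge=0)
    pink_noise_sd: float = Field(0.5, ge=0)
    white_noise_sd: float = Field(0.5, ge=0)
    blink_rate: float = Field(0.0, ge=0)


class PreprocessSection(_Section):
    band_low_hz: float = Field(0.1, gt=0)
    band_high_hz: float = Field(15.0, gt=0)
    resample_to_hz: float | None = None
    tmin: float = -0.2
    tmax: float = 1.2
    ica_reject: bool = False
    ica_z_threshold: float = Field(3.0, gt=0)


class LabelingSection(_Section):
    near_window: float = Field(0.5, gt=0)
    mode: str = Field("symmetric", pattern="^(symmetric|before_only|after_only)$")


class XdawnSection(_Section):
    n_components: int = Field(6, ge=1)


class SvmSection(_Section):
    C: float = Field(1.0, gt=0)
    gamma: str | float = "scale"
    class_weight: str | None = "balanced"


class CnnSection(_Section):
    temporal_filters: int = Field(8, ge=1)
    temporal_kernel: int = Field(11, ge=2)
    spatial_filters: int = Field(16, ge=1)
    block_filters: tuple[int, ...] = (32,)
    block_kernel: int = Field(5, ge=2)
    pool_size: int = Field(3, ge=1)
    learning_rate: float = Field(1e-3, gt=0)
    lr_decay: float = Field(0.8, gt=0, le=1)
    lr_step: int = Field(50, ge=1)
    n_epochs: int = Field(100, ge=1)
    batch_size: int = Field(90, ge=2)
    minibatch_size: int = Field(30, ge=1)


class EvaluateSection(_Section):
    methods: tuple[str, ...] = ("svm_binary", "svm_ternary", "cnn_binary", "cnn_ternary")


class RunConfig(_Section):
    """Top-level configuration with nested per-module sections."""

    seed: int = 0
    out_dir: str = "runs"
    scale: str = Field("desk", pattern="^(desk|full)$")
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    labeling: LabelingSection = Field(default_factory=LabelingSection)
    xdawn: XdawnSection = Field(default_factory=XdawnSection)
    svm: SvmSection = Field(default_factory=SvmSection)
    cnn: CnnSection = Field(default_factory=CnnSection)
    evaluate: EvaluateSection = Field(default_factory=EvaluateSection)

    def apply_scale(self) -> "RunConfig":
        """Return a copy with the full-scale geometry when scale == "full"."""
        if self.scale != "full":
            return self
        full = self.model_copy(deep=True)
        full.simulate.n_channels = 272
        full.simulate.n_blocks = 14
        full.simulate.n_sessions = 11
        fs = CnnSpec.full_scale()
        for name in ("temporal_filters", "temporal_kernel", "spatial_filters",
                     "block_filters", "block_kernel", "pool_size", "n_epochs",
                     "batch_size", "minibatch_size"):
            setattr(full.cnn, name, getattr(fs, name))
        return full

    def experiment_config(self) -> ExperimentConfig:
        """Flatten into the :class:`ExperimentConfig` the evaluator consumes."""
        s = self.simulate
        return ExperimentConfig(
            n_subjects=s.n_subjects, n_sessions=s.n_sessions, n_blocks=s.n_blocks,
            block_size=s.block_size, target_fraction=s.target_fraction,
            presentation_rate=s.presentation_rate, sampling_rate=s.sampling_rate,
            n_channels=s.n_channels, erp_amplitude=s.erp_amplitude,
            erp_latency_jitter_sd=s.erp_latency_jitter_sd,
            ssvep_amplitude=s.ssvep_amplitude, pink_noise_sd=s.pink_noise_sd,
            white_noise_sd=s.white_noise_sd, near_window=self.labeling.near_window,
            labeling_mode=self.labeling.mode, xdawn_components=self.xdawn.n_components,
            svm=SvmSpec(C=self.svm.C, gamma=self.svm.gamma,
                        class_weight=self.svm.class_weight),
            cnn_epochs=self.cnn.n_epochs, cnn_batch=self.cnn.batch_size,
            methods=self.evaluate.methods, seed=self.seed,
        )

    def cnn_spec(self, n_classes: int, n_channels: int, n_times: int = 140) -> CnnSpec:
        c = self.cnn
        return CnnSpec(n_channels=n_channels, n_times=n_times, n_classes=n_classes,
                       temporal_filters=c.temporal_filters, temporal_kernel=c.temporal_kernel,
                       spatial_filters=c.spatial_filters, block_filters=tuple(c.block_filters),
                       block_kernel=c.block_kernel, pool_size=c.pool_size,
                       learning_rate=c.learning_rate, lr_decay=c.lr_decay,
                       lr_step=c.lr_step, n_epochs=c.n_epochs,
                       batch_size=c.batch_size, minibatch_size=c.minibatch_size)


def _format_errors(exc: ValidationError) -> str:
    msgs = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        msgs.append(f"{loc}: {err['msg']}")
    return "; ".join(msgs)


def load_config(path) -> RunConfig:
    """Read, validate and default-fill a YAML config file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_errors(exc)) from exc


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False))
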