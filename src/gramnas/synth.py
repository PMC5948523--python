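"""Synthetic role-tagged multichannel sensor recordings.

Emulates the raw-table shape the preprocessing chain expects: a
whitespace-separated timestep x channel table with a label column, a schema
file tagging each column's role, class-dependent body-channel signatures
(offset plus sinusoid, so temporal context matters), label-independent
quaternion/object-environment noise channels, and missing values occurring
in runs (as dropped wireless-sensor connections do).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import ChannelSchema, SensorFrame

__all__ = [
    "SynthConfig",
    "SegmentTable",
    "generate_frame",
    "opportunity_like_fixture",
    "schema_for_config",
]


@dataclass(frozen=True)
class SynthConfig:
    n_classes: int = 3                 # including the null class 0
    n_body: int = 8
    n_quaternion: int = 0
    n_object_env: int = 0
    n_timesteps: int = 6000
    mean_bout_length: int = 60         # activity segment length (timesteps)
    min_bout_length: int = 20
    mean_null_length: int = 30
    signature_offset_scale: float = 1.0
    signature_amplitude: float = 0.5
    noise_scale: float = 0.1
    missing_run_rate: float = 0.0      # expected runs per 1000 timesteps/channel
    mean_missing_run_length: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least a null class and one activity")
        if self.n_body < 1:
            raise ValueError("need at least one body channel")
        if min(self.n_quaternion, self.n_object_env, self.n_timesteps) < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_scale < 0:
            raise ValueError("noise scale must be non-negative")
        if self.missing_run_rate < 0:
            raise ValueError("missing run rate must be non-negative")


@dataclass
class SegmentTable:
    """Ground-truth activity bouts: (start, end) half-open, label."""

    starts: np.ndarray
    ends: np.ndarray
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.labels)


def schema_for_config(config: SynthConfig) -> ChannelSchema:
    names, roles = [], []
    for i in range(config.n_body):
        names.append(f"body_{i}")
        roles.append("body")
    for i in range(config.n_quaternion):
        names.append(f"quat_{i}")
        roles.append("quaternion")
    for i in range(config.n_object_env):
        names.append(f"objenv_{i}")
        roles.append("object_env")
    names.append("label")
    roles.append("label")
    return ChannelSchema(names=tuple(names), roles=tuple(roles))


def _label_sequence(config: SynthConfig, rng: np.random.Generator):
    """Alternating null stretches and activity bouts."""
    T = config.n_timesteps
    labels = np.zeros(T, dtype=int)
    starts, ends, seg_labels = [], [], []
    t = 0
    while t < T:
        null_len = int(rng.exponential(config.mean_null_length)) + 1
        t_start = min(t + null_len, T)
        if t_start >= T:
            break
        bout = config.min_bout_length + int(
            rng.exponential(max(1, config.mean_bout_length - config.min_bout_length))
        )
        t_end = min(t_start + bout, T)
        cls = int(rng.integers(1, config.n_classes))
        labels[t_start:t_end] = cls
        starts.append(t_start)
        ends.append(t_end)
        seg_labels.append(cls)
        t = t_end
    table = SegmentTable(
        starts=np.array(starts, dtype=int),
        ends=np.array(ends, dtype=int),
        labels=np.array(seg_labels, dtype=int),
    )
    return labels, table


def _signatures(config: SynthConfig, rng: np.random.Generator):
    """Per (class, body channel): offset, sinusoid amplitude and frequency.

    The null class emits a zero signature.  Offsets are spread evenly across
    classes with per-channel jitter so classes separate at modest noise.
    """
    K, C = config.n_classes, config.n_body
    offsets = np.zeros((K, C))
    amps = np.zeros((K, C))
    freqs = np.zeros((K, C))
    for k in range(1, K):
        offsets[k] = (
            k * config.signature_offset_scale
            + rng.normal(0, 0.1 * config.signature_offset_scale, size=C)
        )
        amps[k] = config.signature_amplitude * rng.uniform(0.5, 1.0, size=C)
        freqs[k] = rng.uniform(0.02, 0.1, size=C)  # cycles per timestep
    return offsets, amps, freqs


def _insert_missing_runs(
    mask: np.ndarray, config: SynthConfig, rng: np.random.Generator
) -> None:
    if config.missing_run_rate == 0:
        return
    T, C = mask.shape
    expected_runs = config.missing_run_rate * T / 1000.0
    for c in range(C):
        for _ in range(rng.poisson(expected_runs)):
            length = int(rng.exponential(config.mean_missing_run_length)) + 1
            start = int(rng.integers(0, max(1, T - length)))
            mask[start : start + length, c] = True


def generate_frame(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[SensorFrame, SegmentTable]:
    """Generate one recording plus its ground-truth segment table.

    Deterministic per config seed (or per passed rng).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels, segments = _label_sequence(config, rng)
    offsets, amps, freqs = _signatures(config, rng)
    T = config.n_timesteps
    t_axis = np.arange(T)[:, None]
    body = (
        offsets[labels]
        + amps[labels] * np.sin(2 * np.pi * freqs[labels] * t_axis)
        + rng.normal(0, config.noise_scale, size=(T, config.n_body))
    )
    other = rng.normal(
        0, max(config.noise_scale, 1e-12),
        size=(T, config.n_quaternion + config.n_object_env),
    )
    values = np.concatenate([body, other], axis=1)
    mask = np.zeros_like(values, dtype=bool)
    _insert_missing_runs(mask, config, rng)
    schema = schema_for_config(config)
    keep = [i for i, r in enumerate(schema.roles) if r != "label"]
    frame = SensorFrame(
        values=values,
        mask=mask,
        labels=labels,
        channel_names=tuple(schema.names[i] for i in keep),
        channel_roles=tuple(schema.roles[i] for i in keep),
    )
    return frame, segments


def opportunity_like_fixture(seed: int = 0) -> SensorFrame:
    """A frame with the channel-role composition of the real gesture-
    recognition tables: 113 body + 16 quaternion + 119 object/environment
    channels plus the label column, 18 classes, >= 2000 timesteps."""
    config = SynthConfig(
        n_classes=18,
        n_body=113,
        n_quaternion=16,
        n_object_env=119,
        n_timesteps=2000,
        missing_run_rate=2.0,
        seed=seed,
    )
    frame, _ = generate_frame(config)
    return frame
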