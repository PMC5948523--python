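"""Sensor-table preprocessing: channel filtering, gap interpolation,
min-max normalization, and sliding-window tensor extraction.

Pipeline order is fixed: filter -> interpolate (interior gaps) -> zero-fill
(boundary gaps) -> normalize -> window.  Normalization statistics are meant
to come from the training split; evaluation data is clipped to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ROLES",
    "ChannelSchema",
    "SensorFrame",
    "WindowedDataset",
    "SchemaError",
    "read_sensor_table",
    "write_sensor_table",
    "read_schema",
    "write_schema",
    "filter_channels",
    "interpolate_missing",
    "compute_norm_stats",
    "normalize",
    "slide_windows",
]

ROLES = ("body", "quaternion", "object_env", "label", "ignore")


class SchemaError(ValueError):
    """Schema/table mismatch or invalid channel-role layout."""


@dataclass(frozen=True)
class ChannelSchema:
    """Per-column names and roles for a raw sensor table (label included)."""

    names: tuple[str, ...]
    roles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.roles):
            raise SchemaError("names and roles differ in length")
        for role in self.roles:
            if role not in ROLES:
                raise SchemaError(f"unknown role {role!r}")
        if self.roles.count("label") != 1:
            raise SchemaError("schema must have exactly one label column")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def label_index(self) -> int:
        return self.roles.index("label")

    def channel_indices(self, *roles: str) -> list[int]:
        wanted = set(roles)
        return [i for i, r in enumerate(self.roles) if r in wanted]


@dataclass
class SensorFrame:
    """Timestep x channel values with a missing mask and per-timestep labels.

    ``values``/``mask`` exclude the label column; ``channel_names`` and
    ``channel_roles`` align with the value columns.
    """

    values: np.ndarray                  # (T, C) float
    mask: np.ndarray                    # (T, C) bool, True = missing
    labels: np.ndarray                  # (T,) int
    channel_names: tuple[str, ...]
    channel_roles: tuple[str, ...]
    norm_stats: tuple[np.ndarray, np.ndarray] | None = None  # (min, max) per channel

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must equal timestep count")
        if len(self.channel_names) != self.values.shape[1]:
            raise ValueError("channel metadata does not match value columns")

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class WindowedDataset:
    """Sliding windows as an ``N x 1 x w x C`` tensor with per-window labels."""

    tensor: np.ndarray        # (N, 1, w, C)
    labels: np.ndarray        # (N,)
    origins: np.ndarray       # (N,) start timestep of each window
    window_size: int
    window_step: int

    @property
    def n_windows(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_channels(self) -> int:
        return self.tensor.shape[3]


def read_schema(path: str | Path) -> ChannelSchema:
    """Read a delimited schema file: ``index<TAB>name<TAB>role`` per line."""
    names: list[str] = []
    roles: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 3:
            raise SchemaError(f"malformed schema line: {raw!r}")
        names.append(fields[1])
        roles.append(fields[2])
    return ChannelSchema(names=tuple(names), roles=tuple(roles))


def write_schema(schema: ChannelSchema, path: str | Path) -> None:
    lines = [
        f"{i}\t{name}\t{role}"
        for i, (name, role) in enumerate(zip(schema.names, schema.roles))
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sensor_table(
    path: str | Path,
    schema: ChannelSchema,
    *,
    sentinel: float = np.nan,
) -> SensorFrame:
    """Read a whitespace-separated numeric table into a SensorFrame.

    Missing values are encoded by ``sentinel`` (default: literal NaN).  The
    column count must match the schema; a non-numeric cell raises with its
    row index.
    """
    rows: list[list[float]] = []
    for row_idx, raw in enumerate(Path(path).read_text().splitlines()):
        line = raw.strip()
        if not line:
            continue
        cells = line.split()
        if len(cells) != len(schema):
            raise SchemaError(
                f"row {row_idx}: expected {len(schema)} columns, got {len(cells)}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise ValueError(f"non-numeric cell in row {row_idx}") from exc
    if rows:
        table = np.asarray(rows, dtype=float)
    else:
        table = np.empty((0, len(schema)), dtype=float)

    label_col = schema.label_index
    keep = [i for i in range(len(schema)) if i != label_col]
    values = table[:, keep]
    labels_raw = table[:, label_col]
    if np.isnan(labels_raw).any():
        raise ValueError("label column contains missing values")
    if np.isnan(sentinel):
        mask = np.isnan(values)
    else:
        mask = values == sentinel
    return SensorFrame(
        values=values,
        mask=mask,
        labels=labels_raw.astype(int),
        channel_names=tuple(schema.names[i] for i in keep),
        channel_roles=tuple(schema.roles[i] for i in keep),
    )


def write_sensor_table(
    frame: SensorFrame,
    path: str | Path,
    *,
    sentinel: float = np.nan,
) -> None:
    """Write the frame back to the whitespace-separated dialect, label last."""
    values = frame.values.copy()
    values[frame.mask] = sentinel
    with open(path, "w") as fh:
        for t in range(frame.n_timesteps):
            cells = [repr(float(v)) for v in values[t]]
            cells.append(str(int(frame.labels[t])))
            fh.write(" ".join(cells) + "\n")


def filter_channels(frame: SensorFrame) -> SensorFrame:
    """Keep body channels only, dropping quaternion/object-environment/ignore
    columns.  Raises if no body channel would remain."""
    keep = [i for i, r in enumerate(frame.channel_roles) if r == "body"]
    if not keep:
        raise SchemaError("no body channels remain after filtering")
    return replace(
        frame,
        values=frame.values[:, keep],
        mask=frame.mask[:, keep],
        channel_names=tuple(frame.channel_names[i] for i in keep),
        channel_roles=tuple(frame.channel_roles[i] for i in keep),
        norm_stats=None,
    )


def interpolate_missing(frame: SensorFrame) -> SensorFrame:
    """Linearly interpolate interior missing runs per channel, then zero-fill
    leading/trailing runs that have no neighbour on one side."""
    values = frame.values.copy()
    T = frame.n_timesteps
    idx = np.arange(T)
    for c in range(frame.n_channels):
        missing = frame.mask[:, c]
        if not missing.any():
            continue
        known = ~missing
        if not known.any():
            values[:, c] = 0.0
            continue
        known_idx = idx[known]
        values[missing, c] = np.interp(idx[missing], known_idx, values[known, c])
        # np.interp clamps at the boundaries; the contract is zero-fill there
        values[: known_idx[0], c] = 0.0
        values[known_idx[-1] + 1 :, c] = 0.0
    return replace(frame, values=values, mask=np.zeros_like(frame.mask))


def compute_norm_stats(frame: SensorFrame) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-channel (min, max); requires no missing values."""
    if frame.mask.any():
        raise ValueError("compute_norm_stats requires a gap-free frame")
    if frame.n_timesteps == 0:
        raise ValueError("cannot compute stats on an empty frame")
    return frame.values.min(axis=0), frame.values.max(axis=0)


def normalize(
    frame: SensorFrame,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
    *,
    clip: bool = False,
) -> SensorFrame:
    """Min-max map each channel to [0, 1]: ``(x - min) / (max - min)``.

    Channels with ``max == min`` map to 0.  With ``clip`` (for evaluation
    splits normalized with training statistics) values are clipped to [0, 1].
    """
    if frame.mask.any():
        raise ValueError("normalize requires a gap-free frame")
    if stats is None:
        stats = compute_norm_stats(frame)
    lo, hi = np.asarray(stats[0], dtype=float), np.asarray(stats[1], dtype=float)
    if lo.shape != (frame.n_channels,) or hi.shape != (frame.n_channels,):
        raise ValueError("stats do not cover all channels")
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)
    values = (frame.values - lo) / safe
    values[:, span == 0] = 0.0
    if clip:
        values = np.clip(values, 0.0, 1.0)
    return replace(frame, values=values, norm_stats=(lo, hi))


def slide_windows(
    frame: SensorFrame,
    window_size: int,
    window_step: int,
    *,
    label_rule: str = "last",
) -> WindowedDataset:
    """Extract overlapping windows starting at 0, wstep, 2*wstep, ...

    ``N = floor((T - w) / wstep) + 1`` for ``T >= w``; otherwise an empty
    dataset (with a warning).  The tensor axis order is (window, 1, time,
    channel).  ``label_rule`` is ``last`` (label of the final timestep) or
    ``majority`` (modal label, lowest class id on ties).
    """
    if window_size < 1 or window_step < 1:
        raise ValueError("window_size and window_step must be >= 1")
    if label_rule not in ("last", "majority"):
        raise ValueError(f"unknown label rule {label_rule!r}")
    T, C = frame.values.shape
    if T < window_size:
        warnings.warn("fewer timesteps than window size; empty dataset")
        return WindowedDataset(
            tensor=np.empty((0, 1, window_size, C)),
            labels=np.empty((0,), dtype=int),
            origins=np.empty((0,), dtype=int),
            window_size=window_size,
            window_step=window_step,
        )
    views = np.lib.stride_tricks.sliding_window_view(
        frame.values, window_size, axis=0
    )  # (T - w + 1, C, w)
    starts = np.arange(0, T - window_size + 1, window_step)
    tensor = views[starts].transpose(0, 2, 1)[:, None, :, :].copy()
    if label_rule == "last":
        labels = frame.labels[starts + window_size - 1]
    else:
        labels = np.array(
            [
                np.bincount(frame.labels[s : s + window_size]).argmax()
                for s in starts
            ],
            dtype=int,
        )
    return WindowedDataset(
        tensor=tensor,
        labels=labels.astype(int),
        origins=starts.astype(int),
        window_size=window_size,
        window_step=window_step,
    )
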