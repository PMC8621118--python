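"""Core data containers for wearable-IMU balance-assessment pipelines.

The Berg balance scale (BBS) protocol instruments a subject with eight IMU
sensors, each emitting nine channels (3-axis acceleration, pitch/roll/yaw,
and 3-axis accumulated rotation), for 72 synchronous time series. A
recording covers a whole assessment session; annotated windows inside it
locate individual task performances, each labelled with a therapist score
in 0..4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SENSOR_NAMES = ("FH", "B", "RtW", "LtW", "RtA", "LtA", "RtH", "LtH")
CHANNEL_NAMES = ("Acx", "Acy", "Acz", "P", "R", "Y", "Rox", "Roy", "Roz")

#: channel names (within each sensor) that hold accumulated rotation counts
ROTATION_CHANNELS = ("Rox", "Roy", "Roz")

N_TASKS = 14
N_SCORES = 5


@dataclass(frozen=True)
class SensorLayout:
    """Fixed ordering of sensors and per-sensor channels.

    Columns of a recording are ordered sensor-major: all nine channels of
    the first sensor, then all nine of the second, and so on.
    """

    sensor_names: tuple[str, ...] = SENSOR_NAMES
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    @property
    def n_channels(self) -> int:
        return len(self.sensor_names) * len(self.channel_names)

    @property
    def column_names(self) -> list[str]:
        return [f"{s}_{c}" for s in self.sensor_names for c in self.channel_names]

    def is_rotation_column(self, index: int) -> bool:
        """True if flat column ``index`` is an accumulated-rotation channel."""
        name = self.channel_names[index % len(self.channel_names)]
        return name in ROTATION_CHANNELS


DEFAULT_LAYOUT = SensorLayout()


@dataclass
class MultiChannelRecording:
    """One continuous multichannel IMU recording.

    Parameters
    ----------
    data
        Array of shape ``(n_samples, n_channels)``; with the default layout
        ``n_channels`` is 72.
    sampling_rate_hz
        Acquisition rate in Hz (100 for the clinical hardware emulated here).
    layout
        Sensor/channel ordering for the columns.
    """

    data: np.ndarray
    sampling_rate_hz: float = 100.0
    layout: SensorLayout = field(default_factory=SensorLayout)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (time x channels)")
        if self.data.shape[1] != self.layout.n_channels:
            raise ValueError(
                f"recording has {self.data.shape[1]} channels, layout "
                f"requires {self.layout.n_channels}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass(frozen=True)
class SegmentAnnotation:
    """Half-open window ``[start_index, end_index)`` of one task performance."""

    task_id: int
    score: int
    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if not 1 <= self.task_id <= N_TASKS:
            raise ValueError(f"task_id must be in 1..{N_TASKS}, got {self.task_id}")
        if self.score not in range(N_SCORES):
            raise ValueError(f"score must be in 0..4, got {self.score}")
        if not 0 <= self.start_index < self.end_index:
            raise ValueError(
                f"need 0 <= start < end, got [{self.start_index}, {self.end_index})"
            )

    def validate_against(self, recording: MultiChannelRecording) -> None:
        if self.end_index > recording.n_samples:
            raise ValueError(
                f"annotation end_index {self.end_index} exceeds recording "
                f"length {recording.n_samples}"
            )

    def to_dict(self) -> dict:
        return {
            "task_id": self.task_id,
            "score": self.score,
            "start_index": self.start_index,
            "end_index": self.end_index,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentAnnotation":
        return cls(
            task_id=int(d["task_id"]),
            score=int(d["score"]),
            start_index=int(d["start_index"]),
            end_index=int(d["end_index"]),
        )


@dataclass
class TaskDataset:
    """Fixed-length samples and score labels for one BBS task.

    ``samples`` has shape ``(n_samples, time_length, n_channels)``; all
    samples share one time length (shorter segments are zero-padded at the
    tail before they enter a dataset). ``provenance`` records, for samples
    created by oversampling, the parent indices and blend coefficient.
    """

    samples: np.ndarray
    labels: np.ndarray
    task_id: int
    sampling_rate_hz: float = 100.0
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.samples.ndim != 3:
            raise ValueError("samples must be 3-D (n, time, channels)")
        if len(self.labels) != len(self.samples):
            raise ValueError("labels length must match number of samples")
        if len(self.labels) and not np.all((self.labels >= 0) & (self.labels < N_SCORES)):
            raise ValueError("labels must lie in 0..4")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def time_length(self) -> int:
        return self.samples.shape[1]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[2]

    def class_counts(self) -> dict[int, int]:
        return {s: int(np.sum(self.labels == s)) for s in range(N_SCORES)}

    # -- serialization: compressed array archive + JSON sidecar -------------

    def save(self, path_prefix: str | Path) -> None:
        prefix = Path(path_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(prefix.with_suffix(".npz"), samples=self.samples)
        sidecar = {
            "task_id": self.task_id,
            "sampling_rate_hz": self.sampling_rate_hz,
            "labels": self.labels.tolist(),
            "provenance": self.provenance,
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path_prefix: str | Path) -> "TaskDataset":
        prefix = Path(path_prefix)
        with np.load(prefix.with_suffix(".npz")) as arc:
            samples = arc["samples"]
        meta = json.loads(prefix.with_suffix(".json").read_text())
        return cls(
            samples=samples,
            labels=np.asarray(meta["labels"], dtype=int),
            task_id=int(meta["task_id"]),
            sampling_rate_hz=float(meta["sampling_rate_hz"]),
            provenance=list(meta.get("provenance", [])),
        )
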