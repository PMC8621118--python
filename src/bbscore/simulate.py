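"""Synthetic wearable-IMU recordings for balance-task scoring pipelines.

The clinical recordings this package was designed around are private, so
this module generates structurally matched stand-ins: 72 channels (8
sensors x 9 channels) at 100 Hz, cut into per-task segments of varying
length, each labelled with a score 0..4, with class imbalance on demand.

Signal model, per channel of a task segment:

* a task-specific low-frequency motif (two tones below 5 Hz) whose
  amplitude grows with the score and whose leading frequency shifts with
  the score — two independent, spectrally visible class cues; a third cue
  is temporal: higher scores complete the task faster, so segment
  duration shrinks with score;
* a fixed postural-sway component just below 10 Hz, shared by all classes,
  which pins the knee of the corpus spectral profile;
* score-dependent mid-band content (6..8 Hz), gated by ``separation``;
* smooth low-pass background noise (below ~4 Hz);
* optional tremor: a high-frequency (>15 Hz) tone plus broadband noise,
  scaled by ``tremor_level``.

With ``separation=0`` every score-dependent term collapses to its baseline,
so classes are statistically indistinguishable by construction. Rotation
channels (Rox/Roy/Roz) integrate bounded increments of the oscillatory
signal, emulating accumulated rotation counts.

Determinism: each (seed, subject, task) triple owns an independent RNG
stream, so datasets are bit-reproducible under subject-parallel generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from scipy.signal.windows import tukey

from .datasets import (
    DEFAULT_LAYOUT,
    N_SCORES,
    MultiChannelRecording,
    SegmentAnnotation,
    SensorLayout,
    TaskDataset,
)
from .preprocessing import zero_pad

__all__ = [
    "SimConfig",
    "generate_recording",
    "generate_task_dataset",
    "write_recording_csv",
    "read_recording_csv",
    "RecordingParseError",
]

# fixed structural constants of the generator (not exposed as dials: they
# define the synthetic study conditions)
_MOTIF_AMP_RANGE = (0.7, 1.2)
_MOTIF2_AMP_RANGE = (0.3, 0.7)
_SWAY_AMP = 0.45
_MID_AMP = 0.12
_NOISE_SIGMA = 0.10
_NOISE_CUT_HZ = 4.0
_TASK_STREAM_KEY = 0xB55  # namespaces the per-task structural RNG


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic corpus.

    ``separation`` scales every between-class difference (0 = classes
    identical in distribution); ``tremor_level`` scales the high-frequency
    (>15 Hz) component. ``class_counts`` maps score -> number of segments
    per task across the whole cohort.
    """

    sampling_rate_hz: float = 100.0
    n_subjects: int = 10
    class_counts: dict[int, int] = field(
        default_factory=lambda: {s: 20 for s in range(N_SCORES)}
    )
    separation: float = 1.0
    tremor_level: float = 0.05
    task_ids: tuple[int, ...] = tuple(range(1, 15))
    segment_length_range_s: tuple[float, float] = (2.5, 3.5)
    seed: int = 0
    layout: SensorLayout = field(default_factory=SensorLayout)

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not self.task_ids:
            raise ValueError("task_ids must be non-empty")
        if any(not 1 <= t <= 14 for t in self.task_ids):
            raise ValueError(f"task_ids must lie in 1..14, got {self.task_ids}")
        if any(s not in range(N_SCORES) for s in self.class_counts):
            raise ValueError("class_counts keys must be scores 0..4")
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class_counts values must be >= 0")
        if self.separation < 0 or self.tremor_level < 0:
            raise ValueError("separation and tremor_level must be >= 0")
        lo, hi = self.segment_length_range_s
        if not 0 < lo <= hi:
            raise ValueError("segment_length_range_s must be positive and ordered")


def _task_channel_params(task_id: int, n_channels: int) -> dict[str, np.ndarray]:
    """Per-channel motif parameters, a deterministic function of the task."""
    rng = np.random.default_rng([_TASK_STREAM_KEY, task_id])
    return {
        "f1": rng.uniform(0.8, 3.2, n_channels),
        "f2": rng.uniform(1.0, 4.5, n_channels),
        "a1": rng.uniform(*_MOTIF_AMP_RANGE, n_channels),
        "a2": rng.uniform(*_MOTIF2_AMP_RANGE, n_channels),
        "f_sway": rng.uniform(9.05, 9.3, n_channels),
        "a_sway": _SWAY_AMP * rng.uniform(0.8, 1.2, n_channels),
        "f_mid": rng.uniform(6.0, 8.0, n_channels),
        # canonical motif phases: task segments are annotation-aligned, so
        # the waveform shape is reproducible across performances
        "ph1": rng.uniform(0, 2 * np.pi, n_channels),
        "ph2": rng.uniform(0, 2 * np.pi, n_channels),
        "ph_mid": rng.uniform(0, 2 * np.pi, n_channels),
    }


def _lowpass(x: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    b, a = butter(4, cutoff_hz / (fs / 2), btype="low")
    return filtfilt(b, a, x, axis=-1)


def _generate_segment(
    config: SimConfig, task_id: int, score: int, rng: np.random.Generator
) -> np.ndarray:
    """One (time x channels) segment for a given task and score."""
    fs = config.sampling_rate_hz
    lo, hi = config.segment_length_range_s
    # higher scores complete the task faster: duration shrinks with score
    duration = rng.uniform(lo, hi) / (1.0 + 0.05 * score * config.separation)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    layout = config.layout
    n_ch = layout.n_channels
    p = _task_channel_params(task_id, n_ch)

    amp_scale = 1.0 + score * config.separation / 4.0
    f1 = p["f1"] + score * config.separation * 0.2
    # motif phases jitter around the task's canonical ones (segments are
    # annotation-aligned); the background sway phase is fully random
    jitter = 0.4 * rng.standard_normal((3, n_ch))
    sway_phase = rng.uniform(0, 2 * np.pi, n_ch)

    osc = (
        amp_scale * p["a1"] * np.sin(2 * np.pi * np.outer(t, f1) + p["ph1"] + jitter[0])
        + amp_scale
        * p["a2"]
        * np.sin(2 * np.pi * np.outer(t, p["f2"]) + p["ph2"] + jitter[1])
        + p["a_sway"] * np.sin(2 * np.pi * np.outer(t, p["f_sway"]) + sway_phase)
        + _MID_AMP
        * score
        * config.separation
        * np.sin(2 * np.pi * np.outer(t, p["f_mid"]) + p["ph_mid"] + jitter[2])
    )
    noise = _lowpass(rng.standard_normal((n_ch, n)) * _NOISE_SIGMA, _NOISE_CUT_HZ, fs).T
    osc = osc + noise

    if config.tremor_level > 0:
        f_tr = rng.uniform(18.0, 40.0, n_ch)
        ph_tr = rng.uniform(0, 2 * np.pi, n_ch)
        tremor = np.sin(2 * np.pi * np.outer(t, f_tr) + ph_tr)
        tremor = tremor + 0.3 * rng.standard_normal((n, n_ch))
        osc = osc + config.tremor_level * tremor

    # motion ramps up from rest and settles back: a tapered envelope keeps
    # segment edges near zero, so trailing zero-padding stays continuous
    osc = osc * tukey(n, alpha=0.6)[:, None]

    data = osc.copy()
    rot_cols = [c for c in range(n_ch) if layout.is_rotation_column(c)]
    # accumulated-rotation channels: integrals of bounded, zero-mean
    # increments — the subject returns to the starting orientation
    inc = np.clip(osc[:, rot_cols], -1.5, 1.5)
    inc = inc - inc.mean(axis=0, keepdims=True)
    data[:, rot_cols] = np.cumsum(inc, axis=0) * (2.0 / fs)
    return data


def _segment_stream(
    config: SimConfig, subject_id: int, task_id: int, *extra: int
) -> np.random.Generator:
    return np.random.default_rng([config.seed, subject_id, task_id, *extra])


def generate_recording(
    config: SimConfig, subject_id: int
) -> tuple[MultiChannelRecording, list[SegmentAnnotation]]:
    """One subject's continuous session: one segment per configured task.

    Each task's score is drawn with probability proportional to
    ``class_counts``; segments are separated by short low-activity gaps.
    Deterministic given ``(config.seed, subject_id)``.
    """
    if subject_id < 0:
        raise ValueError("subject_id must be >= 0")
    scores = np.array(sorted(s for s, c in config.class_counts.items() if c > 0))
    if scores.size == 0:
        raise ValueError("class_counts has no positive entries")
    weights = np.array([config.class_counts[s] for s in scores], dtype=float)
    weights /= weights.sum()

    fs = config.sampling_rate_hz
    n_ch = config.layout.n_channels
    chunks: list[np.ndarray] = []
    annotations: list[SegmentAnnotation] = []
    cursor = 0
    for task_id in sorted(config.task_ids):
        rng = _segment_stream(config, subject_id, task_id)
        gap_n = int(round(rng.uniform(0.5, 1.0) * fs))
        gap = _lowpass(rng.standard_normal((n_ch, gap_n)) * 0.02, _NOISE_CUT_HZ, fs).T
        score = int(rng.choice(scores, p=weights))
        seg = _generate_segment(config, task_id, score, rng)
        chunks.extend([gap, seg])
        start = cursor + gap_n
        end = start + len(seg)
        annotations.append(SegmentAnnotation(task_id, score, start, end))
        cursor = end
    data = np.vstack(chunks)
    return MultiChannelRecording(data, fs, config.layout), annotations


def generate_task_dataset(config: SimConfig, task_id: int) -> TaskDataset:
    """All subjects' segments for one task, zero-padded to equal length.

    Label counts equal ``config.class_counts`` exactly; segment draws are
    attributed to subjects round-robin. The only preprocessing applied is
    trailing zero-padding to the longest segment.
    """
    if task_id not in config.task_ids:
        raise ValueError(f"task {task_id} not in configured task_ids")
    segments: list[np.ndarray] = []
    labels: list[int] = []
    i = 0
    for score in range(N_SCORES):
        for _ in range(config.class_counts.get(score, 0)):
            subject = i % config.n_subjects
            replicate = i // config.n_subjects
            rng = _segment_stream(config, subject, task_id, score, replicate)
            segments.append(_generate_segment(config, task_id, score, rng))
            labels.append(score)
            i += 1
    if not segments:
        raise ValueError("class_counts produce zero samples")
    return TaskDataset(
        samples=zero_pad(segments),
        labels=np.array(labels),
        task_id=task_id,
        sampling_rate_hz=config.sampling_rate_hz,
    )


# -- CSV / JSON round-trip ---------------------------------------------------


class RecordingParseError(ValueError):
    """Raised when a recording CSV or annotation file is malformed."""


def write_recording_csv(
    recording: MultiChannelRecording,
    annotations: list[SegmentAnnotation],
    path_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` (time + 72 data columns) and ``<prefix>.annotations.json``."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_suffix(".csv")
    ann_path = prefix.parent / (prefix.name + ".annotations.json")
    time = np.arange(recording.n_samples) / recording.sampling_rate_hz
    df = pd.DataFrame(recording.data, columns=recording.layout.column_names)
    df.insert(0, "time", time)
    df.to_csv(csv_path, index=False, float_format="%.10g")
    for ann in annotations:
        ann.validate_against(recording)
    ann_path.write_text(json.dumps([a.to_dict() for a in annotations], indent=1))
    return csv_path, ann_path


def read_recording_csv(
    path_prefix: str | Path, layout: SensorLayout = DEFAULT_LAYOUT
) -> tuple[MultiChannelRecording, list[SegmentAnnotation]]:
    """Inverse of :func:`write_recording_csv`; validates header and values."""
    prefix = Path(path_prefix)
    csv_path = prefix.with_suffix(".csv")
    ann_path = prefix.parent / (prefix.name + ".annotations.json")
    df = pd.read_csv(csv_path)
    expected = ["time"] + layout.column_names
    if list(df.columns) != expected:
        missing = [c for c in expected if c not in df.columns]
        extra = [c for c in df.columns if c not in expected]
        raise RecordingParseError(
            f"{csv_path}: header mismatch (expected {len(expected)} columns, "
            f"got {len(df.columns)}; missing {missing[:3]}, unexpected {extra[:3]})"
        )
    for col in layout.column_names:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            row = int((df[col].isna() | bad).idxmax())
            raise RecordingParseError(
                f"{csv_path}: non-numeric or missing value in column {col!r}, row {row}"
            )
    time = df["time"].to_numpy()
    if len(time) > 1:
        dt = np.diff(time)
        rate = 1.0 / np.median(dt)
    else:
        rate = 100.0
    data = df[layout.column_names].to_numpy(dtype=float)
    recording = MultiChannelRecording(data, float(round(rate, 6)), layout)
    annotations = []
    if ann_path.exists():
        for d in json.loads(ann_path.read_text()):
            ann = SegmentAnnotation.from_dict(d)
            ann.validate_against(recording)
            annotations.append(ann)
    return recording, annotations
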