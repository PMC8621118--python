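"""Signal cleanup chain for IMU task data.

Order of operations (applied per recording, then per task):
EMD denoising -> per-channel min-max normalization -> segment extraction ->
trailing zero-padding to the task's longest segment -> integer-factor
down-sampling. Padding happens at the original rate; normalization precedes
segmentation so the padded zeros coincide with each channel's minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .datasets import MultiChannelRecording, SegmentAnnotation, TaskDataset
from .emd import emd

__all__ = [
    "EMDConfig",
    "emd_decompose",
    "emd_denoise",
    "denoise_recording",
    "minmax_normalize",
    "extract_segments",
    "zero_pad",
    "downsample",
]


@dataclass(frozen=True)
class EMDConfig:
    """Settings for EMD denoising.

    The denoised signal is resynthesized from IMFs ``keep_imfs[0]`` through
    ``keep_imfs[1]`` (1-based, inclusive) plus the residue. The default
    (10 IMFs, keep 1..7) discards the three lowest-frequency IMFs only when
    a signal actually decomposes into more than seven; short or smooth
    signals pass through unchanged.
    """

    max_imfs: int = 10
    keep_imfs: tuple[int, int] = (1, 7)
    sift_tolerance: float = 0.05
    max_siftings: int = 100
    boundary: str = "mirror"

    def __post_init__(self) -> None:
        lo, hi = self.keep_imfs
        if not (1 <= lo <= hi <= self.max_imfs):
            raise ValueError(
                f"keep_imfs {self.keep_imfs} must satisfy 1 <= lo <= hi <= max_imfs"
            )
        if self.boundary != "mirror":
            raise ValueError("only mirror boundary handling is supported")


def emd_decompose(
    signal: np.ndarray, config: EMDConfig = EMDConfig()
) -> tuple[list[np.ndarray], np.ndarray]:
    """Decompose one channel into IMFs plus residue (see :func:`bbscore.emd.emd`)."""
    return emd(
        signal,
        max_imfs=config.max_imfs,
        sift_tolerance=config.sift_tolerance,
        max_siftings=config.max_siftings,
    )


def emd_denoise(signal: np.ndarray, config: EMDConfig = EMDConfig()) -> np.ndarray:
    """Suppress high-frequency noise by partial EMD resynthesis.

    Note on an easy confusion: IMFs are ordered from highest to lowest
    frequency, so "keep 1..7 of 10" keeps the seven *highest*-frequency
    modes in EMD index order. For inertial data the tail modes beyond the
    seventh carry slow drift that the residue already represents; the
    residue itself is always added back so the signal keeps its baseline.
    """
    imfs, residue = emd_decompose(signal, config)
    lo, hi = config.keep_imfs
    kept = imfs[lo - 1 : hi]
    if len(imfs) <= hi - lo + 1:
        kept = imfs  # fewer modes than the keep range: pass-through
    out = residue.copy()
    for m in kept:
        out += m
    return out


def denoise_recording(
    recording: MultiChannelRecording, config: EMDConfig = EMDConfig()
) -> MultiChannelRecording:
    """Apply :func:`emd_denoise` independently to every channel."""
    data = np.column_stack(
        [emd_denoise(recording.data[:, c], config) for c in range(recording.data.shape[1])]
    )
    return MultiChannelRecording(data, recording.sampling_rate_hz, recording.layout)


def minmax_normalize(obj, scope: str = "channel"):
    """Linearly map values to [0, 1].

    ``scope='channel'`` rescales each channel independently (per recording
    for 2-D input, per sample for a :class:`TaskDataset`), removing unit
    differences between acceleration, angle and rotation channels.
    ``scope='global'`` uses one min/max over the whole array. Constant
    channels map to 0.
    """
    if scope not in ("channel", "global"):
        raise ValueError(f"unknown scope {scope!r}")

    def _scale(arr: np.ndarray, axis) -> np.ndarray:
        lo = arr.min(axis=axis, keepdims=True)
        hi = arr.max(axis=axis, keepdims=True)
        span = hi - lo
        out = np.where(span > 0, (arr - lo) / np.where(span > 0, span, 1.0), 0.0)
        return out

    if isinstance(obj, MultiChannelRecording):
        axis = 0 if scope == "channel" else None
        return MultiChannelRecording(
            _scale(obj.data, axis), obj.sampling_rate_hz, obj.layout
        )
    if isinstance(obj, TaskDataset):
        axis = 1 if scope == "channel" else None
        if scope == "channel":
            scaled = np.stack([_scale(s, 0) for s in obj.samples]) if len(obj) else obj.samples
        else:
            scaled = _scale(obj.samples, None)
        return replace(obj, samples=scaled)
    arr = np.asarray(obj, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("input contains non-finite values")
    if scope == "global" or arr.ndim == 1:
        return _scale(arr, None)
    return _scale(arr, tuple(range(arr.ndim - 1)))


def extract_segments(
    recording: MultiChannelRecording, annotations: list[SegmentAnnotation]
) -> list[tuple[int, int, np.ndarray]]:
    """Slice out each annotated task window as ``(task_id, score, segment)``.

    Windows are half-open; overlapping annotations are allowed and each is
    returned independently.
    """
    out = []
    for ann in annotations:
        ann.validate_against(recording)
        out.append((ann.task_id, ann.score, recording.data[ann.start_index : ann.end_index]))
    return out


def zero_pad(segments: list[np.ndarray], target_length: int | None = None) -> np.ndarray:
    """Stack variable-length segments into one array by trailing zero-padding.

    ``target_length`` defaults to the longest segment. Original values are
    never altered; a segment longer than the target is an error.
    """
    if not segments:
        return np.zeros((0, target_length or 0, 0))
    lengths = [len(s) for s in segments]
    if target_length is None:
        target_length = max(lengths)
    if max(lengths) > target_length:
        raise ValueError(
            f"segment of length {max(lengths)} exceeds target_length {target_length}"
        )
    n_ch = segments[0].shape[1]
    out = np.zeros((len(segments), target_length, n_ch))
    for i, seg in enumerate(segments):
        if seg.shape[1] != n_ch:
            raise ValueError("segments differ in channel count")
        out[i, : len(seg)] = seg
    return out


def downsample(
    dataset: TaskDataset, target_rate_hz: float, antialias: bool = False
) -> TaskDataset:
    """Decimate every sample to ``target_rate_hz`` by keeping every f-th row.

    The decimation factor ``f = original_rate / target_rate`` must be an
    integer; rows 0, f, 2f, ... are kept, so the output length is
    ``ceil(length / f)``. No anti-alias filter is applied by default: the
    denoising stage has already removed content near the old Nyquist
    frequency. Pass ``antialias=True`` to insert a zero-phase Butterworth
    low-pass at the new Nyquist frequency first.
    """
    orig = dataset.sampling_rate_hz
    if target_rate_hz <= 0:
        raise ValueError("target rate must be positive")
    factor = orig / target_rate_hz
    if abs(factor - round(factor)) > 1e-9:
        divisors = [orig / d for d in range(1, int(orig) + 1) if orig % d == 0]
        raise ValueError(
            f"cannot decimate {orig} Hz to {target_rate_hz} Hz: non-integer "
            f"factor; allowed target rates include {sorted(set(divisors))}"
        )
    factor = int(round(factor))
    if factor == 1:
        return replace(dataset, samples=dataset.samples.copy())
    samples = dataset.samples
    if antialias:
        b, a = butter(4, (target_rate_hz / 2) / (orig / 2), btype="low")
        samples = filtfilt(b, a, samples, axis=1)
    return replace(
        dataset,
        samples=samples[:, ::factor, :].copy(),
        sampling_rate_hz=float(target_rate_hz),
    )
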