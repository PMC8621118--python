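"""Data-driven sampling-rate selection.

Most of the spectral content of balance-task motion lies well below 10 Hz.
To pick a sampling rate we profile, over an entire corpus, what fraction of
accumulated FFT amplitude lies at or below each integer frequency N for
N = 1..50 Hz; once the per-Hz marginal gain falls below a threshold, the
cutoff frequency is fixed and the rate is set to twice the cutoff (Nyquist).
The procedure, per sample: take an n-point FFT of each of the 72 channels
(signals zero-extended to n), sum amplitudes over channels per bin, group
bins by the ceiling of their frequency in Hz, accumulate up to each N,
normalize by the total at or below 50 Hz, and express as a percentage.
Percentages are averaged over samples within a task, then over tasks.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datasets import TaskDataset

__all__ = [
    "SpectralProfile",
    "amplitude_spectrum",
    "accumulated_information_profile",
    "select_cutoff",
    "select_sampling_rate",
]

MAX_PROFILE_HZ = 50


@dataclass(frozen=True)
class SpectralProfile:
    """Accumulated-amplitude percentage at each integer frequency 1..50 Hz."""

    frequencies_hz: np.ndarray
    accumulated_percent: np.ndarray
    n_fft: int

    def __post_init__(self) -> None:
        acc = np.asarray(self.accumulated_percent, dtype=float)
        if len(acc) != len(self.frequencies_hz):
            raise ValueError("profile arrays differ in length")
        if np.any(np.diff(acc) < -1e-9):
            raise ValueError("accumulated percentages must be non-decreasing")
        if abs(acc[-1] - 100.0) > 1e-9:
            raise ValueError("profile must end at 100%")

    def marginals(self) -> np.ndarray:
        """Per-Hz increase ``profile(M+1) - profile(M)`` for M = 1..49."""
        return np.diff(self.accumulated_percent)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["frequency_hz", "accumulated_percent"])
            for f, p in zip(self.frequencies_hz, self.accumulated_percent):
                w.writerow([int(f), f"{p:.6f}"])


def amplitude_spectrum(signal: np.ndarray, n_fft: int) -> np.ndarray:
    """FFT magnitudes of bins 1..n_fft/2 (DC excluded), signal zero-extended."""
    signal = np.asarray(signal, dtype=float)
    if n_fft % 2 != 0:
        raise ValueError("n_fft must be even")
    if n_fft < signal.shape[-1]:
        raise ValueError(
            f"n_fft {n_fft} is smaller than signal length {signal.shape[-1]}"
        )
    spectrum = np.abs(np.fft.rfft(signal, n=n_fft, axis=-1))
    return spectrum[..., 1 : n_fft // 2 + 1]


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def accumulated_information_profile(corpus: list[TaskDataset]) -> SpectralProfile:
    """Corpus-wide accumulated-amplitude percentages for N = 1..50 Hz.

    The FFT length is fixed per corpus at the smallest power of two that
    covers the longest padded sample. All datasets must share a sampling
    rate of at least 100 Hz so the 50 Hz ceiling is representable.
    """
    if not corpus:
        raise ValueError("empty corpus")
    rates = {ds.sampling_rate_hz for ds in corpus}
    if len(rates) != 1:
        raise ValueError(f"corpus mixes sampling rates: {sorted(rates)}")
    rate = rates.pop()
    if rate < 2 * MAX_PROFILE_HZ:
        raise ValueError(
            f"sampling rate {rate} Hz cannot represent {MAX_PROFILE_HZ} Hz content"
        )
    n_fft = _next_pow2(max(ds.time_length for ds in corpus))

    freqs = np.arange(1, n_fft // 2 + 1) * rate / n_fft
    # integer-Hz grouping: bin at f Hz contributes to N = ceil(f)
    group = np.ceil(freqs - 1e-12).astype(int)
    usable = group <= MAX_PROFILE_HZ

    task_profiles = []
    for ds in corpus:
        if len(ds) == 0:
            raise ValueError(f"task {ds.task_id} dataset is empty")
        # (n, time, ch) -> amplitudes (n, ch, bins) -> sum channels -> (n, bins)
        amps = amplitude_spectrum(np.moveaxis(ds.samples, 1, 2), n_fft)
        per_bin = amps.sum(axis=1)[:, usable]
        binned = np.zeros((len(ds), MAX_PROFILE_HZ))
        np.add.at(binned.T, group[usable] - 1, per_bin.T)
        cum = np.cumsum(binned, axis=1)
        total = cum[:, -1]
        if np.any(total == 0):
            raise ValueError("a sample has zero spectral amplitude below 50 Hz")
        task_profiles.append((100.0 * cum / total[:, None]).mean(axis=0))

    percent = np.mean(task_profiles, axis=0)
    percent[-1] = 100.0  # guard float accumulation at the normalization point
    return SpectralProfile(
        frequencies_hz=np.arange(1, MAX_PROFILE_HZ + 1),
        accumulated_percent=percent,
        n_fft=n_fft,
    )


def select_cutoff(profile: SpectralProfile, marginal_threshold_percent: float = 1.0) -> int:
    """Smallest N whose every later per-Hz gain is below the threshold.

    Returns the smallest N in 1..49 such that
    ``profile(M+1) - profile(M) < threshold`` for every M >= N. Raises if
    even the last marginal exceeds the threshold.
    """
    if marginal_threshold_percent <= 0:
        raise ValueError("threshold must be positive")
    marg = profile.marginals()  # marg[i] = gain from N=i+1 to N=i+2
    below = marg < marginal_threshold_percent
    if not below.all():
        last_bad = int(np.nonzero(~below)[0][-1])  # marginal at M = last_bad + 1
        if last_bad == len(marg) - 1:
            raise ValueError(
                "no frequency qualifies: the accumulated profile still gains "
                f">= {marginal_threshold_percent}%/Hz at {len(marg)} Hz; "
                "try a larger threshold"
            )
        return last_bad + 2
    return 1


def select_sampling_rate(cutoff_hz: float) -> float:
    """Nyquist rule: the rate that restores content up to ``cutoff_hz``."""
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    return 2.0 * cutoff_hz
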