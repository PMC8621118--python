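"""Empirical mode decomposition (EMD).

Plain (non-ensemble) EMD via sifting: a signal is iteratively split into
intrinsic mode functions (IMFs), ordered from highest to lowest frequency,
plus a low-order residue. Each sifting pass subtracts the mean of the upper
and lower cubic-spline envelopes through the local extrema; extrema are
mirror-extended past both ends so the envelopes are defined over the whole
support. Sifting stops on a Cauchy-type criterion
``sum((h_prev - h)^2) / sum(h_prev^2) < tol`` or after a fixed number of
passes. Decomposition stops when the residue has fewer than two interior
extrema or when the requested number of IMFs is reached.

By construction ``sum(IMFs) + residue`` reproduces the input exactly (up to
floating-point accumulation), since every IMF is literally subtracted from
the running residue.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["emd", "local_extrema"]


def local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior local maxima and minima of ``x``.

    Plateaus count once, at their midpoint. Endpoints are never extrema.
    """
    x = np.asarray(x, dtype=float)
    dx = np.diff(x)
    nonzero = np.nonzero(dx)[0]
    maxima: list[int] = []
    minima: list[int] = []
    if nonzero.size < 2:
        return np.array(maxima, dtype=int), np.array(minima, dtype=int)
    prev = nonzero[0]
    prev_sign = np.sign(dx[prev])
    for i in nonzero[1:]:
        sign = np.sign(dx[i])
        if sign != prev_sign:
            # slope changes somewhere in the plateau x[prev+1 .. i]
            idx = (prev + 1 + i) // 2
            (maxima if prev_sign > 0 else minima).append(idx)
        prev, prev_sign = i, sign
    return np.array(maxima, dtype=int), np.array(minima, dtype=int)


def _mirrored_knots(
    idx: np.ndarray, val: np.ndarray, n: int, n_mirror: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Extend extrema past both ends by reflection about the endpoints."""
    m = min(n_mirror, len(idx))
    left_t = -idx[:m][::-1]
    left_v = val[:m][::-1]
    right_t = 2 * (n - 1) - idx[-m:][::-1]
    right_v = val[-m:][::-1]
    t = np.concatenate([left_t, idx, right_t])
    v = np.concatenate([left_v, val, right_v])
    # reflection can duplicate knots when an extremum sits at an endpoint
    t, keep = np.unique(t, return_index=True)
    return t, v[keep]


def _envelope(idx: np.ndarray, val: np.ndarray, n: int) -> np.ndarray:
    t, v = _mirrored_knots(idx, val, n)
    if len(t) < 2:
        return np.full(n, v[0] if len(t) else 0.0)
    if len(t) < 4:
        # cubic needs 4 knots for not-a-knot; fall back to natural spline
        spline = CubicSpline(t, v, bc_type="natural")
    else:
        spline = CubicSpline(t, v)
    return spline(np.arange(n))


def _mean_envelope(h: np.ndarray) -> np.ndarray | None:
    maxima, minima = local_extrema(h)
    if len(maxima) < 1 or len(minima) < 1 or len(maxima) + len(minima) < 2:
        return None
    upper = _envelope(maxima, h[maxima], len(h))
    lower = _envelope(minima, h[minima], len(h))
    return 0.5 * (upper + lower)


def _sift_imf(residue: np.ndarray, tol: float, max_siftings: int) -> np.ndarray | None:
    h = residue.copy()
    for _ in range(max_siftings):
        mean = _mean_envelope(h)
        if mean is None:
            # residue became (near-)monotone before the first pass finished
            return None if h is residue else h
        h_new = h - mean
        denom = float(np.sum(h * h))
        if denom == 0.0:
            return h_new
        sd = float(np.sum((h - h_new) ** 2)) / denom
        h = h_new
        if sd < tol:
            break
    return h


def emd(
    signal: np.ndarray,
    max_imfs: int = 10,
    sift_tolerance: float = 0.05,
    max_siftings: int = 100,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Decompose ``signal`` into IMFs plus residue.

    Returns ``(imfs, residue)`` with ``sum(imfs) + residue == signal``.
    A constant or monotone signal yields no IMFs and ``residue == signal``.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("emd expects a 1-D signal")
    if signal.size < 4:
        raise ValueError("signal too short for decomposition (need >= 4 samples)")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")

    imfs: list[np.ndarray] = []
    residue = signal.copy()
    while len(imfs) < max_imfs:
        maxima, minima = local_extrema(residue)
        if len(maxima) + len(minima) < 2:
            break
        imf = _sift_imf(residue, sift_tolerance, max_siftings)
        if imf is None:
            break
        imfs.append(imf)
        residue = residue - imf
    return imfs, residue
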