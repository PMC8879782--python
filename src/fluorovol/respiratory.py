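"""Marker-free respiratory signal extraction and phase sorting.

The breathing trace is recovered from the projections themselves with the
Amsterdam-shroud approach: each projection is gradient-filtered along the
detector SI axis, clipped, and collapsed laterally into one column; the
frame-to-frame SI shift of consecutive columns (normalized cross
correlation with sub-pixel refinement) is accumulated and detrended.
Peaks of the trace (end-inhale) delimit breathing cycles; phase is linear
in time within each cycle, and projections are sorted into ``n_bins``
phase bins (default 6) for phase-correlated reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import ProjectionStack
from .phantom import RespiratorySignal

__all__ = [
    "PhaseAssignment",
    "amsterdam_shroud",
    "extract_phase",
    "bin_projections",
    "NoRespirationError",
    "InsufficientCyclesError",
]

log = logging.getLogger(__name__)


class NoRespirationError(RuntimeError):
    """The projection stack shows no detectable breathing motion."""


class InsufficientCyclesError(RuntimeError):
    """Fewer than two breathing peaks detected."""


@dataclass
class PhaseAssignment:
    """Continuous phase in [0, 1), bin index, and detected end-inhale peaks."""

    phase: np.ndarray
    bin_index: np.ndarray
    peaks: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        self.bin_index = np.asarray(self.bin_index, dtype=int)
        self.peaks = np.asarray(self.peaks, dtype=int)
        if np.any(np.diff(self.peaks) <= 0):
            raise ValueError("peaks must be strictly increasing")
        if np.any((self.bin_index < 0) | (self.bin_index >= self.n_bins)):
            raise ValueError("bin index out of range")

    @property
    def median_period_frames(self) -> float:
        return float(np.median(np.diff(self.peaks)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"frame": np.arange(self.phase.size), "phase": self.phase, "bin": self.bin_index}
        )


def _subpixel_shift(a: np.ndarray, b: np.ndarray, max_lag: int) -> float:
    """Shift of content from a to b (pixels, positive = toward higher index).

    Normalized cross-correlation over integer lags with parabolic
    refinement around the maximum.
    """
    a = a - a.mean()
    b = b - b.mean()
    lags = np.arange(-max_lag, max_lag + 1)
    scores = np.empty(lags.size)
    for idx, lag in enumerate(lags):
        if lag >= 0:
            aa, bb = a[: a.size - lag], b[lag:]
        else:
            aa, bb = a[-lag:], b[: b.size + lag]
        denom = np.linalg.norm(aa) * np.linalg.norm(bb)
        scores[idx] = (aa @ bb) / denom if denom > 0 else 0.0
    k = int(np.argmax(scores))
    shift = float(lags[k])
    if 0 < k < lags.size - 1:
        y0, y1, y2 = scores[k - 1], scores[k], scores[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            shift += 0.5 * (y0 - y2) / denom
    return shift


def amsterdam_shroud(
    stack: ProjectionStack,
    clip_percentiles: tuple[float, float] = (1.0, 99.0),
    max_lag: int | None = None,
    variance_threshold: float = 1e-6,
) -> RespiratorySignal:
    """Extract the breathing trace from a projection stack.

    The returned samples are detrended, normalized to [0, 1] and oriented
    inhale-high (content moving inferior on the panel during inhale is
    the physical sign convention: the detector v axis points superior).
    Raises :class:`NoRespirationError` on static content.
    """
    if len(stack) < 2:
        raise ValueError("need at least two frames")
    pix = stack.pixels
    grad = np.gradient(pix, axis=1)  # d/dv per frame (axis 1 = detector rows)
    lo, hi = np.percentile(grad, clip_percentiles)
    shroud = np.clip(grad, lo, hi).sum(axis=2)  # (n_frames, rows)

    rows = shroud.shape[1]
    if max_lag is None:
        max_lag = max(2, rows // 8)
    shifts = np.empty(len(stack) - 1)
    for i in range(1, len(stack)):
        shifts[i - 1] = _subpixel_shift(shroud[i - 1], shroud[i], max_lag)
    # +v is superior; inhale moves anatomy inferior, so negate for inhale-high
    trace = -np.concatenate([[0.0], np.cumsum(shifts)])
    t = stack.times_s
    trace = trace - np.polyval(np.polyfit(t, trace, 1), t)

    if trace.var() < variance_threshold:
        raise NoRespirationError("breathing trace variance below threshold")
    span = trace.max() - trace.min()
    trace = (trace - trace.min()) / span
    frame_rate = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
    return RespiratorySignal(
        trace, t.copy(), frame_rate, params={"method": "amsterdam-shroud"}
    )


def _dominant_period_frames(x: np.ndarray) -> float:
    """Dominant period of a detrended trace via the FFT peak."""
    xd = x - x.mean()
    spec = np.abs(np.fft.rfft(xd))
    spec[0] = 0.0
    k = int(np.argmax(spec))
    if k == 0:
        return float(x.size)
    return x.size / k


def extract_phase(
    signal: RespiratorySignal,
    n_bins: int = 6,
    min_separation_factor: float = 0.6,
    min_prominence_frac: float = 0.2,
) -> PhaseAssignment:
    """Cycle segmentation and phase binning of a breathing trace.

    Peaks (end-inhale) are local maxima with minimum separation
    ``min_separation_factor`` x the FFT-dominant period and prominence at
    least ``min_prominence_frac`` of the trace span.  Phase is linear in
    time between consecutive peaks (0 at each peak); frames before the
    first / after the last peak extrapolate with the adjacent cycle's
    period.
    """
    x = signal.samples
    period = _dominant_period_frames(x)
    distance = max(1, int(round(min_separation_factor * period)))
    span = x.max() - x.min()
    peaks, _ = find_peaks(x, distance=distance, prominence=min_prominence_frac * span)
    if peaks.size < 2:
        raise InsufficientCyclesError("fewer than two breathing peaks detected")

    n = x.size
    idx = np.arange(n)
    phase = np.empty(n)
    periods = np.diff(peaks).astype(float)
    for j in range(peaks.size - 1):
        sel = (idx >= peaks[j]) & (idx < peaks[j + 1])
        phase[sel] = (idx[sel] - peaks[j]) / periods[j]
    before = idx < peaks[0]
    phase[before] = ((idx[before] - peaks[0]) / periods[0]) % 1.0
    after = idx >= peaks[-1]
    phase[after] = ((idx[after] - peaks[-1]) / periods[-1]) % 1.0

    bins = np.clip((phase * n_bins).astype(int), 0, n_bins - 1)
    return PhaseAssignment(phase=phase, bin_index=bins, peaks=peaks, n_bins=n_bins)


def bin_projections(
    stack: ProjectionStack, assignment: PhaseAssignment, n_bins: int | None = None
) -> list[np.ndarray]:
    """Partition frame indices by phase bin (disjoint, exhaustive).

    Returns one index array per bin; empty bins produce a logged warning
    and an empty array (the reconstruction stage decides how to react).
    """
    if n_bins is None:
        n_bins = assignment.n_bins
    if assignment.bin_index.size != len(stack):
        raise ValueError("assignment does not cover the stack")
    out = []
    for b in range(n_bins):
        members = np.nonzero(assignment.bin_index == b)[0]
        if members.size == 0:
            log.warning("phase bin %d is empty", b)
        out.append(members)
    return out
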