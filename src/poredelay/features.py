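"""Signal-level features shared by the rule classifiers.

Normalization, binned standard deviation, global and instantaneous spectral
entropy, and dynamic time warping distance.

Conventions (all 0-based, half-open):

* traces are min-max rescaled to [0, 1] before any binned-SD computation, so
  the sigma < 0.003 rule threshold lives on a unit scale;
* spectral entropy removes the mean before the DFT and retains positive
  frequencies only, so the DC component never dominates the spectrum;
* spectrogram frames are assigned to fractional positions by their center
  sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateTraceError
from .sim import EventTrace

__all__ = [
    "MsdProfile",
    "SpectrogramSpec",
    "SeTrace",
    "normalize_trace",
    "msd_profile",
    "spectral_entropy",
    "instantaneous_se",
    "dtw_distance",
]


@dataclass
class MsdProfile:
    """Per-bin standard deviations of a (normalized) event."""

    sigma_bins: np.ndarray
    bin_edges: list[tuple[int, int]]
    n_bins: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_index": np.arange(self.n_bins),
                "bin_start": [a for a, _ in self.bin_edges],
                "bin_stop": [b for _, b in self.bin_edges],
                "sigma": self.sigma_bins,
            }
        )


@dataclass(frozen=True)
class SpectrogramSpec:
    """Framing and tapering used for instantaneous spectral entropy."""

    window_len: int = 128
    overlap_frac: float = 0.5
    fft_len: int | None = None
    window_shape: str = "hamming"

    def hop(self) -> int:
        h = int(round(self.window_len * (1.0 - self.overlap_frac)))
        if h < 1:
            raise DegenerateTraceError("spectrogram hop must be >= 1 sample")
        return h


@dataclass
class SeTrace:
    """Instantaneous spectral entropy per spectrogram frame, each in [0, 1]."""

    se_values: np.ndarray
    frame_centers: np.ndarray
    frame_fracs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_center": self.frame_centers,
                "frame_frac": self.frame_fracs,
                "se": self.se_values,
            }
        )


def _as_samples(trace) -> np.ndarray:
    if isinstance(trace, EventTrace):
        return trace.samples
    return np.asarray(trace, dtype=float)


def normalize_trace(trace) -> np.ndarray:
    """Min-max rescale a trace to [0, 1]; order preserving, idempotent."""
    x = _as_samples(trace)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateTraceError("constant trace cannot be min-max normalized")
    return (x - lo) / (hi - lo)


def msd_profile(samples, n_bins: int) -> MsdProfile:
    """Partition into ``n_bins`` near-equal contiguous bins; per-bin sample SD.

    Uses the N-1 denominator.  The remainder of an uneven division is spread
    over the leading bins.  Intended to be applied to a normalized trace.
    """
    x = _as_samples(samples)
    n = x.size
    if n_bins < 2:
        raise DegenerateTraceError("n_bins must be >= 2")
    if n < n_bins:
        raise DegenerateTraceError(f"event of {n} samples is shorter than {n_bins} bins")
    edges = np.linspace(0, n, n_bins + 1).astype(int)
    sig = np.empty(n_bins)
    pairs = []
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        seg = x[a:b]
        sig[i] = seg.std(ddof=1) if seg.size > 1 else 0.0
        pairs.append((int(a), int(b)))
    return MsdProfile(sigma_bins=sig, bin_edges=pairs, n_bins=n_bins)


def _entropy_of_power(power: np.ndarray) -> float:
    """Shannon entropy of a power vector, normalized by log2 of its length."""
    total = power.sum()
    if total <= 0.0:
        return 0.0  # flat segment: limiting minimal-entropy case
    p = power / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum() / np.log2(power.size))


def spectral_entropy(samples) -> float:
    """Normalized spectral entropy of a whole signal, in [0, 1].

    The signal mean is removed before the DFT and only positive frequencies
    are retained, so N in the log2(N) normalization is the count of retained
    components.  Equals 1 exactly when all retained components carry equal
    power; approaches 0 for a pure tone.
    """
    x = _as_samples(samples)
    if x.size < 4:
        raise DegenerateTraceError("spectral entropy needs >= 4 samples")
    centred = x - x.mean()
    if not np.any(centred):
        raise DegenerateTraceError("spectral entropy undefined for a constant signal")
    power = np.abs(np.fft.rfft(centred)[1:]) ** 2
    return _entropy_of_power(power)


def instantaneous_se(samples, spec: SpectrogramSpec = SpectrogramSpec()) -> SeTrace:
    """Per-frame spectral entropy (the time-resolved variant used for classification).

    Frames of ``spec.window_len`` samples advance by the hop implied by
    ``spec.overlap_frac``.  Each frame is mean-removed, tapered, transformed,
    and its positive-frequency power distribution converted to a normalized
    entropy.  A zero-power frame (e.g. an exactly constant plateau) maps to
    SE = 0, the flat-signal limit.
    """
    x = _as_samples(samples)
    win = spec.window_len
    if x.size < win:
        raise DegenerateTraceError(
            f"event of {x.size} samples is shorter than the {win}-sample window"
        )
    hop = spec.hop()
    nfft = spec.fft_len or win
    if nfft < win:
        raise DegenerateTraceError("fft_len must be >= window_len")
    from scipy.signal import get_window

    taper = get_window(spec.window_shape, win, fftbins=True)
    n_frames = (x.size - win) // hop + 1
    starts = np.arange(n_frames) * hop
    se = np.empty(n_frames)
    for t, s in enumerate(starts):
        frame = x[s : s + win]
        frame = (frame - frame.mean()) * taper
        power = np.abs(np.fft.rfft(frame, n=nfft)[1:]) ** 2
        se[t] = _entropy_of_power(power)
    centers = starts + win // 2
    return SeTrace(
        se_values=se,
        frame_centers=centers,
        frame_fracs=centers / x.size,
    )


def dtw_distance(a, b) -> float:
    """Classic dynamic time warping distance.

    Absolute-difference local cost, symmetric step pattern
    (diagonal / vertical / horizontal), full dynamic program with no warping
    window; returns the accumulated optimal-path cost.
    """
    xa = _as_samples(a)
    xb = _as_samples(b)
    if xa.size == 0 or xb.size == 0:
        raise DegenerateTraceError("dtw_distance requires non-empty inputs")
    n, m = xa.size, xb.size
    prev = np.full(m + 1, np.inf)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur = np.full(m + 1, np.inf)
        cost = np.abs(xa[i - 1] - xb)
        for j in range(1, m + 1):
            cur[j] = cost[j - 1] + min(prev[j - 1], prev[j], cur[j - 1])
        prev = cur
    return float(prev[m])
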