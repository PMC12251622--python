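"""Trend features: slowly varying energy/frequency descriptors of a 10 s
segment that summarize the signal's volatility and instantaneous frequency
content, complementing the per-cycle morphology features.
"""

from __future__ import annotations

import numpy as np

from .spectral import SpectralFrame, fft_spectrum

SUBBANDS_HZ = ((0.5, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, 4.0), (4.0, 5.0))
STE_N_FRAMES = 20
STE_FRAME_LEN = 80


def stsse(x: np.ndarray, fs: float) -> np.ndarray:
    """Short-time spectral subband energy rate over five 0.5-5 Hz subbands.

    Subband energy is the sum of |X(k)|^2 over bins in the band (left-closed,
    right-open; the last band right-closed); ratios are normalized by the
    total in-band energy and sum to one.  Returns NaNs when the signal has no
    in-band energy.
    """
    x = np.asarray(x, dtype=float)
    if x.size < fs:
        raise ValueError("need at least one second of signal for subband energies")
    frame = fft_spectrum(x, fs)
    power = frame.magnitudes**2
    energies = np.empty(len(SUBBANDS_HZ))
    for i, (lo, hi) in enumerate(SUBBANDS_HZ):
        if i == len(SUBBANDS_HZ) - 1:
            mask = (frame.freqs >= lo) & (frame.freqs <= hi)
        else:
            mask = (frame.freqs >= lo) & (frame.freqs < hi)
        energies[i] = float(power[mask].sum())
    total = energies.sum()
    if total <= 0:
        return np.full(len(SUBBANDS_HZ), np.nan)
    return energies / total


def rms_energy(x: np.ndarray) -> float:
    """Root of the mean of the squared samples."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean(x**2)))


def frame_starts(n: int, n_frames: int = STE_N_FRAMES, frame_len: int = STE_FRAME_LEN) -> np.ndarray:
    """Start indices of ``n_frames`` rectangular frames tiling ``n`` samples.

    Frames overlap with hop floor((n - frame_len) / (n_frames - 1)) so that
    exactly ``n_frames`` frames of ``frame_len`` samples fit; when the signal
    is shorter than one frame a single truncated frame is used.
    """
    if n < frame_len:
        return np.array([0])
    if n_frames == 1:
        return np.array([0])
    hop = (n - frame_len) // (n_frames - 1)
    if hop < 1:
        hop = 1
    starts = np.arange(n_frames) * hop
    return starts[starts + frame_len <= n]


def short_time_energy(
    x: np.ndarray, n_frames: int = STE_N_FRAMES, frame_len: int = STE_FRAME_LEN
) -> np.ndarray:
    """Per-frame energy sum(|x[n]|^2) with a rectangular window."""
    x = np.asarray(x, dtype=float)
    if x.size < frame_len:
        return np.array([float(np.sum(x**2))])
    starts = frame_starts(x.size, n_frames, frame_len)
    return np.array([float(np.sum(x[s : s + frame_len] ** 2)) for s in starts])


def short_time_zcr(
    x: np.ndarray,
    n_frames: int = STE_N_FRAMES,
    frame_len: int = STE_FRAME_LEN,
    demean: bool = True,
) -> np.ndarray:
    """Per-frame zero-crossing rate, (1/(N-1)) * #{x[n] * x[n+1] < 0}.

    By default each frame is mean-removed first: a strictly positive pulse
    train never crosses zero, so the raw rate is degenerate; crossings of the
    frame mean carry the cycle-rate information instead.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return np.array([0.0])

    def _zcr(frame: np.ndarray) -> float:
        f = frame - frame.mean() if demean else frame
        return float(np.sum(f[:-1] * f[1:] < 0) / (frame.size - 1))

    if x.size < frame_len:
        return np.array([_zcr(x)])
    starts = frame_starts(x.size, n_frames, frame_len)
    return np.array([_zcr(x[s : s + frame_len]) for s in starts])


def overall_trend(x: np.ndarray) -> tuple[float, float, float]:
    """(amplitude, mean, population variance) of the whole span."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    return float(x.max() - x.min()), float(x.mean()), float(x.var())
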