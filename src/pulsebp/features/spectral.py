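"""FFT/STFT spectral primitives shared by the frequency and trend features."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass
class SpectralFrame:
    """One-sided magnitude spectrum on the grid f_k = k * fs / n_fft."""

    magnitudes: np.ndarray
    freqs: np.ndarray
    n_fft: int
    fs: float

    def __post_init__(self) -> None:
        if self.magnitudes.shape != self.freqs.shape:
            raise ValueError("magnitudes and freqs must be aligned")


def nextpow2(n: int) -> int:
    """Smallest power of two >= n."""
    if n < 1:
        raise ValueError("n must be positive")
    return 1 << (int(n - 1).bit_length())


def fft_spectrum(x: np.ndarray, fs: float, pad: bool = True) -> SpectralFrame:
    """One-sided FFT magnitude spectrum, zero-padded to 16 * nextpow2(len).

    The heavy zero padding refines the frequency grid so that spectral-peak
    features are not quantized by the short window length.  ``pad=False``
    computes the plain DFT of the frame instead: magnitude-weighted moments
    (centroid, bandwidth, entropy) are biased by the sinc sidelobes that zero
    padding spreads the mass into, so they use the unpadded spectrum.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples for a spectrum")
    n_fft = 16 * nextpow2(x.size) if pad else x.size
    mags = np.abs(np.fft.rfft(x, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    return SpectralFrame(magnitudes=mags, freqs=freqs, n_fft=n_fft, fs=fs)


def spectral_peaks(
    frame: SpectralFrame,
    band: tuple[float, float] = (0.5, 5.0),
    n_peaks: int = 3,
    min_sep_hz: float = 0.25,
) -> list[tuple[float, float]]:
    """Greedy (frequency, magnitude) list of the largest well-separated peaks.

    The first peak (the fundamental) is the magnitude maximum inside ``band``;
    subsequent peaks are the largest local maxima anywhere above ``band[0]``
    that keep at least ``min_sep_hz`` from every already accepted peak, so
    harmonics are found but zero-padding leakage sidelobes are not.
    """
    f, m = frame.freqs, frame.magnitudes
    in_band = (f >= band[0]) & (f <= band[1])
    if not np.any(in_band) or not np.any(m[in_band] > 0):
        return []
    k0 = np.flatnonzero(in_band)[int(np.argmax(m[in_band]))]
    chosen = [(float(f[k0]), float(m[k0]))]

    cand_idx, _ = sps.find_peaks(m)
    cand_idx = cand_idx[f[cand_idx] >= band[0]]
    order = cand_idx[np.argsort(m[cand_idx])[::-1]]
    for k in order:
        if len(chosen) >= n_peaks:
            break
        fk = float(f[k])
        if all(abs(fk - fc) >= min_sep_hz for fc, _ in chosen):
            chosen.append((fk, float(m[k])))
    return chosen


def spectral_centroid(frame: SpectralFrame) -> float:
    """Magnitude-weighted mean frequency (Hz); NaN for a zero spectrum."""
    total = float(np.sum(frame.magnitudes))
    if total <= 0:
        return float("nan")
    return float(np.sum(frame.freqs * frame.magnitudes) / total)


def spectral_bandwidth(frame: SpectralFrame) -> float:
    """Magnitude-weighted RMS distance from the centroid (Hz)."""
    total = float(np.sum(frame.magnitudes))
    if total <= 0:
        return float("nan")
    c = spectral_centroid(frame)
    return float(np.sqrt(np.sum((frame.freqs - c) ** 2 * frame.magnitudes) / total))


def spectral_entropy(frame: SpectralFrame) -> float:
    """Shannon entropy of the normalized power spectrum, scaled to [0, 1]."""
    p = frame.magnitudes**2
    total = float(np.sum(p))
    if total <= 0:
        return float("nan")
    p = p / total
    nz = p[p > 0]
    h = -float(np.sum(nz * np.log2(nz)))
    return h / np.log2(p.size)


def instantaneous_frequency(
    x: np.ndarray, fs: float, nperseg: int = 32
) -> tuple[float, float]:
    """Mean and std of the per-frame STFT spectral centroid (Hz)."""
    x = np.asarray(x, dtype=float)
    nperseg = min(nperseg, x.size)
    if nperseg < 8:
        return float("nan"), float("nan")
    f, _, Z = sps.stft(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    mags = np.abs(Z)
    totals = mags.sum(axis=0)
    valid = totals > 0
    if not np.any(valid):
        return float("nan"), float("nan")
    cent = (f[:, None] * mags[:, valid]).sum(axis=0) / totals[valid]
    return float(np.mean(cent)), float(np.std(cent))
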