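"""Single-cycle pulse delineation: systolic peak, feet, notch, diastolic peak."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from ..records import ROI


class DelineationError(ValueError):
    """The ROI does not contain a usable systolic peak."""


@dataclass
class CycleLandmarks:
    """Indices/values of the cardinal points of the central cycle.

    Indices are positions within the (un-padded) ROI window; times are in
    seconds relative to ``foot_start``.  ``dicrotic_notch`` and
    ``peak_diastolic`` may be None when undetectable (e.g. a pulse without a
    dicrotic wave); features depending on them become NaN.
    """

    peak_systolic: int
    psv: float
    foot_start: int
    foot_end: int
    dicrotic_notch: Optional[int]
    dn: float
    peak_diastolic: Optional[int]
    pdv: float
    fs: float

    @property
    def t_pi(self) -> float:
        """Pulse period in seconds (foot to foot)."""
        return (self.foot_end - self.foot_start) / self.fs

    def time_of(self, index: Optional[int]) -> float:
        """Seconds from foot_start to ``index`` (NaN when index is None)."""
        if index is None:
            return float("nan")
        return (index - self.foot_start) / self.fs

    @property
    def spt(self) -> float:
        return self.time_of(self.peak_systolic)

    @property
    def dnt(self) -> float:
        return self.time_of(self.dicrotic_notch)

    @property
    def dpt(self) -> float:
        return self.time_of(self.peak_diastolic)


def _local_min_index(x: np.ndarray, lo: int, hi: int) -> int:
    """Index of the minimum of x[lo:hi] (absolute index)."""
    return lo + int(np.argmin(x[lo:hi]))


def delineate_cycle(roi: ROI) -> CycleLandmarks:
    """Locate the cardinal points of the central cycle of an ROI.

    The systolic peak is the recorded central peak (falling back to the
    global maximum); the cycle feet are the minima flanking it; the dicrotic
    notch is searched as a local minimum within half a pulse period after the
    peak, falling back to the maximum of the second derivative in the same
    window; the diastolic peak is the first local maximum after the notch,
    falling back to the notch itself.
    """
    x = roi.valid_samples
    if x.size < 5:
        raise DelineationError("ROI too short to delineate")

    peak = int(roi.center_peak)
    if not (0 < peak < x.size - 1):
        peak = int(np.argmax(x))
    if not (0 < peak < x.size - 1):
        raise DelineationError("no interior systolic peak in ROI")

    foot_start = _local_min_index(x, 0, peak)
    foot_end = _local_min_index(x, peak + 1, x.size)
    if foot_end <= peak or foot_start >= peak:
        raise DelineationError("degenerate cycle feet")

    t_pi = (foot_end - foot_start) / roi.fs
    search_hi = min(foot_end, peak + 1 + int(round(0.5 * t_pi * roi.fs)))

    notch: Optional[int] = None
    if search_hi - (peak + 1) >= 3:
        seg = x[peak + 1 : search_hi]
        minima, _ = find_peaks(-seg)
        if minima.size:
            notch = peak + 1 + int(minima[0])
        else:
            d2 = np.gradient(np.gradient(x))
            inner = d2[peak + 1 : search_hi]
            if inner.size >= 3:
                cand = peak + 1 + int(np.argmax(inner))
                if peak < cand < foot_end:
                    notch = cand

    diastolic: Optional[int] = None
    if notch is not None and notch + 1 < foot_end:
        seg = x[notch : foot_end + 1]
        maxima, _ = find_peaks(seg)
        if maxima.size:
            diastolic = notch + int(maxima[0])
        else:
            diastolic = notch  # fallback: notch point

    return CycleLandmarks(
        peak_systolic=peak,
        psv=float(x[peak]),
        foot_start=foot_start,
        foot_end=foot_end,
        dicrotic_notch=notch,
        dn=float(x[notch]) if notch is not None else float("nan"),
        peak_diastolic=diastolic,
        pdv=float(x[diastolic]) if diastolic is not None else float("nan"),
        fs=roi.fs,
    )
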