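"""Filtering, segmentation, quality control and systolic-peak detection.

The processing chain is:

1. fifth-order Butterworth band-pass, 0.5-5 Hz, applied forward-backward
   (zero phase) so peak times are not shifted;
2. partition into non-overlapping 10 s segments, each min-max normalized to
   [0, 1];
3. QC rule 1 - flat runs: three consecutive identical raw samples mark a
   segment as discontinuous/saturated;
4. systolic peak detection with two event-related moving averages (TERMA):
   a short "peak" average (w2 = 0.111 s) and a long "beat" average
   (w1 = 0.667 s); candidate blocks are runs where the peak average exceeds
   the beat average plus an offset alpha = beta * mean(clipped segment),
   beta = 0.03; blocks shorter than the peak-kernel width are dropped and
   each surviving block contributes one peak at its amplitude maximum;
5. QC rule 2 - a segment must contain at least 8 systolic peaks;
6. single-cycle regions of interest: for every interior peak p_i the window
   [p_{i-1}, p_{i+1}] (inclusive) is cut out and labelled with the
   max/min of the aligned ABP over the window;
7. each ROI is shaped to exactly 80 samples (zero-pad tail / truncate).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .records import PPGRecord, ROI, Segment

SEGMENT_SECONDS = 10.0
ROI_TARGET_LEN = 80


@dataclass
class PeakDetectorConfig:
    """TERMA detector settings; defaults are the published constants."""

    w1_s: float = 0.667  # beat-emphasis window (s)
    w2_s: float = 0.111  # peak-emphasis window (s)
    beta: float = 0.03  # threshold offset coefficient
    min_peaks_per_segment: int = 8

    def __post_init__(self) -> None:
        if not (self.w1_s > self.w2_s > 0):
            raise ValueError("windows must satisfy w1_s > w2_s > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class PeakDetectionTrace:
    """Intermediate series of the TERMA detector, kept for inspection."""

    ppg_seg: np.ndarray  # clipped segment
    ppg_beat: np.ndarray  # long moving average
    ppg_peak: np.ndarray  # short moving average
    th_peak: np.ndarray  # threshold series
    blocks: list[tuple[int, int]]  # accepted (start, end) runs, end exclusive
    peaks: np.ndarray  # ascending systolic peak indices


def bandpass_filter(rec: PPGRecord) -> PPGRecord:
    """Zero-phase 0.5-5 Hz fifth-order Butterworth band-pass."""
    if rec.fs <= 10.0:
        raise ValueError(
            f"sampling rate {rec.fs} Hz too low for a 5 Hz passband (need > 10 Hz)"
        )
    sos = sps.butter(5, [0.5, 5.0], btype="bandpass", fs=rec.fs, output="sos")
    out = rec.copy()
    out.samples = sps.sosfiltfilt(sos, rec.samples)
    return out


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """'same'-length uniform moving average with edge replication."""
    if width < 1:
        raise ValueError("kernel width must be >= 1")
    left = width // 2
    right = width - 1 - left
    padded = np.pad(x, (left, right), mode="edge")
    kernel = np.full(width, 1.0 / width)
    return np.convolve(padded, kernel, mode="valid")


def kernel_length(w_s: float, fs: float) -> int:
    """Number of taps of a w-second uniform kernel at rate fs."""
    return max(1, int(round(w_s * fs)))


def segment_record(rec: PPGRecord, raw: PPGRecord | None = None) -> list[Segment]:
    """Cut a (filtered) record into consecutive 10 s min-max-normalized segments.

    ``raw`` optionally supplies the unfiltered record of identical length so
    each segment keeps the original sample values for the flat-run check.
    A trailing remainder shorter than 10 s is discarded.  A segment with zero
    amplitude range cannot be normalized and is flagged ``degenerate_range``.
    """
    seg_len = int(round(SEGMENT_SECONDS * rec.fs))
    n_seg = rec.samples.size // seg_len
    raw_samples = raw.samples if raw is not None else rec.samples
    segments: list[Segment] = []
    for k in range(n_seg):
        i0, i1 = k * seg_len, (k + 1) * seg_len
        chunk = rec.samples[i0:i1]
        lo, hi = float(chunk.min()), float(chunk.max())
        if hi > lo:
            normed = (chunk - lo) / (hi - lo)
            ok, reason = True, ""
        else:
            normed = np.zeros_like(chunk)
            ok, reason = False, "degenerate_range"
        segments.append(
            Segment(
                samples=normed,
                fs=rec.fs,
                parent_id=rec.record_id,
                start_index=i0,
                qc_pass=ok,
                qc_reason=reason,
                raw=raw_samples[i0:i1].copy(),
                abp=None if rec.abp is None else rec.abp[i0:i1].copy(),
            )
        )
    return segments


def reject_flat_runs(seg: Segment) -> Segment:
    """Fail QC iff any three consecutive raw samples are exactly equal."""
    x = seg.raw if seg.raw is not None else seg.samples
    if x.size >= 3:
        flat = (x[:-2] == x[1:-1]) & (x[1:-1] == x[2:])
        if bool(np.any(flat)):
            return replace(seg, qc_pass=False, qc_reason="flat_run")
    return seg


def detect_systolic_peaks(seg: Segment, cfg: PeakDetectorConfig | None = None) -> PeakDetectionTrace:
    """TERMA systolic-peak detection on a filtered, normalized segment.

    The segment is mean-centered, truncated below zero and squared before the
    two moving averages are taken.  Centering restores the zero level that the
    [0, 1] normalization removed (so the clipping step is meaningful) and
    squaring emphasizes the systolic peak over the dicrotic wave, which would
    otherwise produce a second threshold crossing per cycle.
    """
    cfg = cfg or PeakDetectorConfig()
    centered = seg.samples - float(np.mean(seg.samples))
    x = np.clip(centered, 0.0, None) ** 2  # truncate below zero, emphasize peaks
    n_beat = kernel_length(cfg.w1_s, seg.fs)
    n_peak = kernel_length(cfg.w2_s, seg.fs)
    ppg_beat = moving_average(x, n_beat)
    ppg_peak = moving_average(x, n_peak)
    alpha = cfg.beta * float(np.mean(x))
    th_peak = ppg_beat + alpha

    above = ppg_peak > th_peak
    blocks: list[tuple[int, int]] = []
    peaks: list[int] = []
    if np.any(above):
        idx = np.flatnonzero(above)
        run_starts = [int(idx[0])]
        run_ends = []
        gaps = np.flatnonzero(np.diff(idx) > 1)
        for g in gaps:
            run_ends.append(int(idx[g]) + 1)
            run_starts.append(int(idx[g + 1]))
        run_ends.append(int(idx[-1]) + 1)
        for s, e in zip(run_starts, run_ends):
            if e - s >= n_peak:  # block-width gate
                blocks.append((s, e))
                peaks.append(s + int(np.argmax(x[s:e])))
    return PeakDetectionTrace(
        ppg_seg=x,
        ppg_beat=ppg_beat,
        ppg_peak=ppg_peak,
        th_peak=th_peak,
        blocks=blocks,
        peaks=np.asarray(sorted(peaks), dtype=int),
    )


def qc_segment(
    seg: Segment, trace: PeakDetectionTrace, cfg: PeakDetectorConfig | None = None
) -> Segment:
    """Combine the flat-run verdict with the minimum-peak-count rule."""
    cfg = cfg or PeakDetectorConfig()
    out = replace(seg, peaks=trace.peaks)
    if not seg.qc_pass:
        return out
    if trace.peaks.size < cfg.min_peaks_per_segment:
        return replace(out, qc_pass=False, qc_reason="too_few_peaks")
    return replace(out, qc_pass=True, qc_reason="")


def extract_rois(seg: Segment, trace: PeakDetectionTrace | None = None) -> list[ROI]:
    """Cut one single-cycle ROI per interior systolic peak.

    For peaks p_0..p_{n-1}, interior peak p_i (1 <= i <= n-2) yields the
    window [p_{i-1}, p_{i+1}] inclusive.  Labels are the max/min of the
    aligned ABP over the window when ABP is present.
    """
    peaks = trace.peaks if trace is not None else seg.peaks
    if peaks.size < 3:
        return []
    rois: list[ROI] = []
    for i in range(1, peaks.size - 1):
        a, b = int(peaks[i - 1]), int(peaks[i + 1])
        window = seg.samples[a : b + 1].copy()
        sbp = dbp = None
        if seg.abp is not None:
            abp_win = seg.abp[a : b + 1]
            sbp, dbp = float(abp_win.max()), float(abp_win.min())
        rois.append(
            ROI(
                samples=window,
                fs=seg.fs,
                center_peak=int(peaks[i]) - a,
                sbp=sbp,
                dbp=dbp,
                parent_id=seg.parent_id,
                start_index=seg.start_index + a,
            )
        )
    return rois


def shape_to_length(roi: ROI, target: int = ROI_TARGET_LEN) -> ROI:
    """Force the ROI to ``target`` samples: zero-pad the tail or truncate it."""
    n = roi.samples.size
    if n == target:
        return roi
    # original_length records the pre-shaping window length and survives
    # repeated shaping calls
    original = roi.original_length or n
    if n < target:
        samples = np.concatenate([roi.samples, np.zeros(target - n)])
        return replace(roi, samples=samples, padded=True, original_length=original)
    return replace(roi, samples=roi.samples[:target].copy(), original_length=original)


def preprocess_record(
    rec: PPGRecord, cfg: PeakDetectorConfig | None = None, target_len: int = ROI_TARGET_LEN
) -> tuple[list[Segment], list[tuple[Segment, ROI]]]:
    """Run the full chain on one record.

    Returns all segments (with final QC state) and the list of
    (parent segment, shaped ROI) pairs from QC-passing segments.
    """
    cfg = cfg or PeakDetectorConfig()
    filtered = bandpass_filter(rec)
    segments = segment_record(filtered, raw=rec)
    out_segments: list[Segment] = []
    pairs: list[tuple[Segment, ROI]] = []
    for seg in segments:
        seg = reject_flat_runs(seg)
        trace = detect_systolic_peaks(seg, cfg)
        seg = qc_segment(seg, trace, cfg)
        out_segments.append(seg)
        if not seg.qc_pass:
            continue
        for roi in extract_rois(seg, trace):
            pairs.append((seg, shape_to_length(roi, target_len)))
    return out_segments, pairs


def qc_report(segments: list[Segment]) -> "pd.DataFrame":
    """Per-segment QC table (segment_id, qc_pass, reason, n_peaks)."""
    import pandas as pd

    rows = [
        {
            "segment_id": f"{s.parent_id}:{s.start_index}",
            "qc_pass": s.qc_pass,
            "reason": s.qc_reason,
            "n_peaks": int(s.peaks.size),
        }
        for s in segments
    ]
    return pd.DataFrame(rows, columns=["segment_id", "qc_pass", "reason", "n_peaks"])
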