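"""Core data containers shared across the pipeline.

A :class:`PPGRecord` is a continuous photoplethysmogram, optionally with a
time-aligned invasive arterial-pressure (ABP) trace used for labelling.
Downstream stages produce :class:`Segment` (a 10 s quality-controlled window)
and :class:`ROI` (a single-cycle window spanning from the preceding to the
following systolic peak).  A :class:`DatasetBundle` collects the model-ready
per-record blocks of inputs and SBP/DBP labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np


@dataclass
class PPGRecord:
    """A continuous PPG trace with sampling-rate metadata.

    Parameters
    ----------
    samples : ndarray
        Amplitude series in arbitrary units.
    fs : float
        Sampling rate in Hz (the reference ICU waveform rate is 62.4725 Hz).
    abp : ndarray, optional
        Time-aligned arterial blood pressure in mmHg, same length and rate.
    record_id : str
        Identifier used in provenance and QC reports.
    meta : dict
        Free-form provenance map (generator latents, corrupted spans, ...).
    """

    samples: np.ndarray
    fs: float
    abp: Optional[np.ndarray] = None
    record_id: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise ValueError("record has no samples")
        if self.abp is not None:
            self.abp = np.asarray(self.abp, dtype=float)
            if self.abp.shape != self.samples.shape:
                raise ValueError(
                    "ABP trace must be aligned sample-for-sample with the PPG"
                )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def copy(self) -> "PPGRecord":
        return PPGRecord(
            samples=self.samples.copy(),
            fs=self.fs,
            abp=None if self.abp is None else self.abp.copy(),
            record_id=self.record_id,
            meta=dict(self.meta),
        )


@dataclass
class Segment:
    """A 10 s window of a record, min-max normalized, with QC state.

    ``samples`` holds the filtered, normalized amplitudes; ``raw`` keeps the
    unfiltered values of the same span so that the flat-run (saturation) check
    can compare exact ADC codes; ``abp`` is the aligned pressure slice used
    for ROI labelling.
    """

    samples: np.ndarray
    fs: float
    parent_id: str = ""
    start_index: int = 0
    peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    qc_pass: bool = True
    qc_reason: str = ""
    raw: Optional[np.ndarray] = None
    abp: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass
class ROI:
    """A single-cycle region of interest spanning three systolic peaks.

    The window runs from the previous systolic peak to the next one, so it
    contains a full cardiac cycle plus the flanking downstroke and upstroke.
    After :func:`pulsebp.preprocess.shape_to_length` the window is exactly 80
    samples; shorter windows are zero-padded at the tail.
    """

    samples: np.ndarray
    fs: float
    center_peak: int
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    padded: bool = False
    original_length: int = 0
    parent_id: str = ""
    start_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.original_length == 0:
            self.original_length = int(self.samples.size)

    @property
    def valid_samples(self) -> np.ndarray:
        """The un-padded portion of the window (``original_length`` keeps the
        pre-shaping length, which exceeds the array size after truncation)."""
        return self.samples[: min(self.original_length, self.samples.size)]


@dataclass
class DatasetBundle:
    """Per-record blocks of model inputs and [SBP, DBP] labels.

    ``X[n]`` is a ``(p_n, n_feature_cols + seq_len)`` block whose leading
    columns are the manual feature vector and trailing columns the 80-sample
    cycle sequence; ``Y[n]`` is ``(p_n, 2)`` in mmHg.  ``M == len(X)``.
    """

    X: list[np.ndarray]
    Y: list[np.ndarray]
    n_feature_cols: int
    seq_len: int

    def __post_init__(self) -> None:
        if len(self.X) != len(self.Y):
            raise ValueError("X and Y must have the same number of blocks")
        for xb, yb in zip(self.X, self.Y):
            if xb.shape[0] != yb.shape[0]:
                raise ValueError("block row counts disagree between X and Y")
            if yb.shape[1] != 2:
                raise ValueError("label blocks must have two columns [SBP, DBP]")
            if not np.all(np.isfinite(yb)):
                raise ValueError("labels must be finite")
            if np.any(yb[:, 0] <= yb[:, 1]):
                raise ValueError("every row must satisfy SBP > DBP")

    @property
    def M(self) -> int:
        return len(self.X)

    @property
    def n_rois(self) -> int:
        return int(sum(xb.shape[0] for xb in self.X))

    def stacked(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (features, sequences, labels) stacked over all blocks."""
        X = np.vstack(self.X) if self.X else np.empty((0, self.n_feature_cols + self.seq_len))
        Y = np.vstack(self.Y) if self.Y else np.empty((0, 2))
        return X[:, : self.n_feature_cols], X[:, self.n_feature_cols :], Y

    def design_matrix(self) -> np.ndarray:
        """Features and sequences side by side, one row per ROI."""
        return np.vstack(self.X)

    def labels(self) -> np.ndarray:
        return np.vstack(self.Y)
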