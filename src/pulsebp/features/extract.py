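"""Assembly of the full 138-dimensional feature vector for one ROI."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..records import ROI, Segment
from .groups import (
    derivative_features,
    frequency_features,
    morphological_features,
    statistical_features,
    time_domain_features,
)
from .landmarks import CycleLandmarks, DelineationError, delineate_cycle
from .registry import FeatureRegistry, default_registry
from .spectral import fft_spectrum, spectral_bandwidth, spectral_centroid
from .trend import overall_trend, rms_energy, short_time_energy, short_time_zcr, stsse


@dataclass
class FeatureVector:
    """The ordered feature values of one ROI plus an undefined-value mask."""

    values: np.ndarray
    nan_mask: np.ndarray
    roi_ref: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != self.nan_mask.shape:
            raise ValueError("values and nan_mask must be aligned")


def trend_features(segment_samples: np.ndarray, fs: float) -> dict[str, float]:
    """The trend group, computed on the parent 10 s segment."""
    x = np.asarray(segment_samples, dtype=float)
    ratios = stsse(x, fs)
    frame = fft_spectrum(x, fs, pad=False)  # unpadded for weighted moments
    amp, mean, var = overall_trend(x)
    ste = short_time_energy(x)
    zcr = short_time_zcr(x)
    out = {f"STSSE_{i + 1}": float(r) for i, r in enumerate(ratios)}
    out.update(
        {
            "E_RMS": rms_energy(x),
            "spectral_centroid": spectral_centroid(frame),
            "spectral_bandwidth": spectral_bandwidth(frame),
            "trend_amplitude": amp,
            "trend_mean": mean,
            "trend_variance": var,
            "STE_mean": float(np.mean(ste)),
            "STE_var": float(np.var(ste)),
            "STZCR_mean": float(np.mean(zcr)),
            "STZCR_var": float(np.var(zcr)),
        }
    )
    return out


def extract_all(
    roi: ROI,
    parent: Segment,
    registry: Optional[FeatureRegistry] = None,
) -> FeatureVector:
    """Evaluate every registry entry for one ROI.

    Per-cycle groups are computed on the (un-padded) ROI; the trend group on
    the parent segment.  Features whose landmarks are undefined come back as
    NaN with the mask set; the vector itself is always complete.
    """
    registry = registry if registry is not None else default_registry()
    values: dict[str, float] = {}

    lm: Optional[CycleLandmarks] = None
    try:
        lm = delineate_cycle(roi)
    except DelineationError:
        pass

    if lm is not None:
        values.update(time_domain_features(lm, roi))
        values.update(morphological_features(lm, roi))
        values.update(statistical_features(roi, lm))
        values.update(derivative_features(lm, roi))
    else:
        values.update(statistical_features(roi))
    values.update(frequency_features(roi))
    values.update(trend_features(parent.samples, parent.fs))

    vec = np.array([values.get(name, float("nan")) for name in registry.names])
    mask = ~np.isfinite(vec)
    return FeatureVector(
        values=vec,
        nan_mask=mask,
        roi_ref=f"{roi.parent_id}:{roi.start_index}",
    )


class CycleFeatureExtractor:
    """Batch extractor over (ROI, parent segment) pairs.

    Follows the transformer idiom: ``transform`` maps a list of pairs to an
    ``(n, 138)`` array.  Extraction is stateless, so ``fit`` is a no-op kept
    for pipeline compatibility.
    """

    def __init__(self, registry: Optional[FeatureRegistry] = None):
        self.registry = registry

    def _registry(self) -> FeatureRegistry:
        return self.registry if self.registry is not None else default_registry()

    def fit(self, X=None, y=None) -> "CycleFeatureExtractor":
        return self

    def extract(self, roi: ROI, parent: Segment) -> FeatureVector:
        return extract_all(roi, parent, self._registry())

    def transform(self, pairs: list[tuple[Segment, ROI]]) -> np.ndarray:
        reg = self._registry()
        return np.array([extract_all(roi, seg, reg).values for seg, roi in pairs])

    def feature_names_out(self) -> list[str]:
        return self._registry().names
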