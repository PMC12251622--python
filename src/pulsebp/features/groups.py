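"""Per-cycle feature groups: time-domain, morphological, statistical,
frequency-domain and derivative features.  Every function returns a
``{name: value}`` dict whose keys match the registry; undefined quantities
(e.g. notch-dependent values when no dicrotic notch was found) are NaN.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as spstats
from scipy.signal import find_peaks

from ..records import ROI
from .landmarks import CycleLandmarks
from .spectral import (
    fft_spectrum,
    instantaneous_frequency,
    spectral_entropy,
    spectral_peaks,
)

NAN = float("nan")


def _crossing_time_up(x: np.ndarray, i0: int, i1: int, level: float, fs: float) -> float:
    """Seconds from i0 to the first upward crossing of ``level`` in x[i0:i1]."""
    seg = x[i0 : i1 + 1]
    above = seg >= level
    if not np.any(above):
        return NAN
    k = int(np.argmax(above))
    if k == 0:
        return 0.0
    x0, x1 = seg[k - 1], seg[k]
    frac = 0.0 if x1 == x0 else (level - x0) / (x1 - x0)
    return (k - 1 + frac) / fs


def _crossing_time_down(x: np.ndarray, i0: int, i1: int, level: float, fs: float) -> float:
    """Seconds from the last downward crossing of ``level`` in x[i0:i1] to i1."""
    seg = x[i0 : i1 + 1]
    above = seg >= level
    if not np.any(above):
        return NAN
    k = int(len(seg) - 1 - np.argmax(above[::-1]))  # last index still above
    if k == len(seg) - 1:
        return 0.0
    x0, x1 = seg[k], seg[k + 1]
    frac = 0.0 if x1 == x0 else (x0 - level) / (x0 - x1)
    return (len(seg) - 1 - k - frac) / fs


def time_domain_features(lm: CycleLandmarks, roi: ROI) -> dict[str, float]:
    x = roi.valid_samples
    fs = roi.fs
    cyc = x[lm.foot_start : lm.foot_end + 1]
    psv, pdv, dn = lm.psv, lm.pdv, lm.dn
    t_pi, spt, dnt, dpt = lm.t_pi, lm.spt, lm.dnt, lm.dpt
    v_start = float(x[lm.foot_start])
    v_end = float(x[lm.foot_end])
    vi = float(cyc.min())

    # width at half systolic height: time between the half-level crossings
    # on the ascending and descending branches
    half = vi + 0.5 * (psv - vi)
    up = _crossing_time_up(x, lm.foot_start, lm.peak_systolic, half, fs)
    down = _crossing_time_down(x, lm.peak_systolic, lm.foot_end, half, fs)
    width = t_pi - up - down if np.isfinite(up) and np.isfinite(down) else NAN

    # areas by trapezoidal integration (time axis in seconds)
    asc = x[lm.foot_start : lm.peak_systolic + 1]
    desc = x[lm.peak_systolic : lm.foot_end + 1]
    a1 = float(np.trapezoid(asc, dx=1.0 / fs))
    a2 = float(np.trapezoid(desc, dx=1.0 / fs))

    dtd = (lm.foot_end - lm.peak_systolic) / fs
    aid = psv - v_start
    did = psv - v_end
    k_val = (float(cyc.mean()) - vi) / (psv - vi) if psv > vi else NAN
    denom_dpt = t_pi - dpt

    feats = {
        "PSV": psv,
        "PDV": pdv,
        "DN": dn,
        "t_PI": t_pi,
        "PDV_over_PSV": pdv / psv if psv else NAN,
        "PSV_minus_PDV_over_PSV": (psv - pdv) / psv if psv else NAN,
        "DN_over_PSV": dn / psv if psv else NAN,
        "PDV_minus_DN_over_PSV": (pdv - dn) / psv if psv else NAN,
        "SPT": spt,
        "DNT": dnt,
        "DPT": dpt,
        "DPT_minus_SPT": dpt - spt,
        "width_half": width,
        "A2_over_A1": a2 / a1 if a1 else NAN,
        "SPT_over_PSV": spt / psv if psv else NAN,
        "PDV_over_tPI_minus_DPT": pdv / denom_dpt if denom_dpt else NAN,
        "SPT_over_tPI": spt / t_pi if t_pi else NAN,
        "DNT_over_tPI": dnt / t_pi if t_pi else NAN,
        "DPT_over_tPI": dpt / t_pi if t_pi else NAN,
        "DPT_minus_SPT_over_tPI": (dpt - spt) / t_pi if t_pi else NAN,
        "VI": vi,
        "PT": t_pi,  # cycle duration
        "PI": psv - vi,
        "DTD": dtd,
        "AID": aid,
        "DID": did,
        "AS": (psv - v_start) / spt if spt else NAN,
        "DS": (psv - v_end) / dtd if dtd else NAN,
        "K": k_val,
        "AA": a2,
        "DA": a1,
    }
    return feats


def morphological_features(lm: CycleLandmarks, roi: ROI) -> dict[str, float]:
    """Decile threshold levels and rise/fall crossing times.

    The ascending amplitude AID = PSV - value(foot_start) is split into ten
    levels; SW_x is the time from the wave start to the (interpolated)
    upward crossing of level x.  Symmetrically DID and DW_x use the wave end.
    DAS_x = SW_x + DW_x, DDS_x = DW_x / SW_x.
    """
    x = roi.valid_samples
    fs = roi.fs
    v_start = float(x[lm.foot_start])
    v_end = float(x[lm.foot_end])
    aid_amp = lm.psv - v_start
    did_amp = lm.psv - v_end

    feats: dict[str, float] = {}
    for i in range(1, 11):
        # i == 10 maps to PSV exactly; avoid the level drifting above the
        # branch maximum through floating-point accumulation
        lvl_a = lm.psv if i == 10 else v_start + aid_amp * i / 10.0
        lvl_d = lm.psv if i == 10 else v_end + did_amp * i / 10.0
        sw = _crossing_time_up(x, lm.foot_start, lm.peak_systolic, lvl_a, fs)
        dw = _crossing_time_down(x, lm.peak_systolic, lm.foot_end, lvl_d, fs)
        feats[f"AID_{i}"] = lvl_a
        feats[f"DID_{i}"] = lvl_d
        feats[f"SW_{i}"] = sw
        feats[f"DW_{i}"] = dw
        feats[f"DAS_{i}"] = sw + dw
        feats[f"DDS_{i}"] = dw / sw if sw else NAN
    return feats


def statistical_features(roi: ROI, lm: CycleLandmarks | None = None) -> dict[str, float]:
    """Skewness, kurtosis (Pearson convention: normal -> 3), variance and the
    max-to-mean-square ratio over the cycle."""
    x = roi.valid_samples
    if lm is not None:
        x = x[lm.foot_start : lm.foot_end + 1]
    var = float(np.var(x))
    if var == 0:
        return {"SK": NAN, "KU": NAN, "VAR": 0.0, "MF": NAN}
    msq = float(np.mean(x**2))
    return {
        "SK": float(spstats.skew(x)),
        "KU": float(spstats.kurtosis(x, fisher=False)),
        "VAR": var,
        "MF": float(x.max()) / msq if msq else NAN,
    }


def frequency_features(roi: ROI) -> dict[str, float]:
    """Spectral-peak features of the cycle plus STFT-derived scalars.

    The fundamental is the largest magnitude in 0.5-5 Hz (heart rate in bpm
    is 60x this value); the second/third components are the next largest
    spectral peaks at least 0.25 Hz away from already chosen ones.
    """
    x = roi.valid_samples
    out = {k: NAN for k in (
        "f_base", "spmag_base", "f_2", "spmag_2", "f_3", "spmag_3",
        "inst_freq_mean", "inst_freq_std", "spectral_entropy",
    )}
    if x.size < 4:
        return out
    frame = fft_spectrum(x, roi.fs)
    peaks = spectral_peaks(frame)
    if len(peaks) > 0:
        out["f_base"], out["spmag_base"] = peaks[0]
    if len(peaks) > 1:
        out["f_2"], out["spmag_2"] = peaks[1]
    if len(peaks) > 2:
        out["f_3"], out["spmag_3"] = peaks[2]
    out["spectral_entropy"] = spectral_entropy(fft_spectrum(x, roi.fs, pad=False))
    out["inst_freq_mean"], out["inst_freq_std"] = instantaneous_frequency(x, roi.fs)
    return out


def _ordered_extrema(d: np.ndarray) -> tuple[list[int], list[int]]:
    """Plateau-tolerant local maxima and minima indices, in time order.

    Falls back to the global extremum when no interior local extremum exists
    (monotone or piecewise-linear derivative traces).
    """
    maxima = list(find_peaks(d, plateau_size=1)[0])
    minima = list(find_peaks(-d, plateau_size=1)[0])
    if not maxima:
        maxima = [int(np.argmax(d))]
    if not minima:
        minima = [int(np.argmin(d))]
    return maxima, minima


def derivative_features(lm: CycleLandmarks, roi: ROI) -> dict[str, float]:
    x = roi.valid_samples
    fs = roi.fs
    cyc = x[lm.foot_start : lm.foot_end + 1]
    if cyc.size < 5:
        return {}
    d1 = np.gradient(cyc) * fs
    d2 = np.gradient(d1) * fs

    t_pi = lm.t_pi

    def t_of(i: int | None) -> float:
        return NAN if i is None else i / fs

    max1, min1 = _ordered_extrema(d1)
    max2, min2 = _ordered_extrema(d2)

    tff_max = t_of(max1[0])
    tff_min = t_of(min1[0])
    tsf_max = t_of(max1[1]) if len(max1) > 1 else NAN
    tsf_min = t_of(min1[1]) if len(min1) > 1 else NAN
    tfs_max = t_of(max2[0])
    tfs_min = t_of(min2[0])

    fs_max = float(d1.max())
    fs_min = float(d1.min())
    ss_max = float(d2.max())
    if fs_max == 0:
        ratio1 = ratio2 = ratio3 = NAN
    else:
        ratio1 = fs_min / fs_max
        ratio2 = ss_max / fs_max
        ratio3 = (fs_min + ss_max) / fs_max

    def over_tpi(v: float) -> float:
        return v / t_pi if t_pi else NAN

    return {
        "TFF_MAX": tff_max,
        "TFF_MIN": tff_min,
        "TSF_MAX": tsf_max,
        "TSF_MIN": tsf_min,
        "FSMIN_over_FSMAX": ratio1,
        "SSMAX_over_FSMAX": ratio2,
        "FSMIN_plus_SSMAX_over_FSMAX": ratio3,
        "TFS_MAX": tfs_max,
        "TFS_MIN": tfs_min,
        "TFF_MAX_over_tPI": over_tpi(tff_max),
        "TFF_MIN_over_tPI": over_tpi(tff_min),
        "TSF_MAX_over_tPI": over_tpi(tsf_max),
        "TSF_MIN_over_tPI": over_tpi(tsf_min),
        "TFS_MAX_over_tPI": over_tpi(tfs_max),
        "TFS_MIN_over_tPI": over_tpi(tfs_min),
        "TFF_MAX_minus_TFS_MAX_over_tPI": over_tpi(tff_max - tfs_max),
        "TFF_MIN_minus_TFS_MIN_over_tPI": over_tpi(tff_min - tfs_min),
        "TSF_MAX_minus_DNT_over_tPI": over_tpi(tsf_max - lm.dnt),
        "TSF_MIN_minus_DPT_over_tPI": over_tpi(tsf_min - lm.dpt),
    }
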