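"""The catalogue of the 138 manual pulse-waveform features.

The extractor computes 73 catalogue items organized in six groups; items that
are families (the ten-level morphological threshold features, the five
spectral subband ratios, the three overall-trend statistics, the short-time
energy / zero-crossing summaries) expand into several scalars, giving exactly
138 values.  The registry is the single source of truth for feature order,
grouping and the per-target (SBP/DBP) selection annotations, and is validated
on construction.

Group budget: time 31, morphological 60 (6 items x 10 levels),
statistical 4, frequency 9 (6 spectral-peak items + instantaneous-frequency
mean/std + spectral entropy), derivative 19, trend 15 (5 subband ratios +
RMS energy + centroid + bandwidth + 3 overall-trend + STE mean/var +
STZCR mean/var).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_FEATURES = 138

GROUPS = (
    "time",
    "morphological",
    "statistical",
    "frequency",
    "derivative",
    "trend",
)


@dataclass(frozen=True)
class FeatureEntry:
    name: str
    group: str
    sbp_selected: bool = False
    dbp_selected: bool = False
    description: str = ""


@dataclass
class FeatureRegistry:
    entries: list[FeatureEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique")
        for e in self.entries:
            if e.group not in GROUPS:
                raise ValueError(f"unknown group {e.group!r} for {e.name}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {g: 0 for g in GROUPS}
        for e in self.entries:
            counts[e.group] += 1
        return counts

    def selected_mask(self, target: str) -> np.ndarray:
        if target not in ("sbp", "dbp"):
            raise ValueError("target must be 'sbp' or 'dbp'")
        flag = "sbp_selected" if target == "sbp" else "dbp_selected"
        return np.array([getattr(e, flag) for e in self.entries], dtype=bool)

    def validate(self, expected: int = N_FEATURES) -> None:
        if len(self.entries) != expected:
            raise ValueError(
                f"registry holds {len(self.entries)} features, expected {expected}"
            )

    def to_records(self) -> list[dict]:
        return [
            {
                "name": e.name,
                "group": e.group,
                "sbp_selected": e.sbp_selected,
                "dbp_selected": e.dbp_selected,
                "description": e.description,
            }
            for e in self.entries
        ]


def _e(name, group, flags="", desc=""):
    return FeatureEntry(
        name=name,
        group=group,
        sbp_selected="S" in flags,
        dbp_selected="D" in flags,
        description=desc,
    )


def default_registry() -> FeatureRegistry:
    """Build the default 138-feature registry.

    SBP/DBP flags mirror the published per-target selection annotations of
    the feature catalogue; family members inherit the flags of their item.
    """
    ent: list[FeatureEntry] = []

    # --- time domain (31) -------------------------------------------------
    ent += [
        _e("PSV", "time", "SD", "peak systolic value"),
        _e("PDV", "time", "S", "peak diastolic value"),
        _e("DN", "time", "SD", "dicrotic notch value"),
        _e("t_PI", "time", "SD", "pulse period (s)"),
        _e("PDV_over_PSV", "time", "", "PDV / PSV"),
        _e("PSV_minus_PDV_over_PSV", "time", "", "(PSV - PDV) / PSV"),
        _e("DN_over_PSV", "time", "SD", "DN / PSV"),
        _e("PDV_minus_DN_over_PSV", "time", "", "(PDV - DN) / PSV"),
        _e("SPT", "time", "SD", "systolic peak time (s)"),
        _e("DNT", "time", "SD", "dicrotic notch time (s)"),
        _e("DPT", "time", "", "diastolic peak time (s)"),
        _e("DPT_minus_SPT", "time", "SD", "DPT - SPT (s)"),
        _e("width_half", "time", "", "width at half systolic height (s)"),
        _e("A2_over_A1", "time", "SD", "descending / ascending branch area"),
        _e("SPT_over_PSV", "time", "", "SPT / PSV"),
        _e("PDV_over_tPI_minus_DPT", "time", "SD", "PDV / (t_PI - DPT)"),
        _e("SPT_over_tPI", "time", "SD", "SPT / t_PI"),
        _e("DNT_over_tPI", "time", "D", "DNT / t_PI"),
        _e("DPT_over_tPI", "time", "", "DPT / t_PI"),
        _e("DPT_minus_SPT_over_tPI", "time", "", "(DPT - SPT) / t_PI"),
        _e("VI", "time", "", "valley depth (cycle minimum value)"),
        _e("PT", "time", "S", "cycle duration, peak-to-peak (s)"),
        _e("PI", "time", "", "peak height above cycle minimum"),
        _e("DTD", "time", "SD", "decline duration, peak to cycle end (s)"),
        _e("AID", "time", "", "ascending wave height"),
        _e("DID", "time", "", "descending waveform depth"),
        _e("AS", "time", "SD", "rising slope"),
        _e("DS", "time", "D", "downward slope"),
        _e("K", "time", "SD", "pulse K value (mean - min) / (max - min)"),
        _e("AA", "time", "S", "descending-branch area"),
        _e("DA", "time", "SD", "ascending-branch area"),
    ]

    # --- morphological (6 x 10 = 60) --------------------------------------
    for x in range(1, 11):
        ent.append(_e(f"AID_{x}", "morphological", "", f"ascending level {x}/10"))
    for x in range(1, 11):
        ent.append(_e(f"SW_{x}", "morphological", "SD", f"rise time to level {x}/10 (s)"))
    for x in range(1, 11):
        ent.append(_e(f"DID_{x}", "morphological", "", f"descending level {x}/10"))
    for x in range(1, 11):
        ent.append(_e(f"DW_{x}", "morphological", "SD", f"fall time from level {x}/10 (s)"))
    for x in range(1, 11):
        ent.append(_e(f"DAS_{x}", "morphological", "SD", f"SW_{x} + DW_{x} (s)"))
    for x in range(1, 11):
        ent.append(_e(f"DDS_{x}", "morphological", "SD", f"DW_{x} / SW_{x}"))

    # --- statistical (4) --------------------------------------------------
    ent += [
        _e("SK", "statistical", "SD", "skewness over the cycle"),
        _e("KU", "statistical", "SD", "kurtosis over the cycle (Pearson, normal=3)"),
        _e("VAR", "statistical", "SD", "variance over the cycle"),
        _e("MF", "statistical", "SD", "max value / mean-square value"),
    ]

    # --- frequency (9) ----------------------------------------------------
    ent += [
        _e("f_base", "frequency", "", "fundamental frequency (Hz)"),
        _e("spmag_base", "frequency", "S", "magnitude at fundamental"),
        _e("f_2", "frequency", "", "frequency of 2nd-largest component (Hz)"),
        _e("spmag_2", "frequency", "SD", "magnitude of 2nd-largest component"),
        _e("f_3", "frequency", "SD", "frequency of 3rd-largest component (Hz)"),
        _e("spmag_3", "frequency", "SD", "magnitude of 3rd-largest component"),
        _e("inst_freq_mean", "frequency", "", "mean STFT instantaneous frequency (Hz)"),
        _e("inst_freq_std", "frequency", "", "std of STFT instantaneous frequency (Hz)"),
        _e("spectral_entropy", "frequency", "", "normalized spectral entropy"),
    ]

    # --- derivatives (19) -------------------------------------------------
    ent += [
        _e("TFF_MAX", "derivative", "SD", "time of 1st max of 1st derivative (s)"),
        _e("TFF_MIN", "derivative", "D", "time of 1st min of 1st derivative (s)"),
        _e("TSF_MAX", "derivative", "SD", "time of 2nd max of 1st derivative (s)"),
        _e("TSF_MIN", "derivative", "SD", "time of 2nd min of 1st derivative (s)"),
        _e("FSMIN_over_FSMAX", "derivative", "", "min(d1) / max(d1)"),
        _e("SSMAX_over_FSMAX", "derivative", "", "max(d2) / max(d1)"),
        _e("FSMIN_plus_SSMAX_over_FSMAX", "derivative", "", "(min(d1)+max(d2))/max(d1)"),
        _e("TFS_MAX", "derivative", "SD", "time of 1st max of 2nd derivative (s)"),
        _e("TFS_MIN", "derivative", "SD", "time of 1st min of 2nd derivative (s)"),
        _e("TFF_MAX_over_tPI", "derivative", "SD", ""),
        _e("TFF_MIN_over_tPI", "derivative", "SD", ""),
        _e("TSF_MAX_over_tPI", "derivative", "D", ""),
        _e("TSF_MIN_over_tPI", "derivative", "SD", ""),
        _e("TFS_MAX_over_tPI", "derivative", "SD", ""),
        _e("TFS_MIN_over_tPI", "derivative", "SD", ""),
        _e("TFF_MAX_minus_TFS_MAX_over_tPI", "derivative", "D", ""),
        _e("TFF_MIN_minus_TFS_MIN_over_tPI", "derivative", "S", ""),
        _e("TSF_MAX_minus_DNT_over_tPI", "derivative", "", ""),
        _e("TSF_MIN_minus_DPT_over_tPI", "derivative", "SD", ""),
    ]

    # --- trend (15), computed on the parent 10 s segment ------------------
    for i in range(1, 6):
        ent.append(_e(f"STSSE_{i}", "trend", "D", f"energy ratio of subband {i}"))
    ent += [
        _e("E_RMS", "trend", "S", "root-mean-square energy"),
        _e("spectral_centroid", "trend", "SD", "spectral centre of mass (Hz)"),
        _e("spectral_bandwidth", "trend", "SD", "spectral bandwidth (Hz)"),
        _e("trend_amplitude", "trend", "S", "overall trend: max - min"),
        _e("trend_mean", "trend", "S", "overall trend: mean"),
        _e("trend_variance", "trend", "S", "overall trend: variance"),
        _e("STE_mean", "trend", "SD", "mean short-time energy over 20 frames"),
        _e("STE_var", "trend", "SD", "variance of short-time energy"),
        _e("STZCR_mean", "trend", "SD", "mean short-time zero-crossing rate"),
        _e("STZCR_var", "trend", "SD", "variance of short-time zero-crossing rate"),
    ]

    reg = FeatureRegistry(entries=ent)
    reg.validate(N_FEATURES)
    return reg
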