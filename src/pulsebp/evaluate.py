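"""Device-grading statistics for blood-pressure estimators.

Errors are reference minus prediction (mmHg).  The summary reports the mean
error (ME), mean absolute error (MAE) and the standard deviation of the
errors about their mean with the 1/(n-1) normalization.  Device verdicts:

* AAMI: |ME| <= 5 mmHg and SD <= 8 mmHg (both inclusive);
* BHS: grade A/B/C/D from the cumulative percentages of absolute errors
  within 5/10/15 mmHg (A: >=60/85/95, B: >=50/75/90, C: >=40/65/85, all
  three thresholds must be met; comparisons inclusive);
* Bland-Altman: mean difference and limits of agreement mean +/- 1.96 SD;
* Pearson correlation between reference and predicted values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

BHS_THRESHOLDS_MMHG = (5.0, 10.0, 15.0)
BHS_GRADE_TABLE = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}
AAMI_ME_LIMIT = 5.0
AAMI_SD_LIMIT = 8.0


@dataclass
class ErrorSummary:
    errors: np.ndarray  # reference - prediction, mmHg
    me: float
    mae: float
    sd: float
    n: int


@dataclass
class BlandAltman:
    mean_diff: float
    lower_limit: float
    upper_limit: float
    inside_fraction: float


@dataclass
class StandardsReport:
    """Full per-target verdict (typically one for SBP, one for DBP)."""

    summary: ErrorSummary
    aami_pass: bool
    aami_me_ok: bool
    aami_sd_ok: bool
    bhs_cumulative: tuple[float, float, float]
    bhs_grade: str
    bland_altman: BlandAltman
    pearson_r: float

    def as_dict(self) -> dict:
        return {
            "n": self.summary.n,
            "me": self.summary.me,
            "mae": self.summary.mae,
            "sd": self.summary.sd,
            "aami_pass": self.aami_pass,
            "bhs_cumulative": list(self.bhs_cumulative),
            "bhs_grade": self.bhs_grade,
            "bland_altman": {
                "mean_diff": self.bland_altman.mean_diff,
                "lower_limit": self.bland_altman.lower_limit,
                "upper_limit": self.bland_altman.upper_limit,
                "inside_fraction": self.bland_altman.inside_fraction,
            },
            "pearson_r": self.pearson_r,
        }


def _check_pair(ref, pred, min_n=2):
    ref = np.asarray(ref, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if ref.shape != pred.shape:
        raise ValueError("reference and prediction lengths differ")
    if ref.size < min_n:
        raise ValueError(f"need at least {min_n} samples")
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(pred))):
        raise ValueError("inputs must be finite")
    return ref, pred


def error_summary(ref, pred) -> ErrorSummary:
    """ME, MAE and SD (about the mean difference, 1/(n-1)) of ref - pred."""
    ref, pred = _check_pair(ref, pred)
    d = ref - pred
    me = float(np.mean(d))
    mae = float(np.mean(np.abs(d)))
    sd = float(np.sqrt(np.sum((me - d) ** 2) / (d.size - 1)))
    return ErrorSummary(errors=d, me=me, mae=mae, sd=sd, n=int(d.size))


def aami_check(summary: ErrorSummary) -> tuple[bool, bool, bool]:
    """(pass, ME component, SD component); comparisons inclusive."""
    me_ok = abs(summary.me) <= AAMI_ME_LIMIT
    sd_ok = summary.sd <= AAMI_SD_LIMIT
    return me_ok and sd_ok, me_ok, sd_ok


def bhs_cumulative(errors) -> tuple[float, float, float]:
    """Percentages of absolute errors within 5, 10 and 15 mmHg."""
    e = np.abs(np.asarray(errors, dtype=float))
    if e.size == 0:
        raise ValueError("empty error vector")
    return tuple(float(100.0 * np.mean(e <= t)) for t in BHS_THRESHOLDS_MMHG)


def bhs_grade_from_cumulative(cum: tuple[float, float, float]) -> str:
    """Best grade whose three thresholds are all met, else D."""
    for grade in ("A", "B", "C"):
        if all(c >= t for c, t in zip(cum, BHS_GRADE_TABLE[grade])):
            return grade
    return "D"


def bhs_grade(errors) -> tuple[float, float, float, str]:
    cum = bhs_cumulative(errors)
    return (*cum, bhs_grade_from_cumulative(cum))


def bland_altman(ref, pred) -> BlandAltman:
    """Limits of agreement mean +/- 1.96 SD of the differences."""
    ref, pred = _check_pair(ref, pred)
    d = ref - pred
    mean_diff = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = mean_diff - 1.96 * sd, mean_diff + 1.96 * sd
    inside = float(np.mean((d >= lo) & (d <= hi)))
    return BlandAltman(mean_diff=mean_diff, lower_limit=lo, upper_limit=hi, inside_fraction=inside)


def pearson_r(ref, pred) -> float:
    """Product-moment correlation; NaN when either side has zero variance."""
    ref, pred = _check_pair(ref, pred, min_n=3)
    if np.std(ref) == 0 or np.std(pred) == 0:
        return float("nan")
    return float(spstats.pearsonr(ref, pred).statistic)


def standards_report(ref, pred) -> StandardsReport:
    """Compute the full report for one target."""
    summary = error_summary(ref, pred)
    passed, me_ok, sd_ok = aami_check(summary)
    cum = bhs_cumulative(summary.errors)
    return StandardsReport(
        summary=summary,
        aami_pass=passed,
        aami_me_ok=me_ok,
        aami_sd_ok=sd_ok,
        bhs_cumulative=cum,
        bhs_grade=bhs_grade_from_cumulative(cum),
        bland_altman=bland_altman(ref, pred),
        pearson_r=pearson_r(ref, pred) if len(ref) >= 3 else float("nan"),
    )


def bland_altman_plot(ref, pred, ax=None, title: str = ""):
    """Difference-vs-mean scatter with the limits of agreement."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ref, pred = _check_pair(ref, pred)
    ba = bland_altman(ref, pred)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((ref + pred) / 2.0, ref - pred, s=6, alpha=0.4)
    ax.axhline(ba.mean_diff, color="red")
    for y in (ba.lower_limit, ba.upper_limit):
        ax.axhline(y, color="gray", linestyle="--")
    ax.set_xlabel("mean of reference and prediction (mmHg)")
    ax.set_ylabel("difference (mmHg)")
    if title:
        ax.set_title(title)
    return ax


def regression_plot(ref, pred, ax=None, title: str = ""):
    """Prediction-vs-reference scatter with the identity line and r."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ref, pred = _check_pair(ref, pred)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ref, pred, s=6, alpha=0.4)
    lims = [min(ref.min(), pred.min()), max(ref.max(), pred.max())]
    ax.plot(lims, lims, color="red")
    r = pearson_r(ref, pred)
    ax.set_xlabel("reference (mmHg)")
    ax.set_ylabel("predicted (mmHg)")
    ax.set_title(f"{title} r={r:.4f}" if title else f"r={r:.4f}")
    return ax
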