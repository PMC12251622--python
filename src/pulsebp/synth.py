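"""Synthetic PPG + ABP generator.

Each cardiac cycle is modelled as a two-Gaussian pulse

    p(t) = A1 * exp(-(t - mu1)^2 / (2 sigma1^2)) + A2 * exp(-(t - mu2)^2 / (2 sigma2^2))

whose first hump is the systolic upstroke/peak and whose second, smaller hump
is the dicrotic (diastolic) wave, so the waveform carries a detectable
systolic peak, dicrotic notch and diastolic peak.  Ground-truth SBP/DBP per
cycle are a linear function of the cycle's latent shape parameters (systolic
amplitude and inverse rise time for SBP; diastolic decay width and the
dicrotic amplitude ratio for DBP) plus optional Gaussian label noise, which
makes feature-based recovery of blood pressure well-posed by construction.
The aligned synthetic ABP trace is a per-cycle rescaled copy of the pulse so
that the per-cycle maximum/minimum reproduce the stored SBP/DBP exactly.

Artifacts (baseline drift, white noise, saturation plateaus) emulate the
defects the preprocessing QC stage is designed to reject and are injected by
:func:`inject_artifacts` as a separate, optional step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .records import DatasetBundle, PPGRecord


@dataclass
class BPCoupling:
    """Linear map from per-cycle latent pulse parameters to (SBP, DBP) in mmHg.

    SBP = sbp_intercept + sbp_a1 * A1 + sbp_inv_rise / rise_time_s
    DBP = dbp_intercept + dbp_decay * decay_s + dbp_ratio * (A2 / A1)

    where ``rise_time_s = sigma1`` (systolic width in seconds, a proxy for the
    upstroke time) and ``decay_s = sigma2`` (diastolic decay width in
    seconds).  Defaults are tuned so that generated SBP falls in roughly
    [90, 180] mmHg and DBP in [50, 110] mmHg.
    """

    sbp_intercept: float = 10.0
    sbp_a1: float = 60.0
    sbp_inv_rise: float = 5.5
    dbp_intercept: float = 32.0
    dbp_decay: float = 170.0
    dbp_ratio: float = 28.0


@dataclass
class PulseParams:
    """Per-cycle latent ranges (uniform draws unless lo == hi).

    Widths and delays are expressed as fractions of the cycle period.
    """

    a1_range: tuple[float, float] = (0.7, 1.3)  # systolic amplitude
    ratio_range: tuple[float, float] = (0.20, 0.50)  # A2 / A1
    sigma1_frac_range: tuple[float, float] = (0.09, 0.15)  # systolic width / T
    delay_frac_range: tuple[float, float] = (0.30, 0.45)  # (mu2 - mu1) / T
    sigma2_scale_range: tuple[float, float] = (1.2, 1.6)  # sigma2 / sigma1
    mu1_frac: float = 0.30  # systolic peak position within the cycle
    cycle_jitter: float = 0.25  # AR(1) shrink of per-cycle deviation


@dataclass
class SynthConfig:
    """Configuration of the synthetic cohort.

    ``seed`` fixes every source of randomness; generation of record ``i`` is a
    pure function of ``(seed, i)``.
    """

    n_records: int = 20
    duration_s: float = 60.0
    fs: float = 62.4725
    hr_range_bpm: tuple[float, float] = (60.0, 100.0)
    pulse_params: PulseParams = field(default_factory=PulseParams)
    bp_coupling: BPCoupling = field(default_factory=BPCoupling)
    label_noise_sd_mmHg: float = 0.0
    drift_amp: float = 0.0
    drift_freq_hz: float = 0.2
    noise_snr_db: Optional[float] = None  # None = noise-free
    saturation_prob: float = 0.0
    saturation_len_s: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.hr_range_bpm
        if not (30.0 < lo <= hi < 200.0):
            raise ValueError(f"hr_range_bpm must lie inside (30, 200), got {self.hr_range_bpm}")
        if self.label_noise_sd_mmHg < 0:
            raise ValueError("label_noise_sd_mmHg must be >= 0")
        if self.fs <= 0 or self.duration_s <= 0 or self.n_records < 1:
            raise ValueError("invalid synthetic configuration")


def _draw(rng: np.random.Generator, lo: float, hi: float) -> float:
    return lo if lo == hi else float(rng.uniform(lo, hi))


def generate_record(cfg: SynthConfig, index: int) -> PPGRecord:
    """Generate one clean synthetic PPG record with aligned ABP.

    Heart rate is drawn once per record; per-cycle latents wander around the
    record-level values so consecutive cycles are similar but not identical.
    Per-cycle ground truth is stored in ``meta["cycles"]`` as a list of dicts
    with keys ``start``, ``end`` (sample indices), ``peak`` (true systolic
    peak index), ``sbp`` and ``dbp``.
    """
    rng = np.random.default_rng([cfg.seed, index])
    pp = cfg.pulse_params
    cp = cfg.bp_coupling

    n = int(round(cfg.duration_s * cfg.fs))
    hr = _draw(rng, *cfg.hr_range_bpm)
    period_s = 60.0 / hr
    period_n = period_s * cfg.fs

    # record-level mean latents
    base = {
        "a1": _draw(rng, *pp.a1_range),
        "ratio": _draw(rng, *pp.ratio_range),
        "sigma1": _draw(rng, *pp.sigma1_frac_range),
        "delay": _draw(rng, *pp.delay_frac_range),
        "s2scale": _draw(rng, *pp.sigma2_scale_range),
    }
    ranges = {
        "a1": pp.a1_range,
        "ratio": pp.ratio_range,
        "sigma1": pp.sigma1_frac_range,
        "delay": pp.delay_frac_range,
        "s2scale": pp.sigma2_scale_range,
    }

    ppg = np.zeros(n)
    abp = np.zeros(n)
    cycles: list[dict] = []
    t_all = np.arange(n) / cfg.fs

    n_cycles = int(np.ceil(cfg.duration_s / period_s))
    dev = {k: 0.0 for k in base}
    for k in range(n_cycles):
        lat = {}
        for key, (lo, hi) in ranges.items():
            if lo == hi:
                lat[key] = lo
                continue
            half = 0.5 * (hi - lo)
            dev[key] = (1 - pp.cycle_jitter) * dev[key] + pp.cycle_jitter * rng.normal(
                0.0, 0.4 * half
            )
            lat[key] = float(np.clip(base[key] + dev[key], lo, hi))

        start_t = k * period_s
        i0 = int(np.ceil(start_t * cfg.fs)) if k > 0 else 0
        i1 = min(int(np.ceil((start_t + period_s) * cfg.fs)), n)
        if i1 <= i0:
            break
        t = t_all[i0:i1] - start_t

        a1 = lat["a1"]
        a2 = lat["ratio"] * a1
        mu1 = pp.mu1_frac * period_s
        sigma1 = lat["sigma1"] * period_s
        mu2 = mu1 + lat["delay"] * period_s
        sigma2 = lat["s2scale"] * sigma1
        pulse = a1 * np.exp(-((t - mu1) ** 2) / (2 * sigma1**2)) + a2 * np.exp(
            -((t - mu2) ** 2) / (2 * sigma2**2)
        )
        ppg[i0:i1] = pulse

        sbp = cp.sbp_intercept + cp.sbp_a1 * a1 + cp.sbp_inv_rise / sigma1
        dbp = cp.dbp_intercept + cp.dbp_decay * sigma2 + cp.dbp_ratio * lat["ratio"]
        if cfg.label_noise_sd_mmHg > 0:
            sbp += rng.normal(0.0, cfg.label_noise_sd_mmHg)
            dbp += rng.normal(0.0, cfg.label_noise_sd_mmHg)
        # physiology guard: keep a positive pulse pressure even under noise
        dbp = min(dbp, sbp - 10.0)

        pmin, pmax = float(pulse.min()), float(pulse.max())
        if pmax > pmin:
            abp[i0:i1] = dbp + (sbp - dbp) * (pulse - pmin) / (pmax - pmin)
        else:  # degenerate flat cycle
            abp[i0:i1] = dbp

        cycles.append(
            {
                "start": int(i0),
                "end": int(i1),
                "peak": int(i0 + np.argmax(pulse)),
                "sbp": float(sbp),
                "dbp": float(dbp),
            }
        )

    return PPGRecord(
        samples=ppg,
        fs=cfg.fs,
        abp=abp,
        record_id=f"synth-{cfg.seed}-{index}",
        meta={"index": index, "hr_bpm": hr, "cycles": cycles, "seed": cfg.seed},
    )


def inject_artifacts(rec: PPGRecord, cfg: SynthConfig) -> PPGRecord:
    """Add baseline drift, white noise and saturation plateaus to a record.

    With ``saturation_prob`` per 10 s span, a plateau of at least three
    identical samples is written into that span (the defect the flat-run QC
    rule rejects).  Corrupted spans are listed in ``meta["saturated_spans"]``.
    The configuration ``saturation_prob=0, drift_amp=0, noise_snr_db=None``
    leaves the record unchanged.
    """
    out = rec.copy()
    rng = np.random.default_rng([cfg.seed, int(rec.meta.get("index", 0)), 7])
    n = out.samples.size
    t = np.arange(n) / out.fs

    if cfg.drift_amp > 0:
        out.samples = out.samples + cfg.drift_amp * np.sin(
            2 * np.pi * cfg.drift_freq_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if cfg.noise_snr_db is not None and np.isfinite(cfg.noise_snr_db):
        p_sig = float(np.mean(rec.samples**2))
        p_noise = p_sig / (10.0 ** (cfg.noise_snr_db / 10.0))
        out.samples = out.samples + rng.normal(0.0, np.sqrt(p_noise), size=n)

    saturated: list[tuple[int, int]] = []
    if cfg.saturation_prob > 0:
        span = int(round(10.0 * out.fs))
        run = max(3, int(round(cfg.saturation_len_s * out.fs)))
        for s0 in range(0, n - run, span):
            if rng.uniform() < cfg.saturation_prob:
                pos = int(rng.integers(s0, min(s0 + span, n - run)))
                out.samples[pos : pos + run] = out.samples[pos]
                saturated.append((pos, pos + run))
    out.meta["saturated_spans"] = saturated
    return out


def make_dataset(
    cfg: SynthConfig,
    split_frac: float = 0.85,
    registry=None,
    with_artifacts: bool = True,
) -> tuple[DatasetBundle, DatasetBundle]:
    """Generate records, run the preprocessing + feature pipeline, and split.

    The split is at ROI level by a seeded shuffle: ``floor(split_frac * n)``
    ROIs go to the training bundle, the rest to the test bundle.  Blocks in
    each bundle group the ROIs of one source record.
    """
    if not (0.0 < split_frac < 1.0):
        raise ValueError("split_frac must lie in (0, 1)")

    from .features import CycleFeatureExtractor, default_registry
    from .preprocess import PeakDetectorConfig, preprocess_record

    registry = registry if registry is not None else default_registry()
    extractor = CycleFeatureExtractor(registry=registry)
    det_cfg = PeakDetectorConfig()

    rows_f, rows_s, rows_y, rows_rec = [], [], [], []
    for i in range(cfg.n_records):
        rec = generate_record(cfg, i)
        if with_artifacts:
            rec = inject_artifacts(rec, cfg)
        segments, rois = preprocess_record(rec, det_cfg)
        for seg, roi in rois:
            if roi.sbp is None or roi.dbp is None:
                continue
            vec = extractor.extract(roi, seg)
            rows_f.append(vec.values)
            rows_s.append(roi.samples)
            rows_y.append([roi.sbp, roi.dbp])
            rows_rec.append(i)

    if not rows_f:
        raise ValueError("pipeline produced zero labelled ROIs")

    F = np.asarray(rows_f, dtype=float)
    S = np.asarray(rows_s, dtype=float)
    Y = np.asarray(rows_y, dtype=float)
    rec_ids = np.asarray(rows_rec)
    n = F.shape[0]

    rng = np.random.default_rng([cfg.seed, 99])
    order = rng.permutation(n)
    n_train = int(np.floor(split_frac * n))
    idx_train, idx_test = order[:n_train], order[n_train:]

    def _bundle(idx: np.ndarray) -> DatasetBundle:
        Xb, Yb = [], []
        for r in np.unique(rec_ids[idx]):
            sel = idx[rec_ids[idx] == r]
            Xb.append(np.hstack([F[sel], S[sel]]))
            Yb.append(Y[sel])
        return DatasetBundle(X=Xb, Y=Yb, n_feature_cols=F.shape[1], seq_len=S.shape[1])

    return _bundle(idx_train), _bundle(idx_test)
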