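"""Filtering, segmentation, QC rules, TERMA peak detection and ROI shaping."""

import numpy as np
import pytest

from pulsebp.preprocess import (
    PeakDetectorConfig,
    bandpass_filter,
    detect_systolic_peaks,
    extract_rois,
    kernel_length,
    preprocess_record,
    qc_segment,
    reject_flat_runs,
    segment_record,
    shape_to_length,
)
from pulsebp.records import PPGRecord, ROI, Segment
from pulsebp.synth import SynthConfig, generate_record, inject_artifacts

FS = 62.4725


def sine_record(freq_hz, duration_s=30.0, fs=FS):
    t = np.arange(int(round(duration_s * fs))) / fs
    return PPGRecord(samples=np.sin(2 * np.pi * freq_hz * t), fs=fs, record_id="sine")


class TestBandpass:
    @pytest.mark.parametrize(
        "freq,expect",
        [(0.2, "stop"), (2.0, "pass")],
    )
    def test_band_edges(self, freq, expect):
        rec = sine_record(freq)
        out = bandpass_filter(rec)
        # measure amplitude away from the filter edges
        mid = slice(rec.samples.size // 4, 3 * rec.samples.size // 4)
        amp = np.max(np.abs(out.samples[mid]))
        if expect == "stop":
            assert amp < 0.10  # 0.2 Hz baseline wander strongly attenuated
        else:
            assert amp == pytest.approx(1.0, abs=0.05)

    def test_zero_in_zero_out(self):
        rec = PPGRecord(samples=np.zeros(1000), fs=FS)
        assert np.allclose(bandpass_filter(rec).samples, 0.0)

    def test_low_rate_rejected(self):
        rec = PPGRecord(samples=np.ones(100), fs=8.0)
        with pytest.raises(ValueError):
            bandpass_filter(rec)


class TestSegmentation:
    def test_window_counts(self):
        for dur, n_expected in [(95.0, 9), (10.0, 1), (9.9, 0)]:
            n = int(round(dur * FS))
            rec = PPGRecord(samples=np.sin(np.arange(n) * 0.1), fs=FS)
            segs = segment_record(rec)
            assert len(segs) == n_expected

    def test_normalization_range(self):
        rec = sine_record(1.0, duration_s=30.0)
        for seg in segment_record(rec):
            assert seg.samples.min() == pytest.approx(0.0)
            assert seg.samples.max() == pytest.approx(1.0)

    def test_constant_segment_flagged(self):
        rec = PPGRecord(samples=np.ones(int(10 * FS) + 5), fs=FS)
        seg = segment_record(rec)[0]
        assert not seg.qc_pass
        assert seg.qc_reason == "degenerate_range"

    def test_segmentation_idempotent_on_single_segment(self):
        rec = sine_record(1.0, duration_s=10.0)
        seg = segment_record(rec)[0]
        again = segment_record(
            PPGRecord(samples=seg.samples, fs=FS, record_id="seg")
        )[0]
        assert np.allclose(again.samples, seg.samples)


class TestFlatRun:
    def make_seg(self, raw):
        raw = np.asarray(raw, dtype=float)
        return Segment(samples=raw, fs=FS, raw=raw)

    def test_triple_run_fails(self):
        base = list(np.linspace(1, 2, 20))
        seg = self.make_seg([1.0, 2.0, 2.0, 2.0, 3.0] + base)
        out = reject_flat_runs(seg)
        assert not out.qc_pass and out.qc_reason == "flat_run"

    def test_pairs_pass(self):
        seg = self.make_seg([1.0, 2.0, 2.0, 3.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        assert reject_flat_runs(seg).qc_pass

    def test_monotone_ramp_passes(self):
        seg = self.make_seg(np.linspace(0, 1, 100))
        assert reject_flat_runs(seg).qc_pass


class TestPeakDetection:
    def test_kernel_lengths_at_reference_rate(self):
        assert kernel_length(0.667, FS) == 42
        assert kernel_length(0.111, FS) == 7

    def test_all_zero_segment(self):
        seg = Segment(samples=np.zeros(int(10 * FS)), fs=FS)
        trace = detect_systolic_peaks(seg)
        assert trace.peaks.size == 0
        assert trace.blocks == []

    def test_trace_invariants(self, clean_record):
        from pulsebp.preprocess import bandpass_filter

        seg = segment_record(bandpass_filter(clean_record), raw=clean_record)[0]
        trace = detect_systolic_peaks(seg)
        assert np.all(np.diff(trace.peaks) > 0)
        for p in trace.peaks:
            assert any(s <= p < e for s, e in trace.blocks)
        assert trace.ppg_beat.shape == trace.ppg_peak.shape == seg.samples.shape

    @pytest.mark.parametrize("hr", [60, 75, 100])
    def test_precision_recall_on_clean_trains(self, hr):
        cfg = SynthConfig(duration_s=60.0, hr_range_bpm=(float(hr), float(hr)), seed=1)
        rec = generate_record(cfg, 0)
        segments, _ = preprocess_record(rec)
        covered = sum(len(s) for s in segments)
        truth = np.array([c["peak"] for c in rec.meta["cycles"] if c["peak"] < covered])
        detected = np.concatenate(
            [s.peaks + s.start_index for s in segments if s.peaks.size]
        )
        tol = 3
        recall = np.mean([np.min(np.abs(detected - t)) <= tol for t in truth])
        precision = np.mean([np.min(np.abs(truth - d)) <= tol for d in detected])
        assert recall >= 0.95
        assert precision >= 0.95

    def test_noise_robustness(self):
        """At SNR >= 20 dB the per-segment peak count changes by <= 1."""
        cfg_clean = SynthConfig(duration_s=40.0, hr_range_bpm=(75.0, 75.0), seed=4)
        rec = generate_record(cfg_clean, 0)
        clean_segments, _ = preprocess_record(rec)
        cfg_noisy = SynthConfig(duration_s=40.0, hr_range_bpm=(75.0, 75.0), seed=4,
                                noise_snr_db=20.0)
        noisy = inject_artifacts(rec, cfg_noisy)
        noisy_segments, _ = preprocess_record(noisy)
        for c_seg, n_seg in zip(clean_segments, noisy_segments):
            assert abs(int(c_seg.peaks.size) - int(n_seg.peaks.size)) <= 1


class TestQC:
    def make_trace(self, seg, n_peaks):
        from pulsebp.preprocess import PeakDetectionTrace

        peaks = np.linspace(10, len(seg) - 10, n_peaks).astype(int) if n_peaks else np.array([], dtype=int)
        return PeakDetectionTrace(
            ppg_seg=seg.samples, ppg_beat=seg.samples, ppg_peak=seg.samples,
            th_peak=seg.samples, blocks=[], peaks=peaks,
        )

    @pytest.mark.parametrize("n_peaks,expected", [(10, True), (8, True), (7, False)])
    def test_min_peak_boundary(self, n_peaks, expected):
        seg = Segment(samples=np.random.default_rng(0).random(int(10 * FS)), fs=FS)
        out = qc_segment(seg, self.make_trace(seg, n_peaks))
        assert out.qc_pass is expected
        if not expected:
            assert out.qc_reason == "too_few_peaks"

    def test_flat_run_failure_sticks(self):
        seg = Segment(samples=np.zeros(int(10 * FS)), fs=FS, qc_pass=False,
                      qc_reason="flat_run")
        out = qc_segment(seg, self.make_trace(seg, 10))
        assert not out.qc_pass and out.qc_reason == "flat_run"


class TestROIs:
    def test_roi_count_is_interior_peaks(self, clean_record):
        segments, _ = preprocess_record(clean_record)
        seg = segments[0]
        rois = extract_rois(seg)
        assert len(rois) == seg.peaks.size - 2

    def test_three_peaks_single_roi(self):
        seg = Segment(
            samples=np.sin(np.linspace(0, 6 * np.pi, 200)) + 1.0,
            fs=FS,
            peaks=np.array([16, 83, 150]),
        )
        rois = extract_rois(seg)
        assert len(rois) == 1
        assert rois[0].samples.size == 150 - 16 + 1
        assert rois[0].center_peak == 83 - 16

    def test_too_few_peaks_empty(self):
        seg = Segment(samples=np.zeros(100), fs=FS, peaks=np.array([10, 50]))
        assert extract_rois(seg) == []

    def test_labels_match_generator_truth(self):
        cfg = SynthConfig(duration_s=40.0, hr_range_bpm=(70.0, 70.0),
                          label_noise_sd_mmHg=0.0, seed=8)
        rec = generate_record(cfg, 0)
        segments, pairs = preprocess_record(rec)
        assert pairs
        cycles = rec.meta["cycles"]
        for seg, roi in pairs:
            lo = roi.start_index
            hi = lo + roi.original_length - 1
            overlapping = [c for c in cycles if c["start"] <= hi and c["end"] - 1 >= lo]
            assert roi.sbp == pytest.approx(rec.abp[lo : hi + 1].max(), abs=1e-9)
            assert roi.dbp == pytest.approx(rec.abp[lo : hi + 1].min(), abs=1e-9)
            # and the window max/min agree with the per-cycle bookkeeping
            assert roi.sbp <= max(c["sbp"] for c in overlapping) + 1e-9
            assert roi.dbp >= min(c["dbp"] for c in overlapping) - 1e-9

    def test_roi_windows_stay_inside_segment(self, clean_record):
        segments, pairs = preprocess_record(clean_record)
        seg_len = len(segments[0])
        for seg, roi in pairs:
            start = roi.start_index - seg.start_index
            assert 0 <= start
            assert start + roi.original_length <= seg_len


class TestShapeToLength:
    def make_roi(self, n):
        return ROI(samples=np.arange(n, dtype=float) + 1.0, fs=FS, center_peak=n // 2)

    def test_pad_short(self):
        out = shape_to_length(self.make_roi(70), 80)
        assert out.samples.size == 80
        assert out.padded and out.original_length == 70
        assert np.all(out.samples[70:] == 0.0)

    def test_identity(self):
        roi = self.make_roi(80)
        out = shape_to_length(roi, 80)
        assert out is roi

    def test_truncate_long(self):
        out = shape_to_length(self.make_roi(95), 80)
        assert out.samples.size == 80
        assert np.array_equal(out.samples, np.arange(80, dtype=float) + 1.0)

    def test_idempotence(self):
        once = shape_to_length(self.make_roi(70), 80)
        twice = shape_to_length(once, 80)
        assert np.array_equal(once.samples, twice.samples)
        assert twice.original_length == 70
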