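"""Feature extractor oracles: analytic waveforms with closed-form answers,
registry audit, and homogeneity of the full 138-vector."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsebp.features import (
    default_registry,
    delineate_cycle,
    extract_all,
    fft_spectrum,
    frequency_features,
    instantaneous_frequency,
    morphological_features,
    nextpow2,
    overall_trend,
    rms_energy,
    short_time_energy,
    short_time_zcr,
    spectral_bandwidth,
    spectral_centroid,
    statistical_features,
    stsse,
    time_domain_features,
)
from pulsebp.features.groups import derivative_features
from pulsebp.records import ROI, Segment

FS = 62.4725


def two_gaussian_roi(a1=1.0, a2=0.35, sigma1_frac=0.12, delay_frac=0.40,
                     sigma2_scale=1.4, period_s=1.0, fs=FS):
    """Three consecutive identical two-Gaussian pulses, windowed peak-to-peak."""
    mu1 = 0.3 * period_s
    s1 = sigma1_frac * period_s
    mu2 = mu1 + delay_frac * period_s
    s2 = sigma2_scale * s1
    n = int(round(3 * period_s * fs))
    t = np.arange(n) / fs

    def pulse(tt):
        val = np.zeros_like(tt)
        for k in range(-1, 4):
            off = k * period_s
            val += a1 * np.exp(-((tt - off - mu1) ** 2) / (2 * s1**2))
            val += a2 * np.exp(-((tt - off - mu2) ** 2) / (2 * s2**2))
        return val

    x = pulse(t)
    p0 = int(np.argmax(x[: int(period_s * fs)]))
    p1 = p0 + int(round(period_s * fs))
    p2 = p0 + 2 * int(round(period_s * fs))
    window = x[p0 : p2 + 1]
    roi = ROI(samples=window, fs=fs, center_peak=p1 - p0)
    return roi, pulse, (mu1, s1, mu2, s2, period_s, p0, t)


class TestDelineation:
    def test_notch_matches_analytic_minimum(self):
        roi, pulse, (mu1, s1, mu2, s2, period_s, p0, t) = two_gaussian_roi()
        lm = delineate_cycle(roi)
        # oracle: dense-grid minimum of the continuous pulse between the humps
        tt = np.linspace(period_s + mu1, period_s + mu2, 20000)
        t_min = tt[np.argmin(pulse(tt))]
        notch_time_abs = (p0 + lm.dicrotic_notch) / FS
        assert abs(notch_time_abs - t_min) * FS <= 3

    def test_landmark_ordering(self):
        roi, *_ = two_gaussian_roi()
        lm = delineate_cycle(roi)
        assert lm.foot_start < lm.peak_systolic
        assert lm.peak_systolic < lm.dicrotic_notch <= lm.peak_diastolic
        assert lm.peak_diastolic < lm.foot_end
        assert lm.t_pi > 0

    def test_single_gaussian_falls_back(self):
        roi, *_ = two_gaussian_roi(a2=0.0)
        lm = delineate_cycle(roi)  # second-derivative fallback may fire
        vec = extract_all(roi, Segment(samples=np.tile(roi.samples, 9)[:625], fs=FS))
        assert vec.values.size == 138  # vector completes despite missing notch

    def test_symmetric_pulse_peak_centred(self):
        roi, pulse, (mu1, s1, *_rest) = two_gaussian_roi(a2=0.0, sigma1_frac=0.10)
        lm = delineate_cycle(roi)
        rise = lm.spt
        fall = (lm.foot_end - lm.peak_systolic) / FS
        assert rise == pytest.approx(fall, abs=2.5 / FS)

    def test_too_short_roi_rejected(self):
        from pulsebp.features import DelineationError

        with pytest.raises(DelineationError):
            delineate_cycle(ROI(samples=np.array([0.0, 1.0, 0.0]), fs=FS, center_peak=1))


class TestTimeDomain:
    @pytest.fixture()
    def lm_roi(self):
        roi, *_ = two_gaussian_roi()
        return delineate_cycle(roi), roi

    def test_definitional_ratios(self, lm_roi):
        lm, roi = lm_roi
        f = time_domain_features(lm, roi)
        assert f["PDV_over_PSV"] == pytest.approx(f["PDV"] / f["PSV"])
        assert f["PSV_minus_PDV_over_PSV"] == pytest.approx(1 - f["PDV"] / f["PSV"])
        assert f["SPT_over_tPI"] == pytest.approx(f["SPT"] / f["t_PI"])
        assert f["DPT_minus_SPT"] == pytest.approx(f["DPT"] - f["SPT"])
        assert f["PI"] == pytest.approx(f["PSV"] - f["VI"])

    def test_triangle_area_ratio(self):
        # symmetric triangle: ascending and descending areas are equal
        n = 81
        tri = np.concatenate([np.linspace(0, 1, n // 2 + 1), np.linspace(1, 0, n // 2 + 1)[1:]])
        roi = ROI(samples=tri, fs=FS, center_peak=n // 2)
        lm = delineate_cycle(roi)
        f = time_domain_features(lm, roi)
        assert f["A2_over_A1"] == pytest.approx(1.0, abs=0.05)

    def test_k_value_in_unit_range(self, lm_roi):
        lm, roi = lm_roi
        f = time_domain_features(lm, roi)
        assert 0.0 < f["K"] < 1.0


class TestMorphological:
    def test_symmetric_triangle_levels(self):
        n = 81
        tri = np.concatenate([np.linspace(0, 1, n // 2 + 1), np.linspace(1, 0, n // 2 + 1)[1:]])
        roi = ROI(samples=tri, fs=FS, center_peak=n // 2)
        lm = delineate_cycle(roi)
        f = morphological_features(lm, roi)
        for x in range(1, 11):
            assert f[f"SW_{x}"] == pytest.approx(f[f"DW_{x}"], abs=1e-9)
            assert f[f"DDS_{x}"] == pytest.approx(1.0)

    def test_ramp_crossing_linear_in_level(self):
        # sawtooth rising edge: time to reach level x/10 is linear in x
        n = 101
        ramp = np.concatenate([np.linspace(0, 1, n), np.linspace(1, 0, 5)[1:]])
        roi = ROI(samples=ramp, fs=FS, center_peak=n - 1)
        lm = delineate_cycle(roi)
        f = morphological_features(lm, roi)
        sw = np.array([f[f"SW_{x}"] for x in range(1, 11)])
        increments = np.diff(sw)
        assert np.allclose(increments, increments[0], atol=1e-6)

    def test_das_identity(self, sample_roi):
        lm = delineate_cycle(sample_roi)
        f = morphological_features(lm, sample_roi)
        for x in range(1, 11):
            if np.isfinite(f[f"SW_{x}"]) and np.isfinite(f[f"DW_{x}"]):
                assert f[f"DAS_{x}"] == pytest.approx(f[f"SW_{x}"] + f[f"DW_{x}"])


class TestStatistical:
    def test_symmetric_skew_zero(self):
        x = np.sin(np.linspace(0, 2 * np.pi, 201))
        roi = ROI(samples=x - x.min(), fs=FS, center_peak=50)
        f = statistical_features(roi)
        assert f["SK"] == pytest.approx(0.0, abs=1e-6)

    def test_kurtosis_pearson_convention(self, rng):
        x = rng.standard_normal(200_000)
        roi = ROI(samples=x, fs=FS, center_peak=100)
        f = statistical_features(roi)
        assert f["KU"] == pytest.approx(3.0, abs=0.1)  # normal kurtosis = 3

    def test_constant_degenerate(self):
        roi = ROI(samples=np.full(50, 2.0), fs=FS, center_peak=25)
        f = statistical_features(roi)
        assert f["VAR"] == 0.0
        assert np.isnan(f["SK"]) and np.isnan(f["KU"])


class TestSpectralPrimitives:
    def test_fft_padding_rule(self):
        frame = fft_spectrum(np.random.default_rng(0).random(80), FS)
        assert frame.n_fft == 16 * 128  # nextpow2(80) = 128
        assert nextpow2(80) == 128

    def test_pure_tone_peak(self):
        t = np.arange(400) / FS
        frame = fft_spectrum(np.sin(2 * np.pi * 2.0 * t), FS)
        assert frame.freqs[np.argmax(frame.magnitudes)] == pytest.approx(2.0, abs=0.05)

    def test_zero_signal(self):
        frame = fft_spectrum(np.zeros(64), FS)
        assert np.all(frame.magnitudes == 0.0)

    def test_centroid_bandwidth_single_tone(self):
        # whole periods on the DFT grid: the spectrum degenerates to one line
        fs, n = 64.0, 640
        t = np.arange(n) / fs
        frame = fft_spectrum(np.sin(2 * np.pi * 1.6 * t), fs, pad=False)
        assert spectral_centroid(frame) == pytest.approx(1.6, abs=0.05)
        assert spectral_bandwidth(frame) < 2 * fs / n

    def test_centroid_bandwidth_two_tones(self):
        fs, n = 64.0, 4096
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 3.0 * t)
        frame = fft_spectrum(x, fs, pad=False)
        assert spectral_centroid(frame) == pytest.approx(2.0, abs=0.05)
        assert spectral_bandwidth(frame) == pytest.approx(1.0, abs=0.05)

    def test_scale_invariance(self):
        t = np.arange(500) / FS
        x = np.sin(2 * np.pi * 1.3 * t) + 0.4 * np.sin(2 * np.pi * 2.9 * t)
        f1 = fft_spectrum(x, FS)
        f5 = fft_spectrum(5.0 * x, FS)
        assert spectral_centroid(f1) == pytest.approx(spectral_centroid(f5))
        assert spectral_bandwidth(f1) == pytest.approx(spectral_bandwidth(f5))


class TestFrequencyFeatures:
    def test_fundamental_of_pulse_train(self, sample_roi):
        f = frequency_features(sample_roi)
        # the fixture record runs at 75 bpm -> fundamental 1.25 Hz
        assert f["f_base"] * 60.0 == pytest.approx(75.0, abs=6.0)

    def test_second_component_ordering(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 1.0 * t) + 0.5 * np.sin(2 * np.pi * 2.0 * t)
        roi = ROI(samples=x, fs=FS, center_peak=10)
        f = frequency_features(roi)
        assert f["f_base"] == pytest.approx(1.0, abs=0.05)
        assert f["f_2"] == pytest.approx(2.0, abs=0.05)
        assert f["spmag_2"] < f["spmag_base"]


class TestTrend:
    def test_stsse_pure_tone(self):
        t = np.arange(int(10 * FS)) / FS
        ratios = stsse(np.sin(2 * np.pi * 1.5 * t), FS)
        expected = np.array([0, 1, 0, 0, 0.0])
        assert np.all(np.abs(ratios - expected) < 0.02)

    def test_stsse_two_equal_tones(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 0.75 * t) + np.sin(2 * np.pi * 2.5 * t)
        ratios = stsse(x, FS)
        assert ratios[0] == pytest.approx(0.5, abs=0.05)
        assert ratios[2] == pytest.approx(0.5, abs=0.05)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_stsse_normalization_property(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=int(10 * FS))
        ratios = stsse(x, FS)
        assert np.all((ratios >= 0) & (ratios <= 1))
        assert np.sum(ratios) == pytest.approx(1.0, abs=1e-9)

    def test_rms_closed_forms(self):
        assert rms_energy(np.full(100, -3.0)) == pytest.approx(3.0)
        assert rms_energy(np.zeros(10)) == 0.0
        t = np.arange(10_000) / 1000.0
        assert rms_energy(np.sin(2 * np.pi * 5.0 * t)) == pytest.approx(1 / np.sqrt(2), abs=1e-3)

    def test_ste_constant_signal(self):
        e = short_time_energy(np.ones(625))
        assert e.size == 20
        assert np.allclose(e, 80.0)

    def test_ste_zero_signal(self):
        assert np.all(short_time_energy(np.zeros(625)) == 0.0)

    def test_ste_disjoint_frames_conserve_energy(self, rng):
        x = rng.normal(size=20 * 80)  # hop == frame_len: frames tile exactly
        e = short_time_energy(x)
        assert np.sum(e) == pytest.approx(np.sum(x**2))

    def test_zcr_alternating(self):
        x = np.tile([1.0, -1.0], 40)
        assert short_time_zcr(x, demean=False)[0] == pytest.approx(1.0)

    def test_zcr_strictly_positive_raw(self):
        x = np.abs(np.sin(np.arange(80))) + 0.5
        assert short_time_zcr(x, demean=False)[0] == 0.0

    def test_zcr_sine_periods(self):
        k = 4
        n = 80
        t = np.arange(n)
        x = np.sin(2 * np.pi * k * t / n)
        z = short_time_zcr(x, demean=False)[0]
        assert z == pytest.approx(2 * k / (n - 1), abs=1.5 / (n - 1))

    def test_overall_trend(self, rng):
        assert overall_trend(np.linspace(0, 1, 50))[0] == pytest.approx(1.0)
        amp, mean, var = overall_trend(np.full(10, 3.0))
        assert (amp, mean, var) == (0.0, 3.0, 0.0)
        u = rng.uniform(0, 1, 10_000)
        _, m, v = overall_trend(u)
        assert m == pytest.approx(0.5, abs=3 * np.sqrt(1 / 12 / 10_000) + 0.01)
        assert v == pytest.approx(1 / 12, abs=0.01)


class TestRegistryAndVector:
    def test_registry_audit(self, registry):
        assert len(registry) == 138
        assert registry.group_counts() == {
            "time": 31, "morphological": 60, "statistical": 4,
            "frequency": 9, "derivative": 19, "trend": 15,
        }
        assert len(set(registry.names)) == 138
        # spot-check published per-target annotations
        sbp = registry.selected_mask("sbp")
        dbp = registry.selected_mask("dbp")
        assert sbp[registry.index("PSV")] and dbp[registry.index("PSV")]
        assert sbp[registry.index("PDV")] and not dbp[registry.index("PDV")]
        assert not sbp[registry.index("DNT_over_tPI")] and dbp[registry.index("DNT_over_tPI")]
        assert sbp[registry.index("E_RMS")] and not dbp[registry.index("E_RMS")]
        assert not sbp[registry.index("STSSE_1")] and dbp[registry.index("STSSE_1")]

    def test_vector_length_and_determinism(self, sample_roi, sample_segment, registry):
        v1 = extract_all(sample_roi, sample_segment, registry)
        v2 = extract_all(sample_roi, sample_segment, registry)
        assert v1.values.size == 138
        assert np.array_equal(v1.values, v2.values, equal_nan=True)
        assert np.array_equal(v1.nan_mask, ~np.isfinite(v1.values))

    def test_scaling_homogeneity(self, sample_roi, sample_segment, registry):
        """Doubling the amplitude leaves ratio features unchanged and scales
        amplitude-covariant features by the expected power."""
        from dataclasses import replace

        v1 = extract_all(sample_roi, sample_segment, registry).values
        roi2 = replace(sample_roi, samples=2.0 * sample_roi.samples)
        seg2 = replace(sample_segment, samples=2.0 * sample_segment.samples)
        v2 = extract_all(roi2, seg2, registry).values
        idx = {n: i for i, n in enumerate(registry.names)}

        for name in ("PDV_over_PSV", "DN_over_PSV", "SPT", "t_PI", "K",
                     "DDS_5", "SK", "f_base", "spectral_centroid",
                     "STSSE_1", "STSSE_2", "STZCR_mean"):
            a, b = v1[idx[name]], v2[idx[name]]
            if np.isfinite(a):
                assert b == pytest.approx(a, rel=1e-6, abs=1e-9), name
        for name, power in (("PSV", 1), ("PI", 1), ("E_RMS", 1),
                            ("trend_amplitude", 1), ("VAR", 2)):
            a, b = v1[idx[name]], v2[idx[name]]
            assert b == pytest.approx(a * 2**power, rel=1e-6), name

    def test_derivative_times_inside_cycle(self, roi_pairs):
        for seg, roi in roi_pairs[:6]:
            lm = delineate_cycle(roi)
            f = derivative_features(lm, roi)
            for key in ("TFF_MAX_over_tPI", "TFF_MIN_over_tPI"):
                if np.isfinite(f[key]):
                    assert 0.0 <= f[key] <= 1.0


class TestDerivativeOracle:
    def test_gaussian_derivative_extrema(self):
        # d/dt exp(-(t-mu)^2 / 2 sigma^2) has extrema at mu -/+ sigma
        fs = 100.0
        mu, sigma = 1.0, 0.15
        t = np.arange(int(2.0 * fs)) / fs
        x = np.exp(-((t - mu) ** 2) / (2 * sigma**2))
        roi = ROI(samples=x, fs=fs, center_peak=int(mu * fs))
        lm = delineate_cycle(roi)
        f = derivative_features(lm, roi)
        t0 = lm.foot_start / fs
        assert f["TFF_MAX"] + t0 == pytest.approx(mu - sigma, abs=1.5 / fs)
        assert f["TFF_MIN"] + t0 == pytest.approx(mu + sigma, abs=1.5 / fs)


def test_instantaneous_frequency_of_tone():
    t = np.arange(2000) / FS
    mean, std = instantaneous_frequency(np.sin(2 * np.pi * 2.0 * t), FS, nperseg=256)
    assert mean == pytest.approx(2.0, abs=0.6)
    assert std < 0.5
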