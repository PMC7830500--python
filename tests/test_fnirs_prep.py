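"""Preprocessing stages: QC rules, filtering, Beer-Lambert, outliers."""

import numpy as np
import pytest
from scipy.signal import butter, freqz
from scipy.stats import norm

import neuroexpertise.fnirs_prep as prep
from neuroexpertise.fnirs_prep import (
    Geometry,
    QCThresholds,
    QualityMask,
    beer_lambert,
    lowpass,
    preprocess_trial,
    qc_channels,
    remove_outliers,
)
from neuroexpertise.synthdata import (
    ADC_CEILING,
    CohortConfig,
    ExpertiseLabel,
    RawFnirsTrial,
    generate_cohort,
)


def _trial_from_intensities(inten, fs=2.0):
    label = ExpertiseLabel(cls="NV", victory_points=0, hours_per_week=0.0)
    return RawFnirsTrial(
        intensities=inten, fs=fs, baseline_window=(0, 4),
        participant_id=0, trial_id=0, label=label,
        duration_s=inten.shape[2] / fs,
    )


class TestQC:
    def _clean_intensities(self, n=60, level=1000.0):
        rng = np.random.default_rng(0)
        return level * (1 + 0.01 * rng.standard_normal((16, 2, n)))

    def test_saturated_channel_flagged(self):
        inten = self._clean_intensities()
        inten[3] = ADC_CEILING
        mask = qc_channels(_trial_from_intensities(inten), QCThresholds())
        assert mask.reason[3] == "saturated"
        assert not mask.passed[3]

    def test_near_zero_channel_flagged_low_signal(self):
        inten = self._clean_intensities()
        inten[7] = 1e-3
        mask = qc_channels(_trial_from_intensities(inten), QCThresholds())
        assert mask.reason[7] == "low_signal"

    def test_high_variance_channel_flagged_leakage(self):
        rng = np.random.default_rng(1)
        inten = self._clean_intensities()
        inten[11] = np.abs(1000 * (1 + 0.5 * rng.standard_normal((2, 60)))) + 1
        mask = qc_channels(_trial_from_intensities(inten), QCThresholds())
        assert mask.reason[11] == "light_leakage"

    def test_clean_channels_pass(self):
        mask = qc_channels(
            _trial_from_intensities(self._clean_intensities()), QCThresholds()
        )
        assert mask.passed.all()

    def test_mask_consistency_enforced(self):
        with pytest.raises(ValueError):
            QualityMask(passed=np.ones(2, dtype=bool), reason=["ok", "saturated"])

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            QCThresholds(saturation_level=10.0, low_signal_floor=20.0)

    def test_cohort_fail_fraction_tracks_configured_rate(self):
        rate = 0.12
        cfg = CohortConfig(
            n_participants=3, class_counts=(1, 1, 1), n_trials=34,
            channel_fail_rate=rate, seed=8,
        )
        cohort = generate_cohort(cfg)
        thr = QCThresholds()
        fails = total = 0
        for trial, _ in cohort:
            mask = qc_channels(trial, thr)
            fails += (~mask.passed).sum()
            total += mask.passed.size
        se = np.sqrt(rate * (1 - rate) / total)
        assert abs(fails / total - rate) < 3 * se


class TestLowpass:
    def test_constant_series_unchanged(self):
        x = np.full(200, 3.7)
        np.testing.assert_allclose(lowpass(x, fs=2.0), x, rtol=1e-10)

    def test_stopband_attenuation_matches_design(self):
        # oracle: evaluate the squared magnitude response at 0.5 Hz
        fs = 2.0
        b, a = butter(4, 0.14, btype="low", fs=fs)
        w, h = freqz(b, a, worN=[0.5], fs=fs)
        expected_gain = np.abs(h[0]) ** 2  # filtfilt applies twice
        t = np.arange(600) / fs
        x = np.sin(2 * np.pi * 0.5 * t)
        y = lowpass(x, fs=fs)
        amp = np.abs(y[100:-100]).max()
        assert amp < 0.10
        assert amp == pytest.approx(expected_gain, abs=0.02)

    def test_passband_tone_preserved(self):
        fs = 2.0
        t = np.arange(4000) / fs
        x = np.sin(2 * np.pi * 0.01 * t)
        y = lowpass(x, fs=fs)
        assert np.abs(y[500:-500]).max() == pytest.approx(1.0, rel=0.05)

    def test_idempotent_in_passband(self):
        fs = 2.0
        t = np.arange(2000) / fs
        x = np.sin(2 * np.pi * 0.02 * t)
        once = lowpass(x, fs=fs)
        twice = lowpass(once, fs=fs)
        np.testing.assert_allclose(
            twice[200:-200], once[200:-200], atol=5e-3
        )

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass(np.zeros(100), fs=2.0, cutoff=1.5)


class TestBeerLambert:
    def _forward(self, oxy, deoxy, geometry, i0=1000.0):
        eps = geometry.extinction
        path = geometry.source_detector_cm * geometry.dpf
        dod = np.einsum("wk,ckt->cwt", eps, np.stack([oxy, deoxy], axis=1)) * path
        return i0 * 10.0 ** (-dod)

    def test_baseline_intensity_gives_zero_concentration(self):
        inten = np.full((16, 2, 50), 900.0)
        oxy, deoxy = beer_lambert(_trial_from_intensities(inten))
        np.testing.assert_allclose(oxy, 0.0, atol=1e-12)
        np.testing.assert_allclose(deoxy, 0.0, atol=1e-12)

    def test_decade_intensity_drop_is_unit_optical_density(self):
        geometry = Geometry()
        inten = np.full((16, 2, 50), 1000.0)
        inten[0, 0, 30] = 100.0  # baseline/10 at one wavelength sample
        oxy, deoxy = beer_lambert(_trial_from_intensities(inten), geometry=geometry)
        # concentrations at that sample must solve eps @ c * path = (1, 0)
        path = geometry.source_detector_cm * geometry.dpf
        expected = np.linalg.solve(geometry.extinction, [1.0, 0.0]) / path
        assert oxy[0, 30] == pytest.approx(expected[0], rel=1e-10)
        assert deoxy[0, 30] == pytest.approx(expected[1], rel=1e-10)

    def test_forward_inverse_round_trip(self, rng):
        geometry = Geometry()
        oxy_true = rng.normal(0, 1.0, (16, 80))
        deoxy_true = rng.normal(0, 0.4, (16, 80))
        # prepend a zero baseline so I0 is exact
        oxy_full = np.concatenate([np.zeros((16, 4)), oxy_true], axis=1)
        deoxy_full = np.concatenate([np.zeros((16, 4)), deoxy_true], axis=1)
        inten = self._forward(oxy_full, deoxy_full, geometry)
        trial = _trial_from_intensities(inten)
        oxy, deoxy = beer_lambert(trial, geometry=geometry)
        np.testing.assert_allclose(oxy[:, 4:], oxy_true, atol=1e-8)
        np.testing.assert_allclose(deoxy[:, 4:], deoxy_true, atol=1e-8)

    def test_linearity_in_optical_density(self, rng):
        geometry = Geometry()
        oxy = np.concatenate([np.zeros((16, 4)), rng.normal(0, 1, (16, 40))], axis=1)
        deoxy = 0.5 * oxy
        i1 = self._forward(oxy, deoxy, geometry)
        i2 = self._forward(2 * oxy, 2 * deoxy, geometry)
        o1, d1 = beer_lambert(_trial_from_intensities(i1), geometry=geometry)
        o2, d2 = beer_lambert(_trial_from_intensities(i2), geometry=geometry)
        np.testing.assert_allclose(o2, 2 * o1, atol=1e-8)
        np.testing.assert_allclose(d2, 2 * d1, atol=1e-8)

    def test_singular_extinction_rejected(self):
        geom = Geometry(extinction=np.ones((2, 2)))
        inten = np.full((16, 2, 50), 900.0)
        with pytest.raises(ValueError, match="singular"):
            beer_lambert(_trial_from_intensities(inten), geometry=geom)


class TestOutlierRemoval:
    def test_single_spike_masked(self, rng):
        x = rng.standard_normal(200)
        x[57] = x.mean() + 10 * x.std()
        cleaned, mask = remove_outliers(x.copy())
        mu, sd = x.mean(), x.std()
        expected = np.abs(x - mu) > 3 * sd  # brute-force scan
        np.testing.assert_array_equal(mask, expected)
        assert mask[57]

    def test_all_within_three_sd_is_noop(self):
        x = np.array([0.0, 1.0, -1.0, 0.5, -0.5, 0.2])
        cleaned, mask = remove_outliers(x)
        np.testing.assert_array_equal(cleaned, x)
        assert not mask.any()

    def test_zero_variance_returned_unchanged(self):
        x = np.full(10, 2.0)
        cleaned, mask = remove_outliers(x)
        np.testing.assert_array_equal(cleaned, x)
        assert not mask.any()

    def test_gaussian_removal_fraction_matches_normal_tail(self, rng):
        x = rng.standard_normal(100_000)
        _, mask = remove_outliers(x)
        frac = mask.mean()
        expected = 2 * norm.cdf(-3)  # ~0.27%
        assert abs(frac - expected) < 1e-3

    def test_no_sample_beyond_three_sd_of_original_stats(self, rng):
        x = rng.standard_normal(5000)
        x[::100] += 8.0
        cleaned, _ = remove_outliers(x)
        z = np.abs(cleaned - x.mean()) / x.std()
        assert (z <= 3.0 + 1e-12).all()

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers(np.array([1.0, 2.0]))


class TestPipeline:
    def test_stage_call_order(self, small_cohort, monkeypatch):
        calls = []
        originals = {
            "qc_channels": prep.qc_channels,
            "lowpass": prep.lowpass,
            "beer_lambert": prep.beer_lambert,
            "remove_outliers": prep.remove_outliers,
        }
        for name, fn in originals.items():
            def wrapper(*a, __name=name, __fn=fn, **k):
                calls.append(__name)
                return __fn(*a, **k)
            monkeypatch.setattr(prep, name, wrapper)
        preprocess_trial(small_cohort[0][0])
        first = [calls[0], calls[1], calls[2], calls[3]]
        assert first == ["qc_channels", "lowpass", "beer_lambert",
                         "remove_outliers"]

    def test_fixed_grid_and_finite_output(self, small_preprocessed):
        for h, _ in small_preprocessed:
            assert h.oxy.shape == (16, 60)
            assert h.deoxy.shape == (16, 60)
            assert np.isfinite(h.oxy).all()
            assert np.isfinite(h.deoxy).all()
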