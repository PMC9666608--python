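"""The 26-feature bank: closed forms, identities, and scale behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erpscreen.features import (
    FEATURE_NAMES,
    FeatureOptions,
    ZeroSignalError,
    ar_feature,
    band_power_features,
    coefficient_entropy,
    dwt_features,
    extract_feature_tables,
    fractal_dimension,
    peak_amplitudes,
    summary_features,
)
from erpscreen.preprocessing import decompose_bands
from erpscreen.synthetic import BAND_NAMES

from helpers import make_record


class TestWaveletFeatures:
    def test_uniform_coefficients_reach_maximum_entropy(self):
        """N equal-magnitude coefficients have entropy ln N (checked
        against an explicit brute-force sum)."""
        for n in (4, 64, 1000):
            c = np.full(n, 3.7)
            p = c**2 / np.sum(c**2)
            brute = -np.sum(p * np.log(p))
            assert coefficient_entropy(c) == pytest.approx(np.log(n), rel=1e-12)
            assert coefficient_entropy(c) == pytest.approx(brute, rel=1e-12)

    def test_entropy_ratio_identities(self, rng):
        x = rng.normal(size=4096)
        f = dwt_features(x)
        assert f["R-ApEn"] + f["R-DeEn"] == pytest.approx(1.0, abs=1e-12)
        assert f["ApEn-0"] + f["DeEn-0"] == pytest.approx(2.0, abs=1e-12)
        assert max(f["ApEn-1"], f["DeEn-1"]) == pytest.approx(1.0, abs=1e-12)
        assert f["TotalWE"] == pytest.approx(f["ApEn"] + f["DeEn"], abs=1e-12)

    def test_theoretical_entropy_normalization_mode(self, rng):
        x = rng.normal(size=4096)
        f = dwt_features(x, FeatureOptions(entropy_norm="theoretical"))
        # a db4 single-level split of 4096 samples yields 2051 coefficients
        n_coeffs = (4096 + 8 - 1) // 2
        assert f["ApEn-1"] == pytest.approx(f["ApEn"] / np.log(n_coeffs), rel=1e-9)
        assert f["ApEn-1"] <= 1.0 and f["DeEn-1"] <= 1.0

    def test_zero_signal_raises(self):
        with pytest.raises(ZeroSignalError):
            dwt_features(np.zeros(1024))


class TestBandPowerFeatures:
    def test_normalization_identities(self, small_cohort):
        bs = decompose_bands(small_cohort[0])
        feats = band_power_features(bs)
        rbp_sum = sum(feats[b]["RBP"] for b in BAND_NAMES)
        assert rbp_sum == pytest.approx(100.0, abs=1e-9)
        assert max(feats[b]["ABP-0"] for b in BAND_NAMES) == pytest.approx(1.0)
        abp1_mean = np.mean([feats[b]["ABP-1"] for b in BAND_NAMES])
        assert abp1_mean == pytest.approx(1.0, abs=1e-12)

    def test_pure_alpha_tone_maximizes_alpha_abp0(self):
        fs = 640.0
        t = np.arange(0, 10, 1 / fs)
        bs = decompose_bands(make_record(np.sin(2 * np.pi * 10 * t)))
        feats = band_power_features(bs)
        assert feats["Alpha"]["ABP-0"] == pytest.approx(1.0)
        assert feats["Beta"]["ABP-0"] < 0.01

    def test_all_zero_record_raises(self):
        bs = decompose_bands(make_record(np.zeros(2000)))
        with pytest.raises(ZeroSignalError):
            band_power_features(bs)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_behaviour(self, small_cohort, scale):
        """c*x scales ABP by c^2 and leaves every ratio feature and the
        fractal dimension unchanged."""
        rec = small_cohort[0]
        bs = decompose_bands(rec)
        scaled = type(bs)(
            raw=bs.raw * scale, bands={b: s * scale for b, s in bs.bands.items()}
        )
        base = band_power_features(bs)
        scal = band_power_features(scaled)
        for b in BAND_NAMES:
            assert scal[b]["ABP"] == pytest.approx(base[b]["ABP"] * scale**2, rel=1e-9)
            for ratio in ("RBP", "ABP-0", "ABP-1"):
                assert scal[b][ratio] == pytest.approx(base[b][ratio], rel=1e-9)

    def test_scale_invariance_of_entropy_ratios_and_fd(self, rng):
        x = rng.normal(size=4096)
        for c in (0.01, 5.0, 300.0):
            f1, f2 = dwt_features(x), dwt_features(c * x)
            assert f2["R-ApEn"] == pytest.approx(f1["R-ApEn"], rel=1e-9)
            assert f2["R-DeEn"] == pytest.approx(f1["R-DeEn"], rel=1e-9)
            assert fractal_dimension(c * x) == pytest.approx(
                fractal_dimension(x), rel=1e-9
            )


class TestFractalDimension:
    def test_straight_line_has_dimension_one(self):
        assert fractal_dimension(np.linspace(0.0, 1.0, 10_000)) == pytest.approx(
            1.0, abs=0.05
        )

    def test_white_noise_approaches_dimension_two(self, rng):
        assert fractal_dimension(rng.normal(size=10_000)) == pytest.approx(2.0, abs=0.1)

    def test_constant_signal_convention(self):
        assert fractal_dimension(np.full(1000, 3.0)) == 1.0

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            fractal_dimension(np.zeros(10), kmax=8)


class TestAutoregressive:
    def _simulate_ar(self, coefs, n, rng):
        x = np.zeros(n)
        e = rng.normal(size=n)
        p = len(coefs)
        for t in range(p, n):
            x[t] = sum(c * x[t - i - 1] for i, c in enumerate(coefs)) + e[t]
        return x

    def test_ar2_first_coefficient_recovered(self, rng):
        x = self._simulate_ar([0.5, -0.25], 5000, rng)
        assert ar_feature(x, order=2) == pytest.approx(0.5, abs=0.05)

    def test_ar1_coefficient_recovered(self, rng):
        x = self._simulate_ar([0.9], 5000, rng)
        assert ar_feature(x, order=1) == pytest.approx(0.9, abs=0.05)

    def test_white_noise_has_null_coefficients(self, rng):
        x = rng.normal(size=5000)
        from statsmodels.regression.linear_model import burg

        coefs, _ = burg(x - x.mean(), order=2)
        assert np.all(np.abs(coefs) < 0.05)

    def test_constant_signal_raises(self):
        with pytest.raises(ZeroSignalError):
            ar_feature(np.full(1000, 2.0))


class TestSimpleFeatures:
    def test_peak_amplitudes_direct_arithmetic(self):
        ppa, npa = peak_amplitudes(np.array([-1.0, 0.0, 3.0]))
        assert ppa == pytest.approx(3.0 - 2.0 / 3.0)
        assert npa == pytest.approx(-1.0 - 2.0 / 3.0)

    def test_constant_signal_has_zero_peaks(self):
        assert peak_amplitudes(np.full(10, 5.0)) == (0.0, 0.0)

    def test_sign_flip_swaps_peaks(self, rng):
        x = rng.normal(size=100)
        ppa, npa = peak_amplitudes(x)
        ppa_f, npa_f = peak_amplitudes(-x)
        assert ppa_f == pytest.approx(-npa)
        assert npa_f == pytest.approx(-ppa)

    def test_summary_features(self):
        assert summary_features(np.array([1.0, 2.0, 3.0])) == (6.0, 2.0, 2.0)
        assert summary_features(np.zeros(5)) == (0.0, 0.0, 0.0)
        assert summary_features(np.array([1.0, 2.0, 100.0]))[2] == 2.0


class TestFeatureTables:
    def test_structure(self, small_spec, small_tables):
        n_records = 6 * 2 * small_spec.n_per_group
        for band in BAND_NAMES:
            table = small_tables[band]
            assert len(table) == n_records
            assert list(table.columns[:4]) == [
                "subject_id",
                "modality",
                "electrode",
                "group",
            ]
            assert list(table.columns[4:]) == list(FEATURE_NAMES)
            assert not table[list(FEATURE_NAMES)].isna().any().any()

    def test_demographics_constant_within_subject(self, small_tables):
        t = small_tables["Delta"]
        for _, grp in t.groupby("subject_id"):
            assert grp["Gender"].nunique() == 1
            assert grp["FirstChild"].nunique() == 1

    def test_csv_round_trip(self, small_tables, tmp_path):
        path = tmp_path / "features_Theta.csv"
        t = small_tables["Theta"]
        t.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, t, check_exact=False, rtol=1e-12)

    def test_unusable_records_are_excluded_with_count(self, small_cohort, caplog):
        import dataclasses

        bad = dataclasses.replace(
            small_cohort[0], signal=np.full(2000, 500.0), subject_id="BAD"
        )
        tables = extract_feature_tables([bad, small_cohort[1]])
        assert len(tables["Delta"]) == 1
        assert tables["Delta"].subject_id.iloc[0] != "BAD"
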