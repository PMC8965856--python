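"""Welch PSD, band powers, normalization, TBR and the alpha ratio."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from qeeg.recording import CleanEpoch, EegRecording
from qeeg.spectral import (
    DEFAULT_BANDS,
    NormalizedSpectrum,
    PowerSpectrum,
    SpectralConfig,
    alpha_ratio,
    band_power,
    compute_welch_psd,
    expected_n_segments,
    normalize_spectrum,
    per_frequency_spectra,
    theta_beta_ratio,
)

from conftest import make_epoch


def naive_welch_oracle(x, fs, win_len=1.0, overlap=0.5):
    """Brute-force reference: explicit segment loop, naive DFT matrix,
    Hann window, window-power compensation, one-sided doubling."""
    L = int(fs * win_len)
    step = int(L * (1 - overlap))
    w = sps.get_window("hann", L)
    n_seg = (len(x) - L) // step + 1
    dft = np.exp(-2j * np.pi * np.outer(np.arange(L // 2 + 1), np.arange(L)) / L)
    acc = np.zeros(L // 2 + 1)
    for i in range(n_seg):
        seg = x[i * step : i * step + L]
        seg = (seg - seg.mean()) * w
        p = np.abs(dft @ seg) ** 2 / (fs * (w**2).sum())
        p[1:-1] *= 2
        acc += p
    return acc / n_seg / win_len  # density -> per-1-Hz-bin power


def uniform_spectrum(value=1.0, n_ch=1, fmax=50):
    freqs = np.arange(fmax + 1)
    return PowerSpectrum(
        channel_labels=tuple(f"Ch{i}" for i in range(n_ch)),
        freqs=freqs, power=np.full((n_ch, fmax + 1), float(value)),
        n_segments=1, config=SpectralConfig(),
    )


class TestWelch:
    def test_matches_naive_dft_oracle(self, rng):
        x = rng.standard_normal(400)  # 2-s toy signal
        spec = compute_welch_psd(make_epoch(x))
        oracle = naive_welch_oracle(x, 200.0)
        assert np.allclose(spec.power[0], oracle, rtol=1e-6, atol=1e-14)

    def test_zero_signal_gives_zero_spectrum(self):
        spec = compute_welch_psd(make_epoch(np.zeros((3, 12000))))
        assert np.all(spec.power == 0)
        assert spec.n_segments == 119

    def test_sinusoid_parseval_and_localization(self):
        t = np.arange(12000) / 200.0
        spec = compute_welch_psd(make_epoch(np.sin(2 * np.pi * 10 * t)))
        total = spec.power[0].sum()
        assert total == pytest.approx(0.5, rel=0.02)  # variance of unit sinusoid
        in_peak = spec.power[0, (spec.freqs >= 9) & (spec.freqs <= 11)].sum()
        low = spec.power[0, spec.freqs <= 50].sum()
        assert in_peak / low >= 0.99

    def test_white_noise_parseval(self, rng):
        x = rng.standard_normal(12000)
        spec = compute_welch_psd(make_epoch(x))
        assert 0.95 <= spec.power[0].sum() / x.var() <= 1.05

    def test_segment_count_formula(self):
        assert expected_n_segments(12000, 200, 0.5) == 119
        spec = compute_welch_psd(make_epoch(np.zeros(12000)))
        assert spec.n_segments == 119

    def test_sum_aggregate_scales_by_segment_count(self, rng):
        x = rng.standard_normal((2, 12000))
        mean = compute_welch_psd(make_epoch(x))
        total = compute_welch_psd(make_epoch(x), SpectralConfig(aggregate="sum"))
        assert np.allclose(total.power, mean.power * mean.n_segments)

    def test_epoch_too_short(self):
        with pytest.raises(ValueError, match="epoch too short"):
            compute_welch_psd(make_epoch(np.zeros(100)))

    def test_non_finite_samples_rejected(self):
        x = np.zeros(400)
        x[13] = np.nan
        with pytest.raises(ValueError, match="invalid signal"):
            compute_welch_psd(make_epoch(x))


class TestBandPower:
    def test_flat_spectrum_counts_inclusive_bins(self):
        spec = uniform_spectrum(1.0)
        assert band_power(spec, "theta")[0] == 4
        assert band_power(spec, "alpha")[0] == 5
        assert band_power(spec, "beta")[0] == 13
        assert band_power(spec, "total")[0] == 51

    def test_single_bin_spectrum(self):
        spec = uniform_spectrum(0.0)
        spec.power[0, 10] = 7.0
        assert band_power(spec, "alpha")[0] == band_power(spec, "total")[0] == 7.0
        assert band_power(spec, "theta")[0] == 0 == band_power(spec, "beta")[0]

    def test_linearity_under_scaling(self, rng):
        spec = uniform_spectrum(0.0)
        spec.power[:] = rng.uniform(0.1, 2.0, spec.power.shape)
        scaled = uniform_spectrum(0.0)
        scaled.power[:] = 3.5 * spec.power
        for b in ("theta", "alpha", "beta"):
            assert band_power(scaled, b)[0] == pytest.approx(
                3.5 * band_power(spec, b)[0], rel=1e-12)

    def test_band_outside_support(self):
        spec = uniform_spectrum(1.0, fmax=40)
        with pytest.raises(ValueError, match="outside spectrum support"):
            band_power(spec, (35, 45))

    def test_bands_tile_zero_to_fifty(self):
        bins = sorted(
            b for lo, hi in list(DEFAULT_BANDS.values()) + [(26, 50)]
            for b in range(lo, hi + 1)
        )
        assert bins == list(range(51))


class TestNormalization:
    def test_uniform_gives_equal_fractions(self):
        ns = normalize_spectrum(uniform_spectrum(2.0, n_ch=3, fmax=100))
        assert np.allclose(ns.fraction, 1 / 51)
        assert ns.freqs.max() == 50

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_fractions_sum_to_one_and_scale_invariant(self, seed):
        rng = np.random.default_rng(seed)
        spec = uniform_spectrum(0.0, n_ch=2, fmax=100)
        spec.power[:] = rng.uniform(1e-6, 10.0, spec.power.shape)
        ns = normalize_spectrum(spec)
        assert np.allclose(ns.fraction.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((ns.fraction >= 0) & (ns.fraction <= 1))
        scaled = uniform_spectrum(0.0, n_ch=2, fmax=100)
        scaled.power[:] = spec.power * 17.3
        assert np.allclose(normalize_spectrum(scaled).fraction, ns.fraction, atol=1e-12)

    def test_zero_power_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate spectrum"):
            normalize_spectrum(uniform_spectrum(0.0))


class TestRatios:
    def test_tbr_simple_arithmetic(self):
        spec = uniform_spectrum(0.0)
        spec.power[0, 4:8] = 3.0   # theta = 12
        spec.power[0, 13:17] = 1.0  # beta = 4
        assert theta_beta_ratio(spec)[0] == pytest.approx(3.0)

    def test_tbr_flat_spectrum_is_bin_count_ratio(self):
        assert theta_beta_ratio(uniform_spectrum(1.0))[0] == pytest.approx(4 / 13)

    def test_tbr_raw_equals_normalized(self, rng):
        spec = uniform_spectrum(0.0, fmax=100)
        spec.power[:] = rng.uniform(0.1, 5.0, spec.power.shape)
        raw = theta_beta_ratio(spec)[0]
        norm = theta_beta_ratio(normalize_spectrum(spec))[0]
        assert raw == pytest.approx(norm, abs=1e-12)

    def test_tbr_zero_beta_undefined(self):
        spec = uniform_spectrum(0.0)
        spec.power[0, 5] = 1.0
        with pytest.raises(ValueError, match="undefined TBR"):
            theta_beta_ratio(spec)

    def test_alpha_ratio_identity(self):
        spec = uniform_spectrum(1.0, n_ch=2)
        assert np.allclose(alpha_ratio(spec, spec), 1.0)

    def test_alpha_ratio_planted_raw_suppression(self):
        rest = uniform_spectrum(1.0)
        task = uniform_spectrum(1.0)
        task.power[0, 8:13] *= 0.35
        assert alpha_ratio(task, rest)[0] == pytest.approx(0.35)

    def test_alpha_ratio_channel_mismatch(self):
        a = uniform_spectrum(1.0)
        b = uniform_spectrum(1.0, n_ch=2)
        with pytest.raises(ValueError, match="channel mismatch"):
            alpha_ratio(a, b)

    def test_scale_invariance_of_published_quantities(self, rng):
        """Multiplying the recording by c > 0 leaves normalized spectra, TBR
        and the alpha ratio (raw or normalized) unchanged."""
        x = rng.standard_normal((3, 12000)) * 20
        s1 = compute_welch_psd(make_epoch(x))
        s2 = compute_welch_psd(make_epoch(4.7 * x))
        assert np.allclose(normalize_spectrum(s2).fraction,
                           normalize_spectrum(s1).fraction, atol=1e-9)
        assert np.allclose(theta_beta_ratio(s2), theta_beta_ratio(s1), atol=1e-9)
        assert np.allclose(alpha_ratio(s2, s2), alpha_ratio(s1, s1), atol=1e-9)


class TestFeatureTable:
    def test_participant_feature_table_modes(self, rng):
        from qeeg.spectral import spectral_features

        rest = compute_welch_psd(make_epoch(rng.standard_normal((2, 12000)) * 10,
                                            labels=("Fz", "Cz")))
        task = compute_welch_psd(make_epoch(rng.standard_normal((2, 12000)) * 10,
                                            labels=("Fz", "Cz")))
        rest_only = spectral_features(rest)
        assert list(rest_only.channel) == ["Fz", "Cz"]
        assert "alpha_ratio" not in rest_only.columns
        assert np.allclose(rest_only.tbr, theta_beta_ratio(rest))

        raw = spectral_features(rest, task, ratio_mode="raw")
        norm = spectral_features(rest, task, ratio_mode="normalized")
        assert np.allclose(raw.alpha_ratio, alpha_ratio(task, rest))
        assert np.allclose(
            norm.alpha_ratio,
            alpha_ratio(normalize_spectrum(task), normalize_spectrum(rest)))


class TestGroupSpectra:
    def _ns(self, fractions):
        fractions = np.atleast_2d(fractions)
        return NormalizedSpectrum(("Cz",), np.arange(fractions.shape[1]), fractions)

    def test_identical_members_have_zero_sd(self):
        f = np.full((1, 51), 1 / 51)
        df = per_frequency_spectra({"g": [self._ns(f), self._ns(f)]})
        assert np.allclose(df["sd"], 0.0)
        assert np.allclose(df["mean"], 1 / 51)

    def test_means_remain_normalized_and_order_invariant(self, rng):
        members = []
        for _ in range(4):
            p = rng.uniform(0.1, 1, (1, 51))
            members.append(self._ns(p / p.sum()))
        df = per_frequency_spectra({"g": members})
        assert df.groupby("group")["mean"].sum().iloc[0] == pytest.approx(1.0)
        df_rev = per_frequency_spectra({"g": members[::-1]})
        assert np.allclose(df["mean"], df_rev["mean"])
        assert np.allclose(df["sd"], df_rev["sd"])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            per_frequency_spectra({"g": []})
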