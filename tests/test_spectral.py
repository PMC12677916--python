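import numpy as np
import pandas as pd
import pytest

from bcifes.montage import default_montage
from bcifes.spectral import (
    BandScheme,
    PSDMatrix,
    band_power,
    band_power_table,
    dar,
    dtabr,
    global_psd,
    pdbsi,
    relative_psd,
    welch_psd,
)


def averaged_periodogram_oracle(x, fs, window_s=20.0, overlap_s=5.0):
    """Independent Welch oracle: mean one-sided periodogram over windows."""
    nperseg = int(round(window_s * fs))
    step = nperseg - int(round(overlap_s * fs))
    psds = []
    start = 0
    while start + nperseg <= x.size:
        seg = x[start:start + nperseg]
        spec = np.fft.rfft(seg)
        p = (np.abs(spec) ** 2) / (fs * nperseg)
        p[1:] *= 2.0
        if nperseg % 2 == 0:
            p[-1] /= 2.0
        psds.append(p)
        start += step
    return np.fft.rfftfreq(nperseg, 1.0 / fs), np.mean(psds, axis=0)


def flat_psd(value=1.0, df=0.05, fmax=60.0, labels=("a", "b")):
    freqs = np.arange(0.0, fmax + df / 2, df)
    power = np.full((len(labels), freqs.size), value)
    return PSDMatrix(power=power, bin_frequencies=freqs, channel_labels=labels,
                     window_length=1.0 / df, overlap=0.0, n_windows=1)


class TestWelch:
    def test_window_arithmetic_for_two_minute_epoch(self, rng):
        x = rng.standard_normal((1, 30_000))
        psd = welch_psd(x, 250.0)
        assert psd.n_windows == 7  # starts 0, 15, ..., 90 s
        assert psd.df == pytest.approx(0.05)

    def test_matches_independent_periodogram_oracle(self, rng):
        x = rng.standard_normal(30_000)
        psd = welch_psd(x[None], 250.0)
        f_o, p_o = averaged_periodogram_oracle(x, 250.0)
        np.testing.assert_allclose(psd.bin_frequencies, f_o, atol=1e-12)
        np.testing.assert_allclose(psd.power[0], p_o, rtol=1e-9)

    def test_tone_mass_concentrated_at_its_frequency(self):
        t = np.arange(30_000) / 250.0
        x = np.sqrt(2.0) * np.sin(2 * np.pi * 10.0 * t)  # unit RMS
        psd = welch_psd(x[None], 250.0)
        total = psd.power[0].sum()
        near = psd.power[0][(psd.bin_frequencies >= 9.5)
                            & (psd.bin_frequencies <= 10.5)].sum()
        assert near / total >= 0.95

    def test_parseval_integrated_psd_equals_variance(self, rng):
        x = rng.standard_normal(30_000)
        psd = welch_psd(x[None], 250.0)
        integrated = psd.power[0].sum() * psd.df
        assert integrated == pytest.approx(np.mean(x**2), rel=0.05)

    def test_zero_signal_zero_psd(self):
        psd = welch_psd(np.zeros((2, 10_000)), 250.0)
        assert np.all(psd.power == 0.0)

    def test_too_short_epoch_raises(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros((1, 100)), 250.0)


class TestBandPower:
    def test_flat_psd_integrates_to_bandwidth(self):
        psd = flat_psd(1.0)
        assert band_power(psd, 8.0, 13.0)[0] == pytest.approx(5.0)

    def test_band_partition_sums_to_total(self, rng):
        x = rng.standard_normal((3, 30_000))
        psd = welch_psd(x, 250.0)
        total = band_power(psd, 0.5, 60.0)
        parts = sum(band_power(psd, lo, hi) for _, lo, hi in BandScheme())
        np.testing.assert_allclose(parts, total, rtol=1e-6)

    def test_empty_band_raises(self):
        with pytest.raises(ValueError):
            band_power(flat_psd(), 60.5, 61.0)


class TestRelativePSD:
    def test_flat_psd_shares_proportional_to_bandwidth(self):
        # evaluation range 1-60 Hz: delta contributes only 1-4
        shares = relative_psd(flat_psd())
        widths = {"delta": 3.0, "theta": 4.0, "alpha": 5.0,
                  "beta": 17.0, "gamma": 30.0}
        for band, w in widths.items():
            assert shares[band].iloc[0] == pytest.approx(w / 59.0)
        assert shares.sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_single_band_signal_takes_full_share(self):
        psd = flat_psd(0.0)
        mask = (psd.bin_frequencies >= 9.0) & (psd.bin_frequencies < 11.0)
        psd.power[:, mask] = 4.0
        shares = relative_psd(psd)
        assert shares["alpha"].iloc[0] == pytest.approx(1.0)
        assert shares["delta"].iloc[0] == pytest.approx(0.0)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal((2, 30_000))
        a = relative_psd(welch_psd(x, 250.0))
        b = relative_psd(welch_psd(3.0 * x, 250.0))
        pd.testing.assert_frame_equal(a, b)

    def test_zero_power_channel_reported_missing(self):
        psd = flat_psd(0.0)
        shares = relative_psd(psd)
        assert shares.isna().all().all()


class TestRatios:
    @staticmethod
    def _powers(**kw):
        base = {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0,
                "gamma": 1.0}
        base.update(kw)
        return pd.DataFrame({k: [v] for k, v in base.items()}, index=["Cz"])

    def test_dar_arithmetic(self):
        assert dar(self._powers(delta=2.0, alpha=2.0)).global_value == 1.0
        assert dar(self._powers(delta=6.0, alpha=2.0)).global_value == 3.0

    def test_dtabr_arithmetic_and_gamma_irrelevance(self):
        p = self._powers(delta=4.0, theta=4.0, alpha=2.0, beta=2.0)
        assert dtabr(p).global_value == 2.0
        p2 = self._powers(delta=4.0, theta=4.0, alpha=2.0, beta=2.0, gamma=99.0)
        assert dtabr(p2).global_value == 2.0
        assert dtabr(self._powers()).global_value == 1.0

    def test_recovery_pattern_lowers_dar(self):
        pre = self._powers(delta=6.0, alpha=2.0)
        post = self._powers(delta=4.0, alpha=4.0)  # alpha up, delta down
        assert dar(post).global_value < dar(pre).global_value

    def test_zero_alpha_flagged_not_raised(self):
        res = dar(self._powers(alpha=0.0))
        assert np.isnan(res.per_channel.iloc[0])
        assert res.flagged_channels == ("Cz",)


class TestPdBSI:
    @staticmethod
    def _psd(left_value, right_value):
        m = default_montage()
        labels = m.analysis_labels
        freqs = np.arange(0.0, 30.0, 0.5)
        power = np.ones((len(labels), freqs.size))
        for l, r in m.homologous_pairs:
            power[labels.index(l)] = left_value
            power[labels.index(r)] = right_value
        return m, PSDMatrix(power=power, bin_frequencies=freqs,
                            channel_labels=labels, window_length=2.0,
                            overlap=0.0, n_windows=1)

    def test_perfect_symmetry_is_zero(self):
        m, psd = self._psd(2.0, 2.0)
        assert pdbsi(psd, m).value == pytest.approx(0.0)

    def test_three_to_one_asymmetry_is_half(self):
        m, psd = self._psd(1.0, 3.0)
        assert pdbsi(psd, m).value == pytest.approx(0.5)

    def test_silent_hemisphere_approaches_one(self):
        m, psd = self._psd(1e-12, 1.0)
        assert pdbsi(psd, m).value == pytest.approx(1.0, abs=1e-6)

    def test_left_right_swap_invariance(self):
        m, psd_a = self._psd(1.0, 3.0)
        _, psd_b = self._psd(3.0, 1.0)
        assert pdbsi(psd_a, m).value == pytest.approx(pdbsi(psd_b, m).value)

    def test_scale_invariance(self):
        m, psd = self._psd(1.0, 3.0)
        scaled = PSDMatrix(power=10.0 * psd.power,
                           bin_frequencies=psd.bin_frequencies,
                           channel_labels=psd.channel_labels,
                           window_length=2.0, overlap=0.0, n_windows=1)
        assert pdbsi(psd, m).value == pytest.approx(pdbsi(scaled, m).value)

    def test_delta_band_variant_restricts_bins(self):
        m, psd = self._psd(1.0, 3.0)
        # make only delta bins asymmetric
        labels = psd.channel_labels
        mask = psd.bin_frequencies >= 4.0
        psd.power[:, mask] = 1.0
        res = pdbsi(psd, m, band=(0.5, 4.0))
        assert res.value == pytest.approx(0.5)
        whole = pdbsi(psd, m)
        assert whole.value < res.value


class TestGlobalPSD:
    def test_mean_over_22_analysis_channels(self):
        m = default_montage()
        labels = m.analysis_labels
        freqs = np.arange(0.0, 30.0, 0.5)
        power = np.zeros((22, freqs.size))
        power[0] = 2.0
        psd = PSDMatrix(power=power, bin_frequencies=freqs,
                        channel_labels=labels, window_length=2.0, overlap=0.0,
                        n_windows=1)
        np.testing.assert_allclose(global_psd(psd, m), 2.0 / 22.0)

    def test_channel_mismatch_raises(self):
        m = default_montage()
        psd = flat_psd(labels=("a", "b"))
        with pytest.raises(ValueError):
            global_psd(psd, m)


def test_scale_equivariance_of_powers_and_invariance_of_ratios(rng):
    """Scaling the signal by c scales powers by c^2 and leaves DAR/DTABR
    and pdBSI unchanged."""
    m = default_montage()
    x = rng.standard_normal((22, 30_000))
    a = welch_psd(x, 250.0, channel_labels=m.analysis_labels)
    b = welch_psd(2.0 * x, 250.0, channel_labels=m.analysis_labels)
    pa, pb = band_power_table(a), band_power_table(b)
    np.testing.assert_allclose(pb.to_numpy(), 4.0 * pa.to_numpy(), rtol=1e-9)
    assert dar(pa).global_value == pytest.approx(dar(pb).global_value)
    assert dtabr(pa).global_value == pytest.approx(dtabr(pb).global_value)
    assert pdbsi(a, m).value == pytest.approx(pdbsi(b, m).value)
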