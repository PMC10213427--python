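"""Frequency-band ladder construction and ideal-mask band-pass filtering."""

import math

import numpy as np
import pytest

from mfdfc.bands import (
    FrequencyBand,
    band_table,
    bandpass,
    conservative_lowest_frequency,
    make_scheme,
    n3l_band_limits,
    nyquist,
    spectrum,
)


class TestNyquist:
    @pytest.mark.parametrize(
        "tr,expected", [(2.0, 0.25), (1.0, 0.5), (0.72, 1.0 / 1.44)]
    )
    def test_half_sampling_rate(self, tr, expected):
        assert nyquist(tr) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_tr_rejected(self):
        with pytest.raises(ValueError):
            nyquist(0.0)


class TestLadder:
    @pytest.mark.parametrize(
        "k,lo4,hi4",
        [
            (2, 0.2231, 0.6065),
            (3, 0.0821, 0.2231),
            (4, 0.0302, 0.0821),
            (5, 0.0111, 0.0302),
            # e^-5.5 = 0.004087: the 4-d.p. ladder value is 0.0041
            (6, 0.0041, 0.0111),
        ],
    )
    def test_boundaries_to_four_decimals(self, k, lo4, hi4):
        lo, hi = n3l_band_limits(k)
        assert round(lo, 4) == lo4
        assert round(hi, 4) == hi4

    def test_neighbouring_ratio_is_e(self):
        for k in range(2, 10):
            lo, hi = n3l_band_limits(k)
            assert hi / lo == pytest.approx(math.e, rel=1e-12)

    def test_ladder_is_contiguous(self):
        for k in range(2, 9):
            assert n3l_band_limits(k + 1)[1] == pytest.approx(
                n3l_band_limits(k)[0], rel=1e-12
            )

    def test_rejects_indices_below_two(self):
        with pytest.raises(ValueError):
            n3l_band_limits(1)


class TestBandTable:
    def test_seven_bands_at_tr2(self, bands_tr2):
        assert [b.name for b in bands_tr2] == [
            f"Slow-{k}" for k in range(8, 1, -1)
        ]

    def test_clipping_at_both_ends(self, bands_tr2):
        assert bands_tr2[0].f_low == pytest.approx(7.32e-4)
        assert bands_tr2[-1].f_high == pytest.approx(0.25)
        assert bands_tr2[-1].f_low == pytest.approx(0.2231, abs=5e-5)

    def test_contiguous_non_overlapping(self, bands_tr2):
        for a, b in zip(bands_tr2, bands_tr2[1:]):
            assert a.f_high == pytest.approx(b.f_low, rel=1e-9)

    def test_faster_tr_leaves_top_band_unclipped(self):
        # nyquist 1 Hz exceeds Slow-2's theoretical upper edge, so no clipping
        top = band_table(0.5, 142, 4096)[-1]
        assert top.name == "Slow-2"
        assert top.f_high == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_conservative_lowest_frequency(self):
        assert conservative_lowest_frequency(4096, 2.0) == pytest.approx(
            2.44e-4, abs=5e-7
        )


class TestSchemes:
    def test_combined_is_slow5_then_slow4(self):
        s = make_scheme("Combined")
        assert s.band_names == ("Slow-5", "Slow-4")

    def test_conventional_is_single_literal_band(self):
        s = make_scheme("Conventional")
        assert len(s.bands) == 1
        assert (s.bands[0].f_low, s.bands[0].f_high) == (0.01, 0.08)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            make_scheme("Slow-9")


def spectral_mask_oracle(x, band, padded, tr):
    """Direct frequency-domain mask, written independently of bandpass."""
    x = np.asarray(x, float) - np.mean(x)
    X = np.fft.fft(x, n=padded)
    f = np.fft.fftfreq(padded, d=tr)
    keep = (np.abs(f) >= band.f_low) & (np.abs(f) < band.f_high)
    nyq = 1.0 / (2 * tr)
    if band.f_high >= nyq * (1 - 1e-9):
        keep |= np.isclose(np.abs(f), nyq)
    keep[0] = False
    X[~keep] = 0.0
    return np.real(np.fft.ifft(X))[: len(x)]


class TestBandpass:
    def test_constant_series_maps_to_zero(self, slow4):
        out = bandpass(np.full(142, 7.3), slow4)
        assert np.abs(out).max() < 1e-10 * 7.3

    def test_in_band_tone_preserved_on_interior(self, slow4):
        t = np.arange(142) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)
        y = bandpass(x, slow4)
        interior = slice(15, -15)
        rmse = np.sqrt(np.mean((y[interior] - x[interior]) ** 2))
        assert rmse < 0.05 * np.sqrt(np.mean(x[interior] ** 2))

    def test_matches_independent_mask_oracle(self, bands_tr2, rng):
        x = rng.normal(size=142)
        for band in bands_tr2:
            expected = spectral_mask_oracle(x, band, 4096, 2.0)
            np.testing.assert_allclose(bandpass(x, band), expected, atol=1e-10)

    def test_disjoint_bands_sum_to_demeaned_signal(self, bands_tr2, rng):
        x = rng.normal(size=142)
        total = sum(bandpass(x, b) for b in bands_tr2)
        resid = x - x.mean() - total
        interior = slice(10, -10)
        rel = np.linalg.norm(resid[interior]) / np.linalg.norm(x[interior])
        assert rel < 0.01

    def test_idempotent_on_native_grid(self, slow4, rng):
        # without padding the DFT mask is a projection: exactly idempotent
        x = rng.normal(size=142)
        once = bandpass(x, slow4, padded_length=142)
        twice = bandpass(once, slow4, padded_length=142)
        assert np.linalg.norm(twice - once) < 1e-8 * np.linalg.norm(once)

    def test_near_idempotent_with_padding(self, slow4, rng):
        # truncating the padded output re-introduces a little out-of-band
        # leakage, so with padding idempotence is approximate, not exact
        x = rng.normal(size=142)
        once = bandpass(x, slow4)
        twice = bandpass(once, slow4)
        interior = slice(15, -15)
        rel = np.linalg.norm((twice - once)[interior]) / np.linalg.norm(once[interior])
        assert rel < 0.15

    def test_disjoint_band_outputs_nearly_uncorrelated(self, bands_tr2):
        slow5 = next(b for b in bands_tr2 if b.name == "Slow-5")
        slow3 = next(b for b in bands_tr2 if b.name == "Slow-3")
        rs = []
        for seed in range(10):
            x = np.random.default_rng(seed).normal(size=142)
            a = bandpass(x, slow5)
            b = bandpass(x, slow3)
            rs.append(np.corrcoef(a, b)[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_band_above_nyquist_rejected(self):
        band = FrequencyBand("too-high", 0.3, 0.6)
        with pytest.raises(ValueError):
            bandpass(np.ones(64), band, padded_length=256, tr_seconds=2.0)

    def test_non_finite_input_rejected(self, slow4):
        x = np.ones(142)
        x[3] = np.nan
        with pytest.raises(ValueError):
            bandpass(x, slow4)


class TestSpectrum:
    def test_pure_grid_cosine_lands_in_one_bin(self):
        padded = 256
        k = 11
        t = np.arange(padded) * 2.0
        f = k / (padded * 2.0)
        x = 3.0 * np.cos(2 * np.pi * f * t)
        dec = spectrum(x, padded_length=padded)
        assert dec.cosine[k] == pytest.approx(3.0, abs=1e-10)
        assert abs(dec.sine[k]) < 1e-10
        others = np.delete(dec.amplitudes, k)
        assert np.abs(others).max() < 1e-10

    def test_reconstruction_matches_padded_series(self, rng):
        x = rng.normal(size=30)
        dec = spectrum(x, padded_length=64)
        recon = dec.reconstruct()
        padded = np.concatenate([x, np.zeros(34)])
        assert np.linalg.norm(recon - padded) < 1e-8 * np.linalg.norm(padded)

    def test_parseval_against_time_domain_power(self, rng):
        x = rng.normal(size=100)
        padded = 256
        dec = spectrum(x, padded_length=padded)
        spectral_power = dec.cosine[0] ** 2 + 0.5 * np.sum(
            dec.cosine[1:] ** 2 + dec.sine[1:] ** 2
        )
        # the Nyquist bin is unpaired: its power is a^2, not a^2/2
        spectral_power += 0.5 * dec.cosine[-1] ** 2
        time_power = np.sum(x**2) / padded
        assert spectral_power == pytest.approx(time_power, rel=1e-10)
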