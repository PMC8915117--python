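"""Multi-scale decomposition/reconstruction and threshold baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgid.wavelet import (
    WaveletSpec,
    band_ranges,
    dwt_decompose,
    dwt_reconstruct,
    wavelet_threshold_denoise,
)


def band_power(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """FFT-based band-power oracle, independent of the wavelet path."""
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    spec = np.abs(np.fft.rfft(x)) ** 2
    sel = (freqs >= lo) & (freqs < hi)
    return float(spec[sel].sum())


class TestDecomposeReconstruct:
    def test_roundtrip_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=4096)
        d = dwt_decompose(x, 360.0, 8)
        r = dwt_reconstruct(d)
        assert np.max(np.abs(r - x)) < 1e-8 * np.max(np.abs(x))

    def test_perfect_reconstruction_100_random_signals(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(512, 3000))
            x = rng.normal(size=n)
            d = dwt_decompose(x, 360.0, 6)
            r = dwt_reconstruct(d)
            assert np.max(np.abs(r - x)) / np.max(np.abs(x)) < 1e-8

    def test_constant_signal_has_vanishing_details(self):
        d = dwt_decompose(np.full(2048, 5.0), 360.0, 6)
        for detail in d.detail:
            assert np.max(np.abs(detail)) < 1e-10
        # the mean energy lives in the approximations
        assert np.all(np.abs(d.approx[-1]) > 1.0)

    def test_coefficient_counts_and_lengths(self):
        x = np.zeros(4096)
        d = dwt_decompose(x, 360.0, 8)
        assert len(d.approx) == len(d.detail) == 8
        spec = WaveletSpec()
        for j in range(1, 9):
            expected = 4096 / 2**j
            slack = spec.filter_length
            assert abs(len(d.approx[j - 1]) - expected) <= slack

    def test_signal_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            dwt_decompose(np.zeros(64), 360.0, 8)

    def test_unknown_wavelet_raises(self):
        with pytest.raises(ValueError, match="unknown wavelet"):
            WaveletSpec(name="nosuchwavelet99")

    def test_zero_all_coefficients_gives_zero_signal(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=1024)
        d = dwt_decompose(x, 360.0, 5)
        ov = {f"D{j}": np.zeros_like(d.detail[j - 1]) for j in range(1, 6)}
        ov.update({f"A{j}": np.zeros_like(d.approx[j - 1]) for j in range(1, 6)})
        assert np.max(np.abs(dwt_reconstruct(d, ov))) == 0.0

    def test_override_length_mismatch_raises(self):
        d = dwt_decompose(np.zeros(1024), 360.0, 4)
        with pytest.raises(ValueError, match="length"):
            dwt_reconstruct(d, {"D1": np.zeros(3)})

    def test_zeroing_finest_detail_removes_high_band(self):
        # chirp sweeping 1..170 Hz has energy above 90 Hz; zeroing D1 must
        # cut the interior of that band by >= 20 dB (FFT band-power oracle;
        # the 90-110 Hz shoulder is excluded as db8 is not a brick wall)
        from scipy.signal import chirp

        fs = 360.0
        t = np.arange(8192) / fs
        x = chirp(t, f0=1.0, t1=t[-1], f1=170.0)
        d = dwt_decompose(x, fs, 8)
        r = dwt_reconstruct(d, {"D1": np.zeros_like(d.detail[0])})
        before = band_power(x, fs, 110.0, 170.0)
        after = band_power(r, fs, 110.0, 170.0)
        assert 10 * np.log10(before / after) >= 20.0

    def test_energy_conservation(self):
        # Parseval bookkeeping is boundary-free under periodization; the
        # default symmetric padding adds edge coefficients whose surplus
        # energy is excluded from this check
        rng = np.random.default_rng(3)
        x = rng.normal(size=4096)
        d = dwt_decompose(x, 360.0, 6, WaveletSpec(mode="periodization"))
        coeff_energy = sum(float(np.sum(c**2)) for c in d.detail)
        coeff_energy += float(np.sum(d.approx[-1] ** 2))
        sig_energy = float(np.sum(x**2))
        assert abs(coeff_energy - sig_energy) / sig_energy < 0.01


class TestBandRanges:
    @pytest.mark.parametrize(
        "scale,kind,lo,hi",
        [
            (1, "approximation", 0.0, 90.0),
            (2, "approximation", 0.0, 45.0),
            (1, "detail", 90.0, 180.0),
            (2, "detail", 45.0, 90.0),
            (8, "approximation", 0.0, 360 / 2**9),  # 0.703 Hz
        ],
    )
    def test_fs360_bands(self, scale, kind, lo, hi):
        bands = band_ranges(360.0, 8)
        match = [b for b in bands if b.scale == scale and b.kind == kind]
        assert len(match) == 1
        assert match[0].lo == pytest.approx(lo)
        assert match[0].hi == pytest.approx(hi)

    @given(levels=st.integers(1, 12), fs=st.floats(1.0, 10000.0))
    @settings(max_examples=50, deadline=None)
    def test_bands_tile_the_half_spectrum(self, levels, fs):
        bands = band_ranges(fs, levels)
        details = sorted(
            (b for b in bands if b.kind == "detail"), key=lambda b: b.lo
        )
        edges = [fs / 2 ** (levels + 1)] + [b.hi for b in details]
        for prev, band in zip(edges, details):
            assert band.lo == pytest.approx(prev)
        assert details[-1].hi == pytest.approx(fs / 2)
        deepest = [b for b in bands if b.kind == "approximation" and b.scale == levels]
        assert deepest[0].hi == pytest.approx(details[0].lo)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            band_ranges(-1.0, 4)
        with pytest.raises(ValueError):
            band_ranges(360.0, 0)


class TestThresholdDenoise:
    def test_noise_free_constant_unchanged(self):
        x = np.full(4096, 2.0)
        for rule in ("heuristic", "unbiased-estimation"):
            out = wavelet_threshold_denoise(x, 360.0, 6, rule)
            assert np.max(np.abs(out - x)) < 1e-8

    def test_reduces_white_noise_variance(self):
        # Monte-Carlo over 20 seeds: shrinkage must reduce variance
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 4096)
            out = wavelet_threshold_denoise(x, 360.0, 6, "heuristic")
            assert out.var() < x.var()

    def test_unknown_rule_raises(self):
        with pytest.raises(ValueError, match="rule"):
            wavelet_threshold_denoise(np.zeros(1024), 360.0, 4, "bogus")
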