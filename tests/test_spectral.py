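import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import csd as scipy_csd
from scipy.signal import filtfilt, firwin, hilbert

from ictalsync.spectral import (
    CoherencySpectrum,
    EstimationError,
    SpectralParams,
    band_icoh,
    coherency,
    cross_spectra,
    icoh_null_quantile,
    lf_icoh,
    stft_spectrogram,
)

FS = 256.0


def oracle_csd(x, y, fs, segment_s=2.0, overlap=0.5):
    """Welch cross-spectral density by explicit segment loop and DFT matrix."""
    nper = int(round(segment_s * fs))
    hop = nper - int(round(overlap * nper))
    n_seg = 1 + (len(x) - nper) // hop
    k = np.arange(nper)
    m = np.arange(nper // 2 + 1)
    window = 0.5 - 0.5 * np.cos(2 * np.pi * k / nper)  # periodic Hann, explicit
    dft = np.exp(-2j * np.pi * np.outer(k, m) / nper)
    acc = np.zeros(nper // 2 + 1, complex)
    for s in range(n_seg):
        xs = np.asarray(x[s * hop : s * hop + nper], float)
        ys = np.asarray(y[s * hop : s * hop + nper], float)
        xs = xs - xs.mean()
        ys = ys - ys.mean()
        acc += np.conj((xs * window) @ dft) * ((ys * window) @ dft)
    acc /= n_seg
    onesided = np.full(nper // 2 + 1, 2.0)
    onesided[0] = 1.0
    onesided[-1] = 1.0
    return m * fs / nper, acc * onesided / (fs * np.sum(window**2))


def bandlimited(rng, n, fs=FS, lo=1.0, hi=8.0):
    taps = firwin(257, [lo, hi], fs=fs, pass_zero=False)
    return filtfilt(taps, 1.0, rng.standard_normal(n + 512))[256 : 256 + n]


def test_welch_matches_explicit_dft_oracle(rng):
    x = rng.standard_normal(2560)
    y = rng.standard_normal(2560)
    freqs, Sxx, Syy, Sxy = cross_spectra(x, y, FS)
    of, oSxy = oracle_csd(x, y, FS)
    _, oSxx = oracle_csd(x, x, FS)
    assert np.allclose(freqs, of)
    assert np.abs(Sxy - oSxy).max() < 1e-10
    assert np.abs(Sxx - oSxx.real).max() < 1e-10


def test_welch_matches_scipy_csd(rng):
    x = rng.standard_normal(2560)
    y = rng.standard_normal(2560)
    _, _, _, Sxy = cross_spectra(x, y, FS)
    _, Sxy_sp = scipy_csd(
        x, y, fs=FS, window="hann", nperseg=512, noverlap=256, detrend="constant", average="mean"
    )
    assert np.abs(Sxy - Sxy_sp).max() < 1e-12


def test_self_coherency_is_one(rng):
    x = rng.standard_normal(2560)
    coh = coherency(x, x, FS)
    assert np.allclose(coh.values.real, 1.0, atol=1e-9)
    assert np.allclose(coh.values.imag, 0.0, atol=1e-9)


def test_delay_shows_in_cross_phase():
    t = np.arange(0, 10, 1 / FS)
    x = np.cos(2 * np.pi * 4.0 * t)
    d = 8  # samples
    y = np.roll(x, d)
    freqs, _, _, Sxy = cross_spectra(x, y, FS)
    k = np.argmin(np.abs(freqs - 4.0))
    expected = -2 * np.pi * 4.0 * d / FS
    assert np.angle(Sxy[k]) == pytest.approx(expected, abs=0.05)


def test_band_icoh_arithmetic():
    coh = CoherencySpectrum(
        freqs=np.array([2.0, 2.5, 3.0]), values=1j * np.array([0.2, -0.4, 0.6])
    )
    assert band_icoh(coh, (1.0, 4.0), include_upper=False) == pytest.approx(0.4)


def test_band_icoh_real_coherency_is_zero():
    coh = CoherencySpectrum(freqs=np.array([2.0, 5.0]), values=np.array([1.0 + 0j, 1.0 + 0j]))
    assert band_icoh(coh, (1.0, 8.0)) == 0.0


def test_band_icoh_pure_imaginary_is_one():
    coh = CoherencySpectrum(freqs=np.array([2.0, 5.0]), values=np.array([1j, 1j]))
    assert band_icoh(coh, (1.0, 8.0)) == 1.0


def test_band_icoh_empty_band_errors():
    coh = CoherencySpectrum(freqs=np.array([2.0]), values=np.array([0.5j]))
    with pytest.raises(EstimationError, match=r"\[5.0, 6.0\]"):
        band_icoh(coh, (5.0, 6.0))


def test_lf_is_mean_of_delta_and_theta(rng):
    x = bandlimited(rng, 2560)
    y = bandlimited(rng, 2560)
    coh = coherency(x, y, FS)
    delta = band_icoh(coh, (1.0, 4.0), include_upper=False)
    theta = band_icoh(coh, (4.0, 8.0), include_upper=True)
    assert lf_icoh(x, y, FS) == pytest.approx(0.5 * (delta + theta), abs=1e-12)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    a=st.floats(min_value=-50, max_value=50).filter(lambda v: abs(v) > 1e-3),
    b=st.floats(min_value=-50, max_value=50).filter(lambda v: abs(v) > 1e-3),
    seed=st.integers(min_value=0, max_value=100),
)
def test_scale_invariance_and_symmetry(a, b, seed):
    r = np.random.default_rng(seed)
    x = r.standard_normal(2560)
    y = r.standard_normal(2560)
    base = lf_icoh(x, y, FS)
    assert lf_icoh(a * x, b * y, FS) == pytest.approx(base, abs=1e-10)
    assert lf_icoh(y, x, FS) == pytest.approx(base, abs=1e-12)
    assert 0.0 <= base <= 1.0


def test_volume_conduction_rejected(rng):
    """A zero-lag mixture of one source stays at the independent-noise null."""
    common = bandlimited(rng, 2560)
    x = common + 0.05 * rng.standard_normal(2560)
    y = 0.7 * common + 0.05 * rng.standard_normal(2560)
    q99 = icoh_null_quantile(0.99, window_s=10.0, fs=FS, n_reps=1000, seed=7)
    assert lf_icoh(x, y, FS) < q99


def test_quadrature_copy_is_near_perfect_synchrony(rng):
    x = bandlimited(rng, 2560)
    y = np.imag(hilbert(x))  # 90 degrees at every frequency
    assert lf_icoh(x, y, FS) > 0.9


class TestNullQuantile:
    def test_seeded_determinism(self):
        a = icoh_null_quantile(0.5, n_reps=300, seed=1)
        b = icoh_null_quantile(0.5, n_reps=300, seed=1)
        assert a == b

    def test_monotone_in_q(self):
        qs = icoh_null_quantile(np.array([0.1, 0.5, 0.9, 0.99]), n_reps=500, seed=2)
        assert np.all(np.diff(qs) > 0)

    def test_bias_shrinks_with_more_segments(self):
        short = icoh_null_quantile(0.5, window_s=10.0, n_reps=400, seed=3)
        long = icoh_null_quantile(0.5, window_s=60.0, n_reps=400, seed=3)
        assert long < short

    def test_small_n_reps_warns(self):
        with pytest.warns(UserWarning, match="n_reps"):
            icoh_null_quantile(0.5, n_reps=50, seed=4)

    def test_bad_q_rejected(self):
        with pytest.raises(ValueError):
            icoh_null_quantile(1.5, n_reps=200, seed=5)


class TestSpectrogram:
    def test_pure_tone_peaks_at_tone_frequency(self):
        t = np.arange(0, 60, 1 / FS)
        x = np.cos(2 * np.pi * 4.0 * t)
        times, freqs, power = stft_spectrogram(x, FS)
        assert np.all(power >= 0)
        peak = freqs[np.argmax(power, axis=0)]
        assert np.all(peak == 4.0)

    def test_zeros_give_zero_power(self):
        _, _, power = stft_spectrogram(np.zeros(2560), FS)
        assert np.all(power == 0)

    def test_downward_chirp_ridge_is_monotone(self):
        t = np.arange(0, 100, 1 / FS)
        phase = 2 * np.pi * (6.0 * t - 0.5 * (4.0 / 100.0) * t**2)  # 6 -> 2 Hz
        x = np.cos(phase)
        _, freqs, power = stft_spectrogram(x, FS)
        ridge = freqs[np.argmax(power, axis=0)]
        assert np.all(np.diff(ridge) <= 0)

    def test_too_short_signal_errors(self):
        with pytest.raises(EstimationError, match="shorter"):
            stft_spectrogram(np.zeros(100), FS)


def test_single_segment_coherency_rejected():
    x = np.zeros(512)
    with pytest.raises(EstimationError, match="2 segments"):
        cross_spectra(x, x, FS, SpectralParams(segment_s=2.0, overlap=0.0))


def test_unequal_lengths_rejected(rng):
    with pytest.raises(ValueError, match="equal length"):
        cross_spectra(rng.standard_normal(512), rng.standard_normal(640), FS)
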