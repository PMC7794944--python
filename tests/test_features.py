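"""Feature extractor: registry closure, closed-form oracles, brute-force checks."""

import warnings

import numpy as np
import pytest

from pupglearn import features as ft
from pupglearn.synth import SynthConfig, generate_signal

FS = 1000.0


def test_registry_has_102_unique_names_with_fixed_group_sizes():
    assert len(ft.FEATURE_REGISTRY) == 102
    assert len(set(ft.FEATURE_REGISTRY)) == 102
    sizes = [len(v) for v in ft.FEATURE_GROUPS.values()]
    assert sizes == [19, 17, 8, 12, 13, 6, 2, 5, 20]


# ---------------------------------------------------------------------------
# Time domain
# ---------------------------------------------------------------------------

def test_unit_sine_crest_and_rms():
    t = np.arange(1000) / 1000.0
    td = ft.time_domain_features(np.sin(2 * np.pi * t), fs=FS)
    assert td["Crest Factor"] == pytest.approx(np.sqrt(2), rel=1e-6)
    assert td["Root Mean Square"] == pytest.approx(1 / np.sqrt(2), rel=1e-6)


def test_constant_signal_unit_factors_and_sentinels():
    with pytest.warns(UserWarning):
        td = ft.time_domain_features(np.full(100, 2.5), fs=FS)
    assert td["Crest Factor"] == pytest.approx(1.0)
    assert td["Shape Factor"] == pytest.approx(1.0)
    assert td["Impulse Factor"] == pytest.approx(1.0)
    assert td["Skewness"] == 0.0  # sentinel


def test_average_frequency_counts_zero_crossings():
    td = ft.time_domain_features(np.array([1.0, -1.0, 1.0, -1.0]), fs=4.0)
    assert td["Average Frequency"] == pytest.approx(1.0)


@pytest.mark.parametrize("alpha", [2.0, 7.5])
def test_scale_behaviour_of_time_features(alpha, rng):
    x = rng.standard_normal(500)
    a = ft.time_domain_features(x, fs=FS)
    b = ft.time_domain_features(alpha * x, fs=FS)
    for scale_free in ("Crest Factor", "Shape Factor", "Impulse Factor"):
        assert b[scale_free] == pytest.approx(a[scale_free], rel=1e-9)
    assert b["Root Mean Square"] == pytest.approx(alpha * a["Root Mean Square"])
    assert b["Energy"] == pytest.approx(alpha**2 * a["Energy"])


# ---------------------------------------------------------------------------
# Spectral
# ---------------------------------------------------------------------------

def test_pure_tone_centroid_and_median_frequency():
    t = np.arange(2000) / FS
    sp = ft.spectral_features(np.sin(2 * np.pi * 50 * t), fs=FS)
    assert abs(sp["Spectral Centroid"] - 50.0) <= 0.5
    assert abs(sp["Median Frequency"] - 50.0) <= 0.5
    assert abs(sp["Mean Frequency"] - 50.0) <= 0.5


def test_thd_of_half_amplitude_second_harmonic():
    t = np.arange(2000) / FS
    x = np.sin(2 * np.pi * 50 * t) + 0.5 * np.sin(2 * np.pi * 100 * t)
    sp = ft.spectral_features(x, fs=FS)
    assert sp["Total Harmonic Distortions"] == pytest.approx(-6.02, abs=0.5)


def test_thd_of_pure_tone_is_negligible():
    t = np.arange(2000) / FS
    sp = ft.spectral_features(np.sin(2 * np.pi * 50 * t), fs=FS)
    assert sp["Total Harmonic Distortions"] <= -60.0


def test_all_zero_signal_has_no_spectrum():
    with pytest.raises(ValueError):
        ft.spectral_features(np.zeros(256), fs=FS)


# ---------------------------------------------------------------------------
# Cepstral and chroma
# ---------------------------------------------------------------------------

def test_mfcc_scaling_shifts_only_first_coefficient(rng):
    x = rng.standard_normal(4096)
    a = ft.cepstral_features(x, fs=FS)
    b = ft.cepstral_features(3.0 * x, fs=FS)
    assert abs(b["1st Coefficient of MFCC"] - a["1st Coefficient of MFCC"]) > 1e-3
    for name in ("2nd Coefficient of MFCC", "3rd Coefficient of MFCC",
                 "4th Coefficient of MFCC"):
        assert b[name] == pytest.approx(a[name], abs=1e-6)


def test_cepstral_determinism(rng):
    x = rng.standard_normal(4096)
    a = ft.cepstral_features(x, fs=FS)
    b = ft.cepstral_features(x.copy(), fs=FS)
    assert np.array_equal(a.to_numpy(), b.to_numpy())


def test_mfcc_matches_independent_filterbank_computation(rng):
    """Brute-force mel-cepstrum (explicit loops) agrees with the extractor."""
    params = ft.FeatureParams()
    x = rng.standard_normal(params.frame + 2 * params.hop)  # 3 frames
    got = ft.cepstral_features(x, fs=FS, params=params)

    window = np.hanning(params.frame)
    bank = ft.mel_filterbank(params.n_filters, params.frame, FS)
    coeffs = []
    for start in range(0, 3 * params.hop, params.hop):
        frame = x[start:start + params.frame] * window
        power = np.abs(np.fft.rfft(frame)) ** 2
        loge = np.log(np.maximum(bank @ power, 1e-24))
        n = loge.size
        frame_c = []
        for k in range(4):
            basis = np.cos(np.pi * k * (2 * np.arange(n) + 1) / (2 * n))
            scale = np.sqrt(2.0 / n) if k else np.sqrt(1.0 / n)
            frame_c.append(scale * np.sum(basis * loge))
        coeffs.append(frame_c)
    expected = np.mean(coeffs, axis=0)
    np.testing.assert_allclose(got.to_numpy()[:4], expected, rtol=1e-8)


def test_chroma_concentrates_on_reference_pitch_class():
    t = np.arange(8192) / FS
    ch = ft.chroma_features(np.sin(2 * np.pi * 440.0 * t), fs=FS)
    assert int(np.argmax(ch.to_numpy())) == 0  # A440 -> first pitch class

    semitone_up = 440.0 * 2 ** (1 / 12)
    ch2 = ft.chroma_features(np.sin(2 * np.pi * semitone_up * t), fs=FS)
    assert int(np.argmax(ch2.to_numpy())) == 1


def test_chroma_of_silence_is_zero():
    ch = ft.chroma_features(np.zeros(2048), fs=FS)
    assert np.all(ch.to_numpy() == 0.0)


# ---------------------------------------------------------------------------
# sEMG-style
# ---------------------------------------------------------------------------

def test_semg_counting_oracles():
    s = ft.semg_features(np.array([0.0, 1.0, 0.0, 1.0, 0.0]), fs=FS)
    assert s["Wavelength"] == pytest.approx(4.0)
    assert s["Average Amplitude Change"] == pytest.approx(1.0)

    ramp = ft.semg_features(np.linspace(0, 1, 50), fs=FS)
    assert ramp["Slope Sign Change"] == 0

    params = ft.FeatureParams(semg_thresh=0.15)
    w = ft.semg_features(np.array([0.0, 0.1, 0.3]), fs=FS, params=params)
    assert w["Willison Amplitude"] == 1


# ---------------------------------------------------------------------------
# Moment descriptors
# ---------------------------------------------------------------------------

def test_zero_order_moment_is_log_equivariant(rng):
    x = rng.standard_normal(200)
    a = ft.moment_descriptor_features(x, fs=FS)
    b = ft.moment_descriptor_features(2.0 * x, fs=FS)
    assert b["Root Squared Zero Order Moment"] - a[
        "Root Squared Zero Order Moment"
    ] == pytest.approx(np.log(2.0), abs=1e-9)


def test_ramp_waveform_length_ratio_hits_sentinel():
    with pytest.warns(UserWarning):
        m = ft.moment_descriptor_features(np.arange(50.0), fs=FS)
    assert m["Waveform Length Ratio"] == 0.0  # second difference identically 0


def test_moment_descriptors_match_hand_sums():
    x = np.array([0.0, 1.0, 0.0, -1.0, 0.0, 1.0])
    d1 = np.diff(x)
    d2 = np.diff(x, n=2)
    m0 = np.sqrt(np.sum(x**2))
    m2 = np.sqrt(np.sum(d1**2))
    m4 = np.sqrt(np.sum(d2**2))
    got = ft.moment_descriptor_features(x, fs=FS)
    assert got["Root Squared Zero Order Moment"] == pytest.approx(np.log(m0))
    assert got["Root Squared 2nd Order Moment"] == pytest.approx(np.log(m2))
    assert got["Root Squared 4th Order Moment"] == pytest.approx(np.log(m4))
    assert got["Waveform Length Ratio"] == pytest.approx(
        np.log(np.sum(np.abs(d1)) / np.sum(np.abs(d2)))
    )


# ---------------------------------------------------------------------------
# Hjorth
# ---------------------------------------------------------------------------

def test_sine_mobility_approaches_angular_frequency_times_dt():
    dt = 1e-4
    t = np.arange(200_0) * dt
    omega = 2 * np.pi * 5.0
    h = ft.hjorth_features(np.sin(omega * t), fs=1 / dt)
    assert h["Mobility"] == pytest.approx(omega * dt, rel=0.02)


def test_noise_is_more_complex_than_a_sine(rng):
    t = np.arange(2000) / FS
    h_sine = ft.hjorth_features(np.sin(2 * np.pi * 5 * t), fs=FS)
    h_noise = ft.hjorth_features(rng.standard_normal(2000), fs=FS)
    assert h_noise["Complexity"] > h_sine["Complexity"]


def test_hjorth_rejects_constant_input():
    with pytest.raises(ValueError):
        ft.hjorth_features(np.full(100, 1.0), fs=FS)


# ---------------------------------------------------------------------------
# Fractal / chaos
# ---------------------------------------------------------------------------

def test_higuchi_dimension_of_line_and_noise(rng):
    assert ft.higuchi_fd(np.linspace(0, 1, 10_000)) == pytest.approx(1.0, abs=0.05)
    assert ft.higuchi_fd(rng.standard_normal(10_000)) >= 1.8


def test_approximate_entropy_of_perfectly_periodic_signal():
    pattern = np.sin(2 * np.pi * np.arange(10) / 10)
    x = np.tile(pattern, 100)
    assert ft.approximate_entropy(x) <= 0.05


def test_fractal_family_runs_on_pulse_signal():
    sig = generate_signal(SynthConfig(seed=1), "normal", 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f = ft.fractal_chaos_features(sig)
    assert np.all(np.isfinite(f.to_numpy()))
    assert 1.0 <= f["Higuchi's Fractal Dimension"] <= 2.0


# ---------------------------------------------------------------------------
# LTP
# ---------------------------------------------------------------------------

def test_constant_signal_fills_single_uniform_bin():
    lt = ft.ltp_features(np.full(50, 1.0), fs=FS)
    upper, lower = lt.to_numpy()[:10], lt.to_numpy()[10:]
    assert upper[0] == 42 and lower[0] == 42  # all-zero patterns, class 0
    assert upper[1:].sum() == 0 and lower[1:].sum() == 0


def test_ltp_histograms_sum_to_n_minus_8(rng):
    x = rng.standard_normal(300)
    lt = ft.ltp_features(x, fs=FS).to_numpy()
    assert lt[:10].sum() == 292
    assert lt[10:].sum() == 292


def test_ltp_matches_exhaustive_pattern_enumeration(rng):
    x = rng.standard_normal(12)
    t = 0.01
    upper_hist = np.zeros(10)
    lower_hist = np.zeros(10)
    for i in range(4, 8):
        neigh = [x[i + s] for s in (-4, -3, -2, -1, 1, 2, 3, 4)]
        up = [int(v > x[i] + t) for v in neigh]
        lo = [int(v < x[i] - t) for v in neigh]
        for bits, hist in ((up, upper_hist), (lo, lower_hist)):
            transitions = sum(
                bits[k] != bits[(k + 1) % 8] for k in range(8)
            )
            cls = sum(bits) if transitions <= 2 else 9
            hist[cls] += 1
    got = ft.ltp_features(x, fs=FS).to_numpy()
    np.testing.assert_array_equal(got[:10], upper_hist)
    np.testing.assert_array_equal(got[10:], lower_hist)


# ---------------------------------------------------------------------------
# Full vector
# ---------------------------------------------------------------------------

def test_extract_all_returns_102_finite_values_deterministically():
    sig = generate_signal(SynthConfig(seed=8), "hypertension", 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = ft.extract_all(sig)
        b = ft.extract_all(sig)
    assert a.values.size == 102
    assert np.all(np.isfinite(a.values))
    assert np.array_equal(a.values, b.values)
    assert list(a.as_series().index) == ft.FEATURE_REGISTRY


@pytest.mark.parametrize(
    "degenerate",
    [
        np.zeros(2048),
        np.full(2048, 5.0),
        np.linspace(-1, 1, 2048),
        np.r_[np.zeros(2047), 1.0],
    ],
    ids=["zeros", "constant", "ramp", "impulse"],
)
def test_extract_all_never_emits_non_finite_values(degenerate):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vec = ft.extract_all(degenerate, fs=FS)
    assert np.all(np.isfinite(vec.values))
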