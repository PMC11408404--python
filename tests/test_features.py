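"""Feature families: autocorrelation/PSD identities, CWT, NGS, bispectrum/BGS,
and the assembled 12-feature vector."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spindilometer.features import (
    BANDS,
    FEATURE_NAMES,
    FeatureConfig,
    assemble_features,
    autocorrelation,
    band_power,
    bgs,
    bispectrum_diagonal,
    cwt,
    cwt_features,
    default_scales,
    ngs,
    peak_frequency,
    power_spectral_density,
    relative_band_power,
)
from spindilometer.simkit import SimConfig, simulate_recording

FS = 128.0


class TestAutocorrelation:
    def test_constant_signal_is_zero_after_mean_removal(self):
        assert np.allclose(autocorrelation([1.0, 1.0, 1.0, 1.0]), 0.0)

    def test_lag_zero_is_population_variance(self, rng):
        x = rng.normal(size=500)
        assert autocorrelation(x)[0] == pytest.approx(x.var(), rel=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.normal(size=200)
        xd = x - x.mean()
        n = x.size
        oracle = np.array([
            np.sum(xd[: n - lag] * xd[lag:]) / n for lag in range(n)
        ])
        assert np.allclose(autocorrelation(x), oracle, atol=1e-12)

    def test_empty_or_single_sample_rejected(self):
        with pytest.raises(ValueError):
            autocorrelation([])
        with pytest.raises(ValueError):
            autocorrelation([1.0])


class TestPSD:
    def test_sine_peaks_at_carrier_bin(self):
        t = np.arange(1280) / FS
        spec = power_spectral_density(np.sin(2 * np.pi * 13 * t), FS,
                                      method="periodogram")
        assert spec.freqs[np.argmax(spec.power)] == pytest.approx(13.0, abs=0.1)

    def test_parseval_periodogram_power_equals_variance(self, rng):
        x = rng.normal(size=1280)
        spec = power_spectral_density(x, FS, method="periodogram")
        assert spec.power.sum() * spec.df == pytest.approx(x.var(), rel=0.01)

    def test_acf_route_equals_periodogram_wiener_khinchin(self, rng):
        for n in (1280, 1281):  # even and odd lengths
            x = rng.normal(size=n)
            p1 = power_spectral_density(x, FS, method="periodogram")
            p2 = power_spectral_density(x, FS, method="acf")
            assert np.allclose(p1.freqs, p2.freqs)
            scale = np.abs(p1.power).max()
            assert np.allclose(p1.power, p2.power, atol=1e-8 * scale)

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            power_spectral_density(rng.normal(size=100), -1.0)
        with pytest.raises(ValueError):
            power_spectral_density(np.ones(8), FS)
        with pytest.raises(ValueError, match="method"):
            power_spectral_density(rng.normal(size=100), FS, method="burg")


class TestBandPower:
    def test_full_grid_relative_power_is_one(self, rng):
        spec = power_spectral_density(rng.normal(size=1280), FS)
        full = (spec.freqs[0], spec.freqs[-1] + spec.df)
        assert relative_band_power(spec, *full, total=full) == pytest.approx(1.0)

    def test_white_noise_sigma_fraction_matches_flat_spectrum_ratio(self):
        # E[relative sigma power] for white noise = bandwidth ratio 5/29.5
        gen = np.random.default_rng(0)
        vals = []
        for _ in range(200):
            spec = power_spectral_density(gen.normal(size=1280), FS,
                                          method="periodogram")
            vals.append(relative_band_power(spec, 11.0, 16.0))
        assert np.mean(vals) == pytest.approx(5.0 / 29.5, abs=0.01)

    def test_sigma_sine_concentrates_band_power(self):
        t = np.arange(1280) / FS
        spec = power_spectral_density(np.sin(2 * np.pi * 13 * t), FS,
                                      method="periodogram")
        assert relative_band_power(spec, 11.0, 16.0) > 0.9
        assert peak_frequency(spec) == pytest.approx(13.0, abs=0.1)

    def test_band_outside_grid_rejected(self, rng):
        spec = power_spectral_density(rng.normal(size=1280), FS)
        with pytest.raises(ValueError, match="no bins"):
            band_power(spec, 70.0, 80.0)


def _morlet6(u):
    # psi(u) = (pi*B)^(-1/2) exp(-u^2/B) exp(i*2*pi*C*u), B=2, C=6/(2*pi)
    B, C = 2.0, 6.0 / (2 * np.pi)
    return (np.pi * B) ** -0.5 * np.exp(-(u**2) / B) * np.exp(2j * np.pi * C * u)


class TestCWT:
    def test_zero_signal_gives_zero_coefficients(self):
        scal = cwt(np.zeros(640), FS)
        assert np.allclose(np.abs(scal.coeffs), 0.0)
        feats = cwt_features(scal)
        assert all(v == 0.0 for v in feats.values())

    def test_scale_to_hz_map_is_monotone_decreasing(self):
        scal = cwt(np.zeros(640), FS)
        assert np.all(np.diff(scal.scales) > 0)
        assert np.all(np.diff(scal.freqs_hz) < 0)

    def test_sine_peak_scale_matches_direct_integral_oracle(self):
        t = np.arange(640) / FS
        x = np.sin(2 * np.pi * 13 * t)
        scales = default_scales(FS)
        scal = cwt(x, FS, scales)
        impl_peak = int(np.argmax(np.abs(scal.coeffs).mean(axis=1)))
        # direct discretized integral (1/sqrt(a)) sum f(t) conj(psi)((t-b)/a)
        shifts = np.arange(0, 640, 8)
        oracle_mean = []
        for a in scales:
            coeffs = [
                np.sum(x * np.conj(_morlet6((t - b / FS) / (a / FS)))) / np.sqrt(a)
                for b in shifts
            ]
            oracle_mean.append(np.mean(np.abs(coeffs)))
        oracle_peak = int(np.argmax(oracle_mean))
        assert abs(impl_peak - oracle_peak) <= 1
        assert scal.freqs_hz[impl_peak] == pytest.approx(13.0, rel=0.08)

    def test_linearity_amplitude_doubling(self):
        gen = np.random.default_rng(1)
        x = gen.normal(size=640)
        a = cwt_features(cwt(x, FS))
        b = cwt_features(cwt(2 * x, FS))
        assert b["cwt_sigma_max"] == pytest.approx(2 * a["cwt_sigma_max"], rel=1e-9)
        assert b["cwt_sigma_energy"] == pytest.approx(a["cwt_sigma_energy"], rel=1e-9)

    def test_empty_or_negative_scales_rejected(self):
        with pytest.raises(ValueError):
            cwt(np.zeros(64), FS, scales=np.array([]))
        with pytest.raises(ValueError):
            cwt(np.zeros(64), FS, scales=np.array([-1.0, 2.0]))


class TestNGS:
    def test_exact_blom_quantiles_score_one(self):
        from scipy.stats import norm
        n = 200
        j = np.arange(1, n + 1)
        p = norm.ppf((j - 0.375) / (n + 0.25))
        # build a sample whose standardized order statistics equal p
        x = p * 2.0 + 5.0
        sd = x.std(ddof=1)
        q = np.sort((x - x.mean()) / sd)
        expected = 1.0 - np.sum((q - p) ** 2) / np.sum((q - q.mean()) ** 2)
        assert ngs(x) == pytest.approx(expected, abs=1e-12)
        assert ngs(x) == pytest.approx(1.0, abs=0.01)

    def test_gaussian_sample_scores_near_one(self):
        gen = np.random.default_rng(7)
        scores = [ngs(gen.normal(size=2000)) for _ in range(50)]
        assert np.median(scores) > 0.99

    def test_two_point_sample_scores_below_gaussian(self):
        gen = np.random.default_rng(3)
        gauss = ngs(gen.normal(size=2000))
        two_point = ngs(np.array([-1.0, 1.0] * 1000))
        assert two_point < gauss

    def test_score_never_exceeds_one(self, rng):
        for _ in range(20):
            x = rng.standard_t(df=3, size=500)
            assert ngs(x) <= 1.0 + 1e-12

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="20 samples"):
            ngs(np.ones(5))
        with pytest.raises(ValueError, match="zero-variance"):
            ngs(np.ones(50))


class TestBispectrum:
    def test_zero_signal_gives_zero_slice(self):
        sl = bispectrum_diagonal(np.zeros(1280), FS)
        assert np.allclose(sl.P, 0.0)
        assert sl.freqs[-1] <= FS / 4 + 1e-9

    def test_quadratic_phase_coupling_beats_randomized_phases(self):
        # coupled pair (f, 2f) with phi_2f = 2*phi_f lights up the diagonal
        # at f; block averaging cancels phase-randomized contributions, so
        # the phases must vary per block for the contrast to exist
        gen = np.random.default_rng(0)
        block = 160
        tb = np.arange(block) / FS
        f = 4.8  # on the block DFT grid (bin 6 at df = 0.8 Hz)

        def peak(coupled):
            peaks = []
            for _ in range(10):
                blocks = []
                for _ in range(8):
                    phi = gen.uniform(0, 2 * np.pi)
                    phi2 = 2 * phi if coupled else gen.uniform(0, 2 * np.pi)
                    blocks.append(np.cos(2 * np.pi * f * tb + phi)
                                  + np.cos(2 * np.pi * 2 * f * tb + phi2)
                                  + 0.1 * gen.normal(size=block))
                sl = bispectrum_diagonal(np.concatenate(blocks), FS)
                near_f = (sl.freqs > 3.0) & (sl.freqs < 7.0)
                peaks.append(sl.P[near_f].max())
            return np.mean(peaks)

        assert peak(coupled=True) / peak(coupled=False) > 2.0

    def test_gaussian_noise_peak_to_mean_below_coupled_signal(self):
        gen = np.random.default_rng(1)
        t = np.arange(1280) / FS
        phi = 0.7
        x = np.cos(2 * np.pi * 5 * t + phi) + np.cos(2 * np.pi * 10 * t + 2 * phi)
        sl_c = bispectrum_diagonal(x, FS)
        coupled_ratio = sl_c.P.max() / sl_c.P.mean()
        noise_ratios = []
        for _ in range(10):
            sl = bispectrum_diagonal(gen.normal(size=1280), FS)
            noise_ratios.append(sl.P.max() / sl.P.mean())
        assert np.mean(noise_ratios) < coupled_ratio

    def test_short_blocks_rejected(self):
        with pytest.raises(ValueError, match="64"):
            bispectrum_diagonal(np.zeros(256), FS, n_blocks=8)


class TestBGS:
    def _slice(self, rng):
        return bispectrum_diagonal(rng.normal(size=1280), FS)

    def test_equal_bands_give_one(self, rng):
        sl = self._slice(rng)
        assert bgs(sl, (11.0, 16.0), (11.0, 16.0)) == pytest.approx(1.0)

    def test_nested_numerator_bounded_by_one(self, rng):
        sl = self._slice(rng)
        assert 0.0 <= bgs(sl, (11.0, 16.0), (0.5, 30.0)) <= 1.0

    def test_flat_slice_gives_bandwidth_ratio(self):
        freqs = np.arange(0.0, 32.5, 0.5)
        sl = bispectrum_diagonal(np.zeros(1280), FS)
        sl.freqs, sl.P = freqs, np.ones_like(freqs)
        num = ((freqs >= 11) & (freqs < 16)).sum()
        den = ((freqs >= 0.5) & (freqs < 30)).sum()
        assert bgs(sl) == pytest.approx(num / den)
        assert num / den == pytest.approx(5.0 / 29.5, abs=0.01)

    def test_zero_denominator_rejected(self):
        sl = bispectrum_diagonal(np.zeros(1280), FS)
        with pytest.raises(ValueError, match="denominator"):
            bgs(sl)


class TestAssembleFeatures:
    def test_twelve_named_features_in_fixed_order(self, rng):
        feats = assemble_features(rng.normal(size=1280), FS)
        assert list(feats) == list(FEATURE_NAMES)
        assert len(feats) == 12
        assert all(np.isfinite(v) for v in feats.values())
        assert 0.0 <= feats["psd_rel_sigma"] <= 1.0

    def test_stable_across_runs(self, rng):
        x = rng.normal(size=1280)
        assert assemble_features(x, FS) == assemble_features(x, FS)

    def test_offset_invariance_of_every_feature(self, rng):
        x = rng.normal(size=1280)
        a = assemble_features(x, FS)
        b = assemble_features(x + 57.3, FS)
        for name in FEATURE_NAMES:
            assert b[name] == pytest.approx(a[name], rel=1e-9, abs=1e-12), name

    def test_zero_variance_segment_reports_feature_context(self):
        with pytest.raises(ValueError, match="ngs"):
            assemble_features(np.full(1280, 3.0), FS)

    def test_spindle_frame_has_higher_sigma_power_than_background(self):
        cfg = SimConfig(seed=21, duration_s=120.0, amp_sigma_ratio=4.0,
                        channels=("C4-M1",))
        rec, events = simulate_recording(cfg)
        frame_len = 1280
        from spindilometer.simkit import label_segments
        labels = label_segments(events, rec.channel_labels, rec.duration_s)[0]
        assert labels.any() and not labels.all()
        spindle_frame = np.flatnonzero(labels == 1)[0]
        quiet_frame = np.flatnonzero(labels == 0)[0]
        f_sp = assemble_features(
            rec.samples[0, spindle_frame * frame_len:(spindle_frame + 1) * frame_len], FS)
        f_bg = assemble_features(
            rec.samples[0, quiet_frame * frame_len:(quiet_frame + 1) * frame_len], FS)
        assert f_sp["psd_rel_sigma"] > f_bg["psd_rel_sigma"]


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_ngs_bounded_and_bgs_nonnegative_property(seed):
    gen = np.random.default_rng(seed)
    x = gen.normal(size=640) * gen.uniform(0.5, 20.0) + gen.uniform(-50, 50)
    assert ngs(x) <= 1.0 + 1e-12
    sl = bispectrum_diagonal(x, FS)
    assert np.all(sl.P >= 0.0)
    assert bgs(sl) >= 0.0
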