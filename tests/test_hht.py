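"""Hilbert spectrum, spectral summaries, windows and KS comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mechanospectra import (HilbertSpectrum, IMFSet, KVMParams,
                            SyntheticConfig, ToneSpec, central_frequency,
                            emd, energy_density, frequency_distribution,
                            gen_pillar_field, gen_tone_signal,
                            hilbert_spectrum, ks_compare, response_ratio,
                            response_time, total_traction, window_sample)


def _tone_spectrum(f, a=1.0, dt=0.1, duration=200.0, seed=0):
    cfg = SyntheticConfig(seed=seed, sampling_interval=dt, duration=duration,
                          noise_sd=0.0)
    trace = gen_tone_signal(ToneSpec(components=((f, a, 0.0),)), cfg)
    return hilbert_spectrum(emd(trace))


class TestHilbertSpectrum:
    def test_tone_frequency_within_1pct(self):
        spec = _tone_spectrum(0.2)
        f_med = np.nanmedian(spec.frequency[0, spec.interior])
        assert abs(f_med - 0.2) / 0.2 < 0.01

    def test_tone_amplitude_within_1pct(self):
        spec = _tone_spectrum(0.2, a=2.5)
        a_med = np.median(spec.amplitude[0, spec.interior])
        assert abs(a_med - 2.5) / 2.5 < 0.01

    def test_zero_imf_masked(self):
        imfset = IMFSet(imfs=np.zeros((1, 64)), residual=np.zeros(64),
                        times=np.arange(64.0))
        spec = hilbert_spectrum(imfset)
        assert np.all(spec.amplitude == 0)
        assert np.all(np.isnan(spec.frequency))

    def test_interior_excludes_5pct_edges(self):
        spec = _tone_spectrum(0.2)
        n = spec.frequency.shape[1]
        k = int(np.ceil(0.05 * n))
        assert not spec.interior[:k].any() and not spec.interior[-k:].any()
        assert spec.interior.sum() == n - 2 * k


class TestCentralFrequency:
    def test_pure_tone(self):
        spec = _tone_spectrum(0.2)
        assert abs(central_frequency(spec, 0) - 0.2) / 0.2 < 0.01

    def test_two_constant_halves_average(self):
        n = 200
        freq = np.r_[np.full(n // 2, 0.1), np.full(n // 2, 0.3)][None, :]
        amp = np.ones((1, n))
        spec = HilbertSpectrum(frequency=freq, amplitude=amp,
                               sampling_interval=1.0)
        assert central_frequency(spec, 0) == pytest.approx(0.2, rel=1e-9)

    def test_amplitude_scale_invariance(self):
        spec = _tone_spectrum(0.2)
        scaled = HilbertSpectrum(frequency=spec.frequency,
                                 amplitude=spec.amplitude * 7.3,
                                 sampling_interval=spec.sampling_interval)
        assert central_frequency(scaled, 0) == pytest.approx(
            central_frequency(spec, 0), rel=1e-12)

    def test_all_zero_imf_is_nan(self):
        imfset = IMFSet(imfs=np.zeros((1, 64)), residual=np.zeros(64),
                        times=np.arange(64.0))
        assert np.isnan(central_frequency(hilbert_spectrum(imfset), 0))


class TestResponseTimeAndRatio:
    def test_reciprocal(self):
        assert response_time(0.01) == pytest.approx(100.0)
        assert response_time(1.0) == pytest.approx(1.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            response_time(0.0)
        with pytest.raises(ValueError):
            response_ratio(1.0, 0.0)

    def test_analytic_values(self):
        T = 40.0
        assert response_ratio(0.0, T) == 0.0
        assert response_ratio(T, T) == pytest.approx(1 - np.exp(-1))
        assert response_ratio(5 * T, T) > 0.99

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(t1=st.floats(0, 1e4), t2=st.floats(0, 1e4),
           T=st.floats(1e-3, 1e4))
    def test_monotone_and_bounded(self, t1, t2, T):
        r1, r2 = response_ratio(t1, T), response_ratio(t2, T)
        assert 0.0 <= r1 <= 1.0
        if t1 / T < 30:  # below float saturation of 1 - exp(-t/T)
            assert r1 < 1.0
        if t1 < t2:
            assert r1 <= r2


class TestEnergyDensity:
    def test_zero_signal(self):
        imfset = IMFSet(imfs=np.zeros((2, 64)), residual=np.zeros(64),
                        times=np.arange(64.0))
        e, _, matrix = energy_density(hilbert_spectrum(imfset))
        assert np.all(e.values == 0) and np.all(matrix == 0)

    def test_quadratic_in_amplitude(self):
        spec = _tone_spectrum(0.2)
        doubled = HilbertSpectrum(frequency=spec.frequency,
                                  amplitude=2 * spec.amplitude,
                                  sampling_interval=spec.sampling_interval)
        e1, _, _ = energy_density(spec)
        e2, _, _ = energy_density(doubled)
        np.testing.assert_allclose(e2.values, 4 * e1.values, rtol=1e-12)

    def test_tone_mean_energy_is_f_times_a_squared(self):
        f, a = 0.2, 1.5
        spec = _tone_spectrum(f, a=a)
        e, _, _ = energy_density(spec)
        interior_mean = e.values[spec.interior].mean()
        assert interior_mean == pytest.approx(f * a * a, rel=0.02)


class TestWindowSample:
    @pytest.fixture
    def field(self):
        cfg = SyntheticConfig(seed=5, duration=600.0, noise_sd=0.0,
                              cell_radius=50.0)  # mask covers full grid
        return gen_pillar_field(1.0, KVMParams(), cfg)

    def test_full_mask_12x12_window3_gives_16_blocks(self, field):
        assert len(window_sample(field, 3)) == 16

    def test_window_equal_to_grid_is_total_traction(self, field):
        local = window_sample(field, 12)
        assert len(local) == 1
        np.testing.assert_allclose(local[0].values,
                                   total_traction(field).values, rtol=1e-12)

    def test_partition_additivity(self, field):
        local = window_sample(field, 5)  # partial trailing blocks kept
        summed = np.sum([tr.values for tr in local], axis=0)
        np.testing.assert_allclose(summed, total_traction(field).values,
                                   rtol=1e-12)

    def test_rejects_oversized_window(self, field):
        with pytest.raises(ValueError, match="larger than"):
            window_sample(field, 13)


class TestFrequencyDistribution:
    def test_tone_mass_in_one_bin(self):
        spec = _tone_spectrum(0.2)
        edges = np.linspace(0.025, 1.025, 21)  # 0.2 mid-bin
        pdf = frequency_distribution([spec], bins=edges)
        assert pdf.density.sum() == pytest.approx(1.0, abs=1e-12)
        assert pdf.density[np.digitize(0.2, edges) - 1] > 0.99

    def test_bimodal_pooling_counts(self):
        spec_a = _tone_spectrum(0.1)
        spec_b = _tone_spectrum(0.4)
        edges = np.linspace(0.025, 0.525, 11)  # tones mid-bin
        pdf = frequency_distribution([spec_a, spec_b], bins=edges)
        lo = pdf.density[np.digitize(0.1, edges) - 1]
        hi = pdf.density[np.digitize(0.4, edges) - 1]
        # equal amplitudes and equal interior lengths: masses ~equal
        assert lo == pytest.approx(hi, rel=0.05)
        assert lo + hi > 0.98

    def test_rejects_bad_input(self):
        spec = _tone_spectrum(0.2)
        with pytest.raises(ValueError):
            frequency_distribution([spec], bins=[0.0])
        with pytest.raises(ValueError, match="outside"):
            frequency_distribution([spec], bins=[10.0, 11.0])


class TestKSCompare:
    def test_identical_samples(self):
        x = np.linspace(0, 1, 50)
        D, _ = ks_compare(x, x)
        assert D == 0.0

    def test_disjoint_supports(self):
        D, p = ks_compare(np.linspace(0, 1, 50), np.linspace(2, 3, 50))
        assert D == 1.0 and p < 1e-10

    def test_matches_brute_force_ecdf(self):
        rng = np.random.default_rng(17)
        a = rng.normal(0, 1, 200)
        b = rng.normal(0.5, 1, 200)
        D, _ = ks_compare(a, b)
        pooled = np.sort(np.concatenate([a, b]))
        Fa = np.searchsorted(np.sort(a), pooled, side="right") / a.size
        Fb = np.searchsorted(np.sort(b), pooled, side="right") / b.size
        assert D == pytest.approx(np.max(np.abs(Fa - Fb)), abs=1e-12)

    def test_rejects_tiny_samples(self):
        with pytest.raises(ValueError):
            ks_compare([1.0], [1.0, 2.0])
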