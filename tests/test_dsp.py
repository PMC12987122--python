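"""Filter identities, envelope oracle, NSPA contract, spectra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aspids.dsp import (
    BandSpec,
    NormalizedEnvelope,
    attenuation_spectrum,
    average_spectrum,
    bandpass_filter,
    bandpass_gain,
    crest_factor,
    envelope,
    normalized_envelope,
    nspa,
    peak_impulse_spectrum,
    self_noise_baseline,
    Spectrum,
)
from aspids.io import Recording

RATE = 44100.0


def brute_force_nspa(values, rate, edge_exclude=0.005):
    """Independent region-enumeration oracle for the NSPA definition."""
    values = list(values)
    n = len(values)
    margin = int(round(edge_exclude * rate))
    if 2 * margin >= n:
        margin = 0
    vmax = max(values[margin : n - margin] if margin else values)
    region = [v for v in values if 0.5 * vmax <= v <= 0.9 * vmax]
    if not region:
        region = [v for v in values if v >= 0.5 * vmax]
    rms = math.sqrt(sum(v * v for v in region) / len(region))
    return 20.0 * math.log10(rms)


class TestBandpass:
    def test_analytic_gain_is_exactly_one_at_center(self):
        for order in range(1, 9):
            b = BandSpec(1565.0, 6000.0, order)
            assert b.magnitude_response(b.fc) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("order", range(1, 9))
    def test_edge_gain_is_half_power_for_every_order(self, order):
        b = BandSpec(1565.0, 6000.0, order)
        # The algebraic identity fc^2 - f1^2 = f1*fdelta makes the edge
        # gain 1/sqrt(2) independent of order, in both the analytic
        # response and the realized digital filter.
        np.testing.assert_allclose(
            b.magnitude_response([b.f1, b.f2]), 1 / np.sqrt(2), atol=1e-12
        )
        np.testing.assert_allclose(
            bandpass_gain(b, [b.f1, b.f2], RATE), 1 / np.sqrt(2), atol=1e-6
        )

    def test_gain_unimodal_with_max_at_center(self):
        b = BandSpec(1565.0, 6000.0, 4)
        f = np.linspace(100, 9000, 500)
        g = b.magnitude_response(f)
        peak = f[np.argmax(g)]
        assert abs(peak - b.fc) < 30
        # non-decreasing before the peak, non-increasing after (the
        # maximally flat top saturates to 1.0 in float64)
        i = np.argmax(g)
        assert np.all(np.diff(g[: i + 1]) >= 0) and np.all(np.diff(g[i:]) <= 0)

    def test_out_of_band_tone_strongly_attenuated(self):
        """A 500 Hz tone through the 1565-6000 Hz filter drops by at least
        the analytically predicted zero-phase attenuation (>= 40 dB)."""
        b = BandSpec(1565.0, 6000.0, 4)
        predicted = b.magnitude_response(500.0) ** 2  # forward-backward
        assert 20 * np.log10(predicted) < -40
        t = np.arange(int(2 * RATE)) / RATE
        x = np.sin(2 * np.pi * 500.0 * t)
        y = bandpass_filter(x, RATE, b)
        mid = slice(int(0.5 * RATE), int(1.5 * RATE))
        measured = np.sqrt(np.mean(y[mid] ** 2)) / np.sqrt(np.mean(x[mid] ** 2))
        assert 20 * np.log10(measured) < -40
        assert measured == pytest.approx(predicted, rel=0.3)

    def test_zero_phase_preserves_impulse_timing(self):
        t = np.arange(int(1 * RATE)) / RATE
        t0 = 0.5
        x = np.exp(-((t - t0) ** 2) / (2 * 0.002**2)) * np.sin(2 * np.pi * 3000 * t)
        y = bandpass_filter(x, RATE, BandSpec(1565, 6000))
        peak = np.argmax(envelope(y)) / RATE
        assert abs(peak - t0) < 0.001

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(np.zeros(100), 8000.0, BandSpec(1565, 6000))

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            BandSpec(6000, 1565)
        with pytest.raises(ValueError):
            BandSpec(1565, 6000, order=0)


class TestEnvelope:
    def test_tone_envelope_is_amplitude(self):
        t = np.arange(int(0.5 * RATE)) / RATE
        x = 0.7 * np.cos(2 * np.pi * 3000 * t)
        env = envelope(x)
        interior = env[1000:-1000]
        np.testing.assert_allclose(interior, 0.7, rtol=0.01)

    def test_gaussian_burst_envelope_matches_window(self):
        t = np.arange(int(1 * RATE)) / RATE
        window = np.exp(-((t - 0.5) ** 2) / (2 * 0.01**2))
        x = window * np.sin(2 * np.pi * 3000 * t)
        env = envelope(x)
        core = np.abs(t - 0.5) < 0.025
        np.testing.assert_allclose(env[core], window[core], rtol=0.02)

    def test_all_zero_input_gives_zero_envelope(self):
        assert np.all(envelope(np.zeros(100)) == 0)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_envelope_dominates_rectified_signal(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(rng.integers(16, 512))
        assert np.all(envelope(x) >= np.abs(x) - 1e-9)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="short"):
            envelope(np.array([1.0]))


class TestBaselineAndNormalization:
    def test_baseline_positive_and_stationary(self, band):
        rng = np.random.default_rng(0)
        rec = Recording(
            samples=rng.standard_normal((1, int(4 * RATE))) * 1e-3,
            rate=RATE,
            roles=["piezo"],
        )
        full = self_noise_baseline(rec, band).values[0]
        half_n = rec.n_samples // 2
        first = self_noise_baseline(
            Recording(samples=rec.samples[:, :half_n], rate=RATE, roles=["piezo"]),
            band,
        ).values[0]
        second = self_noise_baseline(
            Recording(samples=rec.samples[:, half_n:], rate=RATE, roles=["piezo"]),
            band,
        ).values[0]
        assert full > 0
        assert abs(first - second) / full < 0.05

    def test_baseline_linearity(self, band):
        rng = np.random.default_rng(1)
        samples = rng.standard_normal((1, int(2 * RATE))) * 1e-3
        rec1 = Recording(samples=samples, rate=RATE, roles=["piezo"])
        rec2 = Recording(samples=2 * samples, rate=RATE, roles=["piezo"])
        b1 = self_noise_baseline(rec1, band).values[0]
        b2 = self_noise_baseline(rec2, band).values[0]
        assert b2 == pytest.approx(2 * b1, rel=1e-9)

    def test_silent_channel_rejected(self, band):
        rec = Recording(samples=np.zeros((1, int(RATE))), rate=RATE, roles=["piezo"])
        with pytest.raises(ValueError, match="silent"):
            self_noise_baseline(rec, band)

    def test_self_normalization_near_unity(self, band, reference_recording, baseline):
        """A signal statistically identical to the reference normalizes to
        RMS(V) ~ 1."""
        v = normalized_envelope(
            reference_recording.samples[0], RATE, band, baseline, 0
        )
        assert np.sqrt(np.mean(v.values**2)) == pytest.approx(1.0, rel=0.1)

    def test_band_mismatch_rejected(self, baseline):
        with pytest.raises(ValueError, match="band"):
            normalized_envelope(
                np.random.default_rng(0).standard_normal(int(RATE)),
                RATE,
                BandSpec(500, 6000),
                baseline,
                0,
            )

    def test_normalization_linearity(self, band, baseline):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(int(RATE)) * 1e-3
        v1 = normalized_envelope(x, RATE, band, baseline, 0)
        v2 = normalized_envelope(2 * x, RATE, band, baseline, 0)
        np.testing.assert_allclose(v2.values, 2 * v1.values, rtol=1e-9)


class TestNspa:
    def _random_envelope(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(500, 3000))
        values = rng.gamma(1.5, 1.0, size=n)
        # sprinkle impulse-like peaks
        for _ in range(int(rng.integers(1, 8))):
            values[rng.integers(0, n)] += rng.uniform(5, 50)
        return NormalizedEnvelope(values=values, rate=RATE, band=BandSpec(1565, 6000))

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        v = self._random_envelope(seed)
        expected = brute_force_nspa(v.values, v.rate)
        assert nspa(v).nspa == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000), st.floats(0.01, 100.0))
    def test_scale_law(self, seed, a):
        v = self._random_envelope(seed)
        got = nspa(v.scaled(a)).nspa - nspa(v).nspa
        assert got == pytest.approx(20 * math.log10(a), abs=1e-9)

    def test_joint_signal_baseline_scaling_invariance(self, band):
        """Scaling the raw signal and its self-noise reference together
        leaves NSPA unchanged — sensor sensitivity cancels out."""
        rng = np.random.default_rng(7)
        ref = rng.standard_normal((1, int(2 * RATE))) * 1e-3
        t = np.arange(int(2 * RATE)) / RATE
        sig = ref[0] + 0.05 * np.exp(
            -((t - 1.0) ** 2) / (2 * 0.002**2)
        ) * np.sin(2 * np.pi * 3000 * t)
        results = []
        for scale in (1.0, 7.3):
            baseline = self_noise_baseline(
                Recording(samples=scale * ref, rate=RATE, roles=["piezo"]), band
            )
            v = normalized_envelope(scale * sig, RATE, band, baseline, 0)
            results.append(nspa(v).nspa)
        assert results[0] == pytest.approx(results[1], abs=1e-9)

    def test_constant_envelope_uses_fallback(self):
        v = NormalizedEnvelope(
            values=np.full(1000, 3.0), rate=RATE, band=BandSpec(1565, 6000)
        )
        res = nspa(v)
        assert res.fallback_used
        assert res.nspa == pytest.approx(20 * math.log10(3.0), abs=1e-12)

    def test_all_zero_envelope_rejected(self):
        v = NormalizedEnvelope(
            values=np.zeros(1000), rate=RATE, band=BandSpec(1565, 6000)
        )
        with pytest.raises(ValueError, match="undefined"):
            nspa(v)

    def test_region_bounds_inclusive(self):
        # exact 0.5*Vmax and 0.9*Vmax samples belong to the region
        values = np.zeros(1000)
        values[100] = 10.0  # Vmax
        values[200] = 5.0
        values[300] = 9.0
        res = nspa(NormalizedEnvelope(values=values, rate=1e6, band=BandSpec(1565, 6000)))
        assert res.region_count == 2
        expected = 20 * math.log10(math.sqrt((25 + 81) / 2))
        assert res.nspa == pytest.approx(expected, abs=1e-12)


class TestCrestFactor:
    def test_constant_envelope_is_zero_db(self):
        assert crest_factor(np.full(1000, 2.5)) == pytest.approx(0.0, abs=1e-12)

    def test_single_impulse_closed_form(self):
        n = 4096
        values = np.zeros(n)
        values[n // 2] = 1.0
        assert crest_factor(values) == pytest.approx(10 * math.log10(n), abs=1e-9)

    def test_zero_rms_rejected(self):
        with pytest.raises(ValueError):
            crest_factor(np.zeros(10))


class TestSpectra:
    def test_pure_tone_peak_at_tone_frequency(self):
        t = np.arange(int(1 * RATE)) / RATE
        x = np.sin(2 * np.pi * 3000.0 * t)
        spec = peak_impulse_spectrum(x, RATE)
        assert abs(spec.freqs[np.argmax(spec.power_db)] - 3000.0) <= RATE / int(0.1 * RATE)

    def test_segment_centered_on_largest_impulse(self):
        """With two impulses, the analyzed segment follows the larger one:
        its carrier (4 kHz) dominates the returned spectrum, not the
        smaller impulse's 2.5 kHz carrier."""
        t = np.arange(int(2 * RATE)) / RATE
        x = np.exp(-((t - 0.5) ** 2) / (2 * 0.002**2)) * np.sin(2 * np.pi * 2500 * t)
        x += 2.0 * np.exp(-((t - 1.5) ** 2) / (2 * 0.002**2)) * np.sin(
            2 * np.pi * 4000 * t
        )
        spec = peak_impulse_spectrum(x, RATE)
        f_peak = spec.freqs[np.argmax(spec.power_db)]
        assert abs(f_peak - 4000.0) < 50

    def test_impulse_locator_centers_on_event(self):
        t = np.arange(int(1 * RATE)) / RATE
        t0 = 0.312
        x = np.exp(-((t - t0) ** 2) / (2 * 0.002**2)) * np.sin(2 * np.pi * 3000 * t)
        spec = peak_impulse_spectrum(x, RATE)
        assert abs(spec.center_time - t0) < 0.001

    def test_window_longer_than_recording_rejected(self):
        with pytest.raises(ValueError, match="window"):
            peak_impulse_spectrum(np.zeros(100), RATE, window=0.1)

    def test_identical_spectra_give_zero_attenuation(self):
        f = np.linspace(0, 22050, 100)
        s = Spectrum(freqs=f, power_db=np.full(100, -30.0))
        res = attenuation_spectrum(s, s, cutoff=2000.0)
        assert res.mean_above_cutoff == 0.0
        assert np.all(res.diff_db == 0)

    def test_flat_offset_recovered(self):
        f = np.linspace(0, 22050, 100)
        ext = Spectrum(freqs=f, power_db=np.full(100, -10.0))
        internal = Spectrum(freqs=f, power_db=np.full(100, -55.0))
        res = attenuation_spectrum(ext, internal, cutoff=2000.0)
        assert res.mean_above_cutoff == pytest.approx(45.0)
        assert res.max_above_cutoff == pytest.approx(45.0)

    def test_known_transfer_function_recovered(self):
        """Forward model: pass noise through a known attenuation filter and
        recover the per-bin attenuation within 1 dB."""
        from scipy import signal as sps

        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(8 * RATE))
        atten_db = 45.0
        y = x * 10 ** (-atten_db / 20)
        ext = average_spectrum(x, RATE, segment=0.2)
        internal = average_spectrum(y, RATE, segment=0.2)
        res = attenuation_spectrum(ext, internal, cutoff=2000.0)
        np.testing.assert_allclose(res.diff_db, atten_db, atol=1.0)

    def test_grid_mismatch_rejected(self):
        a = Spectrum(freqs=np.linspace(0, 100, 10), power_db=np.zeros(10))
        b = Spectrum(freqs=np.linspace(0, 200, 10), power_db=np.zeros(10))
        with pytest.raises(ValueError, match="grid"):
            attenuation_spectrum(a, b)
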