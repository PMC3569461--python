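"""Signal-analysis chain tests: filters, DF/OI, cycle lengths, morphology."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atriasim.analysis import (
    DF_BAND, FS_HZ, classify_morphology, cycle_lengths, organization_index,
    preprocess, spectrum,
)
from atriasim.synthetic import make_egm


class TestPreprocess:
    def test_zero_in_zero_out(self):
        out = preprocess(np.zeros(2000))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros(400))

    def test_subband_sinusoid_suppressed(self):
        """5 Hz lies below the 40-250 Hz pass band: >99% power removed."""
        t = np.arange(8000) / FS_HZ
        x = np.sin(2 * np.pi * 5.0 * t)
        bp_power = np.mean(preprocess(x) ** 2)
        assert bp_power < 0.01 * np.mean(x ** 2)

    def test_burst_train_demodulates_to_repetition_rate(self):
        """100 Hz bursts repeating at 5 Hz: the envelope peaks at 5 Hz.

        This demodulation is the purpose of the band-pass/rectify/low-pass
        chain: the output spectrum must peak at the burst repetition rate.
        """
        t = np.arange(8000) / FS_HZ
        carrier = np.sin(2 * np.pi * 100.0 * t)
        gate = (np.mod(t, 0.2) < 0.03).astype(float)  # 30 ms bursts at 5 Hz
        env = preprocess(carrier * gate)
        sp = spectrum(env)
        assert sp.df == pytest.approx(5.0, abs=0.13)


class TestSpectrum:
    def test_requires_4_seconds(self):
        with pytest.raises(ValueError):
            spectrum(np.ones(3000))

    def test_resolution_at_most_0p12_hz(self):
        sp = spectrum(np.random.default_rng(0).normal(size=8000))
        assert np.diff(sp.freqs)[0] <= 0.12

    def test_all_zero_input_flagged_not_nan(self):
        sp = spectrum(np.zeros(8000))
        assert not sp.df_defined
        assert np.all(np.isfinite(sp.power))

    @pytest.mark.parametrize("cl", list(range(120, 251, 10)))
    def test_df_matches_activation_rate_over_cl_sweep(self, cl):
        """DF of a noiseless periodic train = nearest bin to 1000/CL."""
        _, phi = make_egm(cl=float(cl), duration=8000)
        sp = spectrum(preprocess(phi))
        f_true = 1000.0 / cl
        bin_hz = sp.freqs[1] - sp.freqs[0]
        assert abs(sp.df - f_true) <= bin_hz

    def test_amplitude_scaling_leaves_df_and_oi_unchanged(self):
        _, phi = make_egm(cl=130, duration=8000)
        s1 = spectrum(preprocess(phi))
        s2 = spectrum(preprocess(10.0 * phi))
        assert s1.df == s2.df
        assert s1.oi == pytest.approx(s2.oi, rel=1e-9)

    def test_fft_matches_naive_dft_oracle(self):
        """Padded FFT equals the brute-force DFT at every analysis bin."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=1000)
        nfft = 16384
        sig = x - x.mean()
        fast = np.abs(np.fft.rfft(sig, nfft)) ** 2
        freqs = np.fft.rfftfreq(nfft, 1e-3)
        keep = freqs <= 21.0
        k = np.flatnonzero(keep)
        n = np.arange(nfft)
        xp = np.zeros(nfft)
        xp[:1000] = sig
        W = np.exp(-2j * np.pi * np.outer(k, n) / nfft)
        naive = np.abs(W @ xp) ** 2
        np.testing.assert_allclose(fast[keep], naive, rtol=1e-9, atol=1e-6)


class TestOrganizationIndex:
    def test_noiseless_periodic_train_is_highly_organized(self):
        _, phi = make_egm(cl=200, duration=8000)
        sp = spectrum(preprocess(phi))
        assert sp.oi >= 0.9

    def test_added_noise_strictly_lowers_oi(self):
        _, clean = make_egm(cl=130, duration=8000)
        oi_clean = spectrum(preprocess(clean)).oi
        _, noisy = make_egm(cl=130, duration=8000, noise=0.5, seed=11)
        oi_noisy = spectrum(preprocess(noisy)).oi
        assert oi_noisy < oi_clean

    def test_incommensurate_mixture_less_organized_than_either(self):
        _, a = make_egm(cl=130, duration=8000)
        _, b = make_egm(cl=190, duration=8000)
        oi_a = spectrum(preprocess(a)).oi
        oi_b = spectrum(preprocess(b)).oi
        oi_mix = spectrum(preprocess(a + b)).oi
        assert oi_mix < min(oi_a, oi_b)

    def test_undefined_df_raises(self):
        sp = spectrum(np.zeros(8000))
        with pytest.raises(ValueError):
            organization_index(sp)

    @settings(max_examples=25, deadline=None)
    @given(cl=st.floats(115, 260), jitter=st.floats(0, 30),
           noise=st.floats(0, 1), seed=st.integers(0, 2 ** 16))
    def test_oi_always_in_unit_interval(self, cl, jitter, noise, seed):
        _, phi = make_egm(cl=cl, duration=6000, jitter=jitter, noise=noise,
                          seed=seed)
        sp = spectrum(preprocess(phi))
        if sp.df_defined:
            assert 0.0 <= sp.oi <= 1.0


class TestCycleLengths:
    def test_constant_train_recovered_exactly(self):
        _, phi = make_egm(cl=200, duration=6000)
        cls = cycle_lengths(preprocess(phi))
        assert np.all(np.abs(cls - 200.0) <= 1.0)

    def test_jitter_std_recovered(self):
        _, phi = make_egm(cl=250, duration=16000, jitter=15.0, seed=42)
        cls = cycle_lengths(preprocess(phi))
        # successive differences of jittered times have std sqrt(2)*sigma
        assert cls.std() == pytest.approx(np.sqrt(2) * 15.0, rel=0.3)

    def test_single_activation_rejected(self):
        _, phi = make_egm(cl=5000, duration=4000)
        with pytest.raises(ValueError):
            cycle_lengths(preprocess(phi))


class TestMorphology:
    def test_flat_trace_returns_no_activity(self):
        assert classify_morphology(np.zeros(2000)) == []

    @pytest.mark.parametrize("label", ["single", "double", "cfae"])
    def test_clean_fixture_classes_recovered(self, label):
        _, phi = make_egm(cl=260, duration=3000, morphology=label)
        calls = classify_morphology(phi)
        assert len(calls) >= 8
        frac = np.mean([c.cls == label for c in calls])
        assert frac == 1.0

    def test_double_potential_two_negatives_40ms_apart(self):
        _, phi = make_egm(cl=300, duration=2000, morphology="double")
        calls = classify_morphology(phi)
        assert all(c.n_negative == 2 for c in calls)

    def test_cfae_continuous_activity_exceeds_50ms(self):
        _, phi = make_egm(cl=300, duration=2000, morphology="cfae")
        calls = classify_morphology(phi)
        assert all(c.continuous_ms > 50.0 for c in calls)

    def test_label_recovery_on_200_seeded_fixtures(self):
        """>= 95% of noisy, jittered fixtures classified as generated."""
        labels = ["single", "double", "cfae"]
        correct = 0
        for seed in range(200):
            label = labels[seed % 3]
            _, phi = make_egm(cl=240.0, duration=3000, morphology=label,
                              jitter=5.0, noise=0.03, seed=seed)
            calls = classify_morphology(phi)
            if not calls:
                continue
            vals, counts = np.unique([c.cls for c in calls],
                                     return_counts=True)
            if vals[np.argmax(counts)] == label:
                correct += 1
        assert correct >= 190
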