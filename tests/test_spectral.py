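import numpy as np
import pytest

from assrpipe.io_formats import EEGRecording
from assrpipe.preprocessing import Epochs
from assrpipe.simulate import colored_noise
from assrpipe.spectral import (
    PSD,
    aperiodic_slope,
    assr_score,
    band_power,
    evoked_power,
    gamma_power_db,
    itpc,
    morlet_tfr,
    welch_psd,
)

from conftest import sinusoid_epochs


def demodulation_oracle(x, freq, n_cycles, fs):
    """Independent oracle: explicit Gaussian-windowed complex demodulation."""
    sigma = n_cycles / (2 * np.pi * freq)
    n_half = int(round(n_cycles / (2 * freq) * fs))
    u = np.arange(-n_half, n_half + 1) / fs
    g = np.exp(-(u**2) / (2 * sigma**2))
    g = g / g.sum()
    out = np.zeros(len(x), dtype=complex)
    for n in range(len(x)):
        acc = 0.0
        for k in range(len(u)):
            m = n + k - n_half
            if 0 <= m < len(x):
                acc += x[m] * g[k] * np.exp(-1j * 2 * np.pi * freq * u[k])
        out[n] = 2.0 * acc
    return out


class TestMorletTFR:
    def test_sinusoid_power_peaks_at_its_frequency(self):
        ep = sinusoid_epochs(freq=40.0, amplitude=1.5, phases=[0.3, 1.0])
        tfr = morlet_tfr(ep, np.arange(35.0, 46.0))
        mask = (tfr.times >= 0.15) & (tfr.times <= 0.35)
        power = np.abs(tfr.coefficients[..., mask]).mean(axis=(0, 1, 3)) ** 2
        assert tfr.freqs[np.argmax(power)] == 40.0
        # amplitude normalization: |coeff| equals the signal amplitude
        peak = np.abs(tfr.coefficients[:, :, 5, mask]).mean()
        assert peak == pytest.approx(1.5, rel=0.01)

    def test_power_scales_quadratically_with_amplitude(self):
        scores = []
        for a in (1.0, 2.0):
            ep = sinusoid_epochs(amplitude=a, phases=[0.0])
            tfr = morlet_tfr(ep, np.array([40.0]))
            mask = (tfr.times >= 0.15) & (tfr.times <= 0.35)
            scores.append((np.abs(tfr.coefficients[0, 0, 0, mask]) ** 2).mean())
        assert scores[1] / scores[0] == pytest.approx(4.0, rel=0.01)

    def test_agrees_with_complex_demodulation_oracle(self, rng):
        fs = 250.0
        x = colored_noise(500, fs, 1.0, rng) + np.sin(
            2 * np.pi * 40.0 * np.arange(500) / fs
        )
        ep = Epochs(data=x[None, None, :], tmin=-0.5, fs=fs,
                    condition="assr40", channel_labels=["Fz"])
        tfr = morlet_tfr(ep, np.array([40.0]))
        oracle = demodulation_oracle(x, 40.0, 7.0, fs)
        inner = slice(60, 440)  # clear of the zero-padded edges
        err = np.abs(tfr.coefficients[0, 0, 0, inner] - oracle[inner])
        assert err.max() / np.abs(oracle[inner]).max() < 0.02

    def test_wavelet_longer_than_epoch_names_frequency(self):
        ep = sinusoid_epochs()
        with pytest.raises(ValueError, match="4 Hz"):
            morlet_tfr(ep, np.array([4.0, 40.0]))


class TestITPC:
    def test_identical_phases_give_unity(self):
        ep = sinusoid_epochs(phases=[0.7] * 50)
        coh = itpc(morlet_tfr(ep, np.array([40.0])))
        mask = slice(300, 450)
        assert coh[0, 0, mask].min() == pytest.approx(1.0, abs=1e-9)

    def test_antiphase_pair_cancels(self):
        ep = sinusoid_epochs(phases=[0.2, 0.2 + np.pi])
        coh = itpc(morlet_tfr(ep, np.array([40.0])))
        assert coh[0, 0, 300:450].max() == pytest.approx(0.0, abs=1e-9)

    def test_bounded_in_unit_interval(self, rng):
        ep = sinusoid_epochs(phases=rng.uniform(0, 2 * np.pi, 40))
        coh = itpc(morlet_tfr(ep, np.arange(38.0, 43.0)))
        assert np.nanmin(coh) >= 0.0 and np.nanmax(coh) <= 1.0

    def test_uniform_phases_match_rayleigh_null_oracle(self, rng):
        """Mean ITPC of N uniform phases matches the Monte-Carlo Rayleigh
        resultant within 3 standard errors (~sqrt(pi)/(2 sqrt(N)))."""
        N = 110
        # Monte-Carlo oracle on raw unit vectors
        reps = np.abs(
            np.exp(1j * rng.uniform(0, 2 * np.pi, (1000, N))).mean(axis=1)
        )
        oracle_mean, oracle_se = reps.mean(), reps.std(ddof=1) / np.sqrt(1000)
        # estimator on 30 simulated uniform-phase sessions
        vals = []
        for _ in range(30):
            ep = sinusoid_epochs(amplitude=5.0,
                                 phases=rng.uniform(0, 2 * np.pi, N))
            coh = itpc(morlet_tfr(ep, np.array([40.0])))
            vals.append(coh[0, 0, 300:450].mean())
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        tol = 3 * np.sqrt(se**2 + oracle_se**2)
        assert np.mean(vals) == pytest.approx(oracle_mean, abs=tol)
        assert oracle_mean == pytest.approx(np.sqrt(np.pi) / (2 * np.sqrt(N)),
                                            abs=3 * oracle_se)

    def test_requires_two_trials(self):
        ep = sinusoid_epochs(phases=[0.0])
        with pytest.raises(ValueError, match="2 retained"):
            itpc(morlet_tfr(ep, np.array([40.0])))


class TestEvokedPower:
    def test_steady_signal_has_zero_relative_change(self, rng):
        # same-variance noise in baseline and stimulation windows
        data = rng.standard_normal((30, 1, 750))
        ep = Epochs(data=data, tmin=-0.5, fs=500.0, condition="assr40",
                    channel_labels=["Fz"])
        power = evoked_power(morlet_tfr(ep, np.array([40.0])),
                             baseline_window=(-0.4, -0.1))
        stim = (ep.times >= 0.1) & (ep.times <= 0.4)
        assert abs(power[0, 0, stim].mean()) < 0.25

    def test_power_doubling_gives_unit_relative_change(self):
        """Stimulation at sqrt(2) x baseline amplitude doubles power:
        relative change 1.0, equivalently +3.01 dB."""
        fs, n = 500.0, 750
        t = -0.5 + np.arange(n) / fs
        x = np.where(t < 0, 1.0, np.sqrt(2.0)) * np.cos(2 * np.pi * 40 * t)
        ep = Epochs(data=np.tile(x, (3, 1, 1)), tmin=-0.5, fs=fs,
                    condition="assr40", channel_labels=["Fz"])
        tfr = morlet_tfr(ep, np.array([40.0]))
        rel = evoked_power(tfr, (-0.35, -0.15))
        db = evoked_power(tfr, (-0.35, -0.15), mode="db")
        stim = (ep.times >= 0.2) & (ep.times <= 0.35)
        assert rel[0, 0, stim].mean() == pytest.approx(1.0, abs=0.05)
        assert db[0, 0, stim].mean() == pytest.approx(3.01, abs=0.2)

    def test_baseline_must_precede_onset(self):
        ep = sinusoid_epochs(phases=[0.0, 1.0])
        with pytest.raises(ValueError, match="precede"):
            evoked_power(morlet_tfr(ep, np.array([40.0])), (0.1, 0.3))


class TestAssrScore:
    def test_perfect_locking_scores_near_one(self):
        ep = sinusoid_epochs(amplitude=5.0, phases=[1.2] * 20)
        tfr = morlet_tfr(ep, np.arange(38.0, 43.0))
        score = assr_score(tfr, "itpc", roi=("Fz",))
        assert score.value == pytest.approx(1.0, abs=0.01)

    def test_invariant_to_roi_channel_order(self, rng):
        ep = sinusoid_epochs(phases=rng.uniform(0, 2 * np.pi, 10),
                             channel_labels=("Fz", "FCz", "Cz"))
        ep.data += 0.1 * rng.standard_normal(ep.data.shape)
        tfr = morlet_tfr(ep, np.arange(38.0, 43.0))
        a = assr_score(tfr, "itpc", roi=("Fz", "FCz", "Cz")).value
        b = assr_score(tfr, "itpc", roi=("Cz", "Fz", "FCz")).value
        assert a == pytest.approx(b, abs=1e-12)


class TestWelchPSD:
    def test_white_noise_variance_is_conserved(self, rng):
        """Parseval: the PSD of unit-variance noise integrates to ~1."""
        x = rng.standard_normal((1, 60 * 500))
        psd = welch_psd([x], fs=500.0, window_s=2.0)
        total = np.trapezoid(psd.power[0], psd.freqs)
        assert total == pytest.approx(1.0, rel=0.02)

    def test_sinusoid_band_power_is_half_amplitude_squared(self):
        fs, a = 500.0, 3.0
        t = np.arange(int(60 * fs)) / fs
        x = (a * np.sin(2 * np.pi * 40.0 * t))[None, :]
        psd = welch_psd([x], fs=fs, window_s=2.0)
        p = band_power(psd, (35.0, 45.0))
        assert p == pytest.approx(a**2 / 2, rel=0.02)

    def test_window_doubling_halves_bin_width(self, rng):
        x = rng.standard_normal((1, 30 * 500))
        a = welch_psd([x], fs=500.0, window_s=2.0)
        b = welch_psd([x], fs=500.0, window_s=4.0)
        assert np.diff(a.freqs)[0] == pytest.approx(2 * np.diff(b.freqs)[0])

    def test_no_segments_rejected(self):
        with pytest.raises(ValueError, match="no usable"):
            welch_psd([], fs=500.0)


class TestRestingMeasures:
    def test_unit_band_power_is_zero_db_and_log_linear(self):
        freqs = np.arange(1.0, 100.0)
        flat = np.full((1, len(freqs)), 1.0 / 19.93)  # ~1 µV² in 30-50 Hz
        psd = PSD(freqs=freqs, power=flat, channel_labels=["Fz"],
                  window_s=2.0, overlap=0.5)
        db1 = gamma_power_db(psd, roi=("Fz",))
        psd10 = PSD(freqs=freqs, power=10 * flat, channel_labels=["Fz"],
                    window_s=2.0, overlap=0.5)
        db10 = gamma_power_db(psd10, roi=("Fz",))
        assert db1 == pytest.approx(0.0, abs=0.02)
        assert db10 - db1 == pytest.approx(10.0, abs=1e-9)

    @pytest.mark.parametrize("chi", [0.0, 0.5, 1.0, 1.5])
    def test_slope_recovers_generating_exponent(self, chi, rng):
        psds = []
        for _ in range(100):
            x = colored_noise(8 * 500, 500.0, chi, rng)[None, :]
            psds.append(welch_psd([x], fs=500.0, window_s=2.0).power)
        psd = welch_psd([colored_noise(8 * 500, 500.0, chi, rng)[None, :]],
                        fs=500.0, window_s=2.0)
        psd.power = np.mean(psds, axis=0)
        slope, stderr = aperiodic_slope(psd)
        assert slope == pytest.approx(-chi, abs=0.1)

    def test_alpha_peak_in_excluded_band_does_not_bias_fit(self, rng):
        fs = 500.0
        base = [colored_noise(int(20 * fs), fs, 1.0, rng)[None, :]
                for _ in range(20)]
        t = np.arange(int(20 * fs)) / fs
        alpha = (3.0 * np.sin(2 * np.pi * 10.0 * t))[None, :]
        psd_a = welch_psd(base, fs=fs, window_s=2.0)
        psd_b = welch_psd([x + alpha for x in base], fs=fs, window_s=2.0)
        sa, _ = aperiodic_slope(psd_a)
        sb, _ = aperiodic_slope(psd_b)
        assert sa == pytest.approx(sb, abs=0.02)

    def test_too_few_fit_points_rejected(self):
        freqs = np.arange(1.0, 8.0)
        psd = PSD(freqs=freqs, power=np.ones((1, len(freqs))),
                  channel_labels=["Fz"], window_s=2.0, overlap=0.5)
        with pytest.raises(ValueError, match="at least 10"):
            aperiodic_slope(psd)
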