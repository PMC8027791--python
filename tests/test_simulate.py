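import numpy as np
import pytest
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from assrpipe.design import SessionDesign
from assrpipe.simulate import (
    EffectConfig,
    colored_noise,
    simulate_assr_block,
    simulate_feature_table,
    simulate_recording,
)
from assrpipe.stimulus import ClickTrainSpec


def periodogram_slope(chi, rng, n_real=100, n=4096, fs=500.0):
    """Brute-force oracle: log-log slope of the averaged periodogram."""
    psds = []
    for _ in range(n_real):
        f, p = sp_signal.periodogram(colored_noise(n, fs, chi, rng), fs=fs)
        psds.append(p)
    p = np.mean(psds, axis=0)
    mask = (f >= 2.0) & (f <= 100.0)
    return sp_stats.linregress(np.log10(f[mask]), np.log10(p[mask])).slope


class TestColoredNoise:
    def test_white_noise_has_flat_spectrum(self, rng):
        assert abs(periodogram_slope(0.0, rng)) < 0.1

    def test_pink_noise_recovers_exponent(self, rng):
        assert periodogram_slope(1.0, rng) == pytest.approx(-1.0, abs=0.1)

    def test_normalization_contract(self, rng):
        x = colored_noise(50000, 500.0, 1.0, rng)
        assert x.mean() == pytest.approx(0.0, abs=1e-12)
        assert x.std() == pytest.approx(1.0, abs=1e-12)

    def test_negative_exponent_rejected(self, rng):
        with pytest.raises(ValueError):
            colored_noise(100, 500.0, -0.5, rng)


@pytest.fixture(scope="module")
def tiny_spec():
    return ClickTrainSpec(n_standard=5, n_oddball=0)


class TestSimulateRecording:
    def test_bit_identical_under_fixed_seed(self, tiny_spec):
        d = SessionDesign("S01", 1, "high")
        kwargs = dict(timepoint="h1", effect=EffectConfig(), specs=[tiny_spec],
                      resting_segment_s=4.0)
        a = simulate_recording(d, rng=np.random.default_rng(9), **kwargs)
        b = simulate_recording(d, rng=np.random.default_rng(9), **kwargs)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.events.equals(b.events)

    def test_resting_design_two_pairs(self, tiny_spec, rng):
        d = SessionDesign("S01", 1, "placebo")
        rec = simulate_recording(d, "h1", EffectConfig(), specs=[tiny_spec],
                                 rng=rng, resting_segment_s=4.0)
        codes = rec.events["code"]
        assert (codes == "rest/ec").sum() == 2
        assert (codes == "rest/eo").sum() == 2

    def test_trial_markers_embedded(self, tiny_spec, rng):
        d = SessionDesign("S01", 1, "placebo")
        rec = simulate_recording(d, "h1", EffectConfig(), specs=[tiny_spec],
                                 rng=rng, include_resting=False)
        assert (rec.events["code"] == "assr40/standard").sum() == 5

    def test_unknown_dose_condition_rejected(self, tiny_spec, rng):
        d = SessionDesign("S01", 1, "placebo")
        object.__setattr__(d, "dose", "mystery")
        with pytest.raises(ValueError, match="unknown dose"):
            simulate_recording(d, "h1", EffectConfig(), specs=[tiny_spec],
                               rng=rng)

    def test_baseline_timepoint_ignores_session_dose(self, tiny_spec):
        """Pre-dose recordings are drug-free: high-dose session baselines
        equal placebo-session baselines at the same seed."""
        eff = EffectConfig()
        a = simulate_recording(SessionDesign("S01", 1, "high"), "baseline",
                               eff, specs=[tiny_spec],
                               rng=np.random.default_rng(4),
                               resting_segment_s=4.0)
        b = simulate_recording(SessionDesign("S01", 1, "placebo"), "baseline",
                               eff, specs=[tiny_spec],
                               rng=np.random.default_rng(4),
                               resting_segment_s=4.0)
        np.testing.assert_array_equal(a.data, b.data)

    def test_blinks_are_frontal(self, tiny_spec):
        eff = EffectConfig(blink_rate=30.0, noise_amplitude=0.01,
                           alpha_amplitude=0.0, line_noise_amplitude=0.0,
                           ssr_amplitude=dict.fromkeys(
                               ("placebo", "low", "high"), 0.0))
        d = SessionDesign("S01", 1, "placebo")
        rec = simulate_recording(d, "h1", eff, specs=[tiny_spec],
                                 rng=np.random.default_rng(2),
                                 include_resting=False)
        fz = rec.data[rec.channel_labels.index("Fz")]
        pz = rec.data[rec.channel_labels.index("Pz")]
        assert fz.max() > 100.0  # blink transients land frontally
        assert pz.max() < 10.0


class TestFeatureTableSimulator:
    def test_shape_and_baselines(self, rng):
        tab = simulate_feature_table(5, rng)
        # 5 subjects x 3 doses x (1 baseline + 4 post) rows
        assert len(tab) == 5 * 3 * 5
        post = tab[tab["timepoint"] != "baseline"]
        assert post["baseline_value"].notna().all()

    def test_high_dose_effect_is_injected(self, rng):
        tab = simulate_feature_table(
            40, rng, dose_effects={"placebo": 0.0, "low": 0.0, "high": 0.05}
        )
        post = tab[tab["timepoint"] != "baseline"]
        means = post.groupby("dose")["value"].mean()
        assert means["high"] - means["placebo"] == pytest.approx(0.05, abs=0.02)
        assert abs(means["low"] - means["placebo"]) < 0.02
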