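import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dynergy.energy import EnergySequence, WindowSpec
from dynergy.features import (
    BANDS,
    DEAP19,
    SEED17,
    FeatureInventory,
    FeatureTensor,
    approximate_entropy,
    ar_spectrum_features,
    band_limit,
    differential_entropy,
    extract_feature_set,
    higuchi_fd,
    hjorth_band,
    nsi,
    select_named_features,
    time_domain_features,
    wavelet_entropy,
)
from dynergy.signal_io import ValidationError

from .oracles import apen_oracle, higuchi_oracle, nsi_oracle

windows = st.lists(
    st.floats(-100, 100, allow_nan=False), min_size=25, max_size=120
).map(np.asarray)


class TestTimeDomain:
    def test_basic_values(self):
        out = time_domain_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert out["mean"] == 2.5
        assert out["diff1"] == 1.0
        assert out["energy"] == 30.0

    def test_population_sd(self):
        out = time_domain_features(np.array([1.0, 3.0]))
        assert out["sd"] == 1.0  # population (1/N) form

    def test_zero_sd_normalized_zero(self):
        out = time_domain_features(np.ones(50))
        assert out["diff1_norm"] == 0.0
        assert out["diff2_norm"] == 0.0
        assert out["fd"] == 1.0  # constant input convention

    def test_returns_nine(self):
        assert len(time_domain_features(np.arange(40.0))) == 9

    @settings(max_examples=25, deadline=None)
    @given(windows, st.floats(-50, 50), st.floats(0.5, 10))
    def test_translation_scale_covariance(self, x, shift, scale):
        base = time_domain_features(x)
        moved = time_domain_features(x + shift)
        scaled = time_domain_features(x * scale)
        assert moved["mean"] == pytest.approx(base["mean"] + shift, abs=1e-8)
        assert moved["sd"] == pytest.approx(base["sd"], abs=1e-8)
        assert scaled["sd"] == pytest.approx(base["sd"] * scale, rel=1e-9)
        assert scaled["diff1"] == pytest.approx(base["diff1"] * scale, rel=1e-9)
        assert scaled["energy"] == pytest.approx(
            base["energy"] * scale**2, rel=1e-9)
        if base["sd"] > 1e-9:
            assert scaled["diff1_norm"] == pytest.approx(
                base["diff1_norm"], rel=1e-6)
            assert scaled["diff2_norm"] == pytest.approx(
                base["diff2_norm"], rel=1e-6)

    def test_nsi_matches_oracle(self, rng):
        for n in (40, 157, 200):
            x = rng.standard_normal(n)
            assert nsi(x, 20) == pytest.approx(nsi_oracle(x, 20), abs=1e-10)

    def test_nsi_too_short(self):
        with pytest.raises(ValidationError):
            nsi(np.arange(5.0), 20)


class TestHiguchi:
    def test_line_has_dimension_one(self):
        fd = higuchi_fd(np.linspace(0, 10, 800), k_max=8)
        assert 1.0 - 1e-9 <= fd <= 1.05

    def test_matches_oracle(self, rng):
        for n in (50, 120, 200):
            x = rng.standard_normal(n)
            assert higuchi_fd(x, 8) == pytest.approx(
                higuchi_oracle(x, 8), abs=1e-10)

    def test_noise_rougher_than_line(self, rng):
        noise = rng.standard_normal(400)
        assert higuchi_fd(noise) > higuchi_fd(np.linspace(0, 1, 400)) + 0.5


class TestHjorth:
    def test_constant_zero_activity(self):
        assert hjorth_band(np.ones(512), BANDS["alpha"], 128.0) == (0, 0, 0)

    def test_sinusoid_mobility_matches_definition(self):
        fs = 200.0
        t = np.arange(800) / fs
        x = np.sin(2 * np.pi * 10 * t)
        _, mob, comp = hjorth_band(x, BANDS["alpha"], fs)
        # brute-force definition on the identically band-passed samples
        y = band_limit(x, BANDS["alpha"], fs)
        dy = np.diff(y) * fs
        ddy = np.diff(dy) * fs
        mob_ref = np.sqrt(dy.var() / y.var())
        comp_ref = np.sqrt(ddy.var() / dy.var()) / mob_ref
        assert mob == pytest.approx(mob_ref, abs=1e-9)
        assert comp == pytest.approx(comp_ref, abs=1e-9)

    def test_noise_more_complex_than_tone(self):
        fs = 200.0
        t = np.arange(800) / fs
        tone = np.sin(2 * np.pi * 10 * t)
        wins = 0
        for seed in range(20):
            noise = np.random.default_rng(seed).standard_normal(800)
            c_noise = hjorth_band(noise, BANDS["alpha"], fs)[2]
            c_tone = hjorth_band(tone, BANDS["alpha"], fs)[2]
            wins += c_noise > c_tone
        assert wins > 10

    def test_spectral_mode_runs(self, rng):
        out = hjorth_band(rng.standard_normal(512), BANDS["beta"], 128.0,
                          mode="spectral")
        assert all(np.isfinite(out))


class TestARSpectrum:
    def test_sinusoid_peak_in_beta(self, rng):
        fs = 200.0
        t = np.arange(800) / fs
        x = np.sin(2 * np.pi * 20 * t) + 0.01 * rng.standard_normal(800)
        out = ar_spectrum_features(x, fs)
        assert out["ar_max_freq_beta"] == pytest.approx(20.0, abs=0.5)

    def test_white_noise_flat(self, rng):
        x = rng.standard_normal(800)
        out = ar_spectrum_features(x, 200.0)
        expected = 512 * x.var()
        assert abs(out["ar_power_sum_all"] - expected) / expected < 0.20

    def test_scaling_homogeneity(self, rng):
        x = rng.standard_normal(800)
        base = ar_spectrum_features(x, 200.0)
        scaled = ar_spectrum_features(3.0 * x, 200.0)
        for band in ("theta", "alpha", "beta", "gamma", "all"):
            assert scaled[f"ar_power_sum_{band}"] == pytest.approx(
                9.0 * base[f"ar_power_sum_{band}"], rel=1e-6)

    def test_too_short_errors(self):
        with pytest.raises(ValidationError):
            ar_spectrum_features(np.zeros(15), 200.0, order=10)


class TestApEn:
    def test_constant_is_zero(self):
        assert approximate_entropy(np.ones(100), 2, 0.1) == 0.0

    def test_bad_r(self):
        with pytest.raises(ValidationError):
            approximate_entropy(np.arange(50.0), 2, r=-1.0)

    def test_matches_oracle(self, rng):
        for n in (60, 130, 200):
            x = rng.standard_normal(n)
            assert approximate_entropy(x, 2, 0.4) == pytest.approx(
                apen_oracle(x, 2, 0.4), abs=1e-10)

    def test_periodic_frozen_value(self):
        # value frozen from the brute-force oracle before the main build
        x = np.array([0.0, 1.0] * 50)
        expected = 5.1016070083731435e-05
        assert apen_oracle(x, 2, 0.5) == pytest.approx(expected, abs=1e-12)
        assert approximate_entropy(x, 2, 0.5) == pytest.approx(
            expected, abs=1e-10)

    def test_nonnegative(self, rng):
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal(120)
            assert approximate_entropy(x) >= -1e-10


class TestWaveletEntropy:
    def test_returns_eight(self, rng):
        out = wavelet_entropy(rng.standard_normal(512))
        assert len(out) == 8
        assert set(out) == {"we_a6", "we_d1", "we_d2", "we_d3", "we_d4",
                            "we_d5", "we_d6", "we_total"}

    def test_single_component_total_zero(self):
        # constants live entirely in the approximation component
        out = wavelet_entropy(np.full(512, 3.0))
        assert out["we_total"] == pytest.approx(0.0, abs=1e-12)

    def test_equal_energy_total_ln7(self, rng):
        from dynergy import _wavelet as wv

        shapes = [len(c) for c in wv.wavedec(np.zeros(512), 6)]
        coeffs = []
        for s in shapes:
            c = rng.standard_normal(s)
            coeffs.append(c / np.linalg.norm(c))
        signal = wv.waverec(coeffs)
        out = wavelet_entropy(signal)
        assert out["we_total"] == pytest.approx(np.log(7), abs=1e-10)

    def test_noise_exceeds_tone(self):
        fs = 200.0
        t = np.arange(800) / fs
        tone = np.sin(2 * np.pi * 10 * t)
        we_tone = wavelet_entropy(tone)["we_total"]
        wins = sum(
            wavelet_entropy(
                np.random.default_rng(s).standard_normal(800))["we_total"]
            > we_tone
            for s in range(20)
        )
        assert wins > 10


class TestDifferentialEntropy:
    def _band_signal(self, rng, var, fs=200.0, n=800):
        y = band_limit(rng.standard_normal(n), BANDS["alpha"], fs)
        return y / y.std() * np.sqrt(var)

    def test_zero_at_reference_variance(self, rng):
        x = self._band_signal(rng, 1.0 / (2 * np.pi * np.e))
        assert differential_entropy(x, BANDS["alpha"], 200.0) == pytest.approx(
            0.0, abs=1e-9)

    def test_unit_variance_closed_form(self, rng):
        x = self._band_signal(rng, 1.0)
        expected = 0.5 * np.log(2 * np.pi * np.e)
        assert differential_entropy(x, BANDS["alpha"], 200.0) == pytest.approx(
            expected, abs=1e-9)
        assert expected == pytest.approx(1.41894, abs=1e-5)

    def test_scaling_adds_log(self, rng):
        x = self._band_signal(rng, 2.0)
        base = differential_entropy(x, BANDS["alpha"], 200.0)
        scaled = differential_entropy(5.0 * x, BANDS["alpha"], 200.0)
        assert scaled - base == pytest.approx(np.log(5.0), abs=1e-9)

    def test_zero_variance_sentinel(self):
        from dynergy.features import DE_SENTINEL

        assert differential_entropy(
            np.zeros(512), BANDS["alpha"], 200.0) == DE_SENTINEL


class TestInventoryAndExtraction:
    def test_default_inventory_is_49(self):
        inv = FeatureInventory()
        assert len(inv) == 49
        assert len(set(inv.names)) == 49

    def test_extract_table2_shape(self, rng):
        es = EnergySequence(rng.standard_normal(12000), 200.0)
        t = extract_feature_set(es, WindowSpec(4, 2))
        assert t.values.shape == (1, 29, 49)
        assert np.isfinite(t.values).all()

    def test_restricted_inventory_mean(self, rng):
        es = EnergySequence(rng.standard_normal(12000), 200.0)
        inv = FeatureInventory().restrict(["mean"])
        t = extract_feature_set(es, WindowSpec(4, 2), inv)
        assert t.values.shape == (1, 29, 1)
        expected = [es.values[k * 400: k * 400 + 800].mean()
                    for k in range(29)]
        np.testing.assert_allclose(t.values[0, :, 0], expected)

    def test_deterministic(self, rng):
        es = EnergySequence(rng.standard_normal(4000), 200.0)
        inv = FeatureInventory().restrict(["mean", "sd", "fd", "apen",
                                           "de_gamma", "we_total"])
        a = extract_feature_set(es, WindowSpec(4, 2), inv)
        b = extract_feature_set(es, WindowSpec(4, 2), inv)
        np.testing.assert_array_equal(a.values, b.values)

    def test_unknown_inventory_name(self):
        with pytest.raises(ValidationError, match="available"):
            FeatureInventory().restrict(["bogus"])


@pytest.fixture(scope="module")
def tensor():
    rng = np.random.default_rng(3)
    es = EnergySequence(rng.standard_normal(4000), 200.0)
    return extract_feature_set(es, WindowSpec(4, 2))


class TestNamedSubsets:

    def test_seed17(self, tensor):
        out = select_named_features(tensor, "seed17")
        assert out.n_features == 17
        assert len(SEED17) == 17

    def test_deap19(self, tensor):
        out = select_named_features(tensor, "deap19")
        assert out.n_features == 19
        assert len(DEAP19) == 19

    def test_custom_single(self, tensor):
        out = select_named_features(tensor, ["mean"])
        assert out.n_features == 1
        i = tensor.feature_names.index("mean")
        np.testing.assert_array_equal(out.values[:, :, 0],
                                      tensor.values[:, :, i])

    def test_order_preserved(self, tensor):
        out = select_named_features(tensor, ["sd", "mean"])
        assert out.feature_names == ["sd", "mean"]

    def test_unknown_name_lists_available(self, tensor):
        with pytest.raises(ValidationError, match="available"):
            select_named_features(tensor, ["nope"])
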