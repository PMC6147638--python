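import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from freqlayer.bands import ALPHA, BETA, FrequencyBand, THETA
from freqlayer.coordination import (
    MIConfig,
    bandpass,
    block_permutation_surrogate,
    build_frequency_network,
    default_bin_count,
    mi_matrix,
    mutual_information,
    normalize01,
    practical_bin_count,
    restrict_to_multiplex,
    surrogate_mi_matrix,
    threshold_weights,
)
from freqlayer.timeseries import TimeSeriesSet

FS = 508.63


def _sine(freq, n, fs=FS, amp=1.0):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        # 10 Hz through alpha [8, 12]: spectral peak within 5%
        n = 8192
        x = _sine(10.0, n)
        ts = TimeSeriesSet(x[None, :], FS)
        out = bandpass(ts, ALPHA)
        amp_in = np.abs(np.fft.rfft(x)).max()
        amp_out = np.abs(np.fft.rfft(out.values[0])).max()
        assert amp_out == pytest.approx(amp_in, rel=0.05)
        assert out.band == ALPHA

    def test_stopband_rejected(self):
        # 50 Hz through alpha: residual RMS < 1% of input RMS
        n = 8192
        x = _sine(50.0, n)
        out = bandpass(TimeSeriesSet(x[None, :], FS), ALPHA)
        assert np.sqrt(np.mean(out.values**2)) < 0.01 * np.sqrt(np.mean(x**2))

    def test_dc_rejected(self):
        n = 8192
        x = np.full(n, 3.7)
        out = bandpass(TimeSeriesSet(x[None, :], FS), ALPHA)
        assert np.sqrt(np.mean(out.values**2)) < 1e-6 * 3.7

    def test_band_above_nyquist_rejected(self):
        ts = TimeSeriesSet(np.random.default_rng(0).standard_normal((1, 8192)), 100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(ts, FrequencyBand("high", 30, 60))

    def test_too_few_samples_rejected(self):
        ts = TimeSeriesSet(np.random.default_rng(0).standard_normal((1, 200)), FS)
        with pytest.raises(ValueError, match="too few"):
            bandpass(ts, ALPHA)

    def test_shape_preserved(self):
        ts = TimeSeriesSet(np.random.default_rng(0).standard_normal((3, 8192)), FS)
        out = bandpass(ts, BETA)
        assert out.values.shape == (3, 8192)


class TestBinCounts:
    @pytest.mark.parametrize("t,expected", [(100, 50), (149646, 74825), (15, 10)])
    def test_printed_rule(self, t, expected):
        assert default_bin_count(t) == expected

    def test_below_10_rejected(self):
        with pytest.raises(ValueError):
            default_bin_count(9)

    def test_practical_rule(self):
        # 5 * round(sqrt(t/10)); sqrt(2000) = 44.7 -> 45 -> 225
        assert practical_bin_count(20000) == 225
        assert practical_bin_count(10) == 5

    def test_config_resolution(self):
        assert MIConfig(n_bins=7).resolve_bins(1000) == 7
        assert MIConfig(n_bins="paper").resolve_bins(100) == 50
        assert MIConfig(n_bins="sqrt").resolve_bins(20000) == 225

    def test_invalid_bins(self):
        with pytest.raises(ValueError):
            MIConfig(n_bins=1)
        with pytest.raises(ValueError):
            MIConfig(n_bins="magic")


class TestMutualInformation:
    def test_independent_hand_case_exact_zero(self):
        # joint histogram is exactly the product of the marginals
        x = np.array([1.0, 1.0, 2.0, 2.0])
        y = np.array([1.0, 2.0, 1.0, 2.0])
        assert mutual_information(x, y, 2) == 0.0

    def test_perfect_dependence_ln2(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert mutual_information(x, x, 2) == pytest.approx(math.log(2), abs=1e-12)

    def test_independent_long_samples_below_surrogate_threshold(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(20000)
        y = rng.standard_normal(20000)
        mi = mutual_information(x, y, 64)
        null = [
            mutual_information(x, rng.permutation(y), 64) for _ in range(100)
        ]
        assert mi < np.quantile(null, 0.95)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            mutual_information(np.arange(4.0), np.arange(5.0), 2)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mutual_information(np.ones(10), np.arange(10.0), 2)

    @settings(max_examples=25, deadline=None)
    @given(
        xy=hnp.arrays(
            float,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=2).map(
                lambda s: (2, 30)
            ),
            elements=st.floats(-100, 100, allow_nan=False),
        ),
        n_bins=st.integers(2, 12),
    )
    def test_symmetry_and_nonnegativity(self, xy, n_bins):
        x, y = xy
        if x.max() == x.min() or y.max() == y.min():
            return
        mi_xy = mutual_information(x, y, n_bins)
        mi_yx = mutual_information(y, x, n_bins)
        assert mi_xy == mi_yx
        assert mi_xy >= -1e-12

    @settings(max_examples=25, deadline=None)
    @given(
        xy=hnp.arrays(
            float, (2, 64), elements=st.floats(-50, 50, allow_nan=False)
        ),
        n_bins=st.integers(2, 8),
    )
    def test_self_mi_dominates(self, xy, n_bins):
        # data-processing sanity: MI(x, x) >= MI(x, y) under the same binning
        x, y = xy
        if x.max() == x.min() or y.max() == y.min():
            return
        assert (
            mutual_information(x, x, n_bins)
            >= mutual_information(x, y, n_bins) - 1e-12
        )


class TestBlockSurrogate:
    def test_single_block_is_identity(self, rng):
        ts = TimeSeriesSet(rng.standard_normal((2, 500)), FS)
        cfg = MIConfig(surrogate_block_length=500, seed=0)
        out = block_permutation_surrogate(ts, cfg)
        np.testing.assert_array_equal(out.values, ts.values)

    def test_multiset_preserved(self, rng):
        ts = TimeSeriesSet(rng.standard_normal((3, 1000)), FS)
        cfg = MIConfig(surrogate_block_length=64, seed=1)
        out = block_permutation_surrogate(ts, cfg)
        for ch in range(3):
            np.testing.assert_array_equal(
                np.sort(out.values[ch]), np.sort(ts.values[ch])
            )

    def test_trailing_remainder_kept_in_place(self, rng):
        ts = TimeSeriesSet(rng.standard_normal((1, 1030)), FS)
        cfg = MIConfig(surrogate_block_length=1018, seed=2)
        out = block_permutation_surrogate(ts, cfg)
        np.testing.assert_array_equal(out.values[0, 1018:], ts.values[0, 1018:])

    def test_ar1_autocorrelation_preserved(self):
        # within-block structure survives: lag-1 autocorrelation within 0.05
        rng = np.random.default_rng(3)
        n = 20000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = 0.9 * x[i - 1] + eps[i]
        ts = TimeSeriesSet(x[None, :], FS)
        out = block_permutation_surrogate(ts, MIConfig(surrogate_block_length=1018, seed=4))

        def acf1(v):
            v = v - v.mean()
            return float(np.dot(v[:-1], v[1:]) / np.dot(v, v))

        assert abs(acf1(out.values[0]) - acf1(x)) < 0.05

    def test_block_longer_than_series_rejected(self, rng):
        ts = TimeSeriesSet(rng.standard_normal((1, 100)), FS)
        with pytest.raises(ValueError):
            block_permutation_surrogate(ts, MIConfig(surrogate_block_length=200))

    def test_seed_determinism(self, rng):
        ts = TimeSeriesSet(rng.standard_normal((2, 1000)), FS)
        cfg = MIConfig(surrogate_block_length=100, seed=5)
        a = block_permutation_surrogate(ts, cfg)
        b = block_permutation_surrogate(ts, cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_same_permutation_mode(self, rng):
        base = rng.standard_normal(1000)
        ts = TimeSeriesSet(np.vstack([base, base]), FS)
        cfg = MIConfig(surrogate_block_length=100, same_permutation=True, seed=6)
        out = block_permutation_surrogate(ts, cfg)
        np.testing.assert_array_equal(out.values[0], out.values[1])


class TestThresholdAndNormalize:
    def test_threshold_arithmetic(self):
        MI = np.array([[0.0, 0.5], [0.5, 0.0]])
        MI_rand = np.array([[0.0, 0.2], [0.2, 0.0]])
        W = threshold_weights(MI, MI_rand)
        assert W[0, 1] == pytest.approx(0.3)

    def test_equal_matrices_give_all_zero(self, rng):
        MI = rng.random((5, 5))
        MI = (MI + MI.T) / 2
        W = threshold_weights(MI, MI)
        assert np.all(W == 0)

    def test_threshold_nonnegative_symmetric(self, rng):
        MI = rng.random((6, 6))
        MI = (MI + MI.T) / 2
        R = rng.random((6, 6))
        R = (R + R.T) / 2
        W = threshold_weights(MI, R)
        assert np.all(W >= 0)
        np.testing.assert_array_equal(W, W.T)
        assert np.all(np.diag(W) == 0)

    def test_normalize_affine_endpoints(self):
        W = np.array([[0.0, 0.15], [0.3, 0.0]])
        M = normalize01(W)
        assert sorted(np.unique(M)) == [0.0, 0.5, 1.0]

    def test_normalize_identity_on_01_range(self):
        W = np.array([[0.0, 0.4], [1.0, 0.3]])
        np.testing.assert_allclose(normalize01(W), W)

    def test_normalize_contract(self, rng):
        W = rng.random((8, 8))
        M = normalize01(W)
        assert M.min() == 0.0
        assert M.max() == 1.0

    def test_constant_w_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize01(np.full((3, 3), 0.2))


class TestMatricesAndPipeline:
    @pytest.fixture
    def band_series(self):
        from freqlayer.synthetic_signals import SyntheticSignalConfig, generate_signals

        cfg = SyntheticSignalConfig(
            n_channels=3, bands=(ALPHA, BETA), n_samples=6000, noise_sd=0.1, seed=17
        )
        ts, _ = generate_signals(cfg)
        return [bandpass(ts, ALPHA), bandpass(ts, BETA)]

    def test_mi_matrix_shape_and_symmetry(self, band_series):
        cfg = MIConfig(n_bins=16, seed=0)
        MI = mi_matrix(band_series, cfg)
        assert MI.shape == (6, 6)
        np.testing.assert_array_equal(MI, MI.T)
        assert np.all(np.diag(MI) == 0)
        assert np.all(MI >= -1e-12)

    def test_surrogate_matrix_deterministic(self, band_series):
        cfg = MIConfig(n_bins=16, surrogate_block_length=500, seed=3)
        A = surrogate_mi_matrix(band_series, cfg)
        B = surrogate_mi_matrix(band_series, cfg)
        np.testing.assert_array_equal(A, B)

    def test_surrogate_averaging_reduces_spread(self, band_series):
        one = MIConfig(n_bins=16, surrogate_block_length=500, n_surrogates=1, seed=3)
        many = MIConfig(n_bins=16, surrogate_block_length=500, n_surrogates=6, seed=3)
        A = surrogate_mi_matrix(band_series, one)
        B = surrogate_mi_matrix(band_series, many)
        assert A.shape == B.shape
        # averaged entries stay within the plausible single-draw range
        assert B.max() <= A.max() * 3

    def test_pipeline_determinism_and_slicing(self):
        from freqlayer.synthetic_signals import SyntheticSignalConfig, generate_signals

        cfg = SyntheticSignalConfig(
            n_channels=4, bands=(ALPHA, BETA), n_samples=6000, noise_sd=0.1, seed=23
        )
        ts, _ = generate_signals(cfg)
        mic = MIConfig(n_bins=16, surrogate_block_length=500, seed=5)
        net1, meta1 = build_frequency_network(ts, [ALPHA, BETA], mic)
        net2, _ = build_frequency_network(ts, [ALPHA, BETA], mic)
        assert net1.n_layers == 2
        assert net1.layer_sizes == [4, 4]
        for lg1, lg2 in zip(net1.layers, net2.layers):
            np.testing.assert_array_equal(lg1.weights, lg2.weights)
        np.testing.assert_array_equal(
            net1.couplings[(0, 1)].block, net2.couplings[(0, 1)].block
        )
        assert meta1["n_bins"] == 16
        assert meta1["bands"] == ["alpha", "beta"]

    def test_unfiltered_monolayer_path(self):
        from freqlayer.synthetic_signals import SyntheticSignalConfig, generate_signals

        cfg = SyntheticSignalConfig(
            n_channels=3, bands=(ALPHA,), n_samples=3000, noise_sd=0.2, seed=31
        )
        ts, _ = generate_signals(cfg)
        net, meta = build_frequency_network(
            ts, None, MIConfig(n_bins=16, surrogate_block_length=300, seed=1)
        )
        assert net.n_layers == 1
        assert meta["bands"] == ["unfiltered"]
        assert not net.couplings


class TestMultiplexRestriction:
    def _net(self, rng):
        from freqlayer.network import InterlayerCoupling, LayerGraph, SupraNetwork

        W = rng.random((4, 4))
        W = np.triu(W, 1)
        W = W + W.T
        B = rng.random((4, 4))
        return SupraNetwork(
            [LayerGraph(W), LayerGraph(W.copy())],
            {(0, 1): InterlayerCoupling(B, structure="full")},
        )

    def test_off_diagonal_zeroed(self, rng):
        net = self._net(rng)
        mp = restrict_to_multiplex(net)
        blk = mp.couplings[(0, 1)].block
        assert np.count_nonzero(blk) <= 4
        np.testing.assert_array_equal(np.diag(blk), np.diag(net.couplings[(0, 1)].block))

    def test_idempotent(self, rng):
        net = self._net(rng)
        once = restrict_to_multiplex(net)
        twice = restrict_to_multiplex(once)
        np.testing.assert_array_equal(
            once.couplings[(0, 1)].block, twice.couplings[(0, 1)].block
        )

    def test_interlayer_strength_dominated(self, rng):
        net = self._net(rng)
        mp = restrict_to_multiplex(net)
        assert mp.couplings[(0, 1)].strength <= net.couplings[(0, 1)].strength

    def test_layers_untouched(self, rng):
        net = self._net(rng)
        mp = restrict_to_multiplex(net)
        for a, b in zip(net.layers, mp.layers):
            np.testing.assert_array_equal(a.weights, b.weights)
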