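"""Morlet decomposition and event-related spectral perturbation."""

import numpy as np
import pytest

from sedyn.bands import DEFAULT_BANDS
from sedyn.ersp import (ERSPMap, TFCoefficients, band_series, cycles_for_freqs,
                        default_freq_grid, ersp, morlet_atom, tf_decompose,
                        topo_snapshot)
from sedyn.preprocess import EpochSet


def make_epochs(data, fs=100.0, window=None, labels=None):
    data = np.asarray(data, dtype=float)
    if window is None:
        window = (0.0, data.shape[2] / fs)
    labels = labels or [f"CH{i}" for i in range(data.shape[1])]
    return EpochSet(data, fs, window, "LOC",
                    np.zeros(data.shape[0]), labels)


def make_tf(coeffs, fs=100.0):
    """TFCoefficients from a raw trials x channels x freqs x times array."""
    coeffs = np.asarray(coeffs, dtype=complex)
    nf, nt = coeffs.shape[2], coeffs.shape[3]
    return TFCoefficients(coeffs=coeffs, freqs_hz=np.arange(1.0, nf + 1),
                          times_s=np.arange(nt) / fs,
                          cycles=np.full(nf, 3.0),
                          valid=np.ones((nf, nt), dtype=bool),
                          channel_labels=[f"CH{i}" for i in
                                          range(coeffs.shape[1])])


class TestTFDecompose:
    def test_pure_tone_amplitude_and_quadratic_scaling(self):
        fs, n = 100.0, 4000
        t = np.arange(n) / fs
        a1 = np.cos(2 * np.pi * 10 * t)
        ep = make_epochs(np.stack([a1, 2 * a1])[:, None, :], fs)
        tf = tf_decompose(ep, freqs=np.array([10.0]))
        mid = slice(1000, 3000)
        p1 = np.abs(tf.coeffs[0, 0, 0, mid]) ** 2
        p2 = np.abs(tf.coeffs[1, 0, 0, mid]) ** 2
        np.testing.assert_allclose(np.sqrt(p1), 1.0, rtol=1e-3)
        np.testing.assert_allclose(p2 / p1, 4.0, rtol=1e-12)

    def test_chirp_ridge_tracks_instantaneous_frequency(self):
        fs, dur = 100.0, 60.0
        t = np.arange(0, dur, 1 / fs)
        f0, f1 = 5.0, 15.0
        inst_f = f0 + (f1 - f0) * t / dur
        phase = 2 * np.pi * np.cumsum(inst_f) / fs
        ep = make_epochs(np.cos(phase)[None, None, :], fs)
        tf = tf_decompose(ep, freqs=np.arange(3.0, 18.0, 0.25))
        mag = np.abs(tf.coeffs[0, 0])
        sel = slice(500, 5500)  # clear of edges
        ridge = tf.freqs_hz[np.argmax(mag[:, sel], axis=0)]
        assert np.max(np.abs(ridge - inst_f[sel])) <= 1.0

    def test_fft_convolution_equals_direct_inner_product(self, rng):
        fs, n = 100.0, 600
        x = rng.normal(size=n)
        ep = make_epochs(x[None, None, :], fs)
        freqs = np.array([4.0, 9.5, 20.0])
        tf = tf_decompose(ep, freqs)
        cycles = cycles_for_freqs(freqs, 3.0, 0.5)
        for fi, (f, cyc) in enumerate(zip(freqs, cycles)):
            atom = morlet_atom(f, cyc, fs)
            half = (atom.size - 1) // 2
            for ti in (half + 3, n // 2, n - half - 4):
                seg = x[ti - half: ti + half + 1]
                # convolving with the conj-symmetric atom equals the inner
                # product of the segment with the conjugate atom
                direct = np.sum(seg * np.conj(atom))
                got = tf.coeffs[0, 0, fi, ti]
                assert abs(got - direct) <= 1e-8 * max(abs(direct), 1e-12)

    def test_edge_samples_flagged_invalid(self):
        ep = make_epochs(np.zeros((1, 1, 500)), 100.0)
        tf = tf_decompose(ep, freqs=np.array([5.0]))
        atom = morlet_atom(5.0, 3.0, 100.0)
        half = (atom.size - 1) // 2
        assert not tf.valid[0, :half].any()
        assert tf.valid[0, half:500 - half].all()

    def test_dc_frequency_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 500)))
        with pytest.raises(ValueError, match="positive"):
            tf_decompose(ep, freqs=np.array([0.0, 5.0]))

    def test_epoch_shorter_than_wavelet_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 50)), 100.0)
        with pytest.raises(ValueError, match="shorter than the wavelet"):
            tf_decompose(ep, freqs=np.array([0.5]))


class TestERSP:
    def test_triple_loop_oracle_on_random_inputs(self, rng):
        for _ in range(5):
            n_k, n_c, n_f, n_t = rng.integers(1, 4), 2, 3, 8
            coeffs = rng.normal(size=(n_k, n_c, n_f, n_t)) \
                + 1j * rng.normal(size=(n_k, n_c, n_f, n_t))
            emap = ersp(make_tf(coeffs))
            expected = np.empty((n_c, n_f, n_t))
            for c in range(n_c):
                for f in range(n_f):
                    for t in range(n_t):
                        acc = 0.0
                        for k in range(n_k):
                            acc += abs(coeffs[k, c, f, t]) ** 2
                        expected[c, f, t] = 10 * np.log10(acc / n_k)
            np.testing.assert_allclose(emap.power_db, expected, atol=1e-12)

    def test_identical_trials_equal_single_trial_power(self, rng):
        single = rng.normal(size=(1, 2, 3, 6)) + 1j * rng.normal(size=(1, 2, 3, 6))
        stacked = np.repeat(single, 7, axis=0)
        np.testing.assert_allclose(ersp(make_tf(stacked)).power_db,
                                   ersp(make_tf(single)).power_db, atol=1e-12)

    def test_baseline_equal_to_signal_gives_zero_db(self, rng):
        coeffs = rng.normal(size=(3, 2, 4, 10)) + 1j * rng.normal(size=(3, 2, 4, 10))
        tf = make_tf(coeffs)
        # constant-over-time power so the time-averaged baseline matches
        const = np.abs(coeffs).mean() * np.ones_like(coeffs)
        tfc = make_tf(const)
        out = ersp(tfc, baseline=tfc)
        assert np.nanmax(np.abs(out.power_db)) < 1e-9

    def test_two_trials_hand_evaluated(self):
        p = 2.5
        coeffs = np.zeros((2, 1, 1, 1), dtype=complex)
        coeffs[0] = np.sqrt(p)
        coeffs[1] = np.sqrt(3 * p) * 1j
        emap = ersp(make_tf(coeffs))
        assert emap.power_db[0, 0, 0] == pytest.approx(10 * np.log10(2 * p),
                                                       rel=1e-12)

    def test_db_additivity_under_gain(self, rng):
        coeffs = rng.normal(size=(4, 1, 2, 5)) + 1j * rng.normal(size=(4, 1, 2, 5))
        g = 3.0
        base = ersp(make_tf(coeffs)).power_db
        scaled = ersp(make_tf(g * coeffs)).power_db
        np.testing.assert_allclose(scaled - base, 20 * np.log10(g), atol=1e-10)

    def test_trial_permutation_invariance(self, rng):
        coeffs = rng.normal(size=(5, 1, 2, 4)) + 1j * rng.normal(size=(5, 1, 2, 4))
        perm = rng.permutation(5)
        np.testing.assert_allclose(ersp(make_tf(coeffs)).power_db,
                                   ersp(make_tf(coeffs[perm])).power_db,
                                   atol=1e-12)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError, match="no trials"):
            ersp(make_tf(np.zeros((0, 1, 1, 1))))


def constant_map(value_db, n_ch=6, fs=100.0, window=(-60.0, 180.0)):
    freqs = default_freq_grid()
    times = window[0] + np.arange(int((window[1] - window[0]) * fs)) / fs
    power = np.full((n_ch, freqs.size, times.size), float(value_db))
    return ERSPMap(power_db=power, freqs_hz=freqs, times_s=times, n_trials=1,
                   channel_labels=["AF3", "AF4", "F1", "F2", "Fz", "POz"][:n_ch])


class TestBandSeriesAndTopo:
    def test_constant_map_gives_constant_series(self):
        emap = constant_map(-7.5)
        series = band_series(emap)
        assert (np.abs(series.to_numpy() + 7.5) < 1e-12).all()

    def test_power_confined_to_upper_alpha_bin(self):
        emap = constant_map(0.0)
        fi = np.argmin(np.abs(emap.freqs_hz - 13.5))
        emap.power_db[:, fi, :] = 30.0
        series = band_series(emap)
        assert series["upper_alpha"].iloc[0] > 3.0
        assert abs(series["delta"].iloc[0]) < 1e-12
        assert abs(series["theta"].iloc[0]) < 1e-12

    def test_band_without_bins_rejected(self):
        from sedyn.bands import Band
        emap = constant_map(0.0)
        with pytest.raises(ValueError, match="no grid frequencies"):
            band_series(emap, bands={"x": Band("x", 45.0, 48.0)})

    def test_uniform_map_gives_equal_channels(self):
        topo = topo_snapshot(constant_map(4.0), "upper_alpha", "post")
        assert (topo == 4.0).all()

    def test_transition_interval_sample_count(self):
        emap = constant_map(0.0)
        from sedyn.ersp import _interval_mask
        assert _interval_mask(emap.times_s, "transition").sum() == 1000

    def test_pre_interval_selects_first_ten_seconds(self):
        emap = constant_map(1.0)
        t = emap.times_s
        emap.power_db[:, :, t < t[0] + 10.0] = 9.0
        topo = topo_snapshot(emap, "upper_alpha", "pre")
        assert (topo == 9.0).all()
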