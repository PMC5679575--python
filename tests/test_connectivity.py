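"""Event-related phase coherence and fronto-parietal phase aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from sedyn.bands import DEFAULT_BANDS, DEFAULT_CHANNELS, FRONTAL_COH, PARIETAL
from sedyn.connectivity import (erpcoh, group_pairs, phase_difference,
                                smooth_blocks)
from sedyn.ersp import tf_decompose
from sedyn.preprocess import EpochSet


def tone_epochs(delays, fs=100.0, n=3000, f=10.0, labels=("a", "b")):
    """Single-trial two-channel epochs of a tone with per-channel delays."""
    t = np.arange(n) / fs
    data = np.stack([np.cos(2 * np.pi * f * (t - d)) for d in delays])
    return EpochSet(data[None], fs, (0.0, n / fs), "LOC", [0.0], list(labels))


class TestERPCOH:
    def test_self_coherence_is_unit_magnitude_zero_phase(self, rng):
        coeffs = rng.normal(size=(6, 4, 20)) + 1j * rng.normal(size=(6, 4, 20))
        series = erpcoh(coeffs, coeffs)
        np.testing.assert_allclose(series.magnitude, 1.0, atol=1e-12)
        np.testing.assert_allclose(phase_difference(series), 0.0, atol=1e-9)

    def test_pure_delay_gives_minus_ninety_degrees(self):
        # first channel lags by 25 ms at 10 Hz -> phase(a)-phase(b) = -90 deg
        ep = tone_epochs([0.025, 0.0])
        tf = tf_decompose(ep, freqs=np.array([10.0]))
        series = erpcoh(tf.channel("a"), tf.channel("b"),
                        tf.freqs_hz, tf.times_s)
        interior = phase_difference(series)[0, 500:2500]
        np.testing.assert_allclose(interior, -90.0, atol=0.5)

    def test_independent_random_phases_concentrate_near_zero(self, rng):
        n = 1000
        pa = np.exp(1j * rng.uniform(0, 2 * np.pi, size=(n, 4, 10)))
        pb = np.exp(1j * rng.uniform(0, 2 * np.pi, size=(n, 4, 10)))
        series = erpcoh(pa, pb)
        assert np.max(series.magnitude) < 0.08

    def test_zero_coefficients_skipped_and_counted(self):
        fa = np.array([[[1.0 + 0j, 0.0]]])
        fb = np.array([[[1.0 + 0j, 1.0 + 0j]]])
        series = erpcoh(fa, fb)
        assert series.n_skipped == 1
        assert series.erpcoh[0, 1] == 0.0

    @given(hnp.arrays(np.complex128, (5, 2, 7),
                      elements=st.complex_numbers(max_magnitude=1e6,
                                                  allow_nan=False,
                                                  allow_infinity=False)),
           hnp.arrays(np.complex128, (5, 2, 7),
                      elements=st.complex_numbers(max_magnitude=1e6,
                                                  allow_nan=False,
                                                  allow_infinity=False)))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_magnitude_bounded_by_one(self, fa, fb):
        series = erpcoh(fa, fb)
        assert np.all(series.magnitude <= 1.0 + 1e-12)

    def test_magnitude_bound_on_bulk_fuzz(self, rng):
        # 10^4 random coefficient pairs
        fa = rng.normal(size=(10, 10, 100)) + 1j * rng.normal(size=(10, 10, 100))
        fb = rng.normal(size=(10, 10, 100)) + 1j * rng.normal(size=(10, 10, 100))
        assert np.all(erpcoh(fa, fb).magnitude <= 1.0 + 1e-12)

    def test_invariant_under_common_per_trial_phase_rotation(self, rng):
        fa = rng.normal(size=(8, 3, 12)) + 1j * rng.normal(size=(8, 3, 12))
        fb = rng.normal(size=(8, 3, 12)) + 1j * rng.normal(size=(8, 3, 12))
        rot = np.exp(1j * rng.uniform(0, 2 * np.pi, 8))[:, None, None]
        m0 = erpcoh(fa, fb).magnitude
        m1 = erpcoh(fa * rot, fb * rot).magnitude
        np.testing.assert_allclose(m0, m1, atol=1e-12)

    def test_triple_loop_oracle(self, rng):
        fa = rng.normal(size=(3, 2, 4)) + 1j * rng.normal(size=(3, 2, 4))
        fb = rng.normal(size=(3, 2, 4)) + 1j * rng.normal(size=(3, 2, 4))
        got = erpcoh(fa, fb).erpcoh
        for f in range(2):
            for t in range(4):
                acc = 0.0
                for k in range(3):
                    z = fa[k, f, t] * np.conj(fb[k, f, t])
                    acc += z / abs(z)
                assert abs(got[f, t] - acc / 3) <= 1e-12


class TestPhaseDifference:
    def test_branch_conventions(self):
        z = np.array([1j, -1.0 + 0j, 1.0 + 0j, -1j])
        np.testing.assert_allclose(phase_difference(z), [90.0, 180.0, 0.0, -90.0])

    def test_zero_magnitude_is_nan(self):
        assert np.isnan(phase_difference(np.array([0.0 + 0j])))[0]

    def test_elementwise_oracle_on_random_phasors(self, rng):
        z = rng.normal(size=50) + 1j * rng.normal(size=50)
        expected = np.degrees(np.arctan2(z.imag, z.real))
        np.testing.assert_allclose(phase_difference(z), expected, atol=1e-12)


class TestSmoothBlocks:
    def test_block_count_arithmetic(self):
        times = np.arange(0, 240.0, 0.5)
        values = np.exp(1j * np.zeros(times.size))
        out = smooth_blocks(values, times, block_s=20.0)
        assert out.block_centers_s.size == 12

    def test_constant_phase_is_identity_on_phase(self):
        times = np.arange(0, 200.0, 0.1)
        values = 0.7 * np.exp(1j * np.deg2rad(33.0)) * np.ones(times.size)
        out = smooth_blocks(values, times)
        np.testing.assert_allclose(out.phase_deg, 33.0, atol=1e-9)

    def test_phase_step_transition_confined_to_sg_window(self):
        # direct evaluation of the block + Savitzky-Golay pipeline: the
        # plateaus are preserved outside the SG support of the step and the
        # cubic's ringing near the step stays small
        times = np.arange(0, 400.0, 0.1)
        phase = np.where(times < 200.0, 0.0, np.pi / 2)
        out = smooth_blocks(np.exp(1j * phase), times)
        ph = out.phase_deg
        step_block = 10  # step at 200 s, 20 s blocks
        np.testing.assert_allclose(ph[: step_block - 2], 0.0, atol=1e-9)
        np.testing.assert_allclose(ph[step_block + 2:], 90.0, atol=1e-9)
        assert np.all(ph > -5.0) and np.all(ph < 95.0)

    def test_too_few_blocks_skips_sg_with_warning(self):
        times = np.arange(0, 60.0, 0.5)
        with pytest.warns(UserWarning, match="Savitzky-Golay"):
            out = smooth_blocks(np.ones(times.size, dtype=complex), times,
                                sg_window_blocks=5)
        assert out.block_centers_s.size == 3


class TestGroupPairs:
    def synth_tf(self, delays_by_channel, fs=100.0, n=3000, f=13.5):
        t = np.arange(n) / fs
        data = np.stack([np.cos(2 * np.pi * f * (t - delays_by_channel[ch]))
                         for ch in DEFAULT_CHANNELS])
        ep = EpochSet(data[None], fs, (0.0, n / fs), "LOC", [0.0],
                      list(DEFAULT_CHANNELS))
        return tf_decompose(ep, freqs=np.arange(12.0, 15.1, 0.5))

    def test_identical_channels_give_zero_phase(self):
        tf = self.synth_tf({ch: 0.0 for ch in DEFAULT_CHANNELS})
        df = group_pairs(tf, bands={"upper_alpha": DEFAULT_BANDS["upper_alpha"]})
        ph = df["upper_alpha_phase_deg"].to_numpy()[500:2500]
        np.testing.assert_allclose(ph, 0.0, atol=1e-6)

    def test_common_parietal_delay_equals_single_pair_phase(self):
        tau = 0.01
        delays = {ch: (tau if ch in PARIETAL else 0.0)
                  for ch in DEFAULT_CHANNELS}
        tf = self.synth_tf(delays)
        df = group_pairs(tf, bands={"upper_alpha": DEFAULT_BANDS["upper_alpha"]})
        single = erpcoh(tf.channel("Fz"), tf.channel("POz"),
                        tf.freqs_hz, tf.times_s)
        agg = df["upper_alpha_phase_deg"].to_numpy()[500:2500]
        # aggregate phase: average complex over band bins of the single pair
        sel = DEFAULT_BANDS["upper_alpha"].contains(tf.freqs_hz)
        ref = phase_difference(single.erpcoh[sel].mean(axis=0))[500:2500]
        np.testing.assert_allclose(agg, ref, atol=1e-8)

    def test_missing_channel_reported(self):
        tf = self.synth_tf({ch: 0.0 for ch in DEFAULT_CHANNELS})
        tf.channel_labels[tf.channel_labels.index("Oz")] = "XX"
        with pytest.raises(ValueError, match="Oz"):
            group_pairs(tf)
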