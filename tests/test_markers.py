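"""Behavioral LOC/ROC marker detection and response scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedyn.markers import (SessionLog, assign_responses, detect_transitions,
                           reaction_curve)
from sedyn.synthetic import generate_response_sequence


def brute_force_markers(hits, min_hits=5, min_misses=10):
    """Independent scan: every (>=5-hit, >=10-miss) maximal-run adjacency.

    For each index where a maximal miss-run starts, scan its length and the
    length of the immediately preceding maximal hit-run (and symmetrically
    for ROC), then keep an alternating subsequence starting at the first
    LOC.
    """
    hits = list(hits)
    n = len(hits)
    raw = []
    for i in range(1, n):
        if hits[i] == hits[i - 1]:
            continue  # not a run boundary
        j = i
        while j < n and hits[j] == hits[i]:
            j += 1
        run_len = j - i
        k = i - 1
        while k >= 0 and hits[k] == hits[i - 1]:
            k -= 1
        prev_len = i - 1 - k
        if not hits[i] and run_len >= min_misses and prev_len >= min_hits:
            raw.append(("LOC", i))
        if hits[i] and run_len >= min_hits and prev_len >= min_misses:
            raw.append(("ROC", i))
    out = []
    expect = "LOC"
    for kind, idx in raw:
        if kind == expect:
            out.append((kind, idx))
            expect = "ROC" if expect == "LOC" else "LOC"
    return out


class TestAssignResponses:
    def test_basic_mapping_and_latencies(self):
        log = SessionLog(stimuli=[1.0, 11.0, 21.0], responses=[1.5, 11.4])
        scored = assign_responses(log)
        assert scored.hits.tolist() == [True, True, False]
        np.testing.assert_allclose(scored.latencies[:2], [0.5, 0.4])
        assert np.isnan(scored.latencies[2])

    def test_first_press_wins_in_interval(self):
        log = SessionLog(stimuli=[0.0, 10.0], responses=[0.4, 0.9])
        scored = assign_responses(log)
        assert scored.hits.tolist() == [True, False]
        assert scored.latencies[0] == pytest.approx(0.4)

    def test_empty_responses_all_miss(self):
        log = SessionLog(stimuli=np.arange(5.0, 55.0, 10.0), responses=[])
        assert not assign_responses(log).hits.any()

    def test_press_before_first_stimulus_ignored(self, caplog):
        log = SessionLog(stimuli=[10.0, 20.0], responses=[5.0, 10.5])
        with caplog.at_level("WARNING", logger="sedyn.markers"):
            scored = assign_responses(log)
        assert scored.hits.tolist() == [True, False]
        assert "before the first stimulus" in caplog.text


class TestDetectTransitions:
    def test_minimal_qualifying_sequence(self):
        pattern = [True] * 5 + [False] * 10 + [True] * 5
        stimuli = 10.0 * np.arange(1, 21)
        m = detect_transitions(pattern, stimuli)
        assert m.kinds == ["LOC", "ROC"]
        assert m.stimulus_indices.tolist() == [5, 15]
        np.testing.assert_allclose(m.times, [60.0, 160.0])

    def test_too_few_preceding_hits_yields_nothing(self):
        pattern = [True] * 4 + [False] * 10 + [True] * 5
        m = detect_transitions(pattern, 10.0 * np.arange(1, 20))
        assert len(m) == 0

    def test_insufficient_stimuli_error(self):
        with pytest.raises(ValueError, match="insufficient stimuli"):
            detect_transitions([True] * 14, 10.0 * np.arange(14))

    @pytest.mark.parametrize("p_hit", [0.3, 0.5, 0.8])
    def test_matches_brute_force_on_random_sequences(self, p_hit):
        # both iid sequences and blocky state-like sequences, many seeds
        for seed in range(50):
            rng = np.random.default_rng(seed + int(p_hit * 1000))
            hits = rng.random(200) < p_hit
            stimuli = np.cumsum(rng.uniform(9, 11, 200))
            m = detect_transitions(hits, stimuli)
            expected = brute_force_markers(hits)
            assert list(zip(m.kinds, m.stimulus_indices.tolist())) == expected

    def test_matches_brute_force_on_blocky_sequences(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            hits = np.concatenate([
                np.full(rng.integers(1, 20), bool(v % 2 == 0))
                for v in range(rng.integers(10, 30))
            ])[:200]
            if hits.size < 15:
                continue
            stimuli = 10.0 * np.arange(1, hits.size + 1)
            m = detect_transitions(hits, stimuli)
            assert (list(zip(m.kinds, m.stimulus_indices.tolist()))
                    == brute_force_markers(hits))

    @given(st.lists(st.booleans(), min_size=15, max_size=120))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_alternation_property(self, pattern):
        m = detect_transitions(pattern, 10.0 * np.arange(1, len(pattern) + 1))
        kinds = m.kinds
        assert all(k1 != k2 for k1, k2 in zip(kinds, kinds[1:]))
        if kinds:
            assert kinds[0] == "LOC"
        assert np.all(np.diff(m.times) > 0) if len(m) > 1 else True

    def test_extra_hits_in_long_hit_run_leave_marker_times_unchanged(self):
        base = [True] * 5 + [False] * 10 + [True] * 5
        stimuli = 10.0 * np.arange(1, 21)
        m0 = detect_transitions(base, stimuli)
        # prepend extra hits at earlier onsets: the >=5-hit run only grows
        extra = [True] * 3 + base
        stimuli_ext = np.concatenate([[-20.0, -10.0, 0.0], stimuli])
        m1 = detect_transitions(extra, stimuli_ext)
        np.testing.assert_allclose(m0.times, m1.times)
        assert m0.kinds == m1.kinds


class TestReactionCurve:
    def test_constant_latency_gives_flat_curve(self):
        stimuli = 10.0 * np.arange(1, 21)
        log = SessionLog(stimuli=stimuli, responses=stimuli + 0.5)
        curve = reaction_curve(log, smoothing_window_s=40.0)
        np.testing.assert_allclose(curve.to_numpy(), 0.5)

    def test_all_misses_gives_empty_curve(self):
        log = SessionLog(stimuli=10.0 * np.arange(1, 21), responses=[])
        curve = reaction_curve(log)
        assert curve.isna().all()

    def test_smoothed_curve_tracks_configured_median(self):
        # lognormal latencies: smoothed curve near the configured median in
        # conscious segments, Monte-Carlo over seeds
        median = 0.6
        devs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            stimuli = np.cumsum(rng.uniform(9, 11, 100))
            lat = rng.lognormal(np.log(median), 0.35, 100)
            log = SessionLog(stimuli=stimuli, responses=stimuli + lat)
            curve = reaction_curve(log, smoothing_window_s=120.0)
            devs.append(curve.mean() - np.exp(np.log(median) + 0.35 ** 2 / 2))
        # mean latency = exp(mu + sigma^2/2); 2 SE across seeds
        assert abs(np.mean(devs)) < 2 * np.std(devs, ddof=1) / np.sqrt(20) + 0.02


class TestGenerateResponseSequence:
    def test_all_hits(self):
        log = generate_response_sequence([True] * 15)
        assert log.stimuli.size == 15 and log.responses.size == 15

    def test_minimal_loc_sequence_by_construction(self):
        log = generate_response_sequence([True] * 5 + [False] * 10)
        scored = assign_responses(log)
        assert scored.hits.tolist() == [True] * 5 + [False] * 10

    def test_alternating_pattern_has_no_long_runs(self):
        pattern = [bool(i % 2) for i in range(40)]
        scored = assign_responses(generate_response_sequence(pattern))
        h = scored.hits
        run, longest_hit, longest_miss = 1, 0, 0
        for i in range(1, h.size):
            run = run + 1 if h[i] == h[i - 1] else 1
            if h[i]:
                longest_hit = max(longest_hit, run)
            else:
                longest_miss = max(longest_miss, run)
        assert longest_hit < 5 and longest_miss < 10
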