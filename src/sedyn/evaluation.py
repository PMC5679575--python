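"""Known-answer evaluation of the full analysis chain on synthetic sessions.

These routines generate sessions with the closed-loop generator, run the
standard analysis (marker detection, epoching, ERSP, fronto-parietal phase,
Beer-Lambert hemodynamics) and score the results against the generator's
ground truth: marker recovery error, upper-alpha power change across
transitions, anteriorization of the post-LOC topography, localization of
the injected fronto-parietal phase step, and detection of the injected
hemodynamic bump.  Null-calibration helpers measure the empirical type-I
error of the interval contrast and of the per-timepoint fNIRS tests under
equal-gain / pure-noise synthesis.
"""

from __future__ import annotations

import numpy as np

from .bands import DEFAULT_BANDS, FRONTAL_ERSP, PARIETAL
from .connectivity import group_pairs, smooth_blocks
from .ersp import band_series, default_freq_grid, ersp, tf_decompose
from .fnirs import HemoSeries, baseline_correct_and_smooth, marker_locked_average, mbll
from .markers import TransitionMarkers, assign_responses, detect_transitions
from .preprocess import EpochSet, downsample, extract_epochs, rereference
from .stats import interval_band_power, paired_contrast
from .synthetic import DEFAULT_BAND_GAINS, SessionConfig, generate_session, synth_band_eeg

UPPER_ALPHA = {"upper_alpha": DEFAULT_BANDS["upper_alpha"]}


def evaluate_session_recovery(seed: int, config: SessionConfig | None = None,
                              analysis_fs: float = 100.0) -> dict:
    """Generate one session, run the analysis, score it against truth.

    Returns marker-recovery distances, the frontal upper-alpha dB change
    across LOC and ROC, the post-LOC frontal-minus-parietal upper-alpha
    topography gap, the localization error of the injected fronto-parietal
    phase step, and whether the injected hemodynamic bump produced an
    overlapping significant interval.
    """
    cfg = config or SessionConfig(seed=seed)
    if config is not None and config.seed != seed:
        raise ValueError("config seed must match the requested seed")
    session = generate_session(cfg)
    truth = session.truth

    scored = assign_responses(session.log)
    detected = detect_transitions(scored.hits, scored.stimuli)
    max_gap = float(np.diff(session.log.stimuli).max())
    # the run rule needs >=10 (LOC) / >=5 (ROC) stimuli after the transition;
    # a marker closer than that to session end is outside the rule's domain
    stimuli = session.log.stimuli
    marker_errors = []
    n_terminal = 0
    for kind, t_true in truth.true_markers:
        n_after = int(np.sum(stimuli > t_true))
        if n_after < (10 if kind == "LOC" else 5):
            n_terminal += 1
            continue
        cand = detected.of_kind(kind)
        marker_errors.append(float(np.min(np.abs(cand - t_true)))
                             if cand.size else np.inf)
    out = {
        "n_true_markers": len(truth.true_markers),
        "n_detectable_markers": len(truth.true_markers) - n_terminal,
        "n_terminal_markers": n_terminal,
        "n_detected": len(detected),
        "marker_errors_s": marker_errors,
        "max_stim_gap_s": max_gap,
    }

    rec_raw = downsample(session.eeg, analysis_fs)
    rec = rereference(rec_raw)
    freqs = default_freq_grid(4.0, 16.0, 0.5)
    for align in ("LOC", "ROC"):
        ep = extract_epochs(rec, detected, align)
        if ep.n_trials == 0:
            out[f"{align.lower()}_delta_db"] = np.nan
            continue
        emap = ersp(tf_decompose(ep, freqs))
        ua = band_series(emap, bands=UPPER_ALPHA)["upper_alpha"]
        t = ua.index.to_numpy()
        first = np.nanmean(ua[t < t[0] + 60.0])
        last = np.nanmean(ua[t > t[-1] - 60.0])
        out[f"{align.lower()}_delta_db"] = float(last - first)
        if align == "LOC":
            from .ersp import topo_snapshot
            topo = topo_snapshot(emap, "upper_alpha", "post")
            out["topo_frontal_minus_parietal_db"] = float(
                topo[list(FRONTAL_ERSP)].mean() - topo[list(PARIETAL)].mean())
        del emap

    # fronto-parietal phase step: analyzed on the recorded reference
    ep = extract_epochs(rec_raw, detected, "LOC")
    if ep.n_trials:
        tf = tf_decompose(ep, np.arange(12.0, 15.01, 0.5))
        gp = group_pairs(tf, bands=UPPER_ALPHA)
        sm = smooth_blocks(gp.attrs["phasor"]["upper_alpha"],
                           gp.index.to_numpy(), block_s=20.0)
        pre = np.mean(sm.phasor[:2])
        pre /= abs(pre)
        dev = np.degrees(np.angle(sm.phasor * np.conj(pre)))
        crossed = np.abs(dev) > 45.0
        est = float(sm.block_centers_s[np.argmax(crossed)]) if crossed.any() \
            else np.nan
        # true step time relative to the detected (epoch-zero) marker
        det_loc = detected.of_kind("LOC")
        true_rel = []
        for t_det in det_loc:
            t_true = truth.marker_times("LOC")
            true_rel.append(float(t_true[np.argmin(np.abs(t_true - t_det))]
                                  - t_det))
        out["phase_step_estimate_s"] = est
        out["phase_step_true_s"] = float(np.mean(true_rel))
        del tf

    hemo = baseline_correct_and_smooth(mbll(session.fnirs))
    try:
        res = marker_locked_average(hemo, detected, "LOC")
        half = cfg.bump_width_s / 2.0
        out["fnirs_bump_detected"] = any(
            iv[0] <= half and iv[1] >= -half for iv in res.intervals["hbo"])
    except ValueError:
        out["fnirs_bump_detected"] = False
    return out


def _null_subject_pair(rng: np.random.Generator, fs: float = 100.0) -> list[float]:
    """Pre/post upper-alpha interval powers for one null (equal-gain) subject."""
    t = np.arange(int(260.0 * fs)) / fs
    zeros = np.zeros(t.size)
    gains = {name: (g_c, g_c) for name, (g_c, _) in DEFAULT_BAND_GAINS.items()}
    data, _ = synth_band_eeg(t, zeros, zeros.astype(bool), FRONTAL_ERSP,
                             gains, rng, fs)
    ep = EpochSet(data[None, :, 2000:26000], fs, (-60.0, 180.0), "LOC",
                  [0.0], list(FRONTAL_ERSP))
    emap = ersp(tf_decompose(ep, np.arange(12.0, 15.01, 0.5)))
    return [interval_band_power(emap, "upper_alpha", "pre"),
            interval_band_power(emap, "upper_alpha", "post")]


def null_contrast_type_one_error(n_cohorts: int = 200, n_subjects: int = 12,
                                 alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical type-I error of the paired interval contrast under the null.

    Subjects are synthesized with equal conscious/unconscious gains, so any
    pre-vs-post difference is noise; the returned rate should sit near
    ``alpha``.
    """
    seq = np.random.SeedSequence(seed)
    hits = 0
    for cohort_seq in seq.spawn(n_cohorts):
        rng = np.random.default_rng(cohort_seq)
        pairs = np.array([_null_subject_pair(rng) for _ in range(n_subjects)])
        hits += paired_contrast(pairs).p_value < alpha
    return hits / n_cohorts


def fnirs_null_flag_fraction(n_trials: int = 20, alpha: float = 0.05,
                             seed: int = 0, fs: float = 15.625) -> float:
    """Fraction of per-timepoint significance flags under pure noise.

    Trials are disjoint windows of iid Gaussian hemodynamic noise, so the
    per-timepoint one-sample t-tests are exact nulls and the flagged
    fraction should approximate ``alpha`` (the tests are uncorrected by
    design).
    """
    rng = np.random.default_rng(seed)
    spacing, half = 300.0, 120.0
    dur = spacing * (n_trials + 1)
    n = int(dur * fs)
    series = HemoSeries(rng.normal(size=(3, n)), rng.normal(size=(3, n)), fs=fs)
    times = spacing * (1.0 + np.arange(n_trials))
    markers = TransitionMarkers(kinds=["LOC"] * n_trials, times=times,
                                stimulus_indices=np.arange(n_trials))
    res = marker_locked_average(series, markers, "LOC",
                                window_s=(-half, half), alpha=alpha)
    flags = np.concatenate([res.significant["hbo"], res.significant["hbr"]])
    return float(flags.mean())
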