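"""Behavioral transition markers from auditory-command response logs.

During patient-controlled sedation the subject hears a "press the button"
command every 9-11 s and presses while conscious.  Loss of consciousness
(LOC) is scored when the subject answered at least the previous 5 commands
and then fails to answer at least the next 10; recovery of consciousness
(ROC) symmetrically when at least 10 consecutive misses are followed by at
least 5 consecutive hits.  The marker time stamp is the onset of the first
missed (LOC) / first answered (ROC) stimulus, which anchors all
marker-locked epoching downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOC_MIN_HITS = 5
LOC_MIN_MISSES = 10
MIN_STIMULI = LOC_MIN_HITS + LOC_MIN_MISSES


@dataclass
class SessionLog:
    """Timestamped stimuli, button presses and bolus deliveries (seconds)."""

    stimuli: np.ndarray
    responses: np.ndarray
    boluses: np.ndarray = field(default_factory=lambda: np.empty(0))
    stage: str = "non_scaling"

    def __post_init__(self) -> None:
        self.stimuli = np.asarray(self.stimuli, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        self.boluses = np.asarray(self.boluses, dtype=float)
        for name in ("stimuli", "responses", "boluses"):
            t = getattr(self, name)
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"{name} times must be strictly increasing")
        if self.stage not in ("non_scaling", "scaling"):
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass
class TransitionMarkers:
    """Ordered LOC/ROC events: (kind, time_s, stimulus_index)."""

    kinds: list[str]
    times: np.ndarray
    stimulus_indices: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.stimulus_indices = np.asarray(self.stimulus_indices, dtype=int)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("marker times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.kinds)

    def of_kind(self, kind: str) -> np.ndarray:
        return self.times[[k == kind for k in self.kinds]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"kind": self.kinds, "time_s": self.times,
             "stimulus_index": self.stimulus_indices}
        )


@dataclass
class StimulusResponses:
    """Per-stimulus scoring: hit flags and first-press latencies."""

    stimuli: np.ndarray
    hits: np.ndarray          # bool per stimulus
    latencies: np.ndarray     # seconds; NaN on miss


def assign_responses(log: SessionLog) -> StimulusResponses:
    """Score each stimulus as hit/miss and attach the first-press latency.

    A press belongs to stimulus ``i`` iff it falls strictly between the
    onset of stimulus ``i`` and the onset of stimulus ``i+1`` (the last
    stimulus owns everything after it).  The first press in an interval
    wins; presses before the first stimulus are ignored with a warning.
    """
    stim = log.stimuli
    if stim.size == 0:
        raise ValueError("session log contains no stimuli")
    n_early = int(np.sum(log.responses <= stim[0]))
    if n_early:
        logger.warning("%d press(es) before the first stimulus ignored", n_early)
    hits = np.zeros(stim.size, dtype=bool)
    lat = np.full(stim.size, np.nan)
    # index of the owning stimulus for each press
    owner = np.searchsorted(stim, log.responses, side="right") - 1
    for i, r in zip(owner, log.responses):
        if i < 0:
            continue
        if not hits[i]:
            hits[i] = True
            lat[i] = r - stim[i]
    return StimulusResponses(stimuli=stim, hits=hits, latencies=lat)


def _runs(hits: np.ndarray) -> list[tuple[bool, int, int]]:
    """Maximal runs of constant value as (value, start, length)."""
    out = []
    start = 0
    for i in range(1, hits.size + 1):
        if i == hits.size or hits[i] != hits[start]:
            out.append((bool(hits[start]), start, i - start))
            start = i
    return out


def detect_transitions(
    hits: Sequence[bool] | np.ndarray,
    stimuli: Sequence[float] | np.ndarray,
    *,
    min_hits: int = LOC_MIN_HITS,
    min_misses: int = LOC_MIN_MISSES,
    enforce_alternation: bool = True,
) -> TransitionMarkers:
    """Detect LOC/ROC markers from the per-stimulus hit/miss sequence.

    A LOC is stamped at the onset of the first missed stimulus of each
    maximal run of >= ``min_misses`` misses immediately preceded by a
    maximal run of >= ``min_hits`` hits; a ROC at the onset of the first
    hit of each maximal run of >= ``min_hits`` hits immediately preceded
    by >= ``min_misses`` misses.  With ``enforce_alternation`` the output
    starts at the first LOC and strictly alternates (a trailing LOC with
    no qualifying ROC stands alone).
    """
    hits = np.asarray(hits, dtype=bool)
    stimuli = np.asarray(stimuli, dtype=float)
    if hits.size != stimuli.size:
        raise ValueError("hits and stimuli must have equal length")
    if hits.size < MIN_STIMULI:
        raise ValueError(
            f"insufficient stimuli: need at least {MIN_STIMULI}, got {hits.size}"
        )
    runs = _runs(hits)
    raw: list[tuple[str, int]] = []
    for j in range(1, len(runs)):
        prev_val, _, prev_len = runs[j - 1]
        val, start, length = runs[j]
        if not val and length >= min_misses and prev_val and prev_len >= min_hits:
            raw.append(("LOC", start))
        elif val and length >= min_hits and not prev_val and prev_len >= min_misses:
            raw.append(("ROC", start))
    if enforce_alternation:
        kept: list[tuple[str, int]] = []
        expect = "LOC"
        for kind, idx in raw:
            if kind == expect:
                kept.append((kind, idx))
                expect = "ROC" if expect == "LOC" else "LOC"
        raw = kept
    kinds = [k for k, _ in raw]
    idx = np.array([i for _, i in raw], dtype=int)
    return TransitionMarkers(kinds=kinds, times=stimuli[idx] if idx.size else
                             np.empty(0), stimulus_indices=idx)


def reaction_curve(
    log: SessionLog,
    smoothing_window_s: float | None = None,
) -> pd.Series:
    """Per-stimulus response latency (s) indexed by stimulus onset time.

    Misses are NaN.  With ``smoothing_window_s`` a centered moving average
    over that time window is returned, ignoring missing values.
    """
    scored = assign_responses(log)
    series = pd.Series(scored.latencies, index=pd.Index(scored.stimuli,
                                                        name="stimulus_onset_s"),
                       name="latency_s")
    if smoothing_window_s is None:
        return series
    half = smoothing_window_s / 2.0
    t = scored.stimuli
    out = np.full(t.size, np.nan)
    for i, ti in enumerate(t):
        sel = (t >= ti - half) & (t <= ti + half)
        vals = scored.latencies[sel]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            out[i] = vals.mean()
    return pd.Series(out, index=series.index, name="latency_s")
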