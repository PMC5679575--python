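"""Event-related phase coherence (ERPCOH) and fronto-parietal phase series.

For two channels a, b with single-trial wavelet coefficients F_k the
event-related phase coherence is the trial mean of the unit-magnitude
cross-spectral phasor,

    ERPCOH_ab(f, t) = (1/n) sum_k F_k^a(f,t) conj(F_k^b(f,t))
                               / |F_k^a(f,t) F_k^b(f,t)|,

whose magnitude (<= 1) measures inter-trial phase locking and whose angle
is the instantaneous phase difference phase(a) - phase(b): channel a
lagging b by tau yields angle -360*f*tau degrees.  Phase series are
summarized by non-overlapping 20 s block averages of the complex phasor
(wrap-safe) followed by Savitzky-Golay smoothing of the real and
imaginary block series, and aggregated over all 5x5 fronto-parietal
channel pairs and band frequency bins by complex averaging.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .bands import DEFAULT_BANDS, FRONTAL_COH, PARIETAL, Band
from .ersp import TFCoefficients

logger = logging.getLogger(__name__)


@dataclass
class PhaseCoherenceSeries:
    """ERPCOH for one channel pair: freqs x times complex, |.| <= 1."""

    erpcoh: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    pair: tuple[str, str]
    n_trials: int
    n_skipped: int = 0            # zero-coefficient (k,f,t) terms excluded

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.erpcoh)

    @property
    def phase_deg(self) -> np.ndarray:
        return phase_difference(self)


def _unit_cross_phasor(fa: np.ndarray, fb: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-trial unit phasors fa*conj(fb)/|fa fb| with zero terms masked.

    The phasor is built as exp(i*(arg fa - arg fb)): algebraically identical
    to the normalized cross product, but immune to the under/overflow of
    |fa*fb| and of complex division for extreme coefficient magnitudes.
    """
    zero = (fa == 0.0) | (fb == 0.0)
    n_skipped = int(zero.sum())
    dphi = (np.arctan2(fa.imag, fa.real) - np.arctan2(fb.imag, fb.real))
    unit = np.exp(1j * dphi)
    unit[zero] = 0.0
    return unit, n_skipped


def erpcoh(
    tf_a: np.ndarray,
    tf_b: np.ndarray,
    freqs_hz: np.ndarray | None = None,
    times_s: np.ndarray | None = None,
    pair: tuple[str, str] = ("a", "b"),
) -> PhaseCoherenceSeries:
    """Event-related phase coherence between two coefficient stacks.

    ``tf_a``/``tf_b`` are trials x freqs x times complex arrays on
    identical grids.  Terms with an exactly zero coefficient product are
    excluded from the trial mean (their unit phasor is undefined) and
    counted in ``n_skipped``.
    """
    tf_a = np.asarray(tf_a)
    tf_b = np.asarray(tf_b)
    if tf_a.shape != tf_b.shape:
        raise ValueError("coefficient stacks must share shape")
    if tf_a.ndim == 2:  # single trial convenience
        tf_a, tf_b = tf_a[None], tf_b[None]
    n = tf_a.shape[0]
    if n < 1:
        raise ValueError("need at least one trial")
    unit, n_skipped = _unit_cross_phasor(tf_a, tf_b)
    counts = np.sum(np.abs(unit) > 0, axis=0)
    with np.errstate(invalid="ignore"):
        coh = np.where(counts > 0, unit.sum(axis=0) / np.maximum(counts, 1), 0.0)
    if n_skipped:
        logger.warning("%d zero-coefficient term(s) skipped in ERPCOH",
                       n_skipped)
    if freqs_hz is None:
        freqs_hz = np.arange(tf_a.shape[1], dtype=float)
    if times_s is None:
        times_s = np.arange(tf_a.shape[2], dtype=float)
    return PhaseCoherenceSeries(erpcoh=coh, freqs_hz=np.asarray(freqs_hz),
                                times_s=np.asarray(times_s), pair=pair,
                                n_trials=n, n_skipped=n_skipped)


def phase_difference(series: PhaseCoherenceSeries | np.ndarray) -> np.ndarray:
    """Four-quadrant phase of ERPCOH in degrees, in (-180, 180].

    Zero-magnitude entries (undefined phase) come back NaN.
    """
    z = series.erpcoh if isinstance(series, PhaseCoherenceSeries) else \
        np.asarray(series)
    deg = np.degrees(np.arctan2(np.imag(z), np.real(z)))
    # arctan2 returns -180 at the branch cut; map to +180
    deg = np.where(deg == -180.0, 180.0, deg)
    return np.where(np.abs(z) == 0.0, np.nan, deg)


@dataclass
class SmoothedPhaseSeries:
    """Block-averaged, Savitzky-Golay-smoothed phase series."""

    block_centers_s: np.ndarray
    phasor: np.ndarray            # complex per block (post-smoothing)
    phase_deg: np.ndarray
    magnitude: np.ndarray
    block_s: float


def smooth_blocks(
    values: np.ndarray,
    times_s: np.ndarray,
    block_s: float = 20.0,
    sg_order: int = 3,
    sg_window_blocks: int = 5,
) -> SmoothedPhaseSeries:
    """Non-overlapping block means of a complex phase series, then SG.

    The complex values are averaged within consecutive ``block_s`` blocks
    (circular-safe), Savitzky-Golay smoothing is applied to the real and
    imaginary block series, and the angle is taken last.  If fewer blocks
    than the SG window exist the SG step is skipped with a warning.  A
    trailing partial block is dropped.
    """
    values = np.asarray(values)
    times_s = np.asarray(times_s, dtype=float)
    if values.shape[-1] != times_s.size:
        raise ValueError("values and times length mismatch")
    dt = float(np.median(np.diff(times_s)))
    per_block = int(round(block_s / dt))
    n_blocks = values.shape[-1] // per_block
    if n_blocks < 1:
        raise ValueError("series shorter than one block")
    trimmed = values[..., : n_blocks * per_block]
    blocks = trimmed.reshape(*values.shape[:-1], n_blocks, per_block).mean(axis=-1)
    centers = times_s[0] + (np.arange(n_blocks) + 0.5) * per_block * dt
    if sg_window_blocks > n_blocks:
        warnings.warn("fewer blocks than the Savitzky-Golay window; "
                      "skipping SG smoothing", stacklevel=2)
        smoothed = blocks
    else:
        win = sg_window_blocks if sg_window_blocks % 2 == 1 else sg_window_blocks + 1
        win = min(win, n_blocks if n_blocks % 2 == 1 else n_blocks - 1)
        order = min(sg_order, win - 1)
        smoothed = (savgol_filter(blocks.real, win, order, axis=-1)
                    + 1j * savgol_filter(blocks.imag, win, order, axis=-1))
    return SmoothedPhaseSeries(
        block_centers_s=centers, phasor=smoothed,
        phase_deg=phase_difference(smoothed),
        magnitude=np.abs(smoothed), block_s=block_s,
    )


def group_pairs(
    tf: TFCoefficients,
    frontal: tuple[str, ...] = FRONTAL_COH,
    parietal: tuple[str, ...] = PARIETAL,
    bands: dict[str, Band] | None = None,
) -> pd.DataFrame:
    """Aggregate fronto-parietal phase difference per band.

    For each frontal x parietal channel pair the ERPCOH is computed, the
    complex phasors are averaged across all pairs and across the band's
    frequency bins (complex averaging avoids wrap-around bias), and the
    angle is taken last.  Returns a DataFrame indexed by epoch time with
    ``<band>_phase_deg`` and ``<band>_magnitude`` columns, plus the
    aggregate complex phasor per band stored in ``df.attrs['phasor']``.
    """
    bands = ({"theta": DEFAULT_BANDS["theta"],
              "upper_alpha": DEFAULT_BANDS["upper_alpha"]}
             if bands is None else bands)
    missing = [c for c in (*frontal, *parietal) if c not in tf.channel_labels]
    if missing:
        raise ValueError(f"missing channels: {missing}")
    pair_sum = np.zeros((tf.freqs_hz.size, tf.times_s.size), dtype=complex)
    n_pairs = 0
    for fch in frontal:
        fa = tf.channel(fch)
        for pch in parietal:
            series = erpcoh(fa, tf.channel(pch), tf.freqs_hz, tf.times_s,
                            pair=(fch, pch))
            pair_sum += series.erpcoh
            n_pairs += 1
    pair_mean = pair_sum / n_pairs
    out = {}
    phasors = {}
    for name, band in bands.items():
        sel = band.contains(tf.freqs_hz)
        if not sel.any():
            raise ValueError(f"band {name} covers no grid frequencies")
        agg = pair_mean[sel].mean(axis=0)
        phasors[name] = agg
        out[f"{name}_phase_deg"] = phase_difference(agg)
        out[f"{name}_magnitude"] = np.abs(agg)
    df = pd.DataFrame(out, index=pd.Index(tf.times_s, name="time_s"))
    df.attrs["phasor"] = phasors
    return df
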