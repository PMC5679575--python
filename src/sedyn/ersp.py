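"""Morlet-wavelet time-frequency decomposition and event-related spectral
perturbation (ERSP).

Each epoch is convolved with complex Morlet atoms on an explicit frequency
grid (default 0.5-40 Hz in 0.5 Hz steps).  The atom at frequency f has
n(f) cycles, increasing linearly from 3 at the lowest analyzed frequency
(default slope 0.5 cycles/Hz), i.e. a Gaussian envelope with sigma_t =
n(f) / (2 pi f).  Atoms are amplitude-normalized so a pure sinusoid of
amplitude A yields |F| = A at its frequency.  Samples closer to an epoch
edge than the truncated atom half-support are flagged invalid (NaN after
averaging) instead of being mirrored, so no fabricated data enters any
statistic.

ERSP is the trial-mean squared modulus,

    ERSP(f, t) = (1/n) sum_k |F_k(f, t)|^2,

reported as 10*log10 power in dB; baseline normalization subtracts the
time-averaged baseline spectrum per channel and frequency, in the dB
domain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .bands import DEFAULT_BANDS, FRONTAL_ERSP, Band
from .preprocess import EpochSet

logger = logging.getLogger(__name__)

ATOM_TRUNCATION_SIGMAS = 3.0


def default_freq_grid(f_min: float = 0.5, f_max: float = 40.0,
                      step: float = 0.5) -> np.ndarray:
    return np.round(np.arange(f_min, f_max + step / 2, step), 6)


def cycles_for_freqs(freqs: np.ndarray, n_cycles_base: float = 3.0,
                     slope_cycles_per_hz: float = 0.5) -> np.ndarray:
    """Linearly increasing cycle counts: base at the lowest frequency."""
    freqs = np.asarray(freqs, dtype=float)
    cyc = n_cycles_base + slope_cycles_per_hz * (freqs - freqs[0])
    return np.maximum(cyc, 1.0)


@dataclass
class TFCoefficients:
    """Complex wavelet coefficients: trials x channels x freqs x times."""

    coeffs: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    cycles: np.ndarray
    valid: np.ndarray            # freqs x times bool: outside edge support
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.freqs_hz) > 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.cycles < 1.0):
            raise ValueError("cycle counts must be >= 1")

    def channel(self, label: str) -> np.ndarray:
        """Coefficients of one channel: trials x freqs x times."""
        return self.coeffs[:, self.channel_labels.index(label)]


def morlet_atom(f: float, n_cycles: float, fs: float) -> np.ndarray:
    """Sampled complex Morlet atom, amplitude-normalized, odd length."""
    sigma_t = n_cycles / (2.0 * np.pi * f)
    half = int(np.ceil(ATOM_TRUNCATION_SIGMAS * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    envelope = np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    atom = envelope * np.exp(2j * np.pi * f * t)
    # a pure cosine of amplitude A projects to (A/2) * sum(envelope)
    return atom / (envelope.sum() / 2.0)


def tf_decompose(
    epochs: EpochSet,
    freqs: np.ndarray | None = None,
    n_cycles_base: float = 3.0,
    slope_cycles_per_hz: float = 0.5,
) -> TFCoefficients:
    """Complex Morlet decomposition of every trial and channel.

    Raises if any requested frequency is non-positive (the wavelet is
    undefined at DC) or if the epoch is shorter than the atom support at
    the lowest frequency.
    """
    freqs = default_freq_grid() if freqs is None else np.asarray(freqs, float)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be strictly positive (no DC atom)")
    cycles = cycles_for_freqs(freqs, n_cycles_base, slope_cycles_per_hz)
    n_trials, n_ch, n_samp = epochs.data.shape
    out = np.empty((n_trials, n_ch, freqs.size, n_samp), dtype=complex)
    valid = np.zeros((freqs.size, n_samp), dtype=bool)
    flat = epochs.data.reshape(n_trials * n_ch, n_samp)
    for fi, (f, cyc) in enumerate(zip(freqs, cycles)):
        atom = morlet_atom(f, cyc, epochs.fs)
        half = (atom.size - 1) // 2
        if atom.size > n_samp:
            raise ValueError(
                f"epoch ({n_samp} samples) shorter than the wavelet support "
                f"({atom.size} samples) at {f} Hz"
            )
        conv = fftconvolve(flat, atom[None, :], mode="same", axes=1)
        out[:, :, fi, :] = conv.reshape(n_trials, n_ch, n_samp)
        valid[fi, half:n_samp - half] = True
    return TFCoefficients(coeffs=out, freqs_hz=freqs, times_s=epochs.times_s,
                          cycles=cycles, valid=valid,
                          channel_labels=list(epochs.channel_labels))


@dataclass
class ERSPMap:
    """Trial-averaged log power: channels x freqs x times in dB.

    Edge-invalid samples are NaN.  ``baseline_db`` holds the subtracted
    per-(channel, frequency) baseline spectrum when normalization was
    applied.
    """

    power_db: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    n_trials: int
    channel_labels: list[str] = field(default_factory=list)
    baseline_db: np.ndarray | None = None

    def channel(self, label: str) -> np.ndarray:
        return self.power_db[self.channel_labels.index(label)]


def ersp(tf: TFCoefficients, baseline: TFCoefficients | None = None) -> ERSPMap:
    """Event-related spectral perturbation in dB.

    Mean over trials of |F_k|^2, 10*log10-converted; if a baseline
    decomposition is given (same channels and frequency grid) its
    time-averaged dB spectrum is subtracted per channel and frequency.
    """
    n = tf.coeffs.shape[0]
    if n == 0:
        raise ValueError("no trials")
    power = np.mean(np.abs(tf.coeffs) ** 2, axis=0)   # ch x f x t
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(power)
    db[:, ~tf.valid] = np.nan
    baseline_db = None
    if baseline is not None:
        if baseline.channel_labels != tf.channel_labels:
            raise ValueError("baseline channels differ from signal channels")
        if not np.array_equal(baseline.freqs_hz, tf.freqs_hz):
            raise ValueError("baseline frequency grid differs")
        bpow = np.mean(np.abs(baseline.coeffs) ** 2, axis=0)
        with np.errstate(divide="ignore"):
            bdb = 10.0 * np.log10(bpow)
        bdb[:, ~baseline.valid] = np.nan
        baseline_db = np.nanmean(bdb, axis=2)          # ch x f
        db = db - baseline_db[:, :, None]
    return ERSPMap(power_db=db, freqs_hz=tf.freqs_hz, times_s=tf.times_s,
                   n_trials=n, channel_labels=list(tf.channel_labels),
                   baseline_db=baseline_db)


def _band_bins(freqs: np.ndarray, band: Band) -> np.ndarray:
    sel = band.contains(freqs)
    if not sel.any():
        raise ValueError(f"band {band.name} covers no grid frequencies")
    return sel


def band_series(
    emap: ERSPMap,
    bands: dict[str, Band] | None = None,
    channels: tuple[str, ...] = FRONTAL_ERSP,
    smooth_window_s: float | None = None,
) -> pd.DataFrame:
    """Per-band dB time series averaged over band bins and a channel subset.

    Returns a DataFrame indexed by epoch time with one column per band.
    Optional centered moving-average smoothing over ``smooth_window_s``.
    """
    bands = DEFAULT_BANDS if bands is None else bands
    missing = [c for c in channels if c not in emap.channel_labels]
    if missing:
        raise ValueError(f"channels not in map: {missing}")
    ch_idx = [emap.channel_labels.index(c) for c in channels]
    sub = emap.power_db[ch_idx]                        # ch x f x t
    cols = {}
    for name, band in bands.items():
        sel = _band_bins(emap.freqs_hz, band)
        with warnings.catch_warnings():
            # edge samples can be all-NaN across a band; NaN output is wanted
            warnings.simplefilter("ignore", RuntimeWarning)
            cols[name] = np.nanmean(sub[:, sel, :], axis=(0, 1))
    df = pd.DataFrame(cols, index=pd.Index(emap.times_s, name="time_s"))
    if smooth_window_s is not None:
        dt = float(np.median(np.diff(emap.times_s)))
        win = max(1, int(round(smooth_window_s / dt)))
        df = df.rolling(win, center=True, min_periods=1).mean()
    return df


# interval names -> selector over the relative time axis
TOPO_INTERVALS = ("pre", "transition", "post", "recovery")


def _interval_mask(times: np.ndarray, interval: str) -> np.ndarray:
    if interval == "pre":
        return times < times[0] + 10.0
    if interval == "transition":
        return (times >= -5.0) & (times < 5.0)
    if interval in ("post", "recovery"):
        return times >= times[-1] - 10.0
    raise ValueError(f"unknown interval {interval!r}; one of {TOPO_INTERVALS}")


def topo_snapshot(emap: ERSPMap, band: Band | str, interval: str) -> pd.Series:
    """Per-channel mean dB over one band and one named 10 s interval.

    Intervals: ``pre`` = first 10 s of the epoch window, ``transition`` =
    [-5, +5] s around the marker, ``post``/``recovery`` = last 10 s.
    Edge-invalid samples are excluded with a warning when they clip the
    interval.
    """
    if isinstance(band, str):
        band = DEFAULT_BANDS[band]
    fsel = _band_bins(emap.freqs_hz, band)
    tsel = _interval_mask(emap.times_s, interval)
    block = emap.power_db[:, fsel][:, :, tsel]
    if np.isnan(block).any():
        logger.warning("interval %r clipped by edge-invalid samples; "
                       "averaging valid samples only", interval)
    vals = np.nanmean(block, axis=(1, 2))
    return pd.Series(vals, index=pd.Index(emap.channel_labels, name="channel"),
                     name=f"{band.name}_{interval}_db")
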