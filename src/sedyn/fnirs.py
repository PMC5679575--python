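"""Modified Beer-Lambert conversion and marker-locked fNIRS statistics.

Two-wavelength (760/850 nm) optical-density changes are converted to
oxy-/deoxy-hemoglobin concentration changes (uM) by inverting, per channel
and sample, the modified Beer-Lambert law

    dOD(lambda) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR] * d * DPF(lambda)

where d is the source-detector distance (cm) and DPF the differential
pathlength factor.  Default extinction coefficients are the Prahl/Cope
compilation (1/(cm*M)); default DPFs are typical adult-head values from the
general DPF equation.  Both ship as overridable configuration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ttest_1samp

from .markers import TransitionMarkers

logger = logging.getLogger(__name__)

# molar extinction coefficients, 1/(cm * mol/L): {wavelength: (HbO, HbR)}
# after the S. Prahl compilation of hemoglobin spectra
DEFAULT_EXTINCTION: dict[float, tuple[float, float]] = {
    760.0: (586.0, 1548.52),
    850.0: (1058.0, 691.32),
}

# differential pathlength factors, adult head (general DPF equation, ~age 27)
DEFAULT_DPF: dict[float, float] = {760.0: 6.1, 850.0: 5.8}

DISTANCE_VALID_CM = (2.0, 3.0)


@dataclass
class FNIRSRecording:
    """Optical-density change time series: channels x wavelengths x samples."""

    dod: np.ndarray
    wavelengths_nm: tuple[float, float]
    fs: float = 15.625
    distances_cm: np.ndarray | float = 3.0
    dpf: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_DPF))
    channel_labels: list[str] | None = None
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.dod = np.asarray(self.dod, dtype=float)
        if self.dod.ndim != 3 or self.dod.shape[1] != 2:
            raise ValueError("dod must be channels x 2 wavelengths x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.distances_cm = np.broadcast_to(
            np.asarray(self.distances_cm, dtype=float), (self.dod.shape[0],)
        ).copy()
        if self.channel_labels is None:
            self.channel_labels = [f"CH{i+1}" for i in range(self.dod.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.dod.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.dod.shape[2]) / self.fs


@dataclass
class HemoSeries:
    """HbO/HbR concentration-change series (uM), channels x samples."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    channel_labels: list[str] | None = None
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must share shape")
        if self.channel_labels is None:
            self.channel_labels = [f"CH{i+1}" for i in range(self.hbo.shape[0])]

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.hbo.shape[1]) / self.fs


def _coupling_matrix(
    wavelengths: tuple[float, float],
    distance_cm: float,
    dpf: dict[float, float],
    extinction: dict[float, tuple[float, float]],
) -> np.ndarray:
    """2x2 matrix mapping (dHbO, dHbR) in uM to dOD at the two wavelengths."""
    m = np.empty((2, 2))
    for i, wl in enumerate(wavelengths):
        eps_hbo, eps_hbr = extinction[wl]
        path = distance_cm * dpf[wl]
        m[i, 0] = eps_hbo * 1e-6 * path  # 1/(cm*M) * 1e-6 -> per uM
        m[i, 1] = eps_hbr * 1e-6 * path
    return m


def forward_mbll(
    hbo: np.ndarray,
    hbr: np.ndarray,
    wavelengths: tuple[float, float] = (760.0, 850.0),
    distances_cm: np.ndarray | float = 3.0,
    dpf: dict[float, float] | None = None,
    extinction: dict[float, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Forward Beer-Lambert: (channels x samples) HbO/HbR in uM -> dOD.

    Returns channels x 2 wavelengths x samples.  This is the generative
    counterpart of :func:`mbll` and closes the round trip exactly.
    """
    dpf = dict(DEFAULT_DPF) if dpf is None else dpf
    extinction = dict(DEFAULT_EXTINCTION) if extinction is None else extinction
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    hbr = np.atleast_2d(np.asarray(hbr, dtype=float))
    dist = np.broadcast_to(np.asarray(distances_cm, dtype=float), (hbo.shape[0],))
    dod = np.empty((hbo.shape[0], 2, hbo.shape[1]))
    for c in range(hbo.shape[0]):
        m = _coupling_matrix(wavelengths, dist[c], dpf, extinction)
        dod[c] = m @ np.vstack([hbo[c], hbr[c]])
    return dod


def mbll(
    rec: FNIRSRecording,
    extinction: dict[float, tuple[float, float]] | None = None,
) -> HemoSeries:
    """Invert the modified Beer-Lambert law channel- and sample-wise."""
    extinction = dict(DEFAULT_EXTINCTION) if extinction is None else extinction
    lo, hi = DISTANCE_VALID_CM
    if np.any((rec.distances_cm < lo) | (rec.distances_cm > hi)):
        warnings.warn(
            f"source-detector distance outside the validated {lo}-{hi} cm range",
            stacklevel=2,
        )
    n_ch, _, n_samp = rec.dod.shape
    hbo = np.empty((n_ch, n_samp))
    hbr = np.empty((n_ch, n_samp))
    for c in range(n_ch):
        m = _coupling_matrix(rec.wavelengths_nm, rec.distances_cm[c],
                             rec.dpf, extinction)
        det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
        if det == 0.0 or not np.isfinite(det):
            raise ValueError("singular extinction/pathlength matrix")
        inv = np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det
        conc = inv @ rec.dod[c]
        hbo[c], hbr[c] = conc[0], conc[1]
    return HemoSeries(hbo=hbo, hbr=hbr, fs=rec.fs,
                      channel_labels=list(rec.channel_labels),
                      start_time_s=rec.start_time_s)


def baseline_correct_and_smooth(
    series: HemoSeries,
    baseline_window_s: tuple[float, float] | float = 180.0,
    ma_window_s: float = 90.0,
) -> HemoSeries:
    """Subtract the per-channel baseline mean, then centered moving average.

    ``baseline_window_s`` is either the window length taken from the start
    of the recording (default 3 min) or an explicit (t0, t1) in recording
    time.  The moving average (default 1.5 min) is centered; edges use the
    samples available.
    """
    t = series.times_s
    if np.isscalar(baseline_window_s):
        t0, t1 = t[0], t[0] + float(baseline_window_s)
    else:
        t0, t1 = baseline_window_s
    sel = (t >= t0) & (t < t1)
    if not sel.any():
        raise ValueError("baseline window outside the recording")

    win = max(1, int(round(ma_window_s * series.fs)))

    def _proc(x: np.ndarray) -> np.ndarray:
        corrected = x - x[:, sel].mean(axis=1, keepdims=True)
        df = pd.DataFrame(corrected.T)
        return df.rolling(win, center=True, min_periods=1).mean().to_numpy().T

    return HemoSeries(hbo=_proc(series.hbo), hbr=_proc(series.hbr),
                      fs=series.fs, channel_labels=list(series.channel_labels),
                      start_time_s=series.start_time_s)


DEFAULT_WINDOWS = {"LOC": (-240.0, 360.0), "ROC": (-360.0, 240.0)}


@dataclass
class MarkerLockedResult:
    """Trial-averaged marker-locked hemodynamics with significance runs."""

    times_s: np.ndarray            # relative to marker
    mean: dict[str, np.ndarray]    # chromophore -> time series (uM)
    se: dict[str, np.ndarray]
    significant: dict[str, np.ndarray] | None   # bool masks (None if n<2)
    intervals: dict[str, list[tuple[float, float]]]
    n_trials: int
    alignment: str


def _contiguous_runs(mask: np.ndarray, times: np.ndarray) -> list[tuple[float, float]]:
    runs = []
    in_run = False
    for i, m in enumerate(mask):
        if m and not in_run:
            start = times[i]
            in_run = True
        elif not m and in_run:
            runs.append((start, times[i - 1]))
            in_run = False
    if in_run:
        runs.append((start, times[-1]))
    return runs


def marker_locked_average(
    series: HemoSeries,
    markers: TransitionMarkers,
    alignment: str,
    window_s: tuple[float, float] | None = None,
    alpha: float = 0.05,
    correction: str | None = None,
) -> MarkerLockedResult:
    """Average channel-mean HbO/HbR around each marker of one kind.

    Windows default to (-4, +6) min for LOC and (-6, +4) min for ROC.
    With >= 2 trials a per-timepoint two-sided one-sample t-test against 0
    flags significant samples (uncorrected by default, matching the
    shaded-interval presentation convention; ``correction='bonferroni'``
    is available) and contiguous significant runs are reported as
    intervals.  Trials whose window leaves the recording are dropped with
    a warning.
    """
    if alignment not in DEFAULT_WINDOWS:
        raise ValueError("alignment must be 'LOC' or 'ROC'")
    w0, w1 = DEFAULT_WINDOWS[alignment] if window_s is None else window_s
    n_samp = int(round((w1 - w0) * series.fs))
    rel_times = w0 + np.arange(n_samp) / series.fs
    t_start = series.start_time_s
    n_total = series.hbo.shape[1]

    trials: dict[str, list[np.ndarray]] = {"hbo": [], "hbr": []}
    n_dropped = 0
    for kind, mt in zip(markers.kinds, markers.times):
        if kind != alignment:
            continue
        i0 = int(np.floor((mt - t_start) * series.fs)) + int(round(w0 * series.fs))
        if i0 < 0 or i0 + n_samp > n_total:
            n_dropped += 1
            continue
        sl = slice(i0, i0 + n_samp)
        trials["hbo"].append(series.hbo[:, sl].mean(axis=0))
        trials["hbr"].append(series.hbr[:, sl].mean(axis=0))
    if n_dropped:
        logger.warning("%d %s trial(s) dropped: window outside recording",
                       n_dropped, alignment)
    n = len(trials["hbo"])
    if n == 0:
        raise ValueError(f"no {alignment} trials fit the recording")

    mean, se, sig, ivals = {}, {}, {}, {}
    for chrom in ("hbo", "hbr"):
        arr = np.asarray(trials[chrom])           # trials x samples
        mean[chrom] = arr.mean(axis=0)
        se[chrom] = (arr.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 else \
            np.full(n_samp, np.nan)
        if n >= 2:
            pvals = ttest_1samp(arr, 0.0, axis=0).pvalue
            thr = alpha / n_samp if correction == "bonferroni" else alpha
            mask = pvals < thr
            sig[chrom] = mask
            ivals[chrom] = _contiguous_runs(mask, rel_times)
        else:
            ivals[chrom] = []
    return MarkerLockedResult(
        times_s=rel_times, mean=mean, se=se,
        significant=sig if n >= 2 else None,
        intervals=ivals, n_trials=n, alignment=alignment,
    )
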