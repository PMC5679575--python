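"""Paired comparisons of frontal band power between consciousness intervals.

The per-subject summary statistic is the mean baseline-normalized ERSP
(dB) over the frontal channel group, one frequency band, and one named
10 s interval of a marker-locked epoch (pre-LOC = first 10 s of the LOC
window, post-LOC = last 10 s, and symmetrically for ROC).  Contrasts are
paired two-sided t-tests on (pre - post) across subjects, so bands whose
power rises after LOC yield negative t and the beta/gamma decrease yields
positive t.  No multiple-testing correction is applied across bands by
default (a Bonferroni switch exists).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_rel

from .bands import DEFAULT_BANDS, FRONTAL_ERSP, Band
from .ersp import ERSPMap, _band_bins, _interval_mask


def interval_band_power(
    emap: ERSPMap,
    band: Band | str,
    interval: str,
    channels: tuple[str, ...] = FRONTAL_ERSP,
) -> float:
    """Mean dB over frontal channels, band bins and the interval samples."""
    if isinstance(band, str):
        band = DEFAULT_BANDS[band]
    missing = [c for c in channels if c not in emap.channel_labels]
    if missing:
        raise ValueError(f"channels not in map: {missing}")
    ch_idx = [emap.channel_labels.index(c) for c in channels]
    fsel = _band_bins(emap.freqs_hz, band)
    tsel = _interval_mask(emap.times_s, interval)
    return float(np.nanmean(emap.power_db[ch_idx][:, fsel][:, :, tsel]))


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class IntervalComparison:
    """One paired pre-vs-post contrast of interval band power."""

    band: str
    contrast: str
    t_stat: float
    p_value: float
    n_subjects: int
    per_subject_values: np.ndarray   # n x 2 (pre, post) dB
    zero_variance: bool = False

    @property
    def stars(self) -> str:
        return stars(self.p_value)


def paired_contrast(
    values: np.ndarray,
    band: str = "",
    contrast: str = "",
) -> IntervalComparison:
    """Paired two-sided t-test on per-subject (pre, post) dB pairs.

    t is computed on the differences pre - post.  Zero-variance
    differences are flagged (t is +/-inf, or 0 for identical columns).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != 2:
        raise ValueError("values must be n_subjects x 2 (pre, post)")
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    pre, post = values[:, 0], values[:, 1]
    d = pre - post
    if np.ptp(d) == 0.0:
        zero_var = True
        if d[0] == 0.0:
            t, p = 0.0, 1.0
        else:
            warnings.warn("zero-variance paired differences", stacklevel=2)
            t, p = float(np.sign(d[0]) * np.inf), 0.0
    else:
        zero_var = False
        res = ttest_rel(pre, post)
        t, p = float(res.statistic), float(res.pvalue)
    return IntervalComparison(band=band, contrast=contrast, t_stat=t,
                              p_value=p, n_subjects=n,
                              per_subject_values=values,
                              zero_variance=zero_var)


def contrast_table(
    subject_maps_loc: list[ERSPMap],
    subject_maps_roc: list[ERSPMap],
    bands: dict[str, Band] | None = None,
    channels: tuple[str, ...] = FRONTAL_ERSP,
    correction: str | None = None,
) -> pd.DataFrame:
    """Band x contrast table of paired t statistics across subjects.

    Rows are bands; columns hold t, p and significance stars for the
    pre-vs-post LOC and pre-vs-post ROC contrasts.  ``correction=
    'bonferroni'`` scales p by the number of bands.
    """
    bands = DEFAULT_BANDS if bands is None else bands
    rows = []
    for name, band in bands.items():
        row: dict[str, object] = {"band": name}
        for label, maps in (("preLOC_vs_postLOC", subject_maps_loc),
                            ("preROC_vs_postROC", subject_maps_roc)):
            pairs = np.array([
                [interval_band_power(m, band, "pre", channels),
                 interval_band_power(m, band, "post", channels)]
                for m in maps
            ])
            cmp_ = paired_contrast(pairs, band=name, contrast=label)
            p = cmp_.p_value
            if correction == "bonferroni":
                p = min(1.0, p * len(bands))
            row[f"{label}_t"] = cmp_.t_stat
            row[f"{label}_p"] = p
            row[f"{label}_stars"] = stars(p)
        rows.append(row)
    return pd.DataFrame(rows).set_index("band")
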