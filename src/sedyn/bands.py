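"""Canonical frequency bands and channel groups for the sedation analysis.

Band edges follow the anesthesia-EEG convention used throughout this
package: delta 0.1-3 Hz, theta 4-7 Hz, lower alpha 8-12 Hz, upper alpha
12-15 Hz and a combined beta/gamma range 15-40 Hz.  Upper alpha (12-15 Hz)
is the band most discriminative of sedative state transitions and is the
default for topographic and connectivity summaries.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Band:
    """A closed frequency interval in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not self.f_low < self.f_high:
            raise ValueError(f"band {self.name}: f_low must be < f_high")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_low + self.f_high)

    def contains(self, f) -> bool:
        return (self.f_low <= f) & (f <= self.f_high)


DEFAULT_BANDS: dict[str, Band] = {
    "delta": Band("delta", 0.1, 3.0),
    "theta": Band("theta", 4.0, 7.0),
    "lower_alpha": Band("lower_alpha", 8.0, 12.0),
    "upper_alpha": Band("upper_alpha", 12.0, 15.0),
    "beta_gamma": Band("beta_gamma", 15.0, 40.0),
}

# Frontal channels used for spectral (ERSP) aggregation.
FRONTAL_ERSP = ("AF3", "AF4", "F1", "F2", "Fz")
# Frontal / parieto-occipital groups used for fronto-parietal phase coherence.
FRONTAL_COH = ("F1", "F2", "F3", "F4", "Fz")
PARIETAL = ("PO3", "PO4", "POz", "Pz", "Oz")

# Minimal montage the synthetic generator emits: union of the groups above.
DEFAULT_CHANNELS = ("AF3", "AF4", "F1", "F2", "F3", "F4", "Fz",
                    "PO3", "PO4", "POz", "Pz", "Oz")
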