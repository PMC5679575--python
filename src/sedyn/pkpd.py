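"""Compartmental PK/PD simulation of plasma and effect-site concentration.

Sedative kinetics are modeled as a mammillary linear compartment system
(1-3 compartments) with first-order intercompartmental rate constants and
a hypothetical effect compartment linked to plasma by

    dCe/dt = ke0 * (Cp - Ce),

so the effect-site concentration (CE) lags plasma with time constant
1/ke0.  The state equation is linear, so the solver propagates the exact
matrix exponential of the augmented system between dose events and grid
points: piecewise-constant infusion input is handled with the standard
augmented-matrix construction and instantaneous boluses as jumps in the
central-compartment amount.  This is exact (to machine precision) for the
stated input class; no ODE stepping error enters.

Drug parameter presets are external-literature configuration, shipped with
citation tags; the engine itself is parameter-agnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.stats import ttest_ind, ttest_rel

from .markers import TransitionMarkers

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PKModel:
    """Mammillary compartment model with an effect-site link.

    Rate constants in 1/min; V1 in L (``per_kg=False``) or L/kg.  ``unit_scale``
    converts the natural mg/L plasma unit into the drug's reporting unit
    (1 -> ug/mL for propofol, 1000 -> ng/mL for midazolam).
    """

    drug: str
    n_compartments: int
    v1: float
    k10: float
    ke0: float
    k12: float = 0.0
    k21: float = 0.0
    k13: float = 0.0
    k31: float = 0.0
    per_kg: bool = True
    unit_scale: float = 1.0
    unit: str = "ug/mL"
    parameter_source: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.n_compartments <= 3:
            raise ValueError("n_compartments must be in 1..3")
        if self.v1 <= 0:
            raise ValueError("V1 must be positive")
        if self.ke0 <= 0:
            raise ValueError("ke0 must be positive")
        for k in ("k10", "k12", "k21", "k13", "k31"):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be >= 0")

    def central_volume_l(self, weight_kg: float) -> float:
        return self.v1 * weight_kg if self.per_kg else self.v1

    def system_matrix(self, weight_kg: float) -> np.ndarray:
        """A of d/dt [a1..an, ce] with amounts in mg, ce in mg/L.

        Rates are per minute; callers working in seconds scale by 1/60.
        """
        n = self.n_compartments
        a = np.zeros((n + 1, n + 1))
        a[0, 0] = -(self.k10 + self.k12 + self.k13)
        if n >= 2:
            a[0, 1] = self.k21
            a[1, 0] = self.k12
            a[1, 1] = -self.k21
        if n >= 3:
            a[0, 2] = self.k31
            a[2, 0] = self.k13
            a[2, 2] = -self.k31
        v1 = self.central_volume_l(weight_kg)
        a[n, 0] = self.ke0 / v1
        a[n, n] = -self.ke0
        return a


# --- literature presets (configuration, not package results) -----------------
# Propofol: Marsh adult model; ke0 1.2/min is the widely used "modified Marsh"
# effect-site constant.  Midazolam: approximate adult two-compartment values
# (clearance ~0.4 L/min/70 kg, distribution half-life ~10 min) with a slow
# effect-site equilibration, flagged approximate.
PRESETS: dict[str, PKModel] = {
    "PPF": PKModel(
        drug="PPF", n_compartments=3, v1=0.228, per_kg=True,
        k10=0.119, k12=0.112, k21=0.055, k13=0.0419, k31=0.0033,
        ke0=0.26, unit_scale=1.0, unit="ug/mL",
        parameter_source="Marsh et al. 1991 BJA; Diprifusor ke0 0.26/min",
    ),
    "MDZ": PKModel(
        drug="MDZ", n_compartments=2, v1=0.45, per_kg=True,
        k10=0.0127, k12=0.10, k21=0.05,
        ke0=0.14, unit_scale=1000.0, unit="ng/mL",
        parameter_source="approximate adult midazolam 2-compartment values "
                         "(CL~0.4 L/min/70 kg); synthetic stand-in preset",
    ),
}


@dataclass
class DoseSchedule:
    """Dose events (start_s, dose_mg, duration_s); duration 0 = bolus."""

    events: list[tuple[float, float, float]]
    weight_kg: float

    def __post_init__(self) -> None:
        self.events = [(float(t), float(d), float(dur)) for t, d, dur in self.events]
        if any(d < 0 for _, d, _ in self.events):
            raise ValueError("negative dose")
        if any(dur < 0 for _, _, dur in self.events):
            raise ValueError("negative duration")
        if self.events != sorted(self.events, key=lambda e: e[0]):
            raise ValueError("events must be time-sorted")
        if self.weight_kg <= 0:
            raise ValueError("weight must be positive")

    @property
    def bolus_times(self) -> np.ndarray:
        return np.array([t for t, _, _ in self.events], dtype=float)


@dataclass
class CEProfile:
    """Plasma (cp) and effect-site (ce) concentration on a time grid."""

    times_s: np.ndarray
    cp: np.ndarray
    ce: np.ndarray
    model: PKModel

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times_s, "cp": self.cp, "ce": self.ce})


class _Propagator:
    """Exact piecewise-constant-input propagator for dx/dt = A x + b u."""

    def __init__(self, a_per_s: np.ndarray, b: np.ndarray) -> None:
        self.a = a_per_s
        self.b = b
        self.n = a_per_s.shape[0]
        self._cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def mats(self, dt: float) -> tuple[np.ndarray, np.ndarray]:
        got = self._cache.get(dt)
        if got is None:
            aug = np.zeros((self.n + 1, self.n + 1))
            aug[: self.n, : self.n] = self.a * dt
            aug[: self.n, self.n] = self.b * dt
            m = expm(aug)
            got = (m[: self.n, : self.n], m[: self.n, self.n])
            self._cache[dt] = got
        return got

    def step(self, x: np.ndarray, dt: float, u: float) -> np.ndarray:
        if dt == 0.0:
            return x
        e, f = self.mats(dt)
        return e @ x + f * u


def simulate_ce(
    schedule: DoseSchedule,
    model: PKModel,
    grid_dt_s: float = 1.0,
    t_end_s: float | None = None,
    x0: np.ndarray | None = None,
) -> CEProfile:
    """Simulate plasma and effect-site concentration for a dose schedule.

    The grid runs 0..t_end at ``grid_dt_s`` spacing; dose events may fall
    off-grid and are handled exactly.  A bolus of D mg raises the central
    amount by D instantly; a finite-duration event is a zero-order infusion
    at D/duration mg/s.
    """
    if t_end_s is None:
        t_end_s = max((t + dur for t, _, dur in schedule.events), default=0.0)
    max_k = max(model.k10, model.k12, model.k21, model.k13, model.k31, model.ke0)
    if grid_dt_s > 60.0 / (10.0 * max_k):
        warnings.warn("grid_dt_s coarse relative to the fastest rate constant",
                      stacklevel=2)
    n_state = model.n_compartments + 1
    a = model.system_matrix(schedule.weight_kg) / 60.0  # per second
    b = np.zeros(n_state)
    b[0] = 1.0  # infusion feeds the central compartment (mg/s)
    prop = _Propagator(a, b)

    times = np.arange(0.0, t_end_s + 0.5 * grid_dt_s, grid_dt_s)
    # boundaries: bolus instants, infusion on/off instants
    boluses: list[tuple[float, float]] = []
    switches: list[tuple[float, float]] = []  # (time, rate delta mg/s)
    for t0, dose, dur in schedule.events:
        if dur == 0.0:
            boluses.append((t0, dose))
        else:
            rate = dose / dur
            switches.append((t0, rate))
            switches.append((t0 + dur, -rate))
    events = sorted(
        [(t, "bolus", v) for t, v in boluses] + [(t, "switch", v) for t, v in switches]
    )

    x = np.zeros(n_state) if x0 is None else np.asarray(x0, dtype=float).copy()
    u = 0.0
    out = np.empty((times.size, n_state))
    cur_t = 0.0
    ev_i = 0
    # apply any events at exactly t=0 before recording the first sample
    for g, tg in enumerate(times):
        while ev_i < len(events) and events[ev_i][0] <= tg:
            te, kind, val = events[ev_i]
            x = prop.step(x, te - cur_t, u)
            cur_t = te
            if kind == "bolus":
                x[0] += val
            else:
                u += val
            ev_i += 1
        x = prop.step(x, tg - cur_t, u)
        cur_t = tg
        out[g] = x
    v1 = model.central_volume_l(schedule.weight_kg)
    cp = out[:, 0] / v1 * model.unit_scale
    ce = out[:, -1] * model.unit_scale
    return CEProfile(times_s=times, cp=cp, ce=ce, model=model)


def ce_at_markers(profile: CEProfile, markers: TransitionMarkers) -> pd.DataFrame:
    """Linearly interpolated CE at each LOC/ROC marker time."""
    t0, t1 = profile.times_s[0], profile.times_s[-1]
    vals = np.full(len(markers), np.nan)
    inside = (markers.times >= t0) & (markers.times <= t1)
    if not inside.all():
        logger.warning("%d marker(s) outside the CE profile range",
                       int((~inside).sum()))
    vals[inside] = np.interp(markers.times[inside], profile.times_s, profile.ce)
    return pd.DataFrame({"kind": markers.kinds, "time_s": markers.times,
                         "ce": vals})


def compare_ce(
    group_a: np.ndarray,
    group_b: np.ndarray,
    paired: bool = True,
) -> tuple[float, float]:
    """Two-sided t-test between two sets of per-subject CE values.

    Paired (default, as for LOC-vs-ROC within subjects) or Welch
    two-sample.  Zero-variance paired differences give t = +/-inf (or 0
    when the groups are identical) with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal-length groups")
        if a.size < 2:
            raise ValueError("need at least 2 pairs")
        d = a - b
        if np.ptp(d) == 0.0:
            if d[0] == 0.0:
                return 0.0, 1.0
            warnings.warn("zero variance of paired differences; t is infinite",
                          stacklevel=2)
            return float(np.sign(d[0]) * np.inf), 0.0
        res = ttest_rel(a, b)
    else:
        res = ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def scale_preset(model: PKModel, **overrides) -> PKModel:
    """Return a preset with selected fields replaced (e.g. a custom ke0)."""
    return replace(model, **overrides)
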