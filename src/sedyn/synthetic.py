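"""Synthetic patient-controlled-sedation sessions with known ground truth.

The generator emulates the experimental conditions of an auditory-command
patient-controlled sedation study: a "press the button" command every
9-11 s (uniform), a button press for every command heard while conscious,
and a bolus delivered on each press that clears the lockout interval
(1 min at the middle dose).  Consciousness is a deterministic function of
the simulated effect-site concentration (CE): the subject flips to
unconscious when CE crosses a threshold upward and recovers when CE falls
below threshold minus a small hysteresis (recovery at a lower CE than
loss, as observed for propofol).  This closed loop — presses drive boluses
drive CE drives responsiveness — produces the repeated LOC/ROC cycles the
analysis needs.

EEG is synthesized per channel as a sum of band-limited oscillations whose
amplitudes switch between conscious and unconscious gains through a 30 s
logistic ramp (spectral transitions under sedation are gradual, not
instantaneous), plus 1/f noise.  Frontal channels receive an extra
upper-alpha gain during unconsciousness (anteriorization), and parietal
channels an optional upper-alpha phase offset during unconsciousness so a
fronto-parietal phase step of known time and size exists for connectivity
checks.  fNIRS optical densities are generated by the exact forward
modified Beer-Lambert model from known HbO/HbR trajectories (raised-cosine
peri-transition bumps plus slow noise), so Beer-Lambert inversion closes
the loop to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bands import DEFAULT_BANDS, DEFAULT_CHANNELS, FRONTAL_COH, FRONTAL_ERSP, PARIETAL
from .fnirs import DEFAULT_DPF, FNIRSRecording, forward_mbll
from .markers import SessionLog
from .pkpd import PRESETS, CEProfile, DoseSchedule, PKModel, _Propagator
from .preprocess import EEGRecording

REQUIRED_FRONTAL = set(FRONTAL_ERSP)
REQUIRED_PARIETAL = set(PARIETAL)

# default band synthesis amplitudes, uV: (conscious, unconscious)
DEFAULT_BAND_GAINS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 2.5),
    "theta": (1.0, 2.0),
    "lower_alpha": (1.5, 3.0),
    "upper_alpha": (1.0, 3.0),
    "beta_gamma": (2.0, 1.0),
}

DEFAULT_CE_THRESHOLD = {"PPF": 1.0, "MDZ": 60.0}  # ug/mL, ng/mL
# middle-dose patient-controlled-sedation protocol boluses
DEFAULT_BOLUS_MG_PER_KG = {"PPF": 0.3, "MDZ": 0.01}
# CE hysteresis (same units): the subject flips unconscious when CE crosses
# the threshold upward and recovers when CE falls below threshold-hysteresis.
# Recovery at a lower CE than loss matches the observed propofol asymmetry;
# without it the closed bolus loop re-crosses the threshold within seconds of
# every recovery and no behavioral ROC (>=5 consecutive hits) can ever occur.
DEFAULT_CE_HYSTERESIS = {"PPF": 0.3, "MDZ": 10.0}


@dataclass
class SessionConfig:
    """Conditions for one synthetic patient-controlled-sedation session."""

    duration_s: float = 3600.0
    stim_interval_bounds: tuple[float, float] = (9.0, 11.0)
    drug: str = "PPF"
    bolus_mg_per_kg: float | None = None  # None -> middle-dose protocol default
    lockout_s: float = 60.0
    baseline_delay_s: float = 300.0   # pre-induction period: pump not armed
    weight_kg: float = 70.0
    ce_threshold: float | None = None    # drug units; None -> per-drug default
    ce_hysteresis: float | None = None   # drug units; None -> per-drug default
    eeg_fs: float = 500.0
    fnirs_fs: float = 15.625
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    band_gains: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_GAINS))
    noise_exponent: float = 1.0
    noise_rms_uv: float = 1.0
    coherent_fraction: float = 0.5
    posterior_alpha_gain: float = 2.5
    private_bandwidth_hz: float = 1.0
    ramp_s: float = 30.0
    anteriorization_gain: float = 2.0
    fp_phase_step_deg: float = 90.0
    latency_median_s: float = 0.6
    latency_sigma: float = 0.35
    n_fnirs_channels: int = 14
    fnirs_distance_cm: float = 3.0
    hbo_bump_um: float = 0.5
    hbr_bump_um: float = 0.2
    bump_width_s: float = 120.0
    fnirs_noise_um: float = 0.05
    stage: str = "non_scaling"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.stim_interval_bounds
        if not 0 < lo <= hi:
            raise ValueError("stim interval bounds must be positive, min <= max")
        if self.drug not in PRESETS:
            raise ValueError(f"unknown drug {self.drug!r}")
        if self.bolus_mg_per_kg is None:
            self.bolus_mg_per_kg = DEFAULT_BOLUS_MG_PER_KG[self.drug]
        for name in ("duration_s", "bolus_mg_per_kg", "lockout_s", "weight_kg",
                     "eeg_fs", "fnirs_fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        missing = (REQUIRED_FRONTAL | REQUIRED_PARIETAL) - set(self.channel_labels)
        if missing:
            raise ValueError(f"montage must include {sorted(missing)}")
        if self.ce_threshold is None:
            self.ce_threshold = DEFAULT_CE_THRESHOLD[self.drug]
        if self.ce_hysteresis is None:
            self.ce_hysteresis = DEFAULT_CE_HYSTERESIS[self.drug]
        if self.ce_hysteresis < 0:
            raise ValueError("ce_hysteresis must be >= 0")
        if self.baseline_delay_s < 0:
            raise ValueError("baseline_delay_s must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    state_times_s: np.ndarray          # PK simulation grid
    state_series: np.ndarray           # 1 = unconscious, on [LOC_i, ROC_i)
    true_markers: list[tuple[str, float]]
    ce_profile: CEProfile
    true_hbo: np.ndarray               # channels x fNIRS samples, uM
    true_hbr: np.ndarray
    true_band_envelopes: dict[str, np.ndarray]  # band -> channels x env samples
    envelope_fs: float
    no_transition: bool = False

    def marker_times(self, kind: str) -> np.ndarray:
        return np.array([t for k, t in self.true_markers if k == kind])


@dataclass
class SyntheticSession:
    config: SessionConfig
    log: SessionLog
    eeg: EEGRecording
    fnirs: FNIRSRecording
    doses: DoseSchedule
    truth: GroundTruth


def _simulate_behavior(
    config: SessionConfig, model: PKModel, rng: np.random.Generator
) -> tuple[SessionLog, DoseSchedule, GroundTruth]:
    """Closed-loop stimulus/response/bolus/CE simulation on a 0.1 s grid."""
    lo, hi = config.stim_interval_bounds
    # pre-draw stimulus onsets (independent of state)
    gaps = rng.uniform(lo, hi, size=int(config.duration_s / lo) + 2)
    stimuli = np.cumsum(gaps)
    stimuli = stimuli[stimuli < config.duration_s]

    dt = 0.1
    times = np.arange(0.0, config.duration_s + dt / 2, dt)
    a = model.system_matrix(config.weight_kg) / 60.0
    b = np.zeros(a.shape[0])
    b[0] = 1.0
    prop = _Propagator(a, b)
    dose_mg = config.bolus_mg_per_kg * config.weight_kg
    thr_loc = config.ce_threshold / model.unit_scale     # mg/L internally
    thr_roc = (config.ce_threshold - config.ce_hysteresis) / model.unit_scale

    x = np.zeros(a.shape[0])
    cur_t = 0.0
    unconscious = False
    last_bolus = -np.inf
    responses: list[float] = []
    boluses: list[float] = []
    markers: list[tuple[str, float]] = []
    state = np.zeros(times.size, dtype=np.int8)
    cp = np.zeros(times.size)
    ce = np.zeros(times.size)
    pending: list[float] = []   # scheduled response times, sorted
    stim_i = 0
    prev_ce = 0.0

    for g in range(1, times.size):
        tg = times[g]
        # events inside (times[g-1], tg]
        while True:
            next_stim = stimuli[stim_i] if stim_i < stimuli.size else np.inf
            next_resp = pending[0] if pending else np.inf
            te = min(next_stim, next_resp)
            if te > tg:
                break
            x = prop.step(x, te - cur_t, 0.0)
            cur_t = te
            if next_resp <= next_stim:
                pending.pop(0)
                responses.append(te)
                if (te >= config.baseline_delay_s
                        and te - last_bolus >= config.lockout_s):
                    x[0] += dose_mg
                    last_bolus = te
                    boluses.append(te)
            else:
                stim_i += 1
                if not unconscious:
                    lat = rng.lognormal(np.log(config.latency_median_s),
                                        config.latency_sigma)
                    nxt = stimuli[stim_i] if stim_i < stimuli.size else \
                        config.duration_s
                    lat = min(lat, max(nxt - te - 1e-3, 1e-3))
                    pending.append(te + lat)
                    pending.sort()
        x = prop.step(x, tg - cur_t, 0.0)
        cur_t = tg
        ce_g = x[-1]
        if not unconscious and ce_g >= thr_loc:
            frac = 0.0 if ce_g == prev_ce else \
                (thr_loc - prev_ce) / (ce_g - prev_ce)
            markers.append(("LOC", times[g - 1] + np.clip(frac, 0, 1) * dt))
            unconscious = True
            pending.clear()    # command processing stops at LOC
        elif unconscious and ce_g < thr_roc:
            frac = 0.0 if ce_g == prev_ce else \
                (thr_roc - prev_ce) / (ce_g - prev_ce)
            markers.append(("ROC", times[g - 1] + np.clip(frac, 0, 1) * dt))
            unconscious = False
        prev_ce = ce_g
        state[g] = np.int8(unconscious)
        cp[g] = x[0]
        ce[g] = ce_g

    v1 = model.central_volume_l(config.weight_kg)
    profile = CEProfile(times_s=times, cp=cp / v1 * model.unit_scale,
                        ce=ce * model.unit_scale, model=model)
    log = SessionLog(stimuli=stimuli, responses=np.asarray(responses),
                     boluses=np.asarray(boluses), stage=config.stage)
    doses = DoseSchedule(events=[(t, dose_mg, 0.0) for t in boluses],
                         weight_kg=config.weight_kg)
    kinds = [k for k, _ in markers]
    no_transition = "LOC" not in kinds or "ROC" not in kinds
    truth = GroundTruth(
        state_times_s=times, state_series=state, true_markers=markers,
        ce_profile=profile, true_hbo=np.empty((0, 0)), true_hbr=np.empty((0, 0)),
        true_band_envelopes={}, envelope_fs=0.0, no_transition=no_transition,
    )
    return log, doses, truth


def _logistic_state(t: np.ndarray, markers: list[tuple[str, float]],
                    ramp_s: float) -> np.ndarray:
    """Smooth 0..1 consciousness->unconsciousness level with logistic ramps."""
    k = 8.0 / ramp_s
    s = np.zeros_like(t)
    for kind, tm in markers:
        sig = 1.0 / (1.0 + np.exp(-np.clip(k * (t - tm), -60, 60)))
        s += sig if kind == "LOC" else -sig
    return np.clip(s, 0.0, 1.0)


def _binary_state(t: np.ndarray, markers: list[tuple[str, float]]) -> np.ndarray:
    """Exact unconscious indicator: 1 on [LOC_i, ROC_i)."""
    s = np.zeros(t.size, dtype=bool)
    times = [tm for _, tm in markers]
    kinds = [k for k, _ in markers]
    # markers alternate; count of boundaries passed determines state
    idx = np.searchsorted(np.asarray(times), t, side="right")
    if kinds and kinds[0] == "LOC":
        s = idx % 2 == 1
    elif kinds:  # starts with ROC (cannot happen from _simulate_behavior)
        s = idx % 2 == 0
    return s


def one_over_f_noise(n: int, exponent: float, rms: float,
                     fs: float, rng: np.random.Generator) -> np.ndarray:
    """Spectrally shaped Gaussian noise with power spectrum 1/f^exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n)
    x *= rms / np.sqrt(np.mean(x ** 2))
    return x


ALPHA_BANDS = ("lower_alpha", "upper_alpha")


def _narrowband_quadratures(
    t: np.ndarray, bandwidth_hz: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Slowly varying unit-variance quadrature pair (Rayleigh-fading tone).

    Complex Gaussian baseband noise drawn at ``bandwidth_hz`` and linearly
    interpolated to the full grid; modulating a carrier with it yields a
    narrowband process (waxing-waning rhythm) instead of a pure sinusoid.
    """
    n_slow = max(int(np.ceil((t[-1] - t[0]) * bandwidth_hz)) + 2, 4)
    t_slow = t[0] + np.arange(n_slow) / bandwidth_hz
    zr = np.interp(t, t_slow, rng.standard_normal(n_slow))
    zi = np.interp(t, t_slow, rng.standard_normal(n_slow))
    # linear interpolation of white noise lowers the variance; restore it
    scale = 1.0 / np.sqrt(2.0 / 3.0)
    return zr * scale, zi * scale


def synth_band_eeg(
    t: np.ndarray,
    smooth_state: np.ndarray,
    binary_state: np.ndarray,
    channel_labels: tuple[str, ...],
    band_gains: dict[str, tuple[float, float]],
    rng: np.random.Generator,
    fs: float,
    noise_exponent: float = 1.0,
    noise_rms_uv: float = 1.0,
    anteriorization_gain: float = 2.0,
    fp_phase_step_deg: float = 0.0,
    coherent_fraction: float = 0.5,
    posterior_alpha_gain: float = 2.5,
    private_bandwidth_hz: float = 1.0,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Band-oscillation + 1/f-noise EEG for arbitrary state trajectories.

    Each band oscillates at the band midpoint.  Per channel the oscillation
    mixes a coherent carrier shared by all channels (``coherent_fraction``
    of the power) with a private narrowband component (independent
    Rayleigh-fading tone, ``private_bandwidth_hz`` wide) — scalp rhythms
    are only partially coherent across sites, and a fully coherent
    oscillator would be annihilated by an average reference.  Amplitudes
    are modulated per channel between the conscious and unconscious gain:
    frontal channels get ``anteriorization_gain`` on the unconscious
    upper-alpha gain, parietal channels get ``posterior_alpha_gain`` on the
    conscious alpha gains (eyes-closed posterior alpha dominance), and
    parietal channels get a phase offset of ``fp_phase_step_deg`` on the
    upper-alpha carrier while unconscious, creating a fronto-parietal phase
    step at each transition.  Returns (channels x samples data in uV,
    band -> per-channel unconscious gains).
    """
    if not 0.0 <= coherent_fraction <= 1.0:
        raise ValueError("coherent_fraction must be in [0, 1]")
    frontal = set(FRONTAL_ERSP) | set(FRONTAL_COH)
    parietal = set(PARIETAL)
    n_ch = len(channel_labels)
    data = np.zeros((n_ch, t.size))
    envelope_gains: dict[str, np.ndarray] = {}
    w_coh = np.sqrt(coherent_fraction)
    w_priv = np.sqrt(1.0 - coherent_fraction)
    step_rad = np.deg2rad(fp_phase_step_deg) * binary_state
    for name, (g_c, g_u) in band_gains.items():
        f_c = DEFAULT_BANDS[name].center
        phi = rng.uniform(0.0, 2.0 * np.pi)
        theta = 2.0 * np.pi * f_c * t + phi
        sin_t, cos_t = np.sin(theta), np.cos(theta)
        if name == "upper_alpha" and fp_phase_step_deg != 0.0:
            # carrier with the state-dependent parietal phase offset
            sin_shift = sin_t * np.cos(step_rad) + cos_t * np.sin(step_rad)
        else:
            sin_shift = sin_t
        del theta
        # envelopes shared by all channels with the same gain pair
        env_cache: dict[tuple[float, float], np.ndarray] = {}
        gains = np.empty(n_ch)
        for c, ch in enumerate(channel_labels):
            g_u_eff = g_u * anteriorization_gain \
                if (name == "upper_alpha" and ch in frontal) else g_u
            g_c_eff = g_c * posterior_alpha_gain \
                if (name in ALPHA_BANDS and ch in parietal) else g_c
            use_shift = name == "upper_alpha" and ch in parietal
            gains[c] = g_u_eff
            key = (g_c_eff, g_u_eff)
            if key not in env_cache:
                env_cache[key] = g_c_eff + (g_u_eff - g_c_eff) * smooth_state
            env = env_cache[key]
            zr, zi = _narrowband_quadratures(t, private_bandwidth_hz, rng)
            carrier = sin_shift if use_shift else sin_t
            osc = w_coh * carrier + w_priv * (zr * sin_t + zi * cos_t)
            data[c] += env * osc
        envelope_gains[name] = gains
    for c in range(n_ch):
        data[c] += one_over_f_noise(t.size, noise_exponent, noise_rms_uv,
                                    fs, rng)
    return data, envelope_gains


def _raised_cosine(t: np.ndarray, center: float, width_s: float) -> np.ndarray:
    u = (t - center) / width_s
    out = np.zeros_like(t)
    sel = np.abs(u) <= 0.5
    out[sel] = 0.5 * (1.0 + np.cos(2.0 * np.pi * u[sel]))
    return out


def generate_session(config: SessionConfig) -> SyntheticSession:
    """Generate one complete synthetic session.

    Same config and seed give bit-identical outputs.  If the CE never
    crosses the threshold the session is flagged ``no_transition`` on the
    ground truth rather than raising.
    """
    seq = np.random.SeedSequence(config.seed)
    rng_beh, rng_eeg, rng_fnirs = [np.random.default_rng(s)
                                   for s in seq.spawn(3)]
    model = PRESETS[config.drug]
    log, doses, truth = _simulate_behavior(config, model, rng_beh)

    # ---- EEG ----
    n_eeg = int(round(config.duration_s * config.eeg_fs))
    t_eeg = np.arange(n_eeg) / config.eeg_fs
    smooth = _logistic_state(t_eeg, truth.true_markers, config.ramp_s)
    binary = _binary_state(t_eeg, truth.true_markers)
    data, _ = synth_band_eeg(
        t_eeg, smooth, binary, config.channel_labels, config.band_gains,
        rng_eeg, config.eeg_fs, config.noise_exponent, config.noise_rms_uv,
        config.anteriorization_gain, config.fp_phase_step_deg,
        config.coherent_fraction, config.posterior_alpha_gain,
        config.private_bandwidth_hz,
    )
    eeg = EEGRecording(data=data, fs=config.eeg_fs,
                       channel_labels=list(config.channel_labels))

    # ground-truth envelopes at a coarse grid (they vary on the ramp scale)
    env_fs = 10.0
    t_env = np.arange(int(round(config.duration_s * env_fs))) / env_fs
    smooth_env = _logistic_state(t_env, truth.true_markers, config.ramp_s)
    frontal = set(FRONTAL_ERSP) | set(FRONTAL_COH)
    parietal = set(PARIETAL)
    envelopes = {}
    for name, (g_c, g_u) in config.band_gains.items():
        env = np.empty((len(config.channel_labels), t_env.size))
        for c, ch in enumerate(config.channel_labels):
            g_u_eff = g_u * config.anteriorization_gain \
                if (name == "upper_alpha" and ch in frontal) else g_u
            g_c_eff = g_c * config.posterior_alpha_gain \
                if (name in ALPHA_BANDS and ch in parietal) else g_c
            env[c] = g_c_eff + (g_u_eff - g_c_eff) * smooth_env
        envelopes[name] = env

    # ---- fNIRS ----
    n_f = int(round(config.duration_s * config.fnirs_fs))
    t_f = np.arange(n_f) / config.fnirs_fs
    n_fch = config.n_fnirs_channels
    bump = np.zeros(t_f.size)
    for _, tm in truth.true_markers:
        bump += _raised_cosine(t_f, tm, config.bump_width_s)
    hbo = np.empty((n_fch, n_f))
    hbr = np.empty((n_fch, n_f))
    smooth_win = max(1, int(round(10.0 * config.fnirs_fs)))
    # unit-RMS smoothed noise so fnirs_noise_um is the actual noise SD
    kernel = np.ones(smooth_win) / np.sqrt(smooth_win)
    for c in range(n_fch):
        slow_o = np.convolve(rng_fnirs.standard_normal(n_f), kernel, "same")
        slow_r = np.convolve(rng_fnirs.standard_normal(n_f), kernel, "same")
        hbo[c] = config.hbo_bump_um * bump + config.fnirs_noise_um * slow_o
        hbr[c] = config.hbr_bump_um * bump + config.fnirs_noise_um * slow_r
    dod = forward_mbll(hbo, hbr, distances_cm=config.fnirs_distance_cm,
                       dpf=dict(DEFAULT_DPF))
    fnirs = FNIRSRecording(dod=dod, wavelengths_nm=(760.0, 850.0),
                           fs=config.fnirs_fs,
                           distances_cm=config.fnirs_distance_cm,
                           dpf=dict(DEFAULT_DPF))

    truth = replace(truth, true_hbo=hbo, true_hbr=hbr,
                    true_band_envelopes=envelopes, envelope_fs=env_fs)
    return SyntheticSession(config=config, log=log, eeg=eeg, fnirs=fnirs,
                            doses=doses, truth=truth)


def generate_response_sequence(
    pattern: list[bool],
    interval_s: float = 10.0,
    latency_s: float = 0.5,
    stage: str = "non_scaling",
) -> SessionLog:
    """Deterministic SessionLog: stimulus i is answered iff pattern[i]."""
    if len(pattern) == 0:
        raise ValueError("pattern must be non-empty")
    if not 0 < latency_s < interval_s:
        raise ValueError("latency must lie within the stimulus interval")
    stimuli = interval_s * (1.0 + np.arange(len(pattern)))
    responses = stimuli[np.asarray(pattern, dtype=bool)] + latency_s
    return SessionLog(stimuli=stimuli, responses=responses,
                      boluses=np.empty(0), stage=stage)
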