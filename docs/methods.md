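# Methods

This note documents the models implemented in `sedyn`, their assumptions,
the defaults that matter, and the design decisions taken where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Behavioral transition markers

Commands ("press the button") arrive every 9–11 s, uniformly at random. A
press belongs to command *i* iff it falls strictly between the onsets of
commands *i* and *i+1*; the first press in an interval wins. LOC is
stamped at the onset of the first missed command of each maximal run of
≥10 misses immediately preceded by a maximal run of ≥5 hits; ROC at the
onset of the first answered command of each ≥5-hit run immediately
preceded by ≥10 misses. A command-onset anchor is used because epochs are
aligned to the marker and onsets are reproducible under resampling.

Two edge rules are ours: (i) the raw run rule can emit two consecutive
LOCs with no qualifying ROC between them (e.g. 5 hits, 10 misses, 2 hits,
3 misses, 5 hits, 10 misses); the detector therefore applies a greedy
alternation filter — start at the first LOC, then keep the next marker of
opposite kind — on by default and verified against an independent
brute-force scan that applies the same filter. (ii) A terminal miss-run
shorter than 10 at session end emits no marker.

## Synthetic sessions

The generator is the package's ground-truth instrument; its defaults are
the study conditions it emulates.

**Closed behavioral loop.** Stimulus onsets are drawn first (uniform 9–11 s
gaps). The pharmacokinetic state advances on a 0.1 s grid by exact matrix
exponentials; each answered command past the 300 s pre-induction baseline
delivers a bolus if the 60 s lockout has elapsed (middle-dose protocol:
0.3 mg/kg propofol or 0.01 mg/kg midazolam). Response latency is
lognormal (median 0.6 s, σ=0.35, capped below the next stimulus) — a
stand-in; only its positivity and cap matter. Consciousness is
deterministic in the effect-site concentration: unconscious when CE
crosses the threshold upward (propofol 1.0 µg/mL, midazolam 60 ng/mL),
conscious again when CE falls below threshold − hysteresis (0.3 µg/mL /
10 ng/mL). The hysteresis is essential, not cosmetic: recovery at exactly
the loss threshold would let the very first post-recovery bolus re-cross
it within seconds, so no ≥5-hit conscious run — hence no detectable
behavioral ROC — could ever occur; recovery at a lower CE than loss is
also what propofol subjects show empirically. Under these defaults a
default 3600 s propofol session produces conscious runs of ~75–90 s,
unconscious runs of ~10 min and 4–5 LOC/ROC cycles; midazolam produces
2 LOC / 1 ROC per hour with ~160 s conscious runs, matching the reported
cycle counts for the two drugs.

**EEG.** Each band (delta/theta/lower alpha/upper alpha/beta-gamma)
oscillates at its midpoint frequency (e.g. 13.5 Hz for upper alpha). Per
channel the oscillation mixes a coherent carrier shared by all channels
(`coherent_fraction`, default 0.5 of power) with an independent
narrowband Rayleigh-fading component (bandwidth 1 Hz): scalp rhythms are
only partially coherent across sites, and a fully coherent oscillator
would be annihilated or phase-scrambled by the average reference.
Band amplitudes ramp between the conscious and unconscious gains through
a 30 s logistic (transitions in sedation spectra are gradual): defaults,
in µV — delta (1, 2.5), theta (1, 2), lower alpha (1.5, 3), upper alpha
(1, 3), beta/gamma (2, 1). Frontal channels get ×2 on the unconscious
upper-alpha gain (anteriorization); parietal channels get ×2.5 on the
conscious alpha gains (eyes-closed posterior dominance) and a +90° phase
offset on the upper-alpha carrier while unconscious, injecting a
fronto-parietal phase step of known time and size. 1/f noise (exponent 1,
1 µV RMS) is added per channel. The generator synthesizes at 500 Hz:
content is band-limited to ≤40 Hz, and 500 Hz keeps the integer 5×
decimation to the 100 Hz analysis rate.

**fNIRS.** True ΔHbO/ΔHbR per channel are raised-cosine bumps (0.5 /
0.2 µM, 2 min wide) centered at each transition plus slow Gaussian noise
(0.05 µM, 10 s smoothing); optical densities follow by the exact forward
Beer–Lambert model, so inversion closes the loop to machine precision.
14 channels at 15.625 Hz, 3 cm source–detector separation.

**What the generator does not emulate:** artifacts (blinks, movement,
scaler noise), volume conduction and realistic head geometry, drifting
electrode impedances, inter-subject PK variability, or any coupling of
hemodynamics to the EEG beyond shared transition times. Passing tests
demonstrate that the analysis recovers known structure under these
idealized conditions; they do not certify artifact robustness on real
recordings.

## Preprocessing

Down-sampling applies a 10th-order Chebyshev type-I low-pass
forward–backward (zero phase) before integer decimation; cutoff 0.8× the
target Nyquist. The filter is normalized to unit DC gain and uses 0.01 dB
design ripple: scipy's even-order Chebyshev-I has −ripple dB at DC, and a
0.05 dB ripple would double under filtfilt to ~1.2% amplitude error,
defeating the <1% passband-fidelity goal; with normalization and 0.01 dB
the passband error stays below 0.25%. Re-referencing subtracts the
instantaneous across-channel mean (a reference-at-infinity scheme would
require a lead-field matrix; average reference preserves all downstream
math). Epoch windows: LOC (−60, +180) s, ROC (−180, +60) s, baseline =
300 s ending at the first bolus, recovery = 240 s ending at stage end;
half-open `[t0, t1)`, marker sample = floor(t·fs), trials whose window
leaves the recording are dropped with a warning, never padded.

## Time–frequency analysis

Complex Morlet atoms on an explicit grid (default 0.5–40 Hz, 0.5 Hz
steps); cycles increase linearly from 3 at the lowest frequency at 0.5
cycles/Hz; σ_t = n/(2πf), atoms truncated at ±3σ_t and amplitude-
normalized so a pure tone of amplitude A gives |F| = A. Samples within
the truncated half-support of an epoch edge are flagged invalid and
excluded (NaN) from every downstream statistic — no mirroring, no
fabricated data. Because the frequency grid is explicit, the FFT
zero-padding ratio of toolbox implementations has no counterpart here and
is not exposed. ERSP is computed in dB (10·log₁₀ of power); baseline
normalization subtracts the time-averaged baseline spectrum per channel
and frequency, in the dB domain.

## Phase connectivity

ERPCOH follows the cross-spectral definition `a·b*`, so its angle is
phase(a) − phase(b): the first channel lagging by τ yields −360·f·τ
degrees; this sign convention is locked by a delay test. Aggregation over
the 25 fronto-parietal pairs and over band bins averages complex phasors,
never raw angles (no wrap-around bias). Block averaging uses
non-overlapping 20 s windows on the complex values; Savitzky–Golay
smoothing (order 3, 5-block window — declared defaults) is applied to the
real and imaginary block series before the final angle, keeping the
operation circular-safe. The pipeline computes connectivity on the
recorded (unreferenced) signals: subtracting the channel mean mixes the
common mode into every pair and systematically distorts pairwise phase —
the classic reference problem in EEG connectivity — while ERSP keeps the
average reference, where it is standard.

## PK/PD simulation

The compartment system plus effect site is linear, so the solver
propagates exact matrix exponentials between dose events and grid points;
piecewise-constant infusions use the augmented-matrix construction (valid
even with zero elimination). Boluses are instantaneous jumps in the
central amount by default; finite-duration events are zero-order
infusions. Presets are citation-tagged configuration, not results:
propofol uses the Marsh adult compartmental constants with the classic
0.26/min effect-site constant — a fast (≥1/min) ke0 equilibrates the
effect site in under a minute and collapses the conscious runs of the
closed loop below the behavioral detection limit — and midazolam uses
approximate adult two-compartment values (CL ≈ 0.4 L/min/70 kg,
ke0 = 0.14/min), flagged approximate. Concentrations are reported in each
drug's native unit (µg/mL, ng/mL); no cross-drug conversion. The engine
is parameter-agnostic and no test depends on preset numbers.

## fNIRS conversion and statistics

The modified Beer–Lambert law is inverted per channel and sample by exact
2×2 solve; extinction coefficients default to the Prahl/Cope hemoglobin
compilation (760 nm: 586 / 1548.52; 850 nm: 1058 / 691.32 cm⁻¹M⁻¹) and
differential pathlength factors to adult-head values (6.1 / 5.8), both
overridable. Baseline correction subtracts the mean of the first 3 min;
smoothing is a centered 1.5 min moving average (edges use available
samples). Marker-locked averages use windows (−4, +6) min for LOC and
(−6, +4) min for ROC; per-timepoint one-sample t-tests against zero at
α = 0.05 are uncorrected by default, matching the shaded-interval
presentation convention (a Bonferroni switch exists), and contiguous
significant runs are reported as intervals.

## Interval statistics

The per-subject summary is mean dB over the frontal channels {AF3, AF4,
F1, F2, Fz}, a band's grid bins, and a named 10 s interval (pre = first
10 s of the epoch window, transition = ±5 s, post/recovery = last 10 s).
Contrasts are paired two-sided t-tests on (pre − post), so power
increases after LOC give negative t for the low-frequency bands and
positive t for beta/gamma. No correction across the five bands by
default.

## Problem sizes and verification

The test suite and acceptance script verify: epoch arithmetic (24000
samples for the −1/+3 min window at 100 Hz); the ERSP and ERPCOH
definitions against scalar triple-loop oracles (1e-12) and the FFT
convolution against direct inner products (1e-8); the marker rule against
an exhaustive brute-force scan (100 random 200-stimulus sequences); the
PK/PD engine against the bi-exponential closed form (1e-8), superposition
(1e-12), mass balance and an adaptive-ODE cross-check; Beer–Lambert
round-trip closure (1e-10); end-to-end ground-truth recovery on 20
independent default sessions (every rule-visible marker — one followed by
enough stimuli to qualify a run; a transition in the last few commands of
a session is structurally invisible to the run rule — within one stimulus
interval,
upper-alpha rise/fall across LOC/ROC by sign test, post-LOC
anteriorization, phase-step localization within one 20 s block, fNIRS
bump detection); and null calibration (paired-contrast type-I error over
200 equal-gain cohorts of 12 subjects; per-timepoint fNIRS flag fraction
under pure noise). The acceptance script defaults to 10 sessions for the
recovery block; the cohort and fuzz sizes above are the package's chosen
verification sizes.

## Known limitations

- The marker rule is exact and binary; no probabilistic state estimation.
- Average reference approximates the reference-free ideal; topographies
  are interpretable only relative to it.
- PK presets are adult population values without covariate adjustment
  beyond weight; the midazolam preset is approximate.
- Per-timepoint fNIRS significance is uncorrected by design; interpret
  interval counts, not individual flags.
- The generator's idealizations (above) bound what green tests prove
  about real recordings.
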