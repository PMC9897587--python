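# Methods

## Task patterns

All patterns are explicit event grids in milliseconds, origin at the first
click of the first passive-listening cycle. A cycle has 8 beats in
quadruple meter: positions 1 and 5 are metrically *strong*, other integer
positions *weak*, and positions k+0.5 are *half-beat*. Defaults: inter-onset
interval 500 ms (120 BPM), 2 listen cycles, 3 tapping cycles.

- **1:1 synchronization** — click on every beat, an 1100 Hz / 20 ms beep on
  beats 1–7 of every cycle (beat 8 silent keeps the cycle boundary
  audible).
- **Reproduction** — identical listen cycles, then a silent grid: the
  participant continues the internalized pulse.
- **1:4 synchronization** — full pattern while listening; during tapping
  only beats 1 and 5 are marked. Unmarked weak positions remain part of
  the grid and serve as matching references for the internalized beats.
- **Non-isochronous** — clicks on all 8 beats; beeps on 7 note positions
  per cycle, 5 on-beat and 2 half-beat. The exact positions are a package
  default, `(1, 2, 3.5, 4, 5, 6.5, 7)`, chosen to satisfy the 5+2
  structure with both strong beats marked; they are overridable because
  only the structure, not the exact placement, is normative.
- **Reaction** — beep onsets accumulate inter-onset intervals drawn
  uniformly from [200, 800] ms over one minute ("quasi-flat" is
  implemented as exactly uniform, the simplest consistent choice); no
  listen phase.

## Tap extraction

Envelope: Chebyshev type I low-pass (order 4, 0.5 dB passband ripple,
100 Hz cutoff) applied forward–backward (`sosfiltfilt`) to the rectified
force, so pulse peaks keep their position. The even-order Chebyshev design
sits at the ripple floor at DC; the filter is renormalized to unity DC
gain so constant force levels pass unchanged. Order/ripple are exposed
defaults, not measurement claims.

Normalization divides by the task-wise maximum; the 20 % peak-height
threshold is therefore an absolute 0.2 on the normalized envelope (global,
not per-tap). Peak picking enforces a 200 ms minimum inter-peak distance
greedily by amplitude priority; each surviving peak is then shifted to the
earliest above-threshold local maximum inside its left suppression
half-window — rebound bounces trail the strike, so the first sharp peak is
the tap instant — unless the shift would break the spacing guarantee.

Synthetic fixtures render at 2 kHz rather than an acquisition-grade
20 kHz; the sampling rate is a free parameter everywhere, and at 2 kHz the
50 ms Hann force pulses are already oversampled 100-fold relative to the
analysis cutoff. Detection on noiseless rendered recordings recovers every
tap within 5 ms (in practice well under 1 ms).

## Matching and descriptors

Matching is tap-driven: every tap joins the reference event minimizing
|Δt|; pulses may go unmatched (missed beats) or be matched twice (extra
taps). The asynchrony is wrapped into the half-open interval
[−IOI/2, +IOI/2); a tap exactly midway between pulses is assigned to the
*later* pulse with asynchrony −IOI/2, so −180° is attainable and +180°
excluded. In the non-isochronous task the references are the 7 note
positions (half-beat taps get half-beat references); in the 1:4 task all 8
grid positions are references regardless of marking.

PLV's denominator is the number of matched taps in the window (the
statistic divides by the number of phase vectors, not pulses); stabilized
windows pool the 16 taps of cycles 2–3 rather than averaging per cycle.
Windowing is by matched reference cycle for paced trains (an early tap
belonging to cycle 2's downbeat lands in the stabilized window even though
it precedes the cycle boundary in time) and ordinal (taps 1–8 / 9–24) for
unpaced and reaction trains. Short trains return the partial window with a
warning rather than failing.

All SDs (CV, RT and TF variability) use the sample (n−1) convention —
trains are short, and the convention is stated because it matters at
n = 16. The drift regression reports the raw OLS slope of ITI on interval
index with its two-sided t-test p-value; since a positive slope means
intervals lengthen, *negative* slopes are labeled acceleration. The
descriptor × task × window design matrix lives in
`TASK_WINDOW_DESCRIPTORS`; drift in the reproduction task is evaluated
over the full 24-tap train and attached to either window's summary.

## Virtual participants

Paced asynchronies are wrapped normal rather than von Mises: asynchrony is
naturally a quantity in ms on a line segment, the wrap only enforces the
matching convention, and at realistic dispersions (≈25°) the two are
indistinguishable. Unpaced trains follow the two-level timing model
ITIₙ = target + drift·n + Cₙ + Mₙ₊₁ − Mₙ with independent normal clock
(C) and motor (M) terms; the telescoping motor delays give the model's
diagnostic lag-1 ITI autocovariance of −motor_sd². Reaction latencies are
normal truncated at zero; a response that would land after the next
stimulus onset is skipped.

Preset parameters: pooled mean phase angle −29.4°, group difference
−10.8° applied symmetrically (fluent-like −24.0°, stutter-like −34.8°),
mean reaction time 232 ms for both groups, and stutter-like unpaced timing
SDs scaled by exp(0.24) so the groups' log-CV difference is exactly 0.24.
Dispersions are not published at the individual level, so the package
chooses once: within-train phase-angle SD 25° (implying PLV ≈ 0.91, a
realistic consistency for healthy adults at 500 ms), reaction-time SD
40 ms, clock/motor SDs 20/10 ms (unpaced CV ≈ 4.9 %, typical for
continuation tapping at this period), force base 0.70 a.u. with +0.019
strong-beat and −0.073 half-beat offsets and 0.05 noise, lapse rates
p_miss = 0.02 and p_extra = 0.01. Presets are parameter bundles for
simulation, not claims about any population.

What the generator does *not* emulate: phase-error correction dynamics
(each paced asynchrony is independent), learning across cycles, amplitude
drift, sensor nonlinearity, movement artifacts, or audio bleed-through
between channels. Passing recovery tests therefore shows the analysis
chain is correct and well-calibrated under the stated generative model —
not that it is robust to every artifact of laboratory recordings.

## Statistics

Group contrasts are seeded label-permutation tests on one aggregated value
per participant × condition (mean difference, or circular-mean difference
for angles), with p = (1 + #{|T*| ≥ |T|}) / (1 + n_perm). This preserves
the inference target of participant-level mixed models at desk scale
without refitting them; reaction time and CV are compared on the log
scale and PLV on the logit scale (clipped at 10⁻⁶ with a reported clip
count). Raw p-values are reported; a Bonferroni flag is available but off
by default. The circular mean raises an error on a zero resultant, and
the ±180° boundary resolves to −180° to match the asynchrony convention.

## Problem sizes and determinism

Tests and the acceptance script simulate dozens of trials at 2 kHz —
enough for 3-standard-error Monte-Carlo bands of a few degrees/ms on the
recovered means. Every stochastic step takes an explicit seed
(`numpy.random.default_rng`); pipeline outputs embed the resolved
configuration, and fixed seed + fixed inputs reproduce CSV outputs
byte-for-byte.

## Known limitations

- Tap detection assumes unipolar force pulses well separated relative to
  the 200 ms suppression window; reaction tasks with sub-200 ms stimulus
  gaps can merge fast consecutive responses (the same limit applies to
  any fixed-distance peak picker).
- CV and PE are computed over detected taps; a missed beat folds a
  double-length interval into the train and inflates both. Handling of
  such trains is a design decision the analysis leaves to the user (the
  ground-truth tables make lapses identifiable in simulation).
- The non-isochronous note placement is a structural default, not a
  measured stimulus.
- Matching is purely nearest-reference; it does not model intentional
  off-beat tapping styles.
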