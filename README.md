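# synctap

Analysis pipeline for sensorimotor synchronization (paced and unpaced
rhythmic finger tapping) experiments, plus a virtual-participant simulator
so the whole chain can be exercised and validated without human data.

The package is aimed at motor-timing researchers who record finger taps as
a force signal alongside the auditory stimulus channel and want the
standard descriptors of synchronization behavior: tap-to-beat asynchrony
and its angular form, phase-locking value, inter-tap-interval variability,
period reproduction error, drift, reaction times, and tapping force by
metrical position.

## The measures

A tap at time *t* matched to its nearest reference pulse at *r* on a grid
with inter-onset interval IOI has asynchrony *a = t − r*, wrapped into
[−IOI/2, +IOI/2), and phase angle

&nbsp;&nbsp;&nbsp;&nbsp;PA = a · 360 / IOI  (degrees, in [−180, +180))

Over a train of N taps the phase-locking value is the mean resultant
length of the unit phase vectors,

&nbsp;&nbsp;&nbsp;&nbsp;PLV = | Σₖ e^(i·PAₖ) | / N ∈ [0, 1],

1 for perfectly consistent tap–stimulus phase. Unpaced trains are
summarized by the coefficient of variation of inter-tap intervals
(CV = 100·sd/mean, %), the periodicity error (|mean ITI − target|, ms) and
the OLS drift slope of ITI against tap number. Reaction trains use the
tap-minus-preceding-stimulus time. Healthy paced tapping shows a *negative
mean asynchrony*: taps anticipate the beat by tens of milliseconds.

The simulator generates paced taps with wrapped-normal asynchronies,
unpaced taps with the two-level central-clock/motor-variance timing model
(whose signature is a lag-1 ITI autocovariance of −motor_sd²), and
reaction taps with truncated-normal latencies; group presets encode
published pooled and group-contrast values (pooled mean PA −29.4°, group
difference −10.8°, mean RT 232 ms, log-CV elevation 0.24).

## Worked example

```python
import synctap as st

pattern = st.make_iso_sync_pattern(ioi_ms=500.0, n_tap_cycles=3, n_listen_cycles=2)
params = st.synthetic.pooled_preset(p_miss=0.0, p_extra=0.0)
taps_true, _ = st.simulate_paced(pattern, params, seed=21)
rec = st.render_force(taps_true, pattern, fs_hz=2000.0)
taps = [t for t in st.extract_taps(rec)
        if t.time_ms >= pattern.tap_phase_start_ms - 250.0]
matched = st.match_nearest_pulse(taps, pattern)
summary = st.summarize_train(matched, st.Task.ISO_SYNC_1_1, "stabilized")
print(f"PLV {summary.plv:.3f}  PA {summary.pa_circmean_deg:+.1f} deg  "
      f"CV {summary.cv_percent:.2f} %")
```

prints

```
PLV 0.949  PA -30.7 deg  CV 8.44 %
```

— a synchronization consistency of 0.949 (close to perfect phase locking),
a mean phase angle of −30.7° (the tap anticipates the beat by about 43 ms
at the 500 ms interval, matching the injected −29.4° up to sampling noise),
and an 8.4 % inter-tap-interval CV for the stabilized window (taps 9–24).

More narrative walk-throughs live in `examples/` (stimulus grids, tap
detection, descriptors, the timing models, a permutation group contrast,
a correlation worked example).
A thin command line (`synctap make-stimuli / simulate / detect / describe /
compare`) wraps the same library calls for shell use.

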