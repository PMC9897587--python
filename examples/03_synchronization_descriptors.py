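"""Compute per-tap and per-train synchronization descriptors.

Runs the full pipeline for one virtual participant on the 1:1
synchronization task and prints the stabilized-window (taps 9-24)
descriptors: phase-locking value (PLV, 1 = perfectly consistent
synchronization), circular-mean phase angle (negative = tapping ahead of
the beat), coefficient of variation of inter-tap intervals, and tapping
force by metrical strength.
"""

import synctap as st

pattern = st.make_iso_sync_pattern(500.0, 3, 2)
# lapse-free for a clean read; a missed tap would fold a ~1000 ms gap
# interval into the CV
params = st.synthetic.pooled_preset(p_miss=0.0, p_extra=0.0)
taps_true, _ = st.simulate_paced(pattern, params, seed=21)
rec = st.render_force(taps_true, pattern, fs_hz=2000.0)
taps = [t for t in st.extract_taps(rec)
        if t.time_ms >= pattern.tap_phase_start_ms - 250.0]

matched = st.match_nearest_pulse(taps, pattern)
summary = st.summarize_train(matched, st.Task.ISO_SYNC_1_1, "stabilized")

print(f"taps in window       : {summary.n_taps}")
print(f"PLV                  : {summary.plv:.3f}")
print(f"mean phase angle     : {summary.pa_circmean_deg:+.1f} deg "
      "(negative = anticipation)")
print(f"CV of intervals      : {summary.cv_percent:.2f} %")
for strength, value in sorted(summary.plv_by_strength.items()):
    n = summary.n_by_strength[strength]
    print(f"PLV on {strength:6s} beats : {value:.3f} (n={n})")
for strength, value in sorted(summary.tf_by_strength.items()):
    print(f"force on {strength:6s} beats: {value:.3f} a.u.")
# A healthy pooled profile: PLV near 0.9, mean phase angle near -30 deg
# (the classic negative mean asynchrony), slightly harder strong beats.
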