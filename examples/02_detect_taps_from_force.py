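"""Detect tap instants in a force recording.

Simulates a virtual participant synchronizing with the 1:1 isochronous
pattern, renders the taps to a 2 kHz force channel, then runs the detection
chain (zero-phase 100 Hz low-pass envelope, task-wise normalization, peak
picking at the 20% threshold with a 200 ms minimum inter-peak distance) and
compares the detected instants with the simulated ground truth.
"""

import numpy as np

import synctap as st

pattern = st.make_iso_sync_pattern(500.0, 3, 2)
params = st.synthetic.pooled_preset(p_miss=0.0, p_extra=0.0)
true_taps, _ = st.simulate_paced(pattern, params, seed=8)
rec = st.render_force(true_taps, pattern, fs_hz=2000.0, noise_sd=0.01, seed=8)

detected = st.extract_taps(rec)
# keep the tapping phase (the two listen cycles contain no taps)
detected = [t for t in detected
            if t.time_ms >= pattern.tap_phase_start_ms - 250.0]

errors = [d.time_ms - t.time_ms for d, t in zip(detected, true_taps)]
print(f"simulated taps : {len(true_taps)}")
print(f"detected taps  : {len(detected)}")
print(f"timing error   : max {np.max(np.abs(errors)):.2f} ms "
      f"(median {np.median(np.abs(errors)):.2f} ms)")
# Detection recovers every rendered tap; errors stay within the sampling
# step plus the smoothing of the 100 Hz envelope (a few ms at most).
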