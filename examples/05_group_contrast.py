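"""Permutation-based group contrast on simulated cohorts.

Simulates 16 stuttering-like and 16 fluent-like virtual participants on the
1:1 synchronization task (two trials each, full render -> detect -> match
chain), aggregates one circular-mean phase angle per participant, and tests
the group difference with a seeded label-permutation test.
"""

import warnings

import numpy as np

import synctap as st
from synctap.descriptors import Window
from synctap.errors import ShortTrainWarning

warnings.simplefilter("ignore", ShortTrainWarning)

pattern = st.make_iso_sync_pattern(500.0, 3, 2)
t_start = pattern.tap_phase_start_ms - pattern.ioi_ms / 2
rng = np.random.default_rng(1234)


def participant_mean_pa(preset: str) -> float:
    angles = []
    for _ in range(2):  # two trials per participant
        taps_true, _ = st.simulate_paced(pattern, st.PRESETS[preset],
                                         seed=int(rng.integers(2**31)))
        rec = st.render_force(taps_true, pattern, fs_hz=2000.0)
        taps = [t for t in st.extract_taps(rec) if t.time_ms >= t_start]
        matched = st.match_nearest_pulse(taps, pattern)
        angles.extend(m.phase_angle_deg
                      for m in st.select_window(matched, Window.STABILIZED,
                                                pattern))
    return st.circular_mean(angles)


pws = [participant_mean_pa("PWS_like") for _ in range(16)]
pns = [participant_mean_pa("PNS_like") for _ in range(16)]

res = st.permutation_test(pws, pns, statistic="circular_mean_diff",
                          n_perm=9999, seed=7)
print(f"mean PA, stutter-like group : {np.mean(pws):+.1f} deg")
print(f"mean PA, fluent-like group  : {np.mean(pns):+.1f} deg")
print(f"group difference            : {res.observed_difference:+.1f} deg "
      f"(injected -10.8)")
print(f"permutation p-value         : {res.p_value:.4f} "
      f"({res.n_permutations} permutations, seed 7)")
# The recovered difference carries the injected sign (stutter-like tapping
# further ahead of the beat); with 16+16 participants the contrast is
# usually significant at the 5% level.
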