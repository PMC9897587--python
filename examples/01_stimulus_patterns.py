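"""Build the five rhythmic-task stimulus patterns and inspect their grids.

Each pattern is an explicit event grid: every 8-beat-cycle position exists,
labeled with its metrical strength, whether a metronome click and/or an
audio beep is played there, and whether it belongs to the passive-listening
phase.
"""

import synctap as st

for name, pattern in [
    ("1:1 synchronization", st.make_iso_sync_pattern(500.0, 3, 2)),
    ("reproduction", st.make_iso_repro_pattern(500.0, 3, 2)),
    ("1:4 synchronization", st.make_one_in_four_pattern(500.0, 3, 2)),
    ("non-isochronous", st.make_noniso_pattern(500.0, 3, 2)),
    ("reaction", st.make_react_sequence(60_000.0, 200.0, 800.0, seed=1)),
]:
    n_click = sum(e.has_click for e in pattern.events)
    n_beep = sum(e.has_beep for e in pattern.events)
    tempo = f"{pattern.tempo_bpm:.0f} BPM" if pattern.ioi_ms else "aperiodic"
    print(f"{name:22s} {len(pattern.events):4d} grid events, "
          f"{n_click:3d} clicks, {n_beep:3d} beeps, {tempo}")

# The 1:1 pattern plays a beep on beats 1-7 of each cycle but never on
# beat 8, and strong beats sit on positions 1 and 5 (quadruple meter):
p = st.make_iso_sync_pattern(500.0, 1, 0)
for e in p.events:
    mark = "click+beep" if e.has_beep else "click     "
    print(f"  t={e.time_ms:6.0f} ms  beat {e.beat_position:.0f} "
          f"({e.strength.value:6s}) {mark}")
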