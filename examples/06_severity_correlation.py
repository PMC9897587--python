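"""Correlation between instrument-scored and self-evaluated severity.

A small worked example of the generic correlation operation: sixteen
adults who stutter, each with a clinician-administered severity-instrument
score and a coarse self-evaluation (1 = mild, 2 = moderate, 3 = severe).
Self-evaluations are ordinal with many ties, so both the Pearson and the
rank-based Spearman coefficients are shown.
"""

import synctap as st

# (instrument score, self-evaluated severity), one pair per participant
severity = [
    (17, 1), (20, 3), (16, 2), (10, 2), (12, 2), (19, 1), (30, 3), (19, 3),
    (26, 3), (26, 3), (10, 2), (13, 1), (19, 2), (18, 1), (18, 2), (34, 3),
]
ssi = [s for s, _ in severity]
self_eval = [e for _, e in severity]

for method in ("pearson", "spearman"):
    r, p = st.correlate(ssi, self_eval, method=method)
    print(f"{method:8s}: r = {r:+.2f}, p = {p:.3f}")
# A moderate positive association: participants who rate themselves more
# severe also score higher on the instrument.
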