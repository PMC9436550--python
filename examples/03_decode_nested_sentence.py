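"""Walk through the decoding pipeline on a hand-built score tensor.

Decoding has three stages: per-span argmax over class scores, boundary
gating (keep spans whose endpoints the boundary task marks inside), and a
greedy highest-score-first sweep that removes *crossing* spans while keeping
properly nested ones.
"""

import numpy as np

from nestner import (LabelSet, boundary_gate, predict_span_labels,
                     resolve_overlaps)

tokens = ["the", "colon", "cancer", "patient"]
labels = LabelSet(("ANAT", "DIS"))

# scores[i, j, c]: class c score for span (i, j); class 0 is non-entity
scores = np.zeros((4, 4, 3))
scores[..., 0] = 1.0
scores[1, 2, 2] = 4.0   # "colon cancer"  -> DIS
scores[1, 1, 1] = 3.0   # "colon"         -> ANAT (nested inside the above)
scores[2, 3, 2] = 2.0   # "cancer patient" -> DIS, crosses "colon cancer"

candidates = predict_span_labels(scores, labels)
print("candidates:", [(m.key, m.score) for m in candidates])

# boundary detector: P(inside) per token — "patient" is predicted outside
probs = np.array([[0.9, 0.1], [0.1, 0.9], [0.1, 0.9], [0.6, 0.4]])
gated = boundary_gate(candidates, probs, threshold=0.5)
print("after gate:", [m.key for m in gated])

final = resolve_overlaps(gated)
print("final:     ", [m.key for m in final])
# "colon cancer" (DIS) and the nested "colon" (ANAT) survive: containment is
# legal.  "cancer patient" was removed twice over — its right endpoint failed
# the boundary gate, and it crosses the higher-scoring "colon cancer".
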