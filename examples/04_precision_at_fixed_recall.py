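"""Precision at a fixed recall target, step by step.

High-recall screening fixes recall near 1 and asks what precision is
achievable there: sweep every score threshold, keep those whose recall
reaches the target, take the most conservative one.
"""

import numpy as np

from altriage import precision_at_recall

rng = np.random.default_rng(0)
# 30 relevant documents scoring high-ish, 170 irrelevant scoring low-ish,
# with overlap so the ranking is imperfect
scores = np.concatenate([rng.normal(0.7, 0.15, 30), rng.normal(0.35, 0.15, 170)])
truth = np.array([1] * 30 + [0] * 170)

for target in (0.5, 0.9, 0.99, 1.0):
    p = precision_at_recall(scores, truth, recall_target=target)
    print(f"recall target {target:4.2f} -> precision {p:.3f}")

# Precision falls as the recall target rises: catching the last few
# relevant documents forces the threshold down into the bulk of the
# irrelevant score distribution.
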