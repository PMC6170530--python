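"""AHP priorities and the consistency ratio on judgment matrices."""

import numpy as np

from coupcoord import PairwiseComparisonMatrix, ahp_priority, consistent_pcm

# a perfectly consistent matrix built from known weights is recovered
pcm = consistent_pcm(["tree", "herb", "litter"], [4, 2, 1])
w, lam, ci, cr = ahp_priority(pcm)
print("consistent matrix:", {k: round(v, 4) for k, v in w.items()},
      f"lambda_max={lam:.4f} CR={cr:.4f}")

# a mildly inconsistent 1-9 scale judgment still yields priorities,
# with CR quantifying how contradictory the comparisons are
judged = PairwiseComparisonMatrix(
    ("tree", "herb", "litter"),
    np.array([[1, 2, 5], [1 / 2, 1, 3], [1 / 5, 1 / 3, 1]]),
)
w, lam, ci, cr = ahp_priority(judged)
print("judged matrix:   ", {k: round(v, 4) for k, v in w.items()},
      f"lambda_max={lam:.4f} CR={cr:.4f}")
print("\nCR <= 0.1 is the conventional bar for acceptable judgments.")
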