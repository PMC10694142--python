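"""Deviation and support transforms of prediction probabilities.

The fusion method never consumes raw probabilities directly: each score is
mapped to a deviation (penalty, small when the classifier is confident) and
a support (reward, large when confident).  This script prints both
transforms across the probability range.
"""

import numpy as np

from fuzzyfuse import deviation_scores, support_scores

probs = np.array([0.0, 0.25, 0.5, 0.75, 0.9, 1.0])
dev = deviation_scores(probs)
sup = support_scores(probs)

print("probability  deviation  support")
for p, d, s in zip(probs, dev, sup):
    print(f"{p:>11.2f}  {d:>9.6f}  {s:>7.6f}")

print()
print(f"max deviation over [0,1]: {dev.max():.6f} (at p=0)")
print(f"min support   over [0,1]: {sup.min():.6f} (at p=0)")
print("deviation's whole range sits below support's, so a product of the")
print("two is steered by deviation — the reason ties are broken its way.")
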