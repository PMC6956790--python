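"""The scoring statistics: per-class MCC, GCC and Q2mem on a worked matrix.

Builds a small confusion matrix by hand and prints every statistic with
its meaning.
"""
import numpy as np

import mitoloc as ml
from mitoloc.records import COMPARTMENTS

# Rows = true (outer, inner, intermembrane, matrix); columns = predicted.
counts = np.array([
    [12, 3, 0, 1],
    [2, 25, 1, 2],
    [1, 2, 5, 0],
    [0, 3, 1, 20],
])
M = ml.ConfusionMatrix(counts, COMPARTMENTS)
print("confusion matrix (rows true, cols predicted):")
print(counts)

for c in COMPARTMENTS:
    print(f"MCC({c:13s}) = {ml.mcc(M, c):+.3f}   (one-vs-rest correlation, -1..1)")
print(f"GCC = {ml.gcc(M):.3f}   (single chi-square-based score over all 4 classes; "
      "0 = random, 1 = perfect)")

true = [c for i, c in enumerate(COMPARTMENTS) for _ in range(counts[i].sum())]
pred = [cj for i in range(4) for j, cj in enumerate(COMPARTMENTS)
        for _ in range(counts[i, j])]
print(f"Q2mem = {ml.q2mem(true, pred):.1f}%   (membrane proteins kept in a "
      "membrane compartment, even if outer/inner are swapped)")
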