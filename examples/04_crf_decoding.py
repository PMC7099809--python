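"""The linear-chain CRF layer on its own, checked against enumeration.

Builds a small random tag lattice, computes the log-partition with the
forward algorithm and the best path with Viterbi, then verifies both by
brute force over all K^n tag paths.
"""

import itertools

import numpy as np

from docrel.crf import TagLattice, log_partition, path_score, viterbi

rng = np.random.default_rng(3)
n, k = 5, 3
lat = TagLattice(emissions=rng.normal(0, 1, (n, k)),
                 transitions=rng.normal(0, 1, (k, k)),
                 start=rng.normal(0, 1, k), stop=rng.normal(0, 1, k))

scores = np.array([path_score(lat, p)
                   for p in itertools.product(range(k), repeat=n)])
best = viterbi(lat)
print(f"lattice: n={n} positions, K={k} tags, {k**n} possible paths")
print(f"log partition (forward algorithm): {log_partition(lat):.6f}")
print(f"log partition (enumeration):       "
      f"{np.logaddexp.reduce(scores):.6f}")
print(f"viterbi path {best.tags}, score {best.score:.6f}")
print(f"best enumerated score:             {scores.max():.6f}")
# The two pairs of numbers agree to floating-point precision; the Viterbi
# score is necessarily <= the log partition (one path vs the sum of all).
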