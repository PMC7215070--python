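"""Encode one protein under all four sequence representations.

Each encoder maps a variable-length amino-acid sequence to a fixed-length
vector: autocovariance (AC, 210 = 30 lags x 7 physicochemical properties),
conjoint triad (CT, 343 = 7^3 group triples), local descriptor (LD, 630 =
10 regions x 63 composition/transition/distribution statistics) and
pseudo-amino-acid composition (PseAAC, 20 + lambda with lambda = 15).
"""

import numpy as np

from ppistack import SimConfig, ac_encode, ct_encode, ld_encode, pseaac_encode
from ppistack.synthetic import simulate_proteome

proteome, _ = simulate_proteome(SimConfig(seed=1, n_proteins=5, n_positive_pairs=1))
rec = next(iter(proteome))
print(f"{rec.id}: {len(rec)} residues")

for name, vec in [
    ("AC", ac_encode(rec.seq)),
    ("CT", ct_encode(rec.seq)),
    ("LD", ld_encode(rec.seq)),
    ("PseAAC", pseaac_encode(rec.seq)),
]:
    print(
        f"{name:7s} len={len(vec):4d}  min={vec.min():+.4f}  "
        f"max={vec.max():+.4f}  sum={vec.sum():+.4f}"
    )
# CT and PseAAC are normalized distributions (sum 1); AC is centered
# covariance (sums near 0); LD concatenates per-region statistics.
print("CT nonzero triads:", int(np.count_nonzero(ct_encode(rec.seq))))
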