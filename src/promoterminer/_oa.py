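"""Two-level orthogonal arrays (L4, L8, L16, ...) via the Walsh/parity
construction.

Row i, generator column c (1 <= c <= 2^p - 1): level = parity of
popcount(i & c).  Any subset of columns is an orthogonal array; factors are
assigned to columns in an order that maximises resolution:

1. the p "basic" columns 1, 2, 4, ..., 2^(p-1) (<= p factors then form a
   replicated full factorial, so main effects are exact);
2. the all-XOR column 2^p - 1 (p + 1 factors give the standard
   resolution-IV half fraction, e.g. 4 factors on L8);
3. remaining columns by descending popcount, then value.
"""

from __future__ import annotations

import numpy as np


def _column_order(p: int) -> list[int]:
    basic = [1 << j for j in range(p)]
    allxor = (1 << p) - 1
    rest = [c for c in range(1, 1 << p)
            if c not in basic and c != allxor]
    rest.sort(key=lambda c: (-bin(c).count("1"), c))
    cols = basic + ([allxor] if allxor not in basic else []) + rest
    return cols


def two_level_oa(n_factors: int) -> np.ndarray:
    """Smallest L_{2^p} two-level orthogonal array with 2^p - 1 >= n_factors.

    Returns an array of shape (2^p, n_factors) with levels {0, 1}.
    """
    if n_factors < 1:
        raise ValueError("need at least one factor")
    p = 1
    while (1 << p) - 1 < n_factors:
        p += 1
    cols = _column_order(p)[:n_factors]
    rows = 1 << p
    oa = np.empty((rows, n_factors), dtype=np.int8)
    for i in range(rows):
        for j, c in enumerate(cols):
            oa[i, j] = bin(i & c).count("1") & 1
    return oa
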