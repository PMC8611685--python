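"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: DVH fractions by
per-voxel counting, signed-rank p-values by full sign enumeration.
"""

from itertools import product

import numpy as np


def dvh_counting_oracle(dose_values, mask_values, edges):
    """Fraction of masked voxels with dose >= each edge, by direct counting."""
    doses = np.asarray(dose_values)[np.asarray(mask_values, dtype=bool)]
    return np.array([(doses >= e).mean() for e in edges])


def midranks(values):
    """Mid-ranks computed from scratch (average of 1-based positions)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j < len(values) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + 1 + j)  # average of positions i+1..j
        i = j
    return ranks


def wilcoxon_enumeration_oracle(pairs):
    """Exact two-sided signed-rank p by enumerating every sign assignment."""
    arr = np.asarray(pairs, dtype=float)
    d = arr[:, 0] - arr[:, 1]
    d = d[d != 0]
    m = len(d)
    assert m >= 1
    ranks = midranks(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n_le = n_ge = 0
    total = 0
    for signs in product((0, 1), repeat=m):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if w <= w_obs + 1e-12:
            n_le += 1
        if w >= w_obs - 1e-12:
            n_ge += 1
    p = 2.0 * min(n_le, n_ge) / total
    return w_obs, min(1.0, p)
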