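"""Independent brute-force oracles used to check the fast implementations."""

from __future__ import annotations

import numpy as np


def brute_force_nonwear(counts, min_bout: int = 60, tolerance: int = 2):
    """Enumerate maximal non-wear windows by exhaustive window search.

    A window [i, j] qualifies when it starts and ends on zero-count
    epochs, spans at least ``min_bout`` epochs, and every non-zero run
    strictly inside it has length <= ``tolerance``. All O(n^2) windows
    are examined via 2-D boolean matrices and the maximal ones (not
    contained in any other qualifying window) are returned as
    half-open (start, end) pairs. Deliberately independent of the
    package's segment-scan implementation.
    """
    counts = np.asarray(counts)
    n = len(counts)
    if n == 0:
        return []
    z = counts == 0
    # positions belonging to a non-zero run longer than the tolerance
    breaker = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if not z[i]:
            j = i
            while j < n and not z[j]:
                j += 1
            if j - i > tolerance:
                breaker[i:j] = True
            i = j
        else:
            i += 1
    P = np.concatenate(([0], np.cumsum(breaker)))
    ii = np.arange(n)[:, None]
    jj = np.arange(n)[None, :]
    qualifies = (
        z[:, None]
        & z[None, :]
        & (jj - ii + 1 >= min_bout)
        & ((P[jj + 1] - P[ii]) == 0)
    )
    # a window is maximal iff it is the only qualifying (i', j') with
    # i' <= i and j' >= j
    S = np.cumsum(qualifies, axis=0)
    S = np.flip(np.cumsum(np.flip(S, axis=1), axis=1), axis=1)
    maximal = qualifies & (S == 1)
    return [(int(i), int(j) + 1) for i, j in zip(*np.nonzero(maximal))]


def ols_fixed_effects(table, outcome: str):
    """Closed-form OLS on the same design as the mixed model's fixed part."""
    import pandas as pd

    X = [np.ones(len(table))]
    names = ["Intercept"]
    sex = (table["sex"] == "female").to_numpy(float)
    X.append(sex)
    names.append("sex[female]")
    for season in ("autumn", "summer", "winter"):
        X.append((table["season"] == season).to_numpy(float))
        names.append(f"season[{season}]")
    X.append(table["age"].to_numpy(float))
    names.append("age")
    X = np.column_stack(X)
    y = table[outcome].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(beta, index=names)
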