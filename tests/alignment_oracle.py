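"""Brute-force affine-gap glocal alignment oracle for test cross-checks.

Deliberately NOT a Gotoh three-state recurrence (which is what the package
implements): this is the cubic gap-cost-function dynamic program, where the
best score ending at (i, j) considers every possible gap length directly.
A gap of length k costs ``gap_open + k * gap_extend``.  Glocal boundary:
free reference prefix (row 0 is zero) and free reference suffix (final max
over the last row); the read must be consumed in full.
"""

from __future__ import annotations

import numpy as np

NEG = -1e18


def glocal_affine_score(
    read: str,
    ref: str,
    match: int = 2,
    mismatch: int = 4,
    gap_open: int = 5,
    gap_extend: int = 1,
) -> int:
    n, m = len(read), len(ref)
    S = np.full((n + 1, m + 1), NEG)
    S[0, :] = 0.0
    for i in range(1, n + 1):
        S[i, 0] = -(gap_open + gap_extend * i)
        row_up = S[i - 1]
        for j in range(1, m + 1):
            s = match if read[i - 1] == ref[j - 1] else -mismatch
            best = row_up[j - 1] + s
            # deletion ending at j: gap over ref[k..j), any start k < j
            ks = np.arange(j)
            best = max(best, np.max(S[i, :j] - gap_open - gap_extend * (j - ks)))
            # insertion ending at i: gap over read[k..i), any start k < i
            ks = np.arange(i)
            best = max(best, np.max(S[:i, j] - gap_open - gap_extend * (i - ks)))
            S[i, j] = best
    return int(np.max(S[n, :]))
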