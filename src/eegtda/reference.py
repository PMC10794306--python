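"""Brute-force persistent homology by full boundary-matrix reduction.

An intentionally naive, self-contained implementation used as an
independent oracle for the production Rips engine: every simplex up to
dimension 2 is enumerated, the full Z/2 boundary matrix is reduced
column-by-column with Python-integer bitsets, and the persistence pairs
are read off the pivots. Exponential in cloud size; intended for clouds
of a few dozen points at most.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["rips_dims01_reference"]


def rips_dims01_reference(points: np.ndarray):
    """Dimension-0/1 Rips persistence of a small point cloud.

    Returns (h0, h1) as (m, 2) arrays of (birth, death), matching the
    conventions of the production engine: zero-persistence intervals are
    dropped, infinite dimension-0 classes have death = inf, intervals are
    sorted by (birth, death).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n == 0:
        raise ValueError("empty point cloud")
    D = squareform(pdist(points)) if n > 1 else np.zeros((1, 1))

    simplices = [((v,), 0.0) for v in range(n)]
    for i, j in combinations(range(n), 2):
        simplices.append(((i, j), D[i, j]))
    for i, j, k in combinations(range(n), 3):
        simplices.append(((i, j, k), max(D[i, j], D[i, k], D[j, k])))
    # filtration order: diameter, then dimension (faces precede cofaces),
    # then lexicographic for determinism
    simplices.sort(key=lambda s: (s[1], len(s[0]), s[0]))
    index = {s: pos for pos, (s, _) in enumerate(simplices)}
    diam = [d for _, d in simplices]

    columns = []
    for simplex, _ in simplices:
        col = 0
        if len(simplex) > 1:
            for f in combinations(simplex, len(simplex) - 1):
                col ^= 1 << index[f]
        columns.append(col)

    low_owner: dict[int, int] = {}
    pairs = []
    for jcol in range(len(columns)):
        col = columns[jcol]
        while col:
            low = col.bit_length() - 1
            if low not in low_owner:
                low_owner[low] = jcol
                pairs.append((low, jcol))
                break
            col ^= columns[low_owner[low]]
        columns[jcol] = col

    paired = set()
    h0, h1 = [], []
    for low, jcol in pairs:
        paired.add(low)
        paired.add(jcol)
        birth, death = diam[low], diam[jcol]
        if death > birth:
            dim = len(simplices[low][0]) - 1
            (h0 if dim == 0 else h1).append((birth, death))
    for pos, (simplex, d) in enumerate(simplices):
        if pos not in paired and columns[pos] == 0 and len(simplex) <= 2:
            (h0 if len(simplex) == 1 else h1).append((d, np.inf))

    def _as_array(bars):
        if not bars:
            return np.empty((0, 2))
        arr = np.array(sorted(bars), dtype=float)
        return arr

    return _as_array(h0), _as_array(h1)
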