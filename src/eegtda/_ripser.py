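"""Vietoris-Rips persistent homology in dimensions 0 and 1.

Persistent cohomology with clearing, in the style of modern Rips codes:
dimension 0 by union-find over the sorted edge list; dimension 1 by
reducing the coboundary columns of the positive (cycle-creating) edges in
reverse filtration order, enumerating triangle cofacets lazily so that the
common zero/short-persistence pairs never materialise a full column.

The filtration is capped at the enclosing radius (min over points of the
max distance to the others); at that scale the complex is a cone, so every
1-cycle is dead and the diagrams are identical to the uncapped ones. A
smaller explicit threshold is honoured, in which case essential 1-cycles
(death = inf) can occur.

All reductions are over Z/2. Simplices of equal diameter are ordered by a
fixed combinatorial tie-break; the resulting diagram is independent of
that choice.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numba.typed import Dict, List
from numba.core import types

__all__ = ["rips_dims01"]

_INF = np.inf


@njit(cache=True)
def _find(parent, a):
    root = a
    while parent[root] != root:
        root = parent[root]
    while parent[a] != root:
        parent[a], a = root, parent[a]
    return root


@njit(cache=True)
def _sorted3(a, b, c):
    if a > b:
        a, b = b, a
    if b > c:
        b, c = c, b
    if a > b:
        a, b = b, a
    return a, b, c


@njit(cache=True)
def _heap_push(keys_d, keys_i, size, d, i):
    # binary min-heap on (d, i) lexicographic; arrays preallocated large enough
    pos = size
    keys_d[pos] = d
    keys_i[pos] = i
    while pos > 0:
        par = (pos - 1) >> 1
        if (keys_d[par] > keys_d[pos]) or (
            keys_d[par] == keys_d[pos] and keys_i[par] > keys_i[pos]
        ):
            keys_d[par], keys_d[pos] = keys_d[pos], keys_d[par]
            keys_i[par], keys_i[pos] = keys_i[pos], keys_i[par]
            pos = par
        else:
            break
    return size + 1


@njit(cache=True)
def _heap_pop(keys_d, keys_i, size):
    size -= 1
    keys_d[0] = keys_d[size]
    keys_i[0] = keys_i[size]
    pos = 0
    while True:
        left = 2 * pos + 1
        right = left + 1
        best = pos
        if left < size and (
            (keys_d[left] < keys_d[best])
            or (keys_d[left] == keys_d[best] and keys_i[left] < keys_i[best])
        ):
            best = left
        if right < size and (
            (keys_d[right] < keys_d[best])
            or (keys_d[right] == keys_d[best] and keys_i[right] < keys_i[best])
        ):
            best = right
        if best == pos:
            break
        keys_d[best], keys_d[pos] = keys_d[pos], keys_d[best]
        keys_i[best], keys_i[pos] = keys_i[pos], keys_i[best]
        pos = best
    return size


@njit(cache=True)
def _push_cofacets(D, cap, n, a, b, keys_d, keys_i, size):
    """Push every triangle cofacet of edge (a, b) present at scale <= cap."""
    dab = D[a, b]
    for k in range(n):
        if k == a or k == b:
            continue
        dak = D[a, k]
        dbk = D[b, k]
        if dak <= cap and dbk <= cap:
            diam = dab
            if dak > diam:
                diam = dak
            if dbk > diam:
                diam = dbk
            i0, i1, i2 = _sorted3(a, b, k)
            enc = (i0 * n + i1) * n + i2
            size = _heap_push(keys_d, keys_i, size, diam, enc)
    return size


@njit(cache=True)
def _rips_core(D, cap):
    n = D.shape[0]

    # ---- edge list within cap, sorted ascending by (diameter, edge id) ----
    n_edges = 0
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] <= cap:
                n_edges += 1
    ei = np.empty(n_edges, dtype=np.int64)
    ej = np.empty(n_edges, dtype=np.int64)
    ed = np.empty(n_edges, dtype=np.float64)
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] <= cap:
                ei[m] = i
                ej[m] = j
                ed[m] = D[i, j]
                m += 1
    order = np.argsort(ed)
    # stabilise ties: within runs of equal diameter, ascend by enumeration id
    s = 0
    while s < n_edges:
        t = s + 1
        while t < n_edges and ed[order[t]] == ed[order[s]]:
            t += 1
        if t - s > 1:
            run = np.sort(order[s:t])
            order[s:t] = run
        s = t

    # ---- dimension 0: union-find (Kruskal) ----
    parent = np.arange(n)
    tree = np.zeros(n_edges, dtype=np.bool_)
    h0_deaths = np.empty(n, dtype=np.float64)
    n_h0 = 0
    for s in range(n_edges):
        e = order[s]
        ra = _find(parent, ei[e])
        rb = _find(parent, ej[e])
        if ra != rb:
            parent[ra] = rb
            tree[e] = True
            h0_deaths[n_h0] = ed[e]
            n_h0 += 1
    n_components = n - n_h0  # infinite dim-0 classes at the cap

    # ---- dimension 1: persistent cohomology over positive edges ----
    pair_col = Dict.empty(key_type=types.int64, value_type=types.int64)
    col_gens = List.empty_list(types.int64[:])
    births = np.empty(n_edges, dtype=np.float64)
    deaths = np.empty(n_edges, dtype=np.float64)
    n_h1 = 0

    heap_cap = 4 * n + 4
    keys_d = np.empty(heap_cap, dtype=np.float64)
    keys_i = np.empty(heap_cap, dtype=np.int64)

    for s in range(n_edges - 1, -1, -1):
        e = order[s]
        if tree[e]:
            continue  # cleared: tree edges are dim-0 deaths
        a, b = ei[e], ej[e]
        de = ed[e]

        # lazy initial pivot: minimal cofacet in (diameter, id) order
        best_d = _INF
        best_enc = -1
        dab = de
        for k in range(n):
            if k == a or k == b:
                continue
            dak = D[a, k]
            dbk = D[b, k]
            if dak <= cap and dbk <= cap:
                diam = dab
                if dak > diam:
                    diam = dak
                if dbk > diam:
                    diam = dbk
                i0, i1, i2 = _sorted3(a, b, k)
                enc = (i0 * n + i1) * n + i2
                if diam < best_d or (diam == best_d and enc < best_enc):
                    best_d = diam
                    best_enc = enc

        if best_enc == -1:
            births[n_h1] = de
            deaths[n_h1] = _INF
            n_h1 += 1
            continue

        if best_enc not in pair_col:
            gens = np.empty(1, dtype=np.int64)
            gens[0] = e
            pair_col[best_enc] = len(col_gens)
            col_gens.append(gens)
            if best_d > de:
                births[n_h1] = de
                deaths[n_h1] = best_d
                n_h1 += 1
            continue

        # genuine reduction: assemble working coboundary in a heap
        gens_list = List.empty_list(types.int64)
        gens_list.append(e)
        size = 0
        # heap may grow beyond initial capacity when columns are added
        need = heap_cap
        size = _push_cofacets(D, cap, n, a, b, keys_d, keys_i, size)
        paired = False
        while True:
            # pop min with Z/2 parity cancellation
            piv_d = 0.0
            piv_i = np.int64(-1)
            while size > 0:
                piv_d = keys_d[0]
                piv_i = keys_i[0]
                size = _heap_pop(keys_d, keys_i, size)
                count = 1
                while size > 0 and keys_i[0] == piv_i and keys_d[0] == piv_d:
                    size = _heap_pop(keys_d, keys_i, size)
                    count += 1
                if count % 2 == 1:
                    break
                piv_i = np.int64(-1)
            if piv_i == -1:
                births[n_h1] = de
                deaths[n_h1] = _INF
                n_h1 += 1
                paired = True  # essential, recorded
                break
            if piv_i not in pair_col:
                pair_col[piv_i] = len(col_gens)
                g_arr = np.empty(len(gens_list), dtype=np.int64)
                for t in range(len(gens_list)):
                    g_arr[t] = gens_list[t]
                col_gens.append(g_arr)
                if piv_d > de:
                    births[n_h1] = de
                    deaths[n_h1] = piv_d
                    n_h1 += 1
                paired = True
                break
            # add the column that owns this pivot
            owner = pair_col[piv_i]
            owner_gens = col_gens[owner]
            grow = size + (owner_gens.shape[0] + 1) * (n + 1)
            if grow > need:
                while need < grow:
                    need *= 2
                new_d = np.empty(need, dtype=np.float64)
                new_i = np.empty(need, dtype=np.int64)
                new_d[:size] = keys_d[:size]
                new_i[:size] = keys_i[:size]
                keys_d = new_d
                keys_i = new_i
            for t in range(owner_gens.shape[0]):
                g = owner_gens[t]
                gens_list.append(g)
                size = _push_cofacets(
                    D, cap, n, ei[g], ej[g], keys_d, keys_i, size
                )
            # pivot triangle itself cancels: it occurs once in the owner's
            # column and once here; both copies are now in the heap and the
            # parity pop removes them.
            size = _heap_push(keys_d, keys_i, size, piv_d, piv_i)
        if not paired:  # pragma: no cover - loop always records
            pass

    return h0_deaths[:n_h0], n_components, births[:n_h1], deaths[:n_h1]


def rips_dims01(D: np.ndarray, threshold: float | None = None):
    """Persistence intervals of the Rips filtration of a distance matrix.

    Parameters
    ----------
    D : (n, n) float array, symmetric, zero diagonal.
    threshold : optional filtration cap; defaults to the enclosing radius,
        which leaves the dimension-0/1 diagrams unchanged.

    Returns
    -------
    h0 : (m0, 2) array of (birth, death); includes infinite bars.
    h1 : (m1, 2) array of (birth, death), finite unless a threshold below
        the enclosing radius truncates the filtration.
    """
    D = np.ascontiguousarray(D, dtype=np.float64)
    n = D.shape[0]
    if n == 0:
        raise ValueError("empty point cloud")
    if n == 1:
        return np.array([[0.0, _INF]]), np.empty((0, 2))
    if threshold is None:
        cap = float(np.min(np.max(D, axis=1)))
    else:
        cap = float(threshold)
    h0_deaths, n_comp, b1, d1 = _rips_core(D, cap)
    h0_deaths = h0_deaths[h0_deaths > 0.0]  # drop zero-persistence merges
    h0 = np.empty((h0_deaths.size + n_comp, 2))
    h0[:, 0] = 0.0
    h0[: h0_deaths.size, 1] = np.sort(h0_deaths)
    h0[h0_deaths.size:, 1] = _INF
    h1 = np.column_stack([b1, d1]) if b1.size else np.empty((0, 2))
    if h1.size:
        h1 = h1[np.lexsort((h1[:, 1], h1[:, 0]))]
    return h0, h1
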