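"""Numba kernels for batch transition-map construction and cycle detection.

Surveys over 10^6 networks and the genetic algorithm both hinge on evaluating
the longest attractor cycle of many small signed networks; these kernels keep
that inner loop in machine code.  Everything here is internal; the public
API lives in :mod:`cyclesym.state_space` and :mod:`cyclesym.ensembles`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def succ_tables(W_batch):
    """Transition tables for a batch of signed threshold networks.

    W_batch : (B, n, n) int8 trit matrices.
    Returns (B, 2**n) int32 successor arrays.

    Input sums are accumulated incrementally: the sums for state x reuse the
    sums of x with its lowest set bit cleared, so each state costs O(n)
    rather than O(n^2).
    """
    B, n, _ = W_batch.shape
    N = 1 << n
    out = np.empty((B, N), dtype=np.int32)
    sums = np.zeros((N, n), dtype=np.int64)
    for b in range(B):
        W = W_batch[b]
        out[b, 0] = 0
        for x in range(1, N):
            lsb = x & (-x)
            j = 0
            v = lsb
            while v > 1:
                v >>= 1
                j += 1
            parent = x ^ lsb
            y = 0
            for i in range(n):
                t = sums[parent, i] + W[j, i]
                sums[x, i] = t
                if t > 0:
                    y |= 1 << i
            out[b, x] = y
    return out


@njit(cache=True)
def max_cycle_lengths(succ):
    """Longest cycle length of each functional graph in a (B, N) batch.

    Iterative path-walking with three-colour marking; linear in N per graph.
    """
    B, N = succ.shape
    out = np.empty(B, dtype=np.int64)
    color = np.empty(N, dtype=np.int8)  # 0 unvisited, 1 on current path, 2 done
    path = np.empty(N, dtype=np.int64)
    for b in range(B):
        s = succ[b]
        color[:] = 0
        best = 1
        for start in range(N):
            if color[start] != 0:
                continue
            v = start
            plen = 0
            while color[v] == 0:
                color[v] = 1
                path[plen] = v
                plen += 1
                v = s[v]
            if color[v] == 1:  # closed a new cycle at v
                clen = 1
                u = s[v]
                while u != v:
                    clen += 1
                    u = s[u]
                if clen > best:
                    best = clen
            for k in range(plen):
                color[path[k]] = 2
        out[b] = best
    return out


@njit(cache=True)
def full_symmetric_counts(succ):
    """Per-network count of states x with tau(¬x) = ¬tau(x), for (B, N) tables."""
    B, N = succ.shape
    out = np.empty(B, dtype=np.int64)
    mask = N - 1
    for b in range(B):
        s = succ[b]
        c = 0
        for x in range(N):
            if s[mask - x] == mask - s[x]:
                c += 1
        out[b] = c
    return out
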