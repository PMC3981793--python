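"""Numba-compiled folding kernels.

All dynamic-programming tables are *interval tables*: cell (i, j) depends only
on the subsequence i..j (0-based, inclusive). A sliding-window scan therefore
computes one banded set of tables per temperature (band width = largest
window) and reads every window's result out of the shared tables, instead of
re-folding each window from scratch.

Recursions (zero multibranch and exterior penalties, internal loops capped):

MFE:
  V(i,j)  = energy of the best structure in which (i, j) pair:
            hairpin | internal loop/stack to (k, l) | multibranch = M2(i+1, j-1)
  M(i,j)  = best energy over arrangements with >= 1 branch in [i, j]
  M2(i,j) = best energy over arrangements with >= 2 branches in [i, j]
  F(i,j)  = best energy over all structures in [i, j] (0 for the open chain)

Partition function (same decomposition, unambiguous by construction — the
rightmost branch is always split off, so every structure is counted once):
  Zb, Zm, Zm2, Z mirror V, M, M2, F with Boltzmann-weighted sums.

Tie-breaking in the MFE traceback is deterministic: hairpin closure first,
then interior candidates by total unpaired count (stack first) and left gap,
then multibranch; interval cells prefer leaving the right end unpaired, then
the smallest split point.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1.0e30
MIN_HAIRPIN = 3      # minimum unpaired bases enclosed by any pair
MAX_INTERNAL = 30    # cap on total unpaired bases of an internal/bulge loop


@njit(cache=True)
def _pair_idx(pair_table, a, b):
    return pair_table[a, b]


@njit(cache=True)
def mfe_tables(seq, span, pair_table, stack_e, hp_e, il_e):
    """Banded MFE tables with backpointers.

    Parameters: encoded sequence, maximum span (window size), 4x4 pair-type
    table, 6x6 stack dG, hairpin/internal dG arrays indexed by loop size.

    Returns (V, VC, VK, VL, M, MK, ML, M2, M2K, F, FK):
      VC: 0 hairpin, 1 interior (k,l in VK,VL), 2 multibranch, -1 unset.
      FK/M* backpointers: -1 means "right end unpaired"; otherwise k of the
      rightmost pair (k, j). ML flags whether the left part of M used M.
    """
    n = seq.shape[0]
    V = np.full((n, n), INF)
    VC = np.full((n, n), -1, dtype=np.int32)
    VK = np.full((n, n), -1, dtype=np.int32)
    VL = np.full((n, n), -1, dtype=np.int32)
    M = np.full((n, n), INF)
    MK = np.full((n, n), -2, dtype=np.int32)
    ML = np.zeros((n, n), dtype=np.int32)
    M2 = np.full((n, n), INF)
    M2K = np.full((n, n), -2, dtype=np.int32)
    F = np.zeros((n, n))
    FK = np.full((n, n), -1, dtype=np.int32)

    for d in range(0, span):          # d = j - i
        for i in range(0, n - d):
            j = i + d
            # ---- V(i, j): (i, j) paired -------------------------------
            pt = pair_table[seq[i], seq[j]]
            if pt >= 0 and d - 1 >= MIN_HAIRPIN:
                u = d - 1
                best = hp_e[u]
                bc, bk, bl = 0, -1, -1
                # interior candidates ordered: stack first, then growing loops
                max_u = u - MIN_HAIRPIN - 2
                if max_u > MAX_INTERNAL:
                    max_u = MAX_INTERNAL
                for tot in range(0, max_u + 1):
                    for u1 in range(0, tot + 1):
                        u2 = tot - u1
                        k = i + 1 + u1
                        l = j - 1 - u2
                        qt = pair_table[seq[k], seq[l]]
                        if qt < 0 or V[k, l] >= INF:
                            continue
                        if tot == 0:
                            g = stack_e[pt, qt]
                        else:
                            g = il_e[tot]
                        cand = g + V[k, l]
                        if cand < best:
                            best = cand
                            bc, bk, bl = 1, k, l
                # multibranch: >= 2 branches strictly inside
                if d >= 2 and M2[i + 1, j - 1] < best:
                    best = M2[i + 1, j - 1]
                    bc, bk, bl = 2, -1, -1
                V[i, j] = best
                VC[i, j] = bc
                VK[i, j] = bk
                VL[i, j] = bl
            # ---- M / M2 / F over [i, j] -------------------------------
            if d == 0:
                F[i, j] = 0.0
                FK[i, j] = -1
                continue
            # right end unpaired
            bm = M[i, j - 1]
            bmk, bml = -1, 0
            bm2 = M2[i, j - 1]
            bm2k = -1
            bf = F[i, j - 1]
            bfk = -1
            for k in range(i, j - MIN_HAIRPIN):
                v = V[k, j]
                if v >= INF:
                    continue
                # M: rightmost branch (k, j); left part empty or M
                if v < bm:
                    bm = v
                    bmk, bml = k, 0
                if k > i and M[i, k - 1] < INF and M[i, k - 1] + v < bm:
                    bm = M[i, k - 1] + v
                    bmk, bml = k, 1
                # M2: rightmost branch (k, j); left part must hold >= 1 branch
                if k > i and M[i, k - 1] < INF and M[i, k - 1] + v < bm2:
                    bm2 = M[i, k - 1] + v
                    bm2k = k
                # F: rightmost external pair (k, j)
                left = F[i, k - 1] if k > i else 0.0
                if left + v < bf:
                    bf = left + v
                    bfk = k
            M[i, j] = bm
            MK[i, j] = bmk
            ML[i, j] = bml
            M2[i, j] = bm2
            M2K[i, j] = bm2k
            F[i, j] = bf
            FK[i, j] = bfk
    return V, VC, VK, VL, M, MK, ML, M2, M2K, F, FK


@njit(cache=True)
def pf_tables(seq, span, pair_table, stack_e, hp_e, il_e, rt):
    """Banded inside partition-function tables (Z, Zb, Zm, Zm2).

    Z(i,j) sums Boltzmann weights of all structures on i..j (1 for the open
    chain); Zb requires (i,j) paired; Zm >= 1 branch; Zm2 >= 2 branches.
    Zm and Zm2 decompose on the rightmost branch, so each arrangement is
    counted exactly once.
    """
    n = seq.shape[0]
    Z = np.ones((n + 1, n + 1))   # padded: index [i, j+1], empty interval = 1
    Zb = np.zeros((n, n))
    Zm = np.zeros((n, n))
    Zm2 = np.zeros((n, n))

    for d in range(0, span):
        for i in range(0, n - d):
            j = i + d
            pt = pair_table[seq[i], seq[j]]
            if pt >= 0 and d - 1 >= MIN_HAIRPIN:
                u = d - 1
                acc = np.exp(-hp_e[u] / rt)
                max_u = u - MIN_HAIRPIN - 2
                if max_u > MAX_INTERNAL:
                    max_u = MAX_INTERNAL
                for tot in range(0, max_u + 1):
                    for u1 in range(0, tot + 1):
                        k = i + 1 + u1
                        l = j - 1 - (tot - u1)
                        qt = pair_table[seq[k], seq[l]]
                        if qt < 0 or Zb[k, l] == 0.0:
                            continue
                        g = stack_e[pt, qt] if tot == 0 else il_e[tot]
                        acc += np.exp(-g / rt) * Zb[k, l]
                if j - 1 > i + 1:
                    # multibranch: >= 2 branches strictly inside (i, j);
                    # Zm2 already accounts for trailing unpaired bases
                    acc += Zm2[i + 1, j - 1]
                Zb[i, j] = acc
            if d == 0:
                Z[i, j + 1] = 1.0
                continue
            zm = Zm[i, j - 1]
            zm2 = Zm2[i, j - 1]
            z = Z[i, j]           # Z(i, j-1)
            for k in range(i, j - MIN_HAIRPIN):
                zb = Zb[k, j]
                if zb == 0.0:
                    continue
                left_m = Zm[i, k - 1] if k > i else 0.0
                zm += (1.0 + left_m) * zb
                if k > i:
                    zm2 += left_m * zb
                z += Z[i, k] * zb   # Z(i, k-1) in padded indexing
            Zm[i, j] = zm
            Zm2[i, j] = zm2
            Z[i, j + 1] = z
    return Z, Zb, Zm, Zm2


@njit(cache=True)
def pf_outside_window(s, e, seq, pair_table, stack_e, il_e, rt, Z, Zb, Zm):
    """Base-pair probabilities for the window [s, e] (0-based inclusive).

    Uses the shared inside tables; the outside pass is local to the window.
    Returns a (n, n) array with p[i, j] for s <= i < j <= e.
    """
    n = seq.shape[0]
    p = np.zeros((n, n))
    Ob = np.zeros((n, n))
    ztot = Z[s, e + 1]
    for d in range(e - s, MIN_HAIRPIN, -1):
        for i in range(s, e - d + 1):
            j = i + d
            if Zb[i, j] == 0.0:
                continue
            # external context: anything left of i, anything right of j
            left = Z[s, i] if i > s else 1.0
            right = Z[j + 1, e + 1] if j < e else 1.0
            acc = left * right
            # enclosed by (a, b) through an internal loop or stack
            pt_in = pair_table[seq[i], seq[j]]
            for u1 in range(0, MAX_INTERNAL + 1):
                a = i - 1 - u1
                if a < s:
                    break
                for u2 in range(0, MAX_INTERNAL + 1 - u1):
                    b = j + 1 + u2
                    if b > e:
                        break
                    if Ob[a, b] == 0.0:
                        continue
                    qt = pair_table[seq[a], seq[b]]
                    if qt < 0:
                        continue
                    tot = u1 + u2
                    g = stack_e[qt, pt_in] if tot == 0 else il_e[tot]
                    acc += Ob[a, b] * np.exp(-g / rt)
            # branch of a multibranch loop closed by (a, b)
            for a in range(s, i):
                for b in range(j + 1, e + 1):
                    if Ob[a, b] == 0.0:
                        continue
                    if pair_table[seq[a], seq[b]] < 0:
                        continue
                    lm = Zm[a + 1, i - 1] if i - 1 >= a + 1 else 0.0
                    rm = Zm[j + 1, b - 1] if b - 1 >= j + 1 else 0.0
                    other = (1.0 + lm) * (1.0 + rm) - 1.0
                    if other > 0.0:
                        acc += Ob[a, b] * other
            Ob[i, j] = acc
            p[i, j] = acc * Zb[i, j] / ztot
    return p
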