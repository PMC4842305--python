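"""Compiled numerical kernels for loop energies and the dense reference DP.

Everything here operates on integer energies in units of 0.01 kcal/mol
(the native unit of nearest-neighbor parameter files), with ``INF`` as
an absorbing infeasibility sentinel, and on
sequences encoded as int64 arrays with 1-based positions (index 0 is a pad).
Base codes follow the nearest-neighbor table convention: N=0, A=1, C=2,
G=3, U=4.  Pair types: CG=1, GC=2, GU=3, UG=4, AU=5, UA=6 (0 = cannot
pair); types > 2 carry the terminal AU/GU closing penalty where a helix
meets the exterior loop or a multiloop.

The energy semantics replicate the standard nearest-neighbor evaluation
with dangling-end contributions disabled (the ``-d0`` convention): hairpin
initiation by loop size with logarithmic extrapolation past size 30,
terminal-mismatch terms for loops of size >= 4, tabulated special tri-,
tetra-, and hexaloops, 1x1/2x1/2x2 internal-loop tables, bulges, Ninio
asymmetry with a cap, and the affine multiloop model a + b*branches +
c*unpaired.
"""

from collections import namedtuple
import math

import numpy as np
from numba import njit

INF = 10_000_000

#: all nearest-neighbor tables plus the model constants, in a flat
#: namedtuple so the compiled kernels can take them as a single argument.
Tables = namedtuple(
    "Tables",
    [
        "pt",        # (5,5) pair-type lookup by base codes
        "stack",     # (8,8) by (outer type, reversed inner type)
        "mmh",       # (8,5,5) hairpin terminal mismatch
        "mmi",       # (8,5,5) generic internal mismatch
        "mm1n",      # (8,5,5) 1xn internal mismatch
        "mm23",      # (8,5,5) 2x3 internal mismatch
        "int11",     # (8,8,5,5)
        "int21",     # (8,8,5,5,5)
        "int22",     # (8,8,5,5,5,5)
        "hairpin",   # (31,) initiation by loop size
        "bulge",     # (31,)
        "internal",  # (31,)
        "ninio",     # per-nucleotide asymmetry penalty
        "max_ninio",  # cap on the asymmetry term
        "lxc",       # coefficient of the logarithmic size extrapolation
        "term_au",   # terminal AU/GU penalty
        "ml_a",      # multiloop initiation
        "ml_b",      # multiloop branch penalty
        "ml_c",      # multiloop unpaired-base penalty
        "m",         # minimum hairpin loop size
        "M",         # maximum number of unpaired bases in an internal loop
        "tri_codes", "tri_e",      # special triloops (encoded 5-mers)
        "tetra_codes", "tetra_e",  # special tetraloops (encoded 6-mers)
        "hexa_codes", "hexa_e",    # special hexaloops (encoded 8-mers)
    ],
)


def make_pair_table() -> np.ndarray:
    pt = np.zeros((5, 5), dtype=np.int64)
    A, C, G, U = 1, 2, 3, 4
    pt[C, G] = 1
    pt[G, C] = 2
    pt[G, U] = 3
    pt[U, G] = 4
    pt[A, U] = 5
    pt[U, A] = 6
    return pt


@njit(cache=True)
def pair_type(T, a, b):
    return T.pt[a, b]


@njit(cache=True)
def au_penalty(T, a, b):
    """Terminal AU/GU penalty of a helix end with closing bases (a, b)."""
    t = T.pt[a, b]
    if t > 2:
        return T.term_au
    return 0


@njit(cache=True)
def _size_extrapolated(table, size, lxc):
    if size <= 30:
        return table[size]
    return table[30] + int(lxc * math.log(size / 30.0))


@njit(cache=True)
def _motif_code(codes, i, length):
    c = 0
    for t in range(length):
        c = c * 5 + codes[i + t]
    return c


@njit(cache=True)
def _motif_lookup(motif_codes, motif_e, code):
    for idx in range(motif_codes.shape[0]):
        if motif_codes[idx] == code:
            return motif_e[idx]
    return INF


@njit(cache=True)
def hairpin_energy_kernel(codes, i, j, T):
    """Free energy of the hairpin loop closed by pair i.j (1-based)."""
    size = j - i - 1
    if size < T.m:
        return INF
    t = T.pt[codes[i], codes[j]]
    if t == 0:
        return INF
    e = _size_extrapolated(T.hairpin, size, T.lxc)
    if size == 3:
        bonus = _motif_lookup(T.tri_codes, T.tri_e, _motif_code(codes, i, 5))
        if bonus < INF:
            return bonus
        if t > 2:
            e += T.term_au
        return e
    if size == 4:
        bonus = _motif_lookup(T.tetra_codes, T.tetra_e, _motif_code(codes, i, 6))
        if bonus < INF:
            return bonus
    elif size == 6:
        bonus = _motif_lookup(T.hexa_codes, T.hexa_e, _motif_code(codes, i, 8))
        if bonus < INF:
            return bonus
    return e + T.mmh[t, codes[i + 1], codes[j - 1]]


@njit(cache=True)
def internal_energy_kernel(codes, i, j, p, q, T):
    """Energy of the internal loop closed by i.j with inner pair p.q.

    Subsumes stacked pairs (zero unpaired bases) and bulges (one side
    unpaired).  Returns INF when either pair is non-complementary or the
    total number of unpaired bases exceeds the loop-size cap M.
    """
    t1 = T.pt[codes[i], codes[j]]
    if t1 == 0:
        return INF
    t2 = T.pt[codes[q], codes[p]]
    if t2 == 0:
        return INF
    n1 = p - i - 1
    n2 = j - q - 1
    if n1 + n2 > T.M:
        return INF
    if n1 > n2:
        nl, ns = n1, n2
    else:
        nl, ns = n2, n1
    if nl == 0:
        return T.stack[t1, t2]
    si1 = codes[i + 1]
    sj1 = codes[j - 1]
    sp1 = codes[p - 1]
    sq1 = codes[q + 1]
    if ns == 0:  # bulge
        e = _size_extrapolated(T.bulge, nl, T.lxc)
        if nl == 1:
            e += T.stack[t1, t2]
        else:
            if t1 > 2:
                e += T.term_au
            if t2 > 2:
                e += T.term_au
        return e
    if ns == 1:
        if nl == 1:
            return T.int11[t1, t2, si1, sj1]
        if nl == 2:
            if n1 == 1:
                return T.int21[t1, t2, si1, sq1, sj1]
            return T.int21[t2, t1, sq1, si1, sp1]
        # 1 x n loop
        e = _size_extrapolated(T.internal, nl + 1, T.lxc)
        e += min(T.max_ninio, (nl - ns) * T.ninio)
        e += T.mm1n[t1, si1, sj1] + T.mm1n[t2, sq1, sp1]
        return e
    if ns == 2:
        if nl == 2:
            return T.int22[t1, t2, si1, sp1, sq1, sj1]
        if nl == 3:
            e = T.internal[5] + T.ninio
            e += T.mm23[t1, si1, sj1] + T.mm23[t2, sq1, sp1]
            return e
    u = nl + ns
    e = _size_extrapolated(T.internal, u, T.lxc)
    e += min(T.max_ninio, (nl - ns) * T.ninio)
    e += T.mmi[t1, si1, sj1] + T.mmi[t2, sq1, sp1]
    return e


@njit(cache=True)
def v_cases_kernel(codes, i, j, vwin, wm2_prev, T):
    """Evaluate the closed-structure recursion V(i,j).

    vwin is the rotating window of V rows (row p lives at p % (M+2));
    wm2_prev is the WM2 row of i+1.  Returns (energy, case, p, q) where
    case is 0 = infeasible, 1 = hairpin, 2 = internal loop with inner pair
    (p, q), 3 = multiloop.  Ties break toward the earlier case in the
    order hairpin, internal (smallest p, then smallest q), multiloop.
    """
    t = T.pt[codes[i], codes[j]]
    if t == 0 or j - i <= T.m:
        return INF, 0, 0, 0
    best = hairpin_energy_kernel(codes, i, j, T)
    case = 1 if best < INF else 0
    bp = 0
    bq = 0
    win = T.M + 2
    pmax = min(i + T.M + 1, j - T.m - 2)
    for p in range(i + 1, pmax + 1):
        rem = T.M - (p - i - 1)
        qmin = p + T.m + 1
        if j - 1 - rem > qmin:
            qmin = j - 1 - rem
        for q in range(qmin, j):
            vpq = vwin[p % win, q]
            if vpq >= INF:
                continue
            e = internal_energy_kernel(codes, i, j, p, q, T)
            if e >= INF:
                continue
            e += vpq
            if e < best:
                best = e
                case = 2
                bp = p
                bq = q
    ml = wm2_prev[j - 1]
    if ml < INF:
        e = ml + T.ml_a + T.ml_b
        if t > 2:
            e += T.term_au
        if e < best:
            best = e
            case = 3
            bp = 0
            bq = 0
    return best, case, bp, bq


@njit(cache=True)
def fill_reference_kernel(codes, T):
    """Dense O(n^3) fill of the loop-based MFE recursions.

    Returns the full upper-triangular matrices V, W, WM, WM2 plus the
    partition-only minima WP (alternatives to W's closed case) and WMP
    (alternatives to WM's closed case), which define candidacy:
    [i,j] is a candidate iff V+au < WP(i,j) or V+b+au < WMP(i,j).

    WM holds minimum energies of non-empty multiloop fragments, where each
    branch pays b plus its terminal penalty and each unpaired base pays c;
    WM2 restricts to fragments with at least two branches.  The multiloop
    case of V is WM2(i+1, j-1) + a + b (+ terminal penalty).
    """
    n = codes.shape[0] - 1
    V = np.full((n + 2, n + 2), INF, dtype=np.int64)
    W = np.zeros((n + 2, n + 2), dtype=np.int64)
    WM = np.full((n + 2, n + 2), INF, dtype=np.int64)
    WM2 = np.full((n + 2, n + 2), INF, dtype=np.int64)
    WP = np.full((n + 2, n + 2), INF, dtype=np.int64)
    WMP = np.full((n + 2, n + 2), INF, dtype=np.int64)
    for i in range(n, 0, -1):
        for j in range(i + 1, n + 1):
            # --- V(i,j): hairpin / internal / multiloop ---
            t = T.pt[codes[i], codes[j]]
            v = INF
            if t != 0 and j - i > T.m:
                v = hairpin_energy_kernel(codes, i, j, T)
                pmax = min(i + T.M + 1, j - T.m - 2)
                for p in range(i + 1, pmax + 1):
                    rem = T.M - (p - i - 1)
                    qmin = p + T.m + 1
                    if j - 1 - rem > qmin:
                        qmin = j - 1 - rem
                    for q in range(qmin, j):
                        vpq = V[p, q]
                        if vpq >= INF:
                            continue
                        e = internal_energy_kernel(codes, i, j, p, q, T)
                        if e >= INF:
                            continue
                        if e + vpq < v:
                            v = e + vpq
                ml = WM2[i + 1, j - 1]
                if ml < INF:
                    e = ml + T.ml_a + T.ml_b
                    if t > 2:
                        e += T.term_au
                    if e < v:
                        v = e
            V[i, j] = v
            auij = T.term_au if t > 2 else 0
            # --- WP / W ---
            wp = W[i, j - 1]
            for k in range(i + 1, j):
                vk = V[k, j]
                if vk >= INF:
                    continue
                tk = T.pt[codes[k], codes[j]]
                auk = T.term_au if tk > 2 else 0
                e = W[i, k - 1] + vk + auk
                if e < wp:
                    wp = e
            WP[i, j] = wp
            w = wp
            if v < INF and v + auij < w:
                w = v + auij
            W[i, j] = w
            # --- WMP / WM / WM2 ---
            wmp = WM[i, j - 1] + T.ml_c if WM[i, j - 1] < INF else INF
            wm2 = WM2[i, j - 1] + T.ml_c if WM2[i, j - 1] < INF else INF
            for k in range(i + 1, j):
                vk = V[k, j]
                if vk >= INF:
                    continue
                tk = T.pt[codes[k], codes[j]]
                auk = T.term_au if tk > 2 else 0
                branch = vk + T.ml_b + auk
                prefix = WM[i, k - 1]
                lead = (k - i) * T.ml_c + branch
                if prefix < INF:
                    if prefix + branch < wmp:
                        wmp = prefix + branch
                    if prefix + branch < wm2:
                        wm2 = prefix + branch
                if lead < wmp:
                    wmp = lead
            WMP[i, j] = wmp
            WM2[i, j] = wm2
            wm = wmp
            if v < INF and v + T.ml_b + auij < wm:
                wm = v + T.ml_b + auij
            WM[i, j] = wm
    return V, W, WM, WM2, WP, WMP
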