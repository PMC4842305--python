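"""Fold reconstruction from candidate lists and trace arrows.

The traceback never touches a full DP matrix.  Whenever the trace enters
a row i of W, WM or WM2, that row is recomputed left-to-right from the
candidate lists alone: a non-candidate interval is partitionable, so its
value is reachable through prefix values of the same row plus candidate
entries (k, V(k,j)).  Closed entries V(i,j) are resolved in fixed order:
hairpin; the registered trace arrow (whose target energy is recomputed as
V(p,q) = V(i,j) - I(i,j,p,q) and checked against the stored value); the
optimal internal loop into a *candidate* inner pair, reconstructed by
minimizing I(i,j,p,q) + V(p,q) over candidate entries inside the loop
window; and finally the multiloop case, taken iff no other case yields
the known energy.  The arrow is consulted before the candidate scan
because an arrow records the forward pass's actual winning inner pair;
this keeps the reconstructed structure bit-identical to the dense
reference traceback even among co-optimal inner pairs.

A failure to match any recursion case is a hard error
(`TraceInconsistencyError`): with intact candidate lists and arrows it
cannot occur, and it is exactly what happens when arrows are withheld —
candidates alone are insufficient to reconstruct the fold.
"""

from __future__ import annotations

from typing import Callable, Dict, Iterable, List, Optional, Tuple

import numpy as np

from ._kernels import (
    INF,
    hairpin_energy_kernel,
    internal_energy_kernel,
)
from .energy import EnergyParams, RnaSequence, energy_of_structure, format_energy
from .sparse import Candidates, SparseResult
from .structure import SecondaryStructure

__all__ = [
    "TraceInconsistencyError",
    "trace",
    "recompute_W_row",
    "recompute_WM_rows",
    "run_trace_engine",
]


class TraceInconsistencyError(RuntimeError):
    """No recursion case reproduces a trace entry's known energy."""


def recompute_W_row(i: int, n: int, cands: Candidates) -> np.ndarray:
    """W(i, j) for all j, from candidate entries only.

    Left-to-right: W[j] = min(W[j-1], min over candidates [k,j] with
    k >= i of W[k-1] + V(k,j) + au).  The k = i term reproduces W's
    closed case, which can win only when [i,j] is a candidate.
    """
    W = np.zeros(n + 2, dtype=np.int64)
    for j in range(i + 1, n + 1):
        best = W[j - 1]
        for k, vk, auk in cands.column(j):
            if k < i:
                break
            e = W[k - 1] + vk + auk
            if e < best:
                best = e
        W[j] = best
    return W


def recompute_WM_rows(i: int, n: int, cands: Candidates,
                      params: EnergyParams) -> Tuple[np.ndarray, np.ndarray]:
    """WM(i, j) and WM2(i, j) for all j, from candidate entries only."""
    b, c = params.ml_b, params.ml_c
    WM = np.full(n + 2, INF, dtype=np.int64)
    WM2 = np.full(n + 2, INF, dtype=np.int64)
    WM[i] = INF
    WM2[i] = INF
    for j in range(i + 1, n + 1):
        wm = WM[j - 1] + c if WM[j - 1] < INF else INF
        wm2 = WM2[j - 1] + c if WM2[j - 1] < INF else INF
        for k, vk, auk in cands.column(j):
            if k < i:
                break
            branch = vk + b + auk
            if k > i and WM[k - 1] < INF:
                e = WM[k - 1] + branch
                if e < wm:
                    wm = e
                if e < wm2:
                    wm2 = e
            lead = (k - i) * c + branch
            if lead < wm:
                wm = lead
        WM[j] = wm
        WM2[j] = wm2
    return WM, WM2


class _RowCache:
    """Keeps the most recently recomputed rows (bounded, O(n) memory)."""

    def __init__(self, compute: Callable[[int], object], keep: int = 2):
        self._compute = compute
        self._keep = keep
        self._cache: Dict[int, object] = {}
        self._order: List[int] = []

    def __call__(self, i: int):
        if i not in self._cache:
            if len(self._order) >= self._keep:
                self._cache.pop(self._order.pop(0))
            self._cache[i] = self._compute(i)
            self._order.append(i)
        return self._cache[i]


def run_trace_engine(seq: RnaSequence, params: EnergyParams, n: int,
                     mfe: int,
                     w_row: Callable[[int], np.ndarray],
                     wm_rows: Callable[[int], Tuple[np.ndarray, np.ndarray]],
                     column_asc: Callable[[int], Iterable[Tuple[int, int, int]]],
                     resolve_v: Callable[[int, int, int], List[Tuple]],
                     ) -> SecondaryStructure:
    """Shared stack-driven traceback over the W/WM/WM2/V case lists.

    The deterministic case order (identical for the sparse and the dense
    reference traceback) is: unpaired-right step; candidate split terms
    with ascending k (the k = i term is the closed case); V resolution
    via `resolve_v`.  Every popped V item carries its exact energy.
    """
    b, c = params.ml_b, params.ml_c
    pairs: List[Tuple[int, int]] = []
    stack: List[Tuple] = [("W", 1, n, mfe)]
    while stack:
        tag, i, j, e = stack.pop()
        if tag == "V":
            pairs.append((i, j))
            stack.extend(resolve_v(i, j, e))
        elif tag == "W":
            W = w_row(i)
            while True:
                if j <= i:
                    if e != 0:
                        raise TraceInconsistencyError(
                            f"W({i},{j}) = {e} on an empty interval")
                    break
                if e == W[j - 1]:
                    j -= 1
                    continue
                matched = False
                for k, vk, auk in column_asc(j):
                    if k < i:
                        continue
                    if W[k - 1] + vk + auk == e:
                        if k - 1 > i:
                            stack.append(("W", i, k - 1, int(W[k - 1])))
                        stack.append(("V", k, j, vk))
                        matched = True
                        break
                if not matched:
                    raise TraceInconsistencyError(
                        f"no case matches W({i},{j}) = {format_energy(e)}")
                break
        elif tag == "WM":
            WM, _WM2 = wm_rows(i)
            while True:
                if WM[j] != e:
                    raise TraceInconsistencyError(
                        f"recomputed WM({i},{j}) = {WM[j]} != traced {e}")
                if WM[j - 1] < INF and e == WM[j - 1] + c:
                    j -= 1
                    continue
                matched = False
                for k, vk, auk in column_asc(j):
                    if k < i:
                        continue
                    branch = vk + b + auk
                    if k > i and WM[k - 1] < INF and WM[k - 1] + branch == e:
                        stack.append(("WM", i, k - 1, int(WM[k - 1])))
                        stack.append(("V", k, j, vk))
                        matched = True
                        break
                    if (k - i) * c + branch == e:
                        stack.append(("V", k, j, vk))
                        matched = True
                        break
                if not matched:
                    raise TraceInconsistencyError(
                        f"no case matches WM({i},{j}) = {format_energy(e)}")
                break
        elif tag == "WM2":
            WM, WM2 = wm_rows(i)
            while True:
                if WM2[j] != e:
                    raise TraceInconsistencyError(
                        f"recomputed WM2({i},{j}) = {WM2[j]} != traced {e}")
                if WM2[j - 1] < INF and e == WM2[j - 1] + c:
                    j -= 1
                    continue
                matched = False
                for k, vk, auk in column_asc(j):
                    if k <= i:
                        continue
                    branch = vk + b + auk
                    if WM[k - 1] < INF and WM[k - 1] + branch == e:
                        stack.append(("WM", i, k - 1, int(WM[k - 1])))
                        stack.append(("V", k, j, vk))
                        matched = True
                        break
                if not matched:
                    raise TraceInconsistencyError(
                        f"no case matches WM2({i},{j}) = {format_energy(e)}")
                break
        else:  # pragma: no cover - engine bug
            raise AssertionError(tag)
    return SecondaryStructure(n, pairs)


def trace(seq: RnaSequence, params: EnergyParams,
          result: SparseResult) -> SecondaryStructure:
    """Reconstruct an MFE structure from a sparse forward-pass result.

    The returned structure's loop-sum energy equals `result.mfe` exactly;
    any mismatch raises `TraceInconsistencyError`.
    """
    T = params.tables()
    codes = seq.codes
    n = result.n
    cands = result.candidates
    arrows = result.arrows
    M, m = params.M, params.m
    a, b = params.ml_a, params.ml_b

    w_row = _RowCache(lambda i: recompute_W_row(i, n, cands))
    wm_rows = _RowCache(lambda i: recompute_WM_rows(i, n, cands, params))

    def resolve_v(i: int, j: int, e: int) -> List[Tuple]:
        if hairpin_energy_kernel(codes, i, j, T) == e:
            return []
        arrow = arrows.lookup((i, j))
        if arrow is not None:
            p, q = arrow.target
            cont = e - int(internal_energy_kernel(codes, i, j, p, q, T))
            if cont != arrow.target_energy:
                raise TraceInconsistencyError(
                    f"arrow ({i},{j})->({p},{q}): stored V = "
                    f"{arrow.target_energy}, recomputed {cont}")
            return [("V", p, q, cont)]
        # optimal internal loop into a candidate inner pair
        pmax = min(i + M + 1, j - m - 2)
        for p in range(i + 1, pmax + 1):
            qmin = max(p + m + 1, j - 1 - (M - (p - i - 1)))
            for q in range(qmin, j):
                vpq = cands.lookup(p, q)
                if vpq is None:
                    continue
                ie = internal_energy_kernel(codes, i, j, p, q, T)
                if ie < INF and ie + vpq == e:
                    return [("V", p, q, vpq)]
        # multiloop iff no other case yields the known energy
        au = T.term_au if T.pt[codes[i], codes[j]] > 2 else 0
        return [("WM2", i + 1, j - 1, e - a - b - au)]

    structure = run_trace_engine(
        seq, params, n, result.mfe, w_row, wm_rows,
        cands.column_asc, resolve_v)
    found = energy_of_structure(seq, structure, params)
    if found != result.mfe:
        raise TraceInconsistencyError(
            f"traced structure energy {format_energy(found)} != "
            f"MFE {format_energy(result.mfe)}")
    return structure
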