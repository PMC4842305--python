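"""Sparsified MFE forward pass with candidate lists and trace arrows.

The dense Zuker recursions keep O(n^2) matrix cells alive; here only a
rotating window of rows is materialized.  An interval [k,j] is a
*candidate* when its closed-structure energy strictly beats every
decomposition of the interval — for the exterior recursion W when
V(k,j) + au < Wp(k,j), and for the multiloop recursion WM when
V(k,j) + b + au < WMp(k,j) (au is the terminal AU/GU penalty of the
closing pair).  Split minimizations need only run over candidates: a
non-candidate's optimum is partitionable and therefore reachable through
smaller fragments.  A single merged per-column list serves both
recursions; entries store V(k,j), so every listed value is the energy of
a feasible closed structure and extra entries can never drive a minimum
below the true optimum.

Working state per row: the current rows of W, WM and WM2, the WM2 row of
i+1 (for the multiloop case of V), and the last M+2 rows of V (for the
internal-loop window).  Superlinear state is limited to the candidate
lists (Z entries) and the garbage-collected trace arrows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ._kernels import INF, v_cases_kernel
from .arrows import TraceArrowStore
from .energy import EnergyParams, RnaSequence

__all__ = [
    "CandidateEntry",
    "Candidates",
    "SparseStats",
    "SparseResult",
    "fold_sparse",
    "sparse_W_cases",
    "sparse_WM_WM2_cases",
    "v_cases",
]

#: (row k, V(k,j), terminal AU/GU penalty of the pair k.j)
CandidateEntry = Tuple[int, int, int]


class Candidates:
    """Per-column candidate lists with O(1) membership lookup.

    Column j holds entries (k, V(k,j), au(k,j)); the forward sweep
    appends them as the row index decreases, so each list is ordered by
    decreasing k and traversing the entries with k > i is linear in
    their number.
    """

    def __init__(self, n: int):
        self.n = n
        self._cols: List[List[CandidateEntry]] = [[] for _ in range(n + 1)]
        self._map: Dict[Tuple[int, int], int] = {}

    def append(self, k: int, j: int, v: int, au: int) -> None:
        col = self._cols[j]
        if col and col[-1][0] <= k:
            raise ValueError("candidates must be appended with decreasing k")
        col.append((k, v, au))
        self._map[(k, j)] = v

    def column(self, j: int) -> List[CandidateEntry]:
        """Entries of column j in decreasing k order."""
        return self._cols[j]

    def column_asc(self, j: int) -> Iterable[CandidateEntry]:
        return reversed(self._cols[j])

    def lookup(self, k: int, j: int) -> Optional[int]:
        return self._map.get((k, j))

    def contains(self, coord: Tuple[int, int]) -> bool:
        return coord in self._map

    @property
    def total(self) -> int:
        """Z: the total number of candidate entries."""
        return len(self._map)


@dataclass(frozen=True)
class SparseStats:
    """The counter set reported by --stats."""

    Z: int
    arrows_registered: int
    arrows_avoided: int
    arrows_gc_removed: int
    arrows_final: int
    arrows_max_simultaneous: int


@dataclass(frozen=True)
class WorkspaceAudit:
    """Shapes of every buffer the forward pass allocated.

    Used to assert the space contract: the sparse path never materializes
    a quadratic matrix — only `v_window_rows` + `aux_rows` row buffers
    plus the candidate and arrow stores.
    """

    n: int
    v_window_rows: int
    aux_rows: int
    buffers: Tuple[Tuple[str, Tuple[int, ...]], ...]

    @property
    def quadratic_buffers(self) -> int:
        return sum(
            1 for _, shape in self.buffers
            if len(shape) >= 2 and min(shape) > 40 and
            np.prod(shape) >= self.n * self.n
        )


@dataclass
class SparseResult:
    mfe: int
    candidates: Candidates
    arrows: TraceArrowStore
    stats: SparseStats
    n: int
    params: EnergyParams
    gc_enabled: bool
    workspace: WorkspaceAudit


def sparse_W_cases(i: int, j: int, W_cur: np.ndarray,
                   column: Sequence[CandidateEntry],
                   v_ij: int, au_ij: int) -> Tuple[int, int]:
    """W(i,j) from the sparsified case list.

    Returns (W(i,j), Wp_hat(i,j)) where the second component minimizes
    only over the decompositions: W(i,j-1) and the candidate splits
    W(i,k-1) + V(k,j) + au.  W(i,i)=0 and W(i,i-1)=0, so the empty first
    fragment is handled uniformly.
    """
    alt = W_cur[j - 1]
    for k, vk, auk in column:
        if k <= i:
            break
        e = W_cur[k - 1] + vk + auk
        if e < alt:
            alt = e
    w = alt
    if v_ij < INF and v_ij + au_ij < w:
        w = v_ij + au_ij
    return w, alt


def sparse_WM_WM2_cases(i: int, j: int, WM_cur: np.ndarray,
                        WM2_cur: np.ndarray,
                        column: Sequence[CandidateEntry],
                        v_ij: int, au_ij: int,
                        ml_b: int, ml_c: int) -> Tuple[int, int, int]:
    """WM(i,j) and WM2(i,j) from the sparsified case lists.

    WM covers non-empty multiloop fragments: the closed case V+b+au, a
    trailing unpaired base WM(i,j-1)+c, and for each candidate [k,j] the
    branch V(k,j)+b+au preceded either by a non-empty fragment
    WM(i,k-1) or by k-i unpaired bases at cost (k-i)*c.  WM2 requires at
    least two branches, so it has no leading-unpaired-only case.
    Returns (WM, WM2, WMp_hat).
    """
    wm_alt = WM_cur[j - 1] + ml_c if WM_cur[j - 1] < INF else INF
    wm2 = WM2_cur[j - 1] + ml_c if WM2_cur[j - 1] < INF else INF
    for k, vk, auk in column:
        if k <= i:
            break
        branch = vk + ml_b + auk
        prefix = WM_cur[k - 1]
        if prefix < INF:
            e = prefix + branch
            if e < wm_alt:
                wm_alt = e
            if e < wm2:
                wm2 = e
        lead = (k - i) * ml_c + branch
        if lead < wm_alt:
            wm_alt = lead
    wm = wm_alt
    if v_ij < INF and v_ij + ml_b + au_ij < wm:
        wm = v_ij + ml_b + au_ij
    return wm, wm2, wm_alt


def v_cases(seq: RnaSequence, i: int, j: int, v_window: np.ndarray,
            wm2_next: np.ndarray, params: EnergyParams
            ) -> Tuple[int, str, int, int]:
    """V(i,j) with its winning case.

    Returns (energy, case, p, q) with case in {"none", "hairpin",
    "internal", "multiloop"}; for the internal case (p, q) is the
    arg-min inner pair under the fixed tie-break (smallest p, then
    smallest q).
    """
    v, case, p, q = v_cases_kernel(seq.codes, i, j, v_window, wm2_next,
                                   params.tables())
    return int(v), ("none", "hairpin", "internal", "multiloop")[case], p, q


def fold_sparse(seq: RnaSequence, params: EnergyParams,
                gc_enabled: bool = True,
                register_arrows: bool = True,
                row_callback: Optional[Callable] = None) -> SparseResult:
    """Sparse energy minimization over rows i = n .. 1.

    For each cell the closed energy V(i,j) is evaluated from the V-row
    window and the WM2 row of i+1; the candidate criteria are applied;
    a trace arrow is registered when V's winning case is an internal
    loop whose inner pair is not a candidate; and W/WM/WM2 of the
    current row are computed from the candidate lists.  After each row,
    arrows sourced M+1 rows above are garbage collected (when
    `gc_enabled`).

    `register_arrows=False` is a fault-injection switch for tests: it
    suppresses arrow storage so the traceback demonstrably fails on
    inputs whose optimal inner pairs are not candidates.
    `row_callback(i, W_row, WM_row, WM2_row)` exposes each finished row
    to instrumentation harnesses.
    """
    T = params.tables()
    n, codes = seq.n, seq.codes
    M, m = params.M, params.m
    a, b, c = params.ml_a, params.ml_b, params.ml_c
    win = M + 2
    pt = T.pt

    v_window = np.full((win, n + 2), INF, dtype=np.int64)
    W_cur = np.zeros(n + 2, dtype=np.int64)
    WM_cur = np.full(n + 2, INF, dtype=np.int64)
    WM2_cur = np.full(n + 2, INF, dtype=np.int64)
    WM2_next = np.full(n + 2, INF, dtype=np.int64)
    workspace = WorkspaceAudit(
        n=n,
        v_window_rows=win,
        aux_rows=4,
        buffers=(
            ("v_window", v_window.shape),
            ("W_row", W_cur.shape),
            ("WM_row", WM_cur.shape),
            ("WM2_row", WM2_cur.shape),
            ("WM2_next_row", WM2_next.shape),
        ),
    )

    cands = Candidates(n)
    arrows = TraceArrowStore()

    mfe = 0
    for i in range(n, 0, -1):
        v_row = v_window[i % win]
        v_row[:] = INF
        W_cur[i - 1] = 0
        W_cur[i] = 0
        WM_cur[i] = INF
        WM2_cur[i] = INF
        for j in range(i + 1, n + 1):
            v, case, bp, bq = v_cases_kernel(codes, i, j, v_window,
                                             WM2_next, T)
            v = int(v)
            v_row[j] = v
            if case == 2 and register_arrows:
                arrows.register(
                    (i, j), (bp, bq),
                    target_energy=int(v_window[bp % win, bq]),
                    target_is_candidate=cands.contains((bp, bq)),
                )
            au_ij = T.term_au if pt[codes[i], codes[j]] > 2 else 0
            column = cands.column(j)
            w, w_alt = sparse_W_cases(i, j, W_cur, column, v, au_ij)
            wm, wm2, wm_alt = sparse_WM_WM2_cases(
                i, j, WM_cur, WM2_cur, column, v, au_ij, b, c)
            W_cur[j] = w
            WM_cur[j] = wm
            WM2_cur[j] = wm2
            if v < INF and (v + au_ij < w_alt or v + b + au_ij < wm_alt):
                cands.append(i, j, v, au_ij)
        if row_callback is not None:
            row_callback(i, W_cur.copy(), WM_cur.copy(), WM2_cur.copy())
        if gc_enabled and i + M + 1 <= n:
            arrows.gc_row(i + M + 1, cands.contains)
        WM2_next, WM2_cur = WM2_cur, WM2_next
    mfe = int(W_cur[n]) if n > 1 else 0

    stats = SparseStats(
        Z=cands.total,
        arrows_registered=arrows.registered,
        arrows_avoided=arrows.avoided,
        arrows_gc_removed=arrows.removed,
        arrows_final=arrows.final,
        arrows_max_simultaneous=arrows.max_simultaneous,
    )
    return SparseResult(
        mfe=mfe, candidates=cands, arrows=arrows, stats=stats,
        n=n, params=params, gc_enabled=gc_enabled, workspace=workspace,
    )
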