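"""Dense O(n^3)-time, O(n^2)-space MFE folding: the correctness oracle.

Implements the same loop-based recursions as the sparse folder but with
full matrices, in the WM2 multiloop formulation so that cell-by-cell
parity with the sparse rows is testable, plus a conventional traceback
and an exhaustive structure enumerator for tiny inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Tuple

import numpy as np

from ._kernels import (
    INF,
    fill_reference_kernel,
    hairpin_energy_kernel,
    internal_energy_kernel,
)
from .energy import EnergyParams, RnaSequence, can_pair
from .sparse import Candidates
from .structure import SecondaryStructure
from .traceback import TraceInconsistencyError, run_trace_engine

__all__ = [
    "DpMatrices",
    "fold_reference",
    "traceback_reference",
    "reference_candidates",
    "enumerate_structures",
]


@dataclass
class DpMatrices:
    """Full upper-triangular DP tables, 1-based.

    W/V/WM/WM2 are the standard loop-based matrices; WP and WMP hold the
    partition-only minima (W's and WM's alternatives to the closed
    case), from which candidacy is decided: [i,j] is a candidate iff
    V + au < WP(i,j) or V + b + au < WMP(i,j).
    """

    V: np.ndarray
    W: np.ndarray
    WM: np.ndarray
    WM2: np.ndarray
    WP: np.ndarray
    WMP: np.ndarray

    @property
    def n(self) -> int:
        return self.W.shape[0] - 2

    def w(self, i: int, j: int) -> int:
        return int(self.W[i, j])

    def v(self, i: int, j: int) -> int:
        return int(self.V[i, j])

    def wm(self, i: int, j: int) -> int:
        return int(self.WM[i, j])

    def wm2(self, i: int, j: int) -> int:
        return int(self.WM2[i, j])


def fold_reference(seq: RnaSequence,
                   params: EnergyParams) -> Tuple[int, DpMatrices]:
    """Fill all matrices bottom-up; the MFE is W(1, n)."""
    V, W, WM, WM2, WP, WMP = fill_reference_kernel(seq.codes, params.tables())
    mats = DpMatrices(V=V, W=W, WM=WM, WM2=WM2, WP=WP, WMP=WMP)
    n = seq.n
    return int(W[1, n]) if n > 1 else 0, mats


def reference_candidates(seq: RnaSequence, params: EnergyParams,
                         mats: DpMatrices) -> Candidates:
    """Candidate lists derived from the dense matrices.

    An interval [i,j] qualifies when its closed energy strictly beats
    every decomposition in W or in WM; this is the same merged criterion
    the sparse forward pass applies on the fly.
    """
    T = params.tables()
    n = seq.n
    b = params.ml_b
    cands = Candidates(n)
    for j in range(2, n + 1):
        for i in range(j - 1, 0, -1):
            v = int(mats.V[i, j])
            if v >= INF:
                continue
            au = T.term_au if T.pt[seq.codes[i], seq.codes[j]] > 2 else 0
            if v + au < mats.WP[i, j] or v + b + au < mats.WMP[i, j]:
                cands.append(i, j, v, au)
    return cands


def traceback_reference(seq: RnaSequence, params: EnergyParams,
                        mats: DpMatrices) -> SecondaryStructure:
    """Conventional traceback over the full matrices.

    Follows the same deterministic case order as the sparse traceback
    (split scans restricted to candidate intervals, internal-loop
    arg-min with smallest p then smallest q), so co-optimal ties resolve
    identically in both.
    """
    T = params.tables()
    codes = seq.codes
    n = seq.n
    M, m = params.M, params.m
    a, b = params.ml_a, params.ml_b
    cands = reference_candidates(seq, params, mats)

    def resolve_v(i: int, j: int, e: int) -> List[Tuple]:
        if hairpin_energy_kernel(codes, i, j, T) == e:
            return []
        pmax = min(i + M + 1, j - m - 2)
        for p in range(i + 1, pmax + 1):
            qmin = max(p + m + 1, j - 1 - (M - (p - i - 1)))
            for q in range(qmin, j):
                vpq = int(mats.V[p, q])
                if vpq >= INF:
                    continue
                ie = internal_energy_kernel(codes, i, j, p, q, T)
                if ie < INF and ie + vpq == e:
                    return [("V", p, q, vpq)]
        au = T.term_au if T.pt[codes[i], codes[j]] > 2 else 0
        cont = e - a - b - au
        if mats.WM2[i + 1, j - 1] != cont:
            raise TraceInconsistencyError(
                f"no case matches V({i},{j}) = {e}")
        return [("WM2", i + 1, j - 1, cont)]

    structure = run_trace_engine(
        seq, params, n, int(mats.W[1, n]) if n > 1 else 0,
        lambda i: mats.W[i],
        lambda i: (mats.WM[i], mats.WM2[i]),
        cands.column_asc, resolve_v)
    return structure


def enumerate_structures(seq: RnaSequence, params: EnergyParams,
                         cap: int = 18) -> Iterator[SecondaryStructure]:
    """Yield every valid pseudoknot-free structure exactly once.

    Recursive decomposition on the leftmost position: it is either
    unpaired or paired to some k; the two cases (and different k) give
    disjoint structure sets, so no duplicates arise.  Intended as a
    brute-force oracle; refuses sequences longer than `cap`.
    """
    n = seq.n
    if n > cap:
        raise ValueError(
            f"exhaustive enumeration capped at n = {cap}, got {n}")

    def gen(i: int, j: int) -> Iterator[List[Tuple[int, int]]]:
        if i > j:
            yield []
            return
        for rest in gen(i + 1, j):
            yield rest
        for k in range(i + params.m + 1, j + 1):
            if not can_pair(seq, i, k, params):
                continue
            for inner in gen(i + 1, k - 1):
                for outer in gen(k + 1, j):
                    yield [(i, k)] + inner + outer

    for pairs in gen(1, n):
        yield SecondaryStructure(n, pairs)
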