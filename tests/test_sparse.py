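"""Sparse forward pass: cell parity, candidate criteria, determinism."""

import numpy as np
import pytest

import sparsefold as sf
from sparsefold._kernels import INF
from sparsefold.sparse import sparse_W_cases, sparse_WM_WM2_cases, v_cases


def _random_seq(seed, lo=10, hi=61):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(lo, hi))
    return sf.random_sequence(sf.GeneratorConfig(
        n=n, gc_fraction=(0.3, 0.5, 0.7)[seed % 3], seed=seed))


@pytest.mark.parametrize("seed", range(12))
def test_row_parity_with_reference(params, seed):
    """Every W/WM/WM2 row of the sparse sweep equals the dense matrices."""
    seq = _random_seq(seed)
    _, mats = sf.fold_reference(seq, params)
    rows = {}
    sf.fold_sparse(seq, params,
                   row_callback=lambda i, W, WM, WM2: rows.__setitem__(
                       i, (W, WM, WM2)))
    for i, (W, WM, WM2) in rows.items():
        n = seq.n
        assert np.array_equal(W[i:n + 1], mats.W[i, i:n + 1]), f"W row {i}"
        assert np.array_equal(WM[i:n + 1], mats.WM[i, i:n + 1]), f"WM row {i}"
        assert np.array_equal(WM2[i:n + 1], mats.WM2[i, i:n + 1]), f"WM2 row {i}"


@pytest.mark.parametrize("seed", range(10))
def test_candidate_parity_and_soundness(params, seed):
    """The sparse candidate set equals the matrix-derived one, and every
    non-candidate is partitionable (its closed energy never strictly
    beats both decomposition minima)."""
    seq = _random_seq(100 + seed)
    _, mats = sf.fold_reference(seq, params)
    ref = sf.reference_candidates(seq, params, mats)
    res = sf.fold_sparse(seq, params)
    assert res.candidates._map == ref._map
    b = params.ml_b
    n = seq.n
    for i in range(1, n + 1):
        for j in range(i + params.m + 1, n + 1):
            v = mats.v(i, j)
            if v >= INF:
                continue
            au = sf.au_penalty(seq, i, j, params)
            is_cand = res.candidates.lookup(i, j) is not None
            strictly_better = (v + au < mats.WP[i, j]
                               or v + b + au < mats.WMP[i, j])
            assert is_cand == bool(strictly_better), (i, j)


class TestWorkedExample:
    """The 11-mer G C C A A A A G G G C from the hairpin-stacking family."""

    def test_column_9_has_no_candidate_row_3(self, params, lemma_seq):
        res = sf.fold_sparse(lemma_seq, params)
        assert all(k != 3 for k, _, _ in res.candidates.column(9))
        assert res.candidates.lookup(3, 9) is None

    def test_v_2_10_wins_internal_loop_into_3_9(self, params, lemma_seq):
        _, mats = sf.fold_reference(lemma_seq, params)
        win, wm2 = _window_from_matrices(mats, 2, lemma_seq.n, params)
        e, case, p, q = v_cases(lemma_seq, 2, 10, win, wm2, params)
        assert (e, case, p, q) == (100, "internal", 3, 9)

    def test_v_3_9_is_hairpin(self, params, lemma_seq):
        _, mats = sf.fold_reference(lemma_seq, params)
        win, wm2 = _window_from_matrices(mats, 3, lemma_seq.n, params)
        e, case, _, _ = v_cases(lemma_seq, 3, 9, win, wm2, params)
        assert (e, case) == (430, "hairpin")

    def test_v_noncomplementary_none(self, params, lemma_seq):
        _, mats = sf.fold_reference(lemma_seq, params)
        win, wm2 = _window_from_matrices(mats, 4, lemma_seq.n, params)
        e, case, _, _ = v_cases(lemma_seq, 4, 10, win, wm2, params)  # A-G
        assert (e, case) == (sf.INF, "none")

    def test_arrow_registered_to_non_candidate_inner_pair(
            self, params, lemma_seq):
        res = sf.fold_sparse(lemma_seq, params)
        arrow = res.arrows.lookup((2, 10))
        assert arrow is not None
        assert arrow.target == (3, 9)
        assert arrow.target_energy == 430


def _window_from_matrices(mats, i, n, params):
    """Build the V-row window and the WM2 row of i+1 from the dense
    matrices, for driving the cell-level operations directly."""
    win = params.M + 2
    v_window = np.full((win, n + 2), INF, dtype=np.int64)
    for p in range(i + 1, min(i + params.M + 1, n) + 1):
        v_window[p % win] = mats.V[p]
    wm2 = mats.WM2[i + 1] if i + 1 <= n else np.full(n + 2, INF, np.int64)
    return v_window, wm2


def test_sparse_W_cases_boundary(params):
    # j = i + 1: no candidates possible, W(i,i) = 0
    W = np.zeros(10, dtype=np.int64)
    w, alt = sparse_W_cases(3, 4, W, [], v_ij=INF, au_ij=0)
    assert (w, alt) == (0, 0)
    w, _ = sparse_W_cases(3, 4, W, [], v_ij=-100, au_ij=50)
    assert w == -50


def test_sparse_WM_cases_below_threshold(params):
    WM = np.full(10, INF, dtype=np.int64)
    WM2 = np.full(10, INF, dtype=np.int64)
    wm, wm2, _ = sparse_WM_WM2_cases(3, 5, WM, WM2, [], INF, 0,
                                     params.ml_b, params.ml_c)
    assert wm == INF and wm2 == INF


@pytest.mark.parametrize("seed", [0, 1])
def test_bit_identical_determinism(params, seed):
    seq = _random_seq(300 + seed, lo=60, hi=100)
    r1 = sf.fold_sparse(seq, params)
    r2 = sf.fold_sparse(seq, params)
    assert r1.mfe == r2.mfe
    assert r1.stats == r2.stats
    assert r1.candidates._map == r2.candidates._map
    assert dict(r1.arrows.items()).keys() == dict(r2.arrows.items()).keys()
    assert sf.trace(seq, params, r1).pairs == sf.trace(seq, params, r2).pairs


def test_stats_and_workspace_fields(params):
    seq = _random_seq(999, lo=80, hi=81)
    res = sf.fold_sparse(seq, params)
    s = res.stats
    assert s.Z == res.candidates.total
    assert s.arrows_final == s.arrows_registered - s.arrows_gc_removed
    assert s.arrows_max_simultaneous >= s.arrows_final
    assert res.workspace.v_window_rows == params.M + 2
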