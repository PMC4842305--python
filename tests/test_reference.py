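"""Dense reference folder: brute-force oracle, traceback, enumeration."""

from functools import lru_cache

import numpy as np
import pytest

import sparsefold as sf


def brute_force_mfe(seq, params):
    return min(
        sf.energy_of_structure(seq, s, params)
        for s in sf.enumerate_structures(seq, params)
    )


def count_structures_independent(seq, params):
    """Second, independent implementation of the structure count."""
    n = seq.n

    @lru_cache(maxsize=None)
    def c(i, j):
        if j - i < 0:
            return 1
        total = c(i + 1, j)  # i unpaired
        for k in range(i + params.m + 1, j + 1):
            if sf.can_pair(seq, i, k, params):
                total += c(i + 1, k - 1) * c(k + 1, j)
        return total

    return c(1, n)


class TestFoldReference:
    def test_no_pair_possible_mfe_zero(self, params):
        mfe, _ = sf.fold_reference(sf.RnaSequence("ACGU"), params)
        assert mfe == 0

    def test_single_base(self, params):
        mfe, _ = sf.fold_reference(sf.RnaSequence("A"), params)
        assert mfe == 0

    def test_worked_example_matrices(self, params, lemma_seq):
        mfe, mats = sf.fold_reference(lemma_seq, params)
        assert mfe == -240  # helix (1,11)(2,10)(3,9)
        assert mats.v(3, 9) == 430
        assert mats.v(2, 10) == 100  # -3.3 + 4.3
        # the closed case of [3,9] never beats a decomposition: with the
        # empty structure admitted, W(3,9) = 0 < V(3,9)
        assert mats.w(3, 9) == 0
        assert mats.v(3, 9) > mats.WP[3, 9]

    def test_region_3_9_best_nonempty_structure_is_hairpin_3_8(
            self, params, lemma_seq):
        # the MFE *structure* of S[3..9] forms the hairpin closed by
        # (3,8), not (3,9): best non-empty energy is H(3,8) = 4.1
        sub = sf.RnaSequence(lemma_seq.residues[2:9])
        best = min(
            (sf.energy_of_structure(sub, s, params), s)
            for s in sf.enumerate_structures(sub, params) if s.pairs
        )
        assert best[0] == 410
        assert best[1].pairs == {(1, 6)}  # = (3, 8) in full coordinates
        assert best[0] < sf.hairpin_energy(lemma_seq, 3, 9, params)

    @pytest.mark.parametrize("seed", range(12))
    def test_brute_force_equivalence_small(self, params, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 17))
        seq = sf.random_sequence(sf.GeneratorConfig(
            n=n, gc_fraction=0.5, seed=seed + 100))
        mfe, _ = sf.fold_reference(seq, params)
        assert mfe == brute_force_mfe(seq, params)

    def test_prefix_monotonicity(self, params):
        # exterior bases are free: removing the first base cannot
        # improve the MFE
        for seed in range(10):
            seq = sf.random_sequence(sf.GeneratorConfig(
                n=40, gc_fraction=0.5, seed=seed))
            full, _ = sf.fold_reference(seq, params)
            suffix, _ = sf.fold_reference(
                sf.RnaSequence(seq.residues[1:]), params)
            assert full <= suffix


class TestTracebackReference:
    def test_unpairable_sequence_empty_structure(self, params):
        seq = sf.RnaSequence("AAAA")
        mfe, mats = sf.fold_reference(seq, params)
        assert sf.traceback_reference(seq, params, mats).to_dotbracket() == "...."

    def test_worked_example_structure(self, params, lemma_seq):
        mfe, mats = sf.fold_reference(lemma_seq, params)
        st = sf.traceback_reference(lemma_seq, params, mats)
        assert st.pairs == {(1, 11), (2, 10), (3, 9)}
        assert sf.energy_of_structure(lemma_seq, st, params) == mfe

    @pytest.mark.parametrize("seed", range(15))
    def test_traceback_energy_identity(self, params, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(10, 70))
        seq = sf.random_sequence(sf.GeneratorConfig(
            n=n, gc_fraction=(0.3, 0.5, 0.7)[seed % 3], seed=seed))
        mfe, mats = sf.fold_reference(seq, params)
        st = sf.traceback_reference(seq, params, mats)
        st.validate(seq, params)
        assert sf.energy_of_structure(seq, st, params) == mfe


class TestEnumerateStructures:
    def test_unpairable(self, params):
        out = list(sf.enumerate_structures(sf.RnaSequence("AAAA"), params))
        assert len(out) == 1 and not out[0].pairs

    def test_single_possible_pair(self, params):
        out = list(sf.enumerate_structures(sf.RnaSequence("GAAAC"), params))
        assert sorted(s.pairs for s in out) == [frozenset(), frozenset({(1, 5)})]

    def test_cap_refused(self, params):
        with pytest.raises(ValueError):
            list(sf.enumerate_structures(
                sf.RnaSequence("A" * 30), params))

    @pytest.mark.parametrize("residues", [
        "GCCAAAAGGGC",
        "GGGGAAAACCCC",
        "GCAUGCAUGCAUGC",
    ])
    def test_count_matches_independent_recursion(self, params, residues):
        seq = sf.RnaSequence(residues)
        structures = list(sf.enumerate_structures(seq, params))
        # exactly once each
        assert len({s.pairs for s in structures}) == len(structures)
        assert len(structures) == count_structures_independent(seq, params)
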