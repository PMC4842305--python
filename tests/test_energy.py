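"""Energy model: parameter loading, loop energies, structure energies."""

import numpy as np
import pytest

import sparsefold as sf
from sparsefold.energy import _builtin_param_file


class TestLoadParams:
    def test_builtin_defaults(self, params):
        assert params.m == 3
        assert params.M == 30
        # multiloop affine model constants of the 2004 set, 0.01 kcal/mol
        assert (params.ml_a, params.ml_b, params.ml_c) == (930, -90, 0)
        assert params.term_au == 50

    def test_stack_cg_cg_matches_file(self, params):
        # CG stacked on CG, read directly from the parameter file
        assert params.stack[1, 1] == -240
        assert params.stack[1, 1] < 0

    def test_stack_table_symmetric(self, params):
        # the published stacking table is symmetric in (outer, inner)
        block = params.stack[1:8, 1:8]
        assert np.array_equal(block, block.T)

    def test_truncated_file_rejected(self, tmp_path):
        full = _builtin_param_file("turner2004").read_text()
        bad = tmp_path / "trunc.par"
        bad.write_text(full[:3000])
        with pytest.raises(sf.ParamError):
            sf.load_params(bad)

    def test_missing_file_and_unknown_builtin(self, tmp_path):
        with pytest.raises(sf.ParamError):
            sf.load_params(tmp_path / "nope.par")
        with pytest.raises(sf.ParamError):
            sf.load_params("turner1887")

    def test_wrong_dialect_rejected(self, tmp_path):
        f = tmp_path / "bad.par"
        f.write_text("# stack\n1 2 3\n")
        with pytest.raises(sf.ParamError):
            sf.load_params(f)


class TestRnaSequence:
    def test_normalization(self):
        s = sf.RnaSequence("gccTaaagggc")
        assert s.residues == "GCCUAAAGGGC"
        assert s.n == 11

    def test_strict_rejects_bad_residue(self):
        with pytest.raises(ValueError, match="position 3"):
            sf.RnaSequence("GCXN")

    def test_lenient_maps_to_n(self, params):
        s = sf.RnaSequence("GCXG", strict=False)
        assert s.residues == "GCNG"
        assert s.codes[3] == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sf.RnaSequence("   ")


class TestCanPair:
    @pytest.mark.parametrize("seq,i,j,expect", [
        ("GAAAAC", 1, 6, True),    # G-C
        ("GAAAAU", 1, 6, True),    # G-U wobble
        ("AAAAAC", 1, 6, False),   # A-C illegal
        ("GAAAC", 1, 5, True),     # j - i = 4 > m
        ("GAAC", 1, 4, False),     # j - i = 3 <= m
    ])
    def test_pairing_rule(self, params, seq, i, j, expect):
        assert sf.can_pair(sf.RnaSequence(seq), i, j, params) is expect


class TestLoopEnergies:
    def test_hairpin_values_of_worked_example(self, params, lemma_seq):
        # H(3,9) = 4.3 kcal/mol, H(3,8) = 4.1 kcal/mol
        assert sf.hairpin_energy(lemma_seq, 3, 9, params) == 430
        assert sf.hairpin_energy(lemma_seq, 3, 8, params) == 410

    def test_hairpin_below_minimum_size_inf(self, params, lemma_seq):
        assert sf.hairpin_energy(lemma_seq, 3, 6, params) == sf.INF

    def test_hairpin_noncomplementary_inf(self, params):
        assert sf.hairpin_energy(
            sf.RnaSequence("AAAAAAAA"), 1, 8, params) == sf.INF

    def test_internal_value_of_worked_example(self, params, lemma_seq):
        # the stacked pair I(2,10,3,9) = -3.3 kcal/mol
        assert sf.internal_energy(lemma_seq, 2, 10, 3, 9, params) == -330

    def test_internal_loop_size_cap(self, params):
        seq = sf.RnaSequence("G" + "A" * 20 + "GAAAC" + "A" * 20 + "C")
        # 40 unpaired bases > M = 30
        assert sf.internal_energy(seq, 1, 47, 22, 26, params) == sf.INF

    def test_internal_noncomplementary_outer_inf(self, params):
        seq = sf.RnaSequence("AACAAAAGAA")
        assert sf.internal_energy(seq, 1, 10, 3, 8, params) == sf.INF

    def test_internal_bad_indices_raise(self, params, lemma_seq):
        with pytest.raises(ValueError):
            sf.internal_energy(lemma_seq, 3, 9, 2, 10, params)


class TestEnergyOfStructure:
    def test_empty_structure_zero(self, params, lemma_seq):
        empty = sf.SecondaryStructure(lemma_seq.n)
        assert sf.energy_of_structure(lemma_seq, empty, params) == 0

    def test_single_hairpin(self, params, lemma_seq):
        st = sf.SecondaryStructure(11, [(3, 9)])
        assert sf.energy_of_structure(lemma_seq, st, params) == 430

    def test_hairpin_plus_stack(self, params, lemma_seq):
        # -3.3 + 4.3 = 1.0 kcal/mol
        st = sf.SecondaryStructure(11, [(2, 10), (3, 9)])
        assert sf.energy_of_structure(lemma_seq, st, params) == 100

    def test_full_helix(self, params, lemma_seq):
        st = sf.SecondaryStructure(11, [(1, 11), (2, 10), (3, 9)])
        assert sf.energy_of_structure(lemma_seq, st, params) == -240

    def test_invalid_structure_rejected(self, params, lemma_seq):
        st = sf.SecondaryStructure(11, [(1, 5)])  # G-A cannot pair
        with pytest.raises(sf.StructureError):
            sf.energy_of_structure(lemma_seq, st, params)


def test_format_energy():
    assert sf.format_energy(-240) == "-2.40"
    assert sf.format_energy(0) == "0.00"
    assert sf.format_energy(105) == "1.05"
    assert sf.kcal(-240) == -2.4
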