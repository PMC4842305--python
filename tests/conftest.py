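"""Shared fixtures.

The `corpus` fixture builds, once per session, the full equivalence
corpus: seeded random sequences spanning lengths 10-150 at three GC
contents, plus the hairpin-stacking family G C^k A^4 G^(k+1) C for
k = 1..20.  Each entry is folded with the dense reference algorithm and
with the sparse algorithm with garbage collection on and off, and both
sparse runs are traced back.  Several tests assert different properties
over the same corpus, so the expensive part runs once.
"""

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pytest

import sparsefold as sf

#: an 78-mer whose MFE fold contains a multiloop (two helices branch
#: from the pair (5, 74)); used wherever a multiloop trace is needed
MULTILOOP_SEQ = (
    "GUCGCUCUUUGGACAGCGCUUUCCUAUGCUUCGGCCUGUCUGUACCUCUAGGAUUUAUGGUGAACACAACUUCGCGAC"
)


@pytest.fixture(scope="session")
def params() -> sf.EnergyParams:
    return sf.load_params("turner2004")


@pytest.fixture(scope="session")
def lemma_seq() -> sf.RnaSequence:
    """The 11-mer worked example G C C A A A A G G G C."""
    return sf.s_k_sequence(2)


@dataclass
class CorpusCase:
    name: str
    seq: sf.RnaSequence
    ref_mfe: int
    ref_struct: sf.SecondaryStructure
    on: sf.SparseResult
    on_struct: sf.SecondaryStructure
    off: sf.SparseResult
    off_struct: sf.SecondaryStructure


def _fold_case(name: str, seq: sf.RnaSequence,
               params: sf.EnergyParams) -> CorpusCase:
    ref_mfe, mats = sf.fold_reference(seq, params)
    ref_struct = sf.traceback_reference(seq, params, mats)
    on = sf.fold_sparse(seq, params, gc_enabled=True)
    off = sf.fold_sparse(seq, params, gc_enabled=False)
    return CorpusCase(
        name=name, seq=seq,
        ref_mfe=ref_mfe, ref_struct=ref_struct,
        on=on, on_struct=sf.trace(seq, params, on),
        off=off, off_struct=sf.trace(seq, params, off),
    )


@pytest.fixture(scope="session")
def corpus(params) -> List[CorpusCase]:
    cases = []
    rng = np.random.default_rng(20160423)
    gcs = (0.3, 0.5, 0.7)
    for idx in range(201):
        n = int(rng.integers(10, 151))
        gc = gcs[idx % 3]
        seed = int(rng.integers(2**31))
        seq = sf.random_sequence(
            sf.GeneratorConfig(n=n, gc_fraction=gc, seed=seed))
        cases.append(_fold_case(f"rand-{idx}-n{n}-gc{gc}", seq, params))
    for k in range(1, 21):
        cases.append(_fold_case(f"s_k-{k}", sf.s_k_sequence(k), params))
    return cases
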