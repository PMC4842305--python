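"""Turner-style nearest-neighbor loop energies with no dangling ends.

Energies are exact integers in 0.01 kcal/mol — the native unit of the
nearest-neighbor parameter files, kept unscaled so that the logarithmic
loop-size extrapolation truncates identically to the standard
implementation; ``INF`` marks infeasibility and absorbs addition.
Conversion to kcal/mol happens only at I/O.  The public operations mirror the loop terms of the
model: hairpin loops H(i,j), internal loops I(i,j,p,q) (subsuming stacks
and bulges), the affine multiloop penalty a + b*branches + c*unpaired, and
terminal AU/GU penalties at exterior-loop and multiloop helix ends.
Parameters are read from nearest-neighbor parameter files in the widely
used Vienna 2.x text dialect; the builtin ``"turner2004"`` set resolves to
the Turner 2004 tables shipped with the locally installed ViennaRNA
distribution.
"""

from __future__ import annotations

import math
import os
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from ._kernels import (
    INF,
    Tables,
    hairpin_energy_kernel,
    internal_energy_kernel,
    make_pair_table,
)
from .structure import SecondaryStructure, StructureError

__all__ = [
    "INF",
    "Energy",
    "RnaSequence",
    "EnergyParams",
    "ParamError",
    "load_params",
    "can_pair",
    "pair_type",
    "au_penalty",
    "hairpin_energy",
    "internal_energy",
    "energy_of_structure",
    "format_energy",
    "kcal",
]

Energy = int  # integer, 0.01 kcal/mol; INF = infeasible

_BASE_CODE = {"N": 0, "A": 1, "C": 2, "G": 3, "U": 4}
_PAIR_TABLE = make_pair_table()


def kcal(e: Energy) -> float:
    """An integer energy as a float in kcal/mol."""
    return e / 100.0


def format_energy(e: Energy) -> str:
    """Render an integer energy as kcal/mol with two decimals."""
    if e >= INF:
        return "inf"
    return f"{e / 100:.2f}"


class ParamError(ValueError):
    """Malformed or incomplete nearest-neighbor parameter file."""


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over {A,C,G,U}, 1-based.

    DNA input is accepted (T is mapped to U).  With ``strict=True`` any
    other letter raises; otherwise it is mapped to the non-pairing
    placeholder N.
    """

    residues: str
    codes: np.ndarray = field(repr=False, compare=False)

    def __init__(self, residues: str, strict: bool = True):
        raw = residues.strip().upper().replace("T", "U")
        if not raw:
            raise ValueError("empty sequence")
        chars = []
        for pos, ch in enumerate(raw, start=1):
            if ch in "ACGU":
                chars.append(ch)
            elif strict:
                raise ValueError(
                    f"illegal residue {ch!r} at position {pos}"
                )
            else:
                chars.append("N")
        seq = "".join(chars)
        codes = np.zeros(len(seq) + 1, dtype=np.int64)
        for pos, ch in enumerate(seq, start=1):
            codes[pos] = _BASE_CODE[ch]
        object.__setattr__(self, "residues", seq)
        object.__setattr__(self, "codes", codes)

    @property
    def n(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


# ---------------------------------------------------------------------------
# parameter set
# ---------------------------------------------------------------------------

@dataclass
class EnergyParams:
    """All nearest-neighbor tables plus the model constants.

    ``ml_a``/``ml_b``/``ml_c`` are the multiloop initiation, branch and
    unpaired-base penalties; ``m`` is the minimum hairpin loop size and
    ``M`` the maximum number of unpaired bases in an internal loop.
    """

    stack: np.ndarray
    mismatch_hairpin: np.ndarray
    mismatch_internal: np.ndarray
    mismatch_internal_1n: np.ndarray
    mismatch_internal_23: np.ndarray
    int11: np.ndarray
    int21: np.ndarray
    int22: np.ndarray
    hairpin_init: np.ndarray
    bulge_init: np.ndarray
    internal_init: np.ndarray
    ninio: int
    max_ninio: int
    term_au: int
    ml_a: int
    ml_b: int
    ml_c: int
    special_loops: Dict[str, int]
    m: int = 3
    M: int = 30
    lxc: float = 107.856
    source: str = "?"

    def __post_init__(self):
        if self.m < 3:
            raise ValueError("minimum hairpin loop size m must be >= 3")
        if self.M < 0:
            raise ValueError("internal loop size cap M must be >= 0")
        self._tables: Optional[Tables] = None

    def tables(self) -> Tables:
        """The flat, kernel-ready view of the parameter set (cached)."""
        if self._tables is None:
            tri, tetra, hexa = [], [], []
            for motif, e in self.special_loops.items():
                code = 0
                for ch in motif:
                    code = code * 5 + _BASE_CODE[ch]
                {5: tri, 6: tetra, 8: hexa}[len(motif)].append((code, e))

            def cols(entries):
                if not entries:
                    return (np.zeros(0, dtype=np.int64),
                            np.zeros(0, dtype=np.int64))
                c, e = zip(*entries)
                return (np.asarray(c, dtype=np.int64),
                        np.asarray(e, dtype=np.int64))

            tri_c, tri_e = cols(tri)
            tetra_c, tetra_e = cols(tetra)
            hexa_c, hexa_e = cols(hexa)
            self._tables = Tables(
                pt=_PAIR_TABLE,
                stack=self.stack,
                mmh=self.mismatch_hairpin,
                mmi=self.mismatch_internal,
                mm1n=self.mismatch_internal_1n,
                mm23=self.mismatch_internal_23,
                int11=self.int11,
                int21=self.int21,
                int22=self.int22,
                hairpin=self.hairpin_init,
                bulge=self.bulge_init,
                internal=self.internal_init,
                ninio=self.ninio,
                max_ninio=self.max_ninio,
                lxc=self.lxc,
                term_au=self.term_au,
                ml_a=self.ml_a,
                ml_b=self.ml_b,
                ml_c=self.ml_c,
                m=self.m,
                M=self.M,
                tri_codes=tri_c, tri_e=tri_e,
                tetra_codes=tetra_c, tetra_e=tetra_e,
                hexa_codes=hexa_c, hexa_e=hexa_e,
            )
        return self._tables


# -- Vienna 2.x dialect reader ----------------------------------------------

_SKIP_SECTIONS = {
    # present in the standard files but unused without dangling ends /
    # duplex folding; recognized and skipped silently
    "stack_enthalpies", "mismatch_hairpin_enthalpies",
    "mismatch_internal_enthalpies", "mismatch_internal_1n_enthalpies",
    "mismatch_internal_23_enthalpies", "mismatch_multi",
    "mismatch_multi_enthalpies", "mismatch_exterior",
    "mismatch_exterior_enthalpies", "dangle5", "dangle5_enthalpies",
    "dangle3", "dangle3_enthalpies", "int11_enthalpies",
    "int21_enthalpies", "int22_enthalpies", "hairpin_enthalpies",
    "bulge_enthalpies", "internal_enthalpies", "END",
}

_TABLE_SHAPES = {
    "stack": 49,
    "mismatch_hairpin": 175,
    "mismatch_internal": 175,
    "mismatch_internal_1n": 175,
    "mismatch_internal_23": 175,
    "int11": 1225,
    "int21": 6125,
    "int22": 9216,
    "hairpin": 31,
    "bulge": 31,
    "internal": 31,
    "ML_params": 6,
    "NINIO": 3,
    "Misc": 4,
}


def _strip_comments(line: str) -> str:
    while "/*" in line:
        a = line.index("/*")
        b = line.find("*/", a)
        if b < 0:
            line = line[:a]
        else:
            line = line[:a] + " " + line[b + 2:]
    return line


def _parse_sections(text: str) -> Dict[str, List[str]]:
    sections: Dict[str, List[str]] = {}
    current: Optional[str] = None
    for raw in text.splitlines():
        if raw.startswith("##"):
            continue
        if raw.startswith("#"):
            current = raw[1:].strip()
            sections.setdefault(current, [])
            continue
        line = _strip_comments(raw).strip()
        if not line or current is None:
            continue
        sections[current].extend(line.split())
    return sections


def _ints(tokens: List[str], section: str) -> np.ndarray:
    out = np.empty(len(tokens), dtype=np.int64)
    for idx, tok in enumerate(tokens):
        if tok.upper() in ("INF", "@"):
            out[idx] = INF
        else:
            try:
                out[idx] = int(round(float(tok)))
            except ValueError as exc:
                raise ParamError(
                    f"section {section!r}: bad token {tok!r}"
                ) from exc
    return out


def _require(sections, name) -> np.ndarray:
    if name not in sections:
        raise ParamError(f"missing required section {name!r}")
    vals = _ints(sections[name], name)
    want = _TABLE_SHAPES[name]
    if name == "Misc":
        if len(vals) < 4:
            raise ParamError(
                f"section 'Misc': expected >= 4 values, got {len(vals)}"
            )
    elif len(vals) != want:
        raise ParamError(
            f"section {name!r}: expected {want} values, got {len(vals)}"
        )
    return vals


def _pairwise_block(vals, *dims) -> np.ndarray:
    return np.asarray(vals, dtype=np.int64).reshape(dims)


def _parse_param_text(text: str, source: str, m: int, M: int) -> EnergyParams:
    if not text.lstrip().startswith("## RNAfold parameter file v2.0"):
        raise ParamError(
            f"{source}: not a Vienna 2.x parameter file "
            "(missing '## RNAfold parameter file v2.0' header)"
        )
    sections = _parse_sections(text)
    for name in sections:
        if name and name not in _TABLE_SHAPES and name not in _SKIP_SECTIONS \
                and name not in ("Triloops", "Tetraloops", "Hexaloops"):
            warnings.warn(f"{source}: skipping unknown section {name!r}")

    stack = np.zeros((8, 8), dtype=np.int64)
    stack[1:8, 1:8] = _pairwise_block(_require(sections, "stack"), 7, 7)

    def mismatch(name):
        t = np.zeros((8, 5, 5), dtype=np.int64)
        t[1:8] = _pairwise_block(_require(sections, name), 7, 5, 5)
        return t

    mmh = mismatch("mismatch_hairpin")
    mmi = mismatch("mismatch_internal")
    mm1n = mismatch("mismatch_internal_1n")
    mm23 = mismatch("mismatch_internal_23")

    int11 = np.zeros((8, 8, 5, 5), dtype=np.int64)
    int11[1:8, 1:8] = _pairwise_block(_require(sections, "int11"), 7, 7, 5, 5)
    int21 = np.zeros((8, 8, 5, 5, 5), dtype=np.int64)
    int21[1:8, 1:8] = _pairwise_block(
        _require(sections, "int21"), 7, 7, 5, 5, 5)
    int22 = np.zeros((8, 8, 5, 5, 5, 5), dtype=np.int64)
    int22[1:7, 1:7, 1:5, 1:5, 1:5, 1:5] = _pairwise_block(
        _require(sections, "int22"), 6, 6, 4, 4, 4, 4)

    hairpin = _require(sections, "hairpin")
    bulge = _require(sections, "bulge")
    internal = _require(sections, "internal")
    mlp = _require(sections, "ML_params")
    ninio = _require(sections, "NINIO")
    misc = _require(sections, "Misc")

    special: Dict[str, int] = {}
    for name, width in (("Triloops", 5), ("Tetraloops", 6), ("Hexaloops", 8)):
        toks = sections.get(name, [])
        if len(toks) % 3 != 0:
            raise ParamError(f"section {name!r}: expected triples, got {toks}")
        for idx in range(0, len(toks), 3):
            motif = toks[idx].upper().replace("T", "U")
            if len(motif) != width or any(c not in "ACGU" for c in motif):
                raise ParamError(f"section {name!r}: bad motif {toks[idx]!r}")
            special[motif] = int(toks[idx + 1])

    return EnergyParams(
        stack=stack,
        mismatch_hairpin=mmh,
        mismatch_internal=mmi,
        mismatch_internal_1n=mm1n,
        mismatch_internal_23=mm23,
        int11=int11,
        int21=int21,
        int22=int22,
        hairpin_init=hairpin,
        bulge_init=bulge,
        internal_init=internal,
        ninio=int(ninio[0]),
        max_ninio=int(ninio[2]),
        term_au=int(misc[2]),
        ml_a=int(mlp[2]),
        ml_b=int(mlp[4]),
        ml_c=int(mlp[0]),
        special_loops=special,
        m=m,
        M=M,
        source=source,
    )


def _builtin_param_file(name: str) -> Path:
    fname = {"turner2004": "rna_turner2004.par",
             "turner1999": "rna_turner1999.par"}.get(name)
    if fname is None:
        raise ParamError(f"unknown builtin parameter set {name!r}")
    roots = [Path(sys.prefix)]
    if os.environ.get("CONDA_PREFIX"):
        roots.append(Path(os.environ["CONDA_PREFIX"]))
    try:  # the ViennaRNA python bindings know their own install prefix
        import RNA  # type: ignore

        roots.append(Path(RNA.__file__).resolve().parents[4])
    except Exception:
        pass
    for root in roots:
        candidate = root / "share" / "ViennaRNA" / fname
        if candidate.is_file():
            return candidate
    raise ParamError(
        f"builtin parameter set {name!r}: file {fname} not found under "
        + ", ".join(str(r / "share" / "ViennaRNA") for r in roots)
    )


def load_params(source: Union[str, Path] = "turner2004",
                m: int = 3, M: int = 30) -> EnergyParams:
    """Load a nearest-neighbor parameter set.

    ``source`` is either a builtin identifier (``"turner2004"``, the
    default) or a path to a parameter file in the Vienna 2.x dialect.
    ``m`` and ``M`` set the minimum hairpin loop size and the internal
    loop size cap.
    """
    src = str(source)
    if isinstance(source, str) and not os.path.exists(source) and "/" not in source:
        path = _builtin_param_file(source)
    else:
        path = Path(source)
        if not path.is_file():
            raise ParamError(f"parameter file not found: {path}")
    text = path.read_text()
    return _parse_param_text(text, src, m=m, M=M)


# ---------------------------------------------------------------------------
# loop-energy operations
# ---------------------------------------------------------------------------

def pair_type(seq: RnaSequence, i: int, j: int) -> int:
    return int(_PAIR_TABLE[seq.codes[i], seq.codes[j]])


def can_pair(seq: RnaSequence, i: int, j: int, params: EnergyParams) -> bool:
    """True iff (S_i, S_j) is a Watson-Crick or wobble pair and j-i > m."""
    return j - i > params.m and pair_type(seq, i, j) != 0


def au_penalty(seq: RnaSequence, i: int, j: int, params: EnergyParams) -> Energy:
    """Terminal AU/GU penalty of a helix closed by i.j, applied where the
    helix meets the exterior loop or a multiloop."""
    return params.term_au if pair_type(seq, i, j) > 2 else 0


def hairpin_energy(seq: RnaSequence, i: int, j: int,
                   params: EnergyParams) -> Energy:
    """H(i,j): the free energy of the hairpin loop closed by i.j."""
    return int(hairpin_energy_kernel(seq.codes, i, j, params.tables()))


def internal_energy(seq: RnaSequence, i: int, j: int, p: int, q: int,
                    params: EnergyParams) -> Energy:
    """I(i,j,p,q): the internal loop closed by i.j with inner pair p.q."""
    if not (i < p < q < j):
        raise ValueError(f"need i < p < q < j, got {(i, p, q, j)}")
    return int(internal_energy_kernel(seq.codes, i, j, p, q, params.tables()))


def energy_of_structure(seq: RnaSequence, structure: SecondaryStructure,
                        params: EnergyParams) -> Energy:
    """Loop-sum free energy E(R) of a structure.

    The structure decomposes uniquely into loops; hairpins contribute H,
    internal loops I, multiloops a + b*(branches + 1) + c*unpaired plus
    terminal penalties for the closing and all branch helices, and
    exterior-loop branches contribute their terminal penalties (unpaired
    exterior bases are free).
    """
    structure.validate(seq, params)
    total = 0
    for i, j in structure.children():  # exterior branches
        total += au_penalty(seq, i, j, params)
    stack: List[Tuple[int, int]] = list(structure.children())
    while stack:
        i, j = stack.pop()
        inner = structure.children(i, j)
        stack.extend(inner)
        if not inner:
            e = hairpin_energy(seq, i, j, params)
        elif len(inner) == 1:
            (p, q), = inner
            e = internal_energy(seq, i, j, p, q, params)
        else:
            unpaired = (j - i - 1) - sum(q - p + 1 for p, q in inner)
            e = (params.ml_a + params.ml_b * (len(inner) + 1)
                 + params.ml_c * unpaired
                 + au_penalty(seq, i, j, params)
                 + sum(au_penalty(seq, p, q, params) for p, q in inner))
        if e >= INF:
            return INF
        total += e
    return total
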