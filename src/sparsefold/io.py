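"""Sequence input (FASTA or plain text) and fold output.

Output follows the two-line convention of standard MFE folders: the
sequence, then the dot-bracket structure followed by the energy in
kcal/mol with two decimals in parentheses.  With stats enabled, a third
tab-separated line reports the sparsification counters: n, the number of
candidates Z, and the final / maximum / avoided / GC-removed trace-arrow
counts.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Iterator, Optional, TextIO, Tuple

from Bio import SeqIO

from .energy import RnaSequence, format_energy
from .sparse import SparseStats
from .structure import SecondaryStructure

__all__ = ["FoldRecord", "read_sequences", "write_fold", "InputError"]


class InputError(ValueError):
    """Unreadable or illegal sequence input."""


@dataclass
class FoldRecord:
    id: str
    sequence: RnaSequence
    structure: SecondaryStructure
    mfe: int  # 0.01 kcal/mol
    stats: Optional[SparseStats] = None


def read_sequences(stream: TextIO, fmt: str = "auto",
                   strict: bool = True) -> Iterator[Tuple[str, RnaSequence]]:
    """Yield (id, sequence) records from FASTA or one-per-line text.

    `fmt="auto"` sniffs FASTA from a leading '>'.  T is normalized to U
    and case is ignored.  Records with other letters raise `InputError`
    (strict) or are skipped with the position reported to stderr
    (lenient).
    """
    text = stream.read()
    if fmt == "auto":
        fmt = "fasta" if text.lstrip().startswith(">") else "plain"
    if fmt == "fasta":
        entries = [(rec.id, str(rec.seq), None)
                   for rec in SeqIO.parse(_io.StringIO(text), "fasta")]
        if not entries and text.strip():
            raise InputError("input looks like FASTA but has no records")
    elif fmt == "plain":
        entries = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if line:
                entries.append((f"seq{len(entries) + 1}", line, lineno))
    else:
        raise InputError(f"unknown input format {fmt!r}")
    for rec_id, raw, lineno in entries:
        try:
            yield rec_id, RnaSequence(raw, strict=True)
        except ValueError as exc:
            where = f"record {rec_id!r}"
            if lineno is not None:
                where += f" (line {lineno})"
            if strict:
                raise InputError(f"{where}: {exc}") from exc
            import sys

            print(f"skipping {where}: {exc}", file=sys.stderr)


def write_fold(record: FoldRecord, with_stats: bool = False) -> str:
    """Render a fold record as two output lines (plus a stats line)."""
    lines = [
        record.sequence.residues,
        f"{record.structure.to_dotbracket()} ({format_energy(record.mfe)})",
    ]
    if with_stats and record.stats is not None:
        s = record.stats
        lines.append("\t".join(str(x) for x in (
            record.sequence.n, s.Z, s.arrows_final,
            s.arrows_max_simultaneous, s.arrows_avoided,
            s.arrows_gc_removed,
        )))
    return "\n".join(lines) + "\n"


def parse_fold(text: str) -> Tuple[str, str, int]:
    """Inverse of `write_fold`'s first two lines: (sequence, dot-bracket,
    energy in 0.01 kcal/mol)."""
    lines = text.strip().splitlines()
    seq = lines[0].strip()
    struct_part, _, e_part = lines[1].rpartition(" ")
    if not (e_part.startswith("(") and e_part.endswith(")")):
        raise InputError(f"malformed fold line: {lines[1]!r}")
    energy = round(float(e_part[1:-1]) * 100)
    return seq, struct_part.strip(), int(energy)
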