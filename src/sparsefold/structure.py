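"""Pseudoknot-free secondary structures as pair sets / dot-bracket strings."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple


class StructureError(ValueError):
    """Raised when a pair set violates a secondary-structure invariant."""


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs over a sequence of length n.

    Pairs are 1-based ``(i, j)`` tuples with ``i < j``.  Each position may
    occur in at most one pair and no two pairs may cross
    (``i < i' < j < j'`` is forbidden).
    """

    n: int
    pairs: FrozenSet[Tuple[int, int]]

    def __init__(self, n: int, pairs: Iterable[Tuple[int, int]] = ()):
        object.__setattr__(self, "n", int(n))
        object.__setattr__(
            self, "pairs", frozenset((int(i), int(j)) for i, j in pairs)
        )
        self._check_wellformed()

    # -- construction / rendering -------------------------------------

    @classmethod
    def from_dotbracket(cls, db: str) -> "SecondaryStructure":
        pairs = []
        stack: List[int] = []
        for pos, ch in enumerate(db, start=1):
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                if not stack:
                    raise StructureError(
                        f"unbalanced ')' at position {pos} in {db!r}"
                    )
                pairs.append((stack.pop(), pos))
            elif ch != ".":
                raise StructureError(f"illegal character {ch!r} at position {pos}")
        if stack:
            raise StructureError(f"unbalanced '(' at position {stack[-1]} in {db!r}")
        return cls(len(db), pairs)

    def to_dotbracket(self) -> str:
        out = ["."] * self.n
        for i, j in self.pairs:
            out[i - 1] = "("
            out[j - 1] = ")"
        return "".join(out)

    # -- invariants ----------------------------------------------------

    def _check_wellformed(self) -> None:
        seen: Dict[int, Tuple[int, int]] = {}
        for i, j in self.pairs:
            if not (1 <= i < j <= self.n):
                raise StructureError(f"pair {(i, j)} out of range for n={self.n}")
            for x in (i, j):
                if x in seen:
                    raise StructureError(
                        f"position {x} occurs in both {seen[x]} and {(i, j)}"
                    )
                seen[x] = (i, j)
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for b in range(a + 1, len(ordered)):
                k, l = ordered[b]
                if k > j:
                    break
                if i < k < j < l:
                    raise StructureError(
                        f"crossing pairs {(i, j)} and {(k, l)} (pseudoknot)"
                    )

    def validate(self, seq, params) -> None:
        """Check sequence-dependent invariants: complementarity and the
        minimum hairpin loop size ``j - i > m``."""
        from .energy import can_pair

        if seq.n != self.n:
            raise StructureError(
                f"structure length {self.n} != sequence length {seq.n}"
            )
        for i, j in sorted(self.pairs):
            if not can_pair(seq, i, j, params):
                raise StructureError(
                    f"pair {(i, j)} is not a legal base pair of {seq.residues!r}"
                )

    # -- traversal helpers ---------------------------------------------

    def pair_map(self) -> Dict[int, int]:
        pm: Dict[int, int] = {}
        for i, j in self.pairs:
            pm[i] = j
            pm[j] = i
        return pm

    def children(self, i: Optional[int] = None, j: Optional[int] = None
                 ) -> List[Tuple[int, int]]:
        """Pairs immediately nested inside (i, j); with no arguments, the
        exterior-loop branches."""
        lo = 1 if i is None else i + 1
        hi = self.n if j is None else j - 1
        pm = self.pair_map()
        out = []
        pos = lo
        while pos <= hi:
            partner = pm.get(pos)
            if partner is not None and partner > pos:
                out.append((pos, partner))
                pos = partner + 1
            else:
                pos += 1
        return out

    def __len__(self) -> int:
        return len(self.pairs)

    def __str__(self) -> str:
        return self.to_dotbracket()
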