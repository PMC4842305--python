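"""Trace arrows with reference-counting garbage collection.

During the sparse forward pass, an arrow records the optimal inner base
pair of a closed entry V(i,j) whenever that inner pair is not a candidate
(candidate inner pairs are reconstructed from the candidate lists, so
their arrows are avoided).  Arrows form an acyclic graph — targets always
lie in strictly larger rows — so inaccessible arrows can be reclaimed by
reference counting: once row i is complete, an arrow sourced in row
i+M+1 can only be reached again through a candidate source or through
another live arrow, and is removed when neither holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

Coord = Tuple[int, int]


@dataclass
class TraceArrow:
    source: Coord
    target: Coord
    target_energy: int  # V(target), kept for consistency checking
    ref_count: int = 0  # number of live arrows whose target is `source`


class DuplicateArrowError(RuntimeError):
    """Two arrows from one source indicate a forward-pass bug."""


@dataclass
class TraceArrowStore:
    """Associative store of trace arrows keyed by source coordinate."""

    _arrows: Dict[Coord, TraceArrow] = field(default_factory=dict)
    _by_row: Dict[int, List[Coord]] = field(default_factory=dict)
    registered: int = 0
    avoided: int = 0
    removed: int = 0
    max_simultaneous: int = 0

    def register(self, source: Coord, target: Coord, target_energy: int,
                 target_is_candidate: bool) -> None:
        """Record the optimal inner pair of a V entry.

        Arrows to candidates are not stored (the candidate list suffices
        to reconstruct them); only the `avoided` counter is bumped.
        """
        if target_is_candidate:
            self.avoided += 1
            return
        if source in self._arrows:
            raise DuplicateArrowError(f"duplicate arrow from {source}")
        arrow = TraceArrow(source, target, target_energy)
        self._arrows[source] = arrow
        self._by_row.setdefault(source[0], []).append(source)
        self.registered += 1
        ta = self._arrows.get(target)
        if ta is not None:
            ta.ref_count += 1
        if len(self._arrows) > self.max_simultaneous:
            self.max_simultaneous = len(self._arrows)

    def lookup(self, source: Coord) -> Optional[TraceArrow]:
        return self._arrows.get(source)

    def gc_row(self, row: int, is_candidate: Callable[[Coord], bool]) -> int:
        """Sweep arrows sourced in `row` after the forward pass has moved
        M+1 rows past it.

        Arrows from non-candidate sources with reference count zero are
        inaccessible; removing one decrements the count at its target,
        which may cascade into rows swept earlier.  Returns the number of
        arrows removed (including cascaded removals).
        """
        removed_before = self.removed
        for source in self._by_row.get(row, []):
            arrow = self._arrows.get(source)
            if arrow is None or is_candidate(source) or arrow.ref_count > 0:
                continue
            self._remove_cascade(source, is_candidate)
        return self.removed - removed_before

    def _remove_cascade(self, source: Coord,
                        is_candidate: Callable[[Coord], bool]) -> None:
        arrow = self._arrows.pop(source)
        self.removed += 1
        ta = self._arrows.get(arrow.target)
        if ta is not None:
            ta.ref_count -= 1
            # the target's row was swept earlier (targets lie in larger
            # rows), so a zero count now means it just became inaccessible
            if ta.ref_count == 0 and not is_candidate(arrow.target):
                self._remove_cascade(arrow.target, is_candidate)

    # -- inspection ----------------------------------------------------

    def __len__(self) -> int:
        return len(self._arrows)

    def __contains__(self, source: Coord) -> bool:
        return source in self._arrows

    def items(self):
        return self._arrows.items()

    @property
    def final(self) -> int:
        return len(self._arrows)
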