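"""Deterministic generators for test inputs.

Random sequences with a target GC content, di-nucleotide shuffles (the
standard Eulerian-path construction, which preserves the exact multiset
of overlapping di-nucleotides and hence the mono-nucleotide composition
and the first and last base), and the hairpin-stacking sequence family
G C^k A^4 G^(k+1) C whose minimum-free-energy inner pairs are not
candidates — the family that makes stored trace arrows indispensable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np

from .energy import RnaSequence

__all__ = [
    "GeneratorConfig",
    "random_sequence",
    "dinucleotide_shuffle",
    "s_k_sequence",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Identical configs always generate identical sequences."""

    n: int
    gc_fraction: float = 0.5
    seed: int = 0


def random_sequence(config: GeneratorConfig) -> RnaSequence:
    """An i.i.d. random sequence with expected GC content `gc_fraction`."""
    if config.n < 1:
        raise ValueError(f"sequence length must be >= 1, got {config.n}")
    if not 0.0 <= config.gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    letters = rng.choice(np.array(list("ACGU")), size=config.n, p=probs)
    return RnaSequence("".join(letters))


def dinucleotide_shuffle(seq: RnaSequence, seed: int = 0) -> RnaSequence:
    """A uniform di-nucleotide-preserving shuffle (Eulerian-path method).

    The sequence is viewed as an Eulerian path in the multigraph whose
    edges are its overlapping di-nucleotides.  A random "last edge" out
    of every vertex except the terminal base is drawn until those edges
    form an arborescence toward the terminal base; the remaining edges
    are permuted uniformly and the path is walked from the first base.
    """
    s = seq.residues
    n = len(s)
    if n < 2:
        raise ValueError("shuffle needs a sequence of length >= 2")
    rng = np.random.default_rng(seed)
    edges: Dict[str, List[str]] = {}
    for x, y in zip(s, s[1:]):
        edges.setdefault(x, []).append(y)
    vertices = sorted(edges)
    last = s[-1]

    def arborescence_ok(last_edge: Dict[str, str]) -> bool:
        # every non-terminal vertex must reach `last` via last edges
        for v in vertices:
            if v == last:
                continue
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    return False
                seen.add(cur)
                cur = last_edge[cur]
        return True

    while True:
        last_edge = {
            v: edges[v][rng.integers(len(edges[v]))]
            for v in vertices if v != last
        }
        if arborescence_ok(last_edge):
            break

    shuffled: Dict[str, List[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        shuffled[v] = rest

    out = [s[0]]
    cur = s[0]
    counts = {v: 0 for v in vertices}
    for _ in range(n - 1):
        nxt = shuffled[cur][counts[cur]]
        counts[cur] += 1
        out.append(nxt)
        cur = nxt
    return RnaSequence("".join(out))


def s_k_sequence(k: int) -> RnaSequence:
    """The sequence G C^k A^4 G^(k+1) C of length 2k + 7.

    For every k >= 1 its single minimum-free-energy helix stacks pairs
    whose inner intervals are non-candidates, so trace arrows are
    required for fold reconstruction at any size.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return RnaSequence("G" + "C" * k + "AAAA" + "G" * (k + 1) + "C")
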