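# sparsefold

Space-efficient sparsified minimum-free-energy (MFE) prediction of
pseudoknot-free RNA secondary structure in the Turner nearest-neighbor
energy model, with no dangling-end terms (the `-d0` convention).

Secondary structure prediction by free-energy minimization is the
work-horse of non-coding RNA analysis. The classical Zuker dynamic
program needs O(n³) time and O(n²) space; for long RNAs the quadratic
memory, not the time, is the binding constraint — and the traceback is
the hard part to make space-efficient, because the optimal inner base
pair of an internal loop need not be recomputable from the surviving
state. `sparsefold` is for anyone who wants MFE folds (identical to
`RNAfold -d0`) with a linear-plus-sparse memory footprint, or who wants
a compact, fully tested Python reference for sparsified folding with
fold reconstruction.

## Method

Energies follow the loop-based model: `E(R) = Σ_loops E^loop`, with
hairpin terms `H(i,j)`, internal-loop terms `I(i,j,p,q)` (stacks and
bulges included, total unpaired size capped at `M = 30`), and affine
multiloops `a + b·p + c·q`. The recursions are the standard
`W / V / WM / WM²` system, where `WM²` holds multiloop fragments with at
least two branches so that `V`'s multiloop case is
`WM²(i+1,j−1) + a + b`.

Sparsification rests on the triangle inequality: an interval `[k,j]` is
a **candidate** iff its closed energy strictly beats every decomposition
(`V(k,j) + au < Ŵᵖ(k,j)` for `W`, `V(k,j) + b + au < ŴMᵖ(k,j)` for
`WM`, where `au` is the terminal AU/GU penalty of the closing pair).
Split minimizations run over candidates only; everything else is
*partitionable* and recomputable on demand. The forward sweep keeps one
rotating window of `M+2` rows of `V`, four length-`n` rows, the
candidate lists (`Z` entries) and **trace arrows**: whenever `V(i,j)`'s
winning case is an internal loop whose inner pair is *not* a candidate,
an arrow `(i,j) → (p,q)` is stored (arrows to candidates are avoided —
they are reconstructed by minimizing `I + V` over candidate entries).
Arrows that can no longer be reached by any future traceback are
reclaimed by reference-counting garbage collection over the acyclic
arrow graph. Time is O(n² + nZ); the working set is Θ(n + Z + T), with
`T` the arrow high-water mark.

The traceback reconstructs the fold from the MFE, the candidates and
the arrows alone, recomputing `W`/`WM`/`WM²` rows on demand; following
an arrow recomputes the inner energy via `V(p,q) = V(i,j) − I(i,j,p,q)`
and checks it against the stored value. A dense O(n²)-space folder with
full matrices is included as the correctness oracle, along with an
exhaustive structure enumerator for tiny inputs.

## Worked example

The 11-mer `GCCAAAAGGGC` is the smallest member of the family
`G C^k A^4 G^(k+1) C` whose optimal inner pairs are not candidates:

```
$ echo GCCAAAAGGGC | sparsefold --stats
GCCAAAAGGGC
(((.....))) (-2.40)
11      4       2       2       1       0
```

The fold is the triple helix `(1,11)(2,10)(3,9)`: two stacks
(−3.4 and −3.3 kcal/mol) against the hairpin `H(3,9) = 4.3`, total
−2.40 kcal/mol. The stats line reports `n`, the number of candidates
`Z = 4`, and final / maximum / avoided / GC-removed trace-arrow counts
(2, 2, 1, 0). The interval `[3,9]` is *not* a candidate — the best
non-empty structure of that region is the hairpin closed by `(3,8)` at
4.1 kcal/mol, cheaper than closing with `(3,9)` at 4.3 — yet `V(2,10)`
is optimally the internal loop with inner pair `(3,9)`, so a trace
arrow `(2,10) → (3,9)` is required; run with arrows withheld, the
traceback fails by construction. That is exactly why candidate lists
alone cannot reconstruct loop-based MFE folds.

Other entry points: `--reference` (dense oracle), `--check` (fold both
ways and verify agreement), `--no-gc` (disable arrow garbage
collection; structure, energy and all counters except the arrow
high-water mark are unchanged), `--random N --seed S` (fold a generated
sequence).

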