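# Methods

## Energy model

`sparsefold` evaluates the Turner 2004 nearest-neighbor model with
dangling-end contributions disabled, reproducing the `-d0` conventions
of standard folders exactly:

- **Hairpins** `H(i,j)`: size-dependent initiation (tabulated to size
  30, logarithmic extrapolation `init(30) + ⌊lxc·ln(u/30)⌋` beyond,
  `lxc = 107.856` in 0.01 kcal/mol), terminal mismatch for loop size
  ≥ 4, tabulated special tri-/tetra-/hexaloops (tetra- and hexaloop
  hits replace the whole term; triloop misses add the AU/GU closing
  penalty instead of a mismatch).
- **Internal loops** `I(i,j,p,q)`: stacking for zero unpaired bases;
  bulges (size 1 keeps the stack term, larger ones pay closing
  penalties); dedicated 1×1 / 2×1 / 2×2 tables; the 1×n and 2×3
  special cases; otherwise generic initiation plus Ninio asymmetry
  (per-nucleotide 0.6 kcal/mol, capped at 3.0) and internal mismatches.
  Total unpaired size is capped at `M`.
- **Multiloops**: affine `a + b·branches + c·unpaired` with
  `a = 9.3`, `b = −0.9`, `c = 0` kcal/mol; the closing pair counts as a
  branch.
- **Helix ends**: terminal AU/GU penalty (0.5 kcal/mol) wherever a
  helix meets the exterior loop or a multiloop; inside hairpin and
  internal loops the penalty is baked into the mismatch tables.

Energies are exact integers in 0.01 kcal/mol — the parameter files'
native unit, kept unscaled so that the logarithmic extrapolation
truncates identically to the reference C implementation; `INF`
(10⁷) marks infeasibility and absorbs addition. Parameters are parsed
from the Vienna 2.x text dialect; enthalpy and dangling sections are
recognized and skipped, unknown sections produce a warning. Defaults
`m = 3` (minimum hairpin loop) and `M = 30` are the universal
conventions and are required to reproduce the worked-example energies.

## Recursions and sparsification

The dense reference uses the `W / V / WM / WM²` system. `WM` holds
non-empty multiloop fragments where each branch pays `b` plus its
terminal penalty; `WM²` requires at least two branches; `V`'s multiloop
case is `WM²(i+1,j−1) + a + b + au`. Two auxiliary matrices, `WP` and
`WMP`, hold the decomposition-only minima of `W` and `WM`; candidacy is
`V + au < WP` or `V + b + au < WMP`. Both recursion systems use a
single-branch split form (`prefix + V(k,j) + penalties` with the branch
rightmost), which makes the dense rows cell-by-cell comparable to the
sparse sweep — a property the test suite asserts directly.

The sparse sweep (rows n → 1, columns left to right) keeps: the current
rows of `W`, `WM`, `WM²`; the `WM²` row of `i+1`; and the last `M+2`
rows of `V` in a rotating buffer. One merged candidate list per column
serves both recursions: an entry is stored when either criterion fires.
Every listed value is the energy of a feasible closed structure, so
surplus entries can never push a minimum below the true optimum, while
all genuine candidates are present; correctness is inherited from the
triangle inequality. Candidate entries carry `V(k,j)` together with the
O(1) terminal penalty of `k.j`, so all split minimizations remain local
to the list.

`WM`'s leading-unpaired case is folded into the candidate minimization
as `(k−i)·c + V(k,j) + b + au`, which removes the need for arrows out
of the `WM(i+1,j)+c` case.

## Trace arrows and garbage collection

During the sweep, `V(i,j)`'s winning case is resolved with a fixed
tie-break (hairpin; internal loop with smallest `p`, then smallest `q`;
multiloop — later cases must win strictly). If the winner is an
internal loop into a candidate, only a counter is bumped (`avoided`);
into a non-candidate, an arrow `(i,j) → (p,q)` is stored together with
`V(p,q)`. Storing the target energy is redundant — the traceback
recomputes it as `V(i,j) − I(i,j,p,q)` — but the equality of the two is
asserted on every arrow followed, which converts energy-model or
recursion bugs into hard failures instead of silent mis-folds.

Arrows always point to strictly larger rows, so the arrow graph is
acyclic and reference counting suffices for garbage collection: after
row `i` completes, arrows sourced in row `i+M+1` whose source is not a
candidate and whose reference count is zero are removed; each removal
decrements its target's count and cascades. Rows `1..M+1` are never
swept (they remain in the final window). Row `M+2` is swept after the
final row; at that point no new referencing arrows can appear, so the
sweep cannot strand a reachable entry. A brute-force accessibility
closure over the full (GC-off) arrow graph confirms that GC keeps
exactly the arrows whose sources remain accessible.

## Traceback

Reconstruction uses only the MFE, candidate lists and arrows. Rows of
`W`/`WM`/`WM²` are recomputed on demand, left to right, from candidate
entries with `k ≥ i` (the `k = i` term reproduces the closed case,
which can only win at a candidate); a bounded row cache keeps the two
most recent rows per kind, so traceback memory stays O(n + Z + T).
`V` entries resolve in the order hairpin → stored arrow → candidate
internal-loop scan → multiloop. The arrow is consulted before the
candidate scan because it records the forward pass's actual winner;
with that order, and with the dense traceback restricted to the same
candidate-split discipline, the two tracebacks produce bit-identical
structures, not merely equal energies — asserted over the whole test
corpus. The multiloop case is taken only when no other case reproduces
the known energy; if nothing matches, a `TraceInconsistencyError` is
raised. Withholding arrows (a fault-injection switch on the forward
pass) makes the traceback fail on the family `G C^k A^4 G^(k+1) C` at
every size — candidates alone cannot reconstruct loop-based folds.

## Synthetic inputs

The generator module provides (i) seeded i.i.d. sequences with a target
GC fraction, (ii) di-nucleotide shuffles by the Eulerian-path
construction, preserving the exact di-nucleotide multiset and the first
and last base, and (iii) the family `G C^k A^4 G^(k+1) C` (length
2k+7), whose MFE helix stacks pairs with non-candidate inner intervals.
Random i.i.d. sequences differ from natural structured RNAs — they are
less repetitive and fold with less stable, shallower structures — so
passing equivalence tests on them demonstrates algorithmic correctness
across input statistics, not biological accuracy of the energy model;
cross-validation of energies and MFEs against an independent
implementation of the same model covers the latter.

## Numerical and testing choices

- All arithmetic is exact integer arithmetic; no floating point enters
  except the logarithmic size extrapolation, whose truncation is
  matched to the reference implementation.
- Tie-breaks are fixed everywhere (case order; smallest `p`, then `q`;
  ascending split position `k`), making candidates, arrows, counters
  and structures bit-reproducible run to run.
- The equivalence corpus folds 201 seeded random sequences with
  n ∈ [10, 150] at GC contents 0.3 / 0.5 / 0.7, plus the family
  members k = 1..20, each with the dense reference and with the sparse
  pass with GC on and off; the sizes keep the full suite at about one
  to two minutes after JIT compilation while covering hundreds of
  multiloop-bearing folds.
- Exhaustive enumeration (n ≤ 16 in tests, hard cap 18) provides a
  model-independent MFE oracle; an independently written counting
  recursion checks the enumerator itself.
- The hot kernels (loop energies, dense fill, the per-cell `V`
  evaluation of the sparse sweep) are numba-compiled; the sparse
  control flow, candidate lists and arrow store remain plain Python
  data structures, which is where the space accounting is asserted.

## Known limitations

- No dangling ends, coaxial stacking, temperature rescaling,
  G-quadruplexes, lonely-pair suppression, or constraint folding.
- Single optimal structure only (deterministic tie-break); no
  suboptimals, partition function or pair probabilities.
- The dense reference keeps six (n+2)² matrices — it is an oracle, not
  a production path; the sparse path is the tool.
- `W(i,j)` admits the empty structure (value 0); the minimum over
  non-empty structures of a region, when needed, is obtained by
  enumeration or from `WM − b`.
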